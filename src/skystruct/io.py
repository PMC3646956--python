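"""File formats and plotting glue: Newick genealogies, FASTA/NEXUS
alignments, skyline summary CSVs and run manifests.

User-facing time is written in years (skyline plots conventionally use kya);
generations appear only internally. Branch lengths in Newick output default
to years via the model generation time.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalescent import Genealogy
from .scenarios import DEFAULT_GENERATION_TIME
from .seqsim import Alignment
from .skyline import SkylinePosterior


def tip_labels(genealogy: Genealogy) -> list[str]:
    """Stable tip labels encoding the deme: ``deme<i>_<k>``."""
    labels = []
    seen: dict[int, int] = {}
    for deme in genealogy.tip_demes:
        k = seen.get(int(deme), 0)
        seen[int(deme)] = k + 1
        labels.append(f"deme{int(deme)}_{k}")
    return labels


def write_newick(
    genealogy: Genealogy,
    unit: str = "years",
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> str:
    """Serialise a genealogy as a Newick string with branch lengths in
    ``years`` (generations x generation time) or ``generations``."""
    if unit not in ("years", "generations"):
        raise ValueError("unit must be 'years' or 'generations'")
    scale = generation_time if unit == "years" else 1.0
    labels = tip_labels(genealogy)
    kids = genealogy.children()
    t = genealogy.node_times

    def fmt(node: int) -> str:
        if node < genealogy.n_tips:
            return labels[node]
        parts = ",".join(
            f"{fmt(c)}:{(t[node] - t[c]) * scale:.10g}" for c in kids[node]
        )
        return f"({parts})"

    return fmt(genealogy.root) + ";"


def genealogy_from_newick(text: str, generation_time: float = DEFAULT_GENERATION_TIME,
                          unit: str = "years") -> Genealogy:
    """Parse a Newick genealogy written by :func:`write_newick`.

    Tip labels must follow the ``deme<i>_<k>`` convention; tips are assumed
    contemporaneous and node depths are recovered from branch lengths.
    """
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick")
    tree.calc_node_ages(ultrametricity_precision=False, is_force_max_age=True)
    scale = 1.0 / generation_time if unit == "years" else 1.0
    tips = [leaf for leaf in tree.leaf_node_iter()]
    n = len(tips)
    order: dict[int, int] = {}
    tip_demes = np.zeros(n, dtype=int)
    for ix, leaf in enumerate(tips):
        label = leaf.taxon.label.replace(" ", "_")
        if not label.startswith("deme"):
            raise ValueError(f"tip label {label!r} does not encode a deme")
        tip_demes[ix] = int(label[4:].split("_")[0])
        order[id(leaf)] = ix
    internals = sorted(
        (nd for nd in tree.preorder_node_iter() if not nd.is_leaf()),
        key=lambda nd: nd.age,
    )
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_times = np.zeros(2 * n - 1)
    for ix, nd in enumerate(internals):
        order[id(nd)] = n + ix
        node_times[n + ix] = nd.age * scale
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            parent[order[id(nd)]] = order[id(nd.parent_node)]
    return Genealogy(n_tips=n, tip_demes=tip_demes, parent=parent, node_times=node_times)


# ---------------------------------------------------------------------------
# Alignments

def write_fasta(alignment: Alignment, path) -> None:
    if alignment.n == 0:
        raise ValueError("cannot write an empty alignment")
    names = _seq_names(alignment)
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(names, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, tip_demes=None) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    if tip_demes is None:
        tip_demes = [int(r.id[4:].split("_")[0]) if r.id.startswith("deme") else 0
                     for r in records]
    return Alignment.from_sequences([str(r.seq) for r in records], tip_demes)


def write_nexus(alignment: Alignment, path) -> None:
    if alignment.n == 0:
        raise ValueError("cannot write an empty alignment")
    names = _seq_names(alignment)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={alignment.n} NCHAR={alignment.L};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for name, seq in zip(names, alignment.sequences):
            fh.write(f"    {name}  {seq}\n")
        fh.write("  ;\nEND;\n")


def write_deme_table(alignment: Alignment, path) -> None:
    """Companion CSV mapping each sequence name to its deme."""
    pd.DataFrame({"tip": _seq_names(alignment), "deme": alignment.tip_demes}).to_csv(
        path, index=False
    )


def _seq_names(alignment: Alignment) -> list[str]:
    seen: dict[int, int] = {}
    names = []
    for deme in alignment.tip_demes:
        k = seen.get(int(deme), 0)
        seen[int(deme)] = k + 1
        names.append(f"deme{int(deme)}_{k}")
    return names


# ---------------------------------------------------------------------------
# Skyline summaries, manifests, plots

def write_skyline_csv(
    posterior: SkylinePosterior,
    path,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> None:
    """Posterior summary as (time_years, median, hpd_lo, hpd_hi)."""
    pd.DataFrame(
        {
            "time_years": posterior.grid * generation_time,
            "median": posterior.median_curve,
            "hpd_lo": posterior.hpd_lo,
            "hpd_hi": posterior.hpd_hi,
        }
    ).to_csv(path, index=False)


def read_skyline_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_psc_csv(posterior: SkylinePosterior, path) -> None:
    pd.DataFrame({"psc": posterior.psc_samples}).to_csv(path, index=False)


@dataclasses.dataclass
class RunManifest:
    command: str
    config: str
    seed: int
    outputs: list[str]
    version: str = "0.1.0"
    timestamp: str = ""

    def write(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["timestamp"] = doc["timestamp"] or datetime.datetime.now().isoformat(
            timespec="seconds"
        )
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def plot_skyline(posterior: SkylinePosterior, model=None, ax=None,
                 generation_time: float = DEFAULT_GENERATION_TIME):
    """Median curve with HPD band (time in kya), census trajectory overlaid."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .coalescent import census_size

    if ax is None:
        _, ax = plt.subplots()
    kya = posterior.grid * generation_time / 1000.0
    ax.fill_between(kya, posterior.hpd_lo, posterior.hpd_hi, alpha=0.3, label="95% HPD")
    ax.plot(kya, posterior.median_curve, label="posterior median")
    if model is not None:
        truth = [census_size(model, t) for t in posterior.grid]
        ax.plot(kya, truth, "k-", lw=2, label="simulated size")
    ax.set_xlabel("time (kya)")
    ax.set_ylabel("female effective size")
    ax.set_yscale("log")
    ax.legend()
    return ax
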