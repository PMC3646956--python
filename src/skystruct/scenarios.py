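"""Structured-population scenarios: demes, migration topology, demographic events
and sampling schemes.

A scenario is a :class:`StructuredModel` — per-deme female counts (haploid mtDNA
copies), a backward migration matrix, and an ordered list of demographic events —
plus a :class:`SamplingScheme` saying how many lineages are drawn from each deme.
Three canonical sampling regimes are supported: *local* (all samples from one
deme), *pooled* (equal samples from several demes) and *scattered* (one sample
per deme).
"""
from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import yaml

#: Default generation time used to convert event times in years to generations.
DEFAULT_GENERATION_TIME = 7.0

EVENT_KINDS = ("exponential_change", "subdivision")
SAMPLING_KINDS = ("local", "pooled", "scattered")


class InvalidModelError(ValueError):
    """A scenario violates a structural invariant."""


@dataclasses.dataclass(frozen=True)
class DemographicEvent:
    """A change in the demographic regime at ``time_years`` before present.

    ``exponential_change`` with factor ``f`` means every deme size equals
    ``f`` times its value at the event's more recent boundary (the present or
    the next more recent event), interpolated exponentially across the phase.
    ``subdivision`` means that, backwards in time, all demes merge into one
    panmictic pool whose size is the sum of the deme sizes (structure is not
    permanent, it arose at the event time).
    """

    time_years: float
    kind: str
    factor: float = 1.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise InvalidModelError(f"unknown event kind {self.kind!r}")
        if not self.time_years > 0:
            raise InvalidModelError("event time must be positive")
        if not self.factor > 0:
            raise InvalidModelError("event factor must be positive")


def decline(time_years: float, fold: float = 10.0, note: str = "") -> DemographicEvent:
    """Forward in time: sizes decline ``fold``-fold from ``time_years`` to the present."""
    return DemographicEvent(time_years, "exponential_change", factor=fold, note=note)


def expansion(time_years: float, fold: float = 10.0, note: str = "") -> DemographicEvent:
    """Forward in time: sizes grow ``fold``-fold from ``time_years`` to the present."""
    return DemographicEvent(time_years, "exponential_change", factor=1.0 / fold, note=note)


def subdivision(time_years: float, note: str = "") -> DemographicEvent:
    return DemographicEvent(time_years, "subdivision", note=note)


@dataclasses.dataclass(frozen=True)
class StructuredModel:
    """Deme sizes, backward migration rates and demographic events.

    ``migration[i, j]`` is the per-lineage, per-generation rate at which a
    lineage currently in deme ``i`` traces back to deme ``j``.
    """

    deme_sizes: np.ndarray
    migration: np.ndarray
    events: tuple[DemographicEvent, ...] = ()
    label: str = ""
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        sizes = np.asarray(self.deme_sizes, dtype=float)
        mig = np.asarray(self.migration, dtype=float)
        object.__setattr__(self, "deme_sizes", sizes)
        object.__setattr__(self, "migration", mig)
        object.__setattr__(self, "events", tuple(self.events))
        d = sizes.shape[0]
        if mig.shape != (d, d):
            raise InvalidModelError("migration matrix shape does not match deme count")
        if np.any(sizes < 1):
            raise InvalidModelError("all deme sizes must be >= 1")
        if np.any(np.diag(mig) != 0):
            raise InvalidModelError("migration matrix must have a zero diagonal")
        if np.any(mig < 0):
            raise InvalidModelError("migration rates must be non-negative")
        times = [e.time_years for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidModelError("events must be sorted by strictly increasing time")
        if self.generation_time <= 0:
            raise InvalidModelError("generation time must be positive")

    @property
    def d(self) -> int:
        return int(self.deme_sizes.shape[0])


@dataclasses.dataclass(frozen=True)
class SamplingScheme:
    """How many lineages are sampled from each deme."""

    kind: str
    counts: Mapping[int, int]
    n_total: int

    def __post_init__(self) -> None:
        if self.kind not in SAMPLING_KINDS:
            raise InvalidModelError(f"unknown sampling kind {self.kind!r}")
        counts = {int(k): int(v) for k, v in self.counts.items() if v > 0}
        object.__setattr__(self, "counts", counts)
        if sum(counts.values()) != self.n_total:
            raise InvalidModelError("counts must sum to n_total")
        if self.kind == "local" and len(counts) != 1:
            raise InvalidModelError("local sampling draws from exactly one deme")
        if self.kind == "scattered" and any(v != 1 for v in counts.values()):
            raise InvalidModelError("scattered sampling draws one lineage per deme")


def build_island_model(
    d: int,
    deme_size: float,
    Nm: float,
    *,
    label: str = "",
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> StructuredModel:
    """Symmetric island model: ``d`` demes of ``deme_size`` females, each
    lineage migrating at total rate ``m = Nm / deme_size`` split equally
    across the other ``d - 1`` demes."""
    if d < 2:
        raise InvalidModelError("an island model needs at least 2 demes")
    if deme_size < 1:
        raise InvalidModelError("deme_size must be >= 1")
    if Nm < 0:
        raise InvalidModelError("Nm must be non-negative")
    m = Nm / deme_size
    mig = np.full((d, d), m / (d - 1))
    np.fill_diagonal(mig, 0.0)
    return StructuredModel(
        deme_sizes=np.full(d, float(deme_size)),
        migration=mig,
        label=label or f"island(d={d}, N={deme_size:g}, Nm={Nm:g})",
        generation_time=generation_time,
    )


def build_stepping_stone_model(
    d: int,
    deme_size: float,
    Nm: float,
    *,
    label: str = "",
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> StructuredModel:
    """One-dimensional circular stepping-stone model: each deme exchanges
    migrants only with its two ring neighbours, at rate ``m / 2`` each,
    with ``m = Nm / deme_size``."""
    if d < 3:
        raise InvalidModelError("a circular stepping-stone model needs at least 3 demes")
    if deme_size < 1:
        raise InvalidModelError("deme_size must be >= 1")
    if Nm < 0:
        raise InvalidModelError("Nm must be non-negative")
    m = Nm / deme_size
    mig = np.zeros((d, d))
    for i in range(d):
        mig[i, (i - 1) % d] = m / 2.0
        mig[i, (i + 1) % d] = m / 2.0
    return StructuredModel(
        deme_sizes=np.full(d, float(deme_size)),
        migration=mig,
        label=label or f"stepping_stone(d={d}, N={deme_size:g}, Nm={Nm:g})",
        generation_time=generation_time,
    )


def model_from_fst_matrix(
    fst,
    deme_size: float,
    *,
    label: str = "",
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> StructuredModel:
    """Data-informed model: invert a pairwise FST matrix to pairwise migrant
    numbers ``Nm_ij = (1/F_ij - 1) / 2`` (haploid island-model inversion) and
    divide by the deme size to get per-lineage rates."""
    values = np.asarray(getattr(fst, "values", fst), dtype=float)
    d = values.shape[0]
    if values.shape != (d, d) or d < 2:
        raise InvalidModelError("FST matrix must be square with at least 2 demes")
    if not np.allclose(values, values.T):
        raise InvalidModelError("FST matrix must be symmetric")
    off = ~np.eye(d, dtype=bool)
    if np.any(values[off] <= 0) or np.any(values[off] >= 1):
        raise InvalidModelError("pairwise FST values must lie strictly in (0, 1)")
    nm = np.zeros((d, d))
    nm[off] = (1.0 / values[off] - 1.0) / 2.0
    mig = nm / float(deme_size)
    np.fill_diagonal(mig, 0.0)
    return StructuredModel(
        deme_sizes=np.full(d, float(deme_size)),
        migration=mig,
        label=label or f"fst_informed(d={d}, N={deme_size:g})",
        generation_time=generation_time,
    )


def add_events(model: StructuredModel, events: Sequence[DemographicEvent]) -> StructuredModel:
    """Return a copy of ``model`` with ``events`` attached (sorted by time)."""
    merged = sorted([*model.events, *events], key=lambda e: e.time_years)
    times = [e.time_years for e in merged]
    if len(set(times)) != len(times):
        raise InvalidModelError("duplicate event times")
    return dataclasses.replace(model, events=tuple(merged))


def make_sampling_scheme(
    kind: str,
    model: StructuredModel,
    n_total: int,
    n_demes_used: int,
    rng: np.random.Generator | None = None,
) -> SamplingScheme:
    """Build a local / pooled / scattered sampling scheme over ``model``.

    When fewer demes than ``model.d`` are used they are chosen uniformly at
    random without replacement using ``rng``.
    """
    if kind not in SAMPLING_KINDS:
        raise InvalidModelError(f"unknown sampling kind {kind!r}")
    if n_demes_used > model.d:
        raise InvalidModelError("cannot use more demes than the model has")
    if n_total < 1 or n_demes_used < 1:
        raise InvalidModelError("n_total and n_demes_used must be positive")
    if kind == "local" and n_demes_used != 1:
        raise InvalidModelError("local sampling uses exactly one deme")
    if kind == "scattered" and n_total != n_demes_used:
        raise InvalidModelError("scattered sampling needs n_total == n_demes_used")
    if kind == "pooled" and n_total % n_demes_used != 0:
        raise InvalidModelError("pooled sampling needs n_demes_used to divide n_total")
    if n_demes_used < model.d:
        if rng is None:
            rng = np.random.default_rng()
        demes = sorted(rng.choice(model.d, size=n_demes_used, replace=False).tolist())
    else:
        demes = list(range(model.d))
    per = n_total // n_demes_used
    return SamplingScheme(kind=kind, counts={int(i): per for i in demes}, n_total=n_total)


# ---------------------------------------------------------------------------
# Scenario configuration files (YAML key-value documents, lossless round trip)

def scenario_to_dict(model: StructuredModel, scheme: SamplingScheme | None = None,
                     seed: int | None = None) -> dict:
    doc: dict = {
        "model": {
            "type": "matrix",
            "d": model.d,
            "deme_sizes": model.deme_sizes.tolist(),
            "migration": model.migration.tolist(),
            "label": model.label,
            "generation_time": model.generation_time,
        },
        "events": [
            {"time_years": e.time_years, "kind": e.kind, "factor": e.factor, "note": e.note}
            for e in model.events
        ],
    }
    if scheme is not None:
        doc["sampling"] = {
            "kind": scheme.kind,
            "n_total": scheme.n_total,
            "counts": {int(k): int(v) for k, v in scheme.counts.items()},
        }
    if seed is not None:
        doc["seed"] = int(seed)
    return doc


def scenario_from_dict(doc: dict) -> tuple[StructuredModel, SamplingScheme | None, int | None]:
    spec = doc["model"]
    kind = spec.get("type", "matrix")
    events = tuple(
        DemographicEvent(e["time_years"], e["kind"], e.get("factor", 1.0), e.get("note", ""))
        for e in doc.get("events", [])
    )
    common = dict(
        label=spec.get("label", ""),
        generation_time=spec.get("generation_time", DEFAULT_GENERATION_TIME),
    )
    if kind == "island":
        model = build_island_model(spec["d"], spec["deme_size"], spec["Nm"], **common)
    elif kind == "stepping_stone":
        model = build_stepping_stone_model(spec["d"], spec["deme_size"], spec["Nm"], **common)
    elif kind == "matrix":
        model = StructuredModel(
            deme_sizes=np.asarray(spec["deme_sizes"], dtype=float),
            migration=np.asarray(spec["migration"], dtype=float),
            **common,
        )
    else:
        raise InvalidModelError(f"unknown model type {kind!r}")
    if events:
        model = add_events(model, events)
    scheme = None
    if "sampling" in doc:
        s = doc["sampling"]
        counts = {int(k): int(v) for k, v in s["counts"].items()}
        scheme = SamplingScheme(kind=s["kind"], counts=counts, n_total=int(s["n_total"]))
    return model, scheme, doc.get("seed")


def save_scenario(path, model: StructuredModel, scheme: SamplingScheme | None = None,
                  seed: int | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(model, scheme, seed), fh, sort_keys=False)


def load_scenario(path) -> tuple[StructuredModel, SamplingScheme | None, int | None]:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
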