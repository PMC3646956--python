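"""Evaluation statistics for skyline inferences against the simulated truth:
coverage of the 95% HPD band, signed mean relative departure (MRD) of the
median curve, PSC false-positive rates, and the two-phase regression of PSC
on deme connectedness.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import FstMatrix, connectedness
from .skyline import SkylinePosterior


@dataclasses.dataclass(frozen=True)
class EvalRecord:
    """Per-replicate summary: the tidy-table analogue of a results-table row."""

    scenario: str
    sampling: str
    replicate: int
    coverage: float
    mrd: float
    psc_mean: float
    deme: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


def records_to_frame(records: Sequence[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def coverage(
    posterior: SkylinePosterior,
    truth: Callable[[np.ndarray], np.ndarray],
    grid: np.ndarray | None = None,
) -> float:
    """Fraction of grid points where the true size lies inside the 95% HPD."""
    if grid is None:
        grid = posterior.grid
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    true_sizes = np.asarray([truth(t) for t in grid], dtype=float)
    inside = (posterior.hpd_lo <= true_sizes) & (true_sizes <= posterior.hpd_hi)
    return float(inside.mean())


def mrd(
    posterior: SkylinePosterior,
    truth: Callable[[np.ndarray], np.ndarray],
    grid: np.ndarray | None = None,
) -> float:
    """Signed mean relative departure of the posterior median from the truth:
    mean over grid points of ``(median(t) - truth(t)) / truth(t)``.
    Under-estimation (the structure-effect decline) gives negative values."""
    if grid is None:
        grid = posterior.grid
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    true_sizes = np.asarray([truth(t) for t in grid], dtype=float)
    if np.any(true_sizes <= 0):
        raise ValueError("true size must be positive on the grid")
    return float(np.mean((posterior.median_curve - true_sizes) / true_sizes))


def false_positive_rate(records: Sequence[EvalRecord], threshold: float = 1.0) -> float:
    """Fraction of constant-size replicates whose posterior mean PSC exceeds
    ``threshold`` — the rate of falsely inferring a size change."""
    if not records:
        raise ValueError("no records")
    psc = np.asarray([r.psc_mean for r in records])
    return float(np.mean(psc > threshold))


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    n: int


def psc_vs_connectedness(
    psc_by_deme: Mapping[int, float],
    fst: FstMatrix,
    split: float = 0.2,
) -> dict:
    """Regress per-deme mean PSC on deme connectedness (mean pairwise FST),
    separately for demes below and above the ``split`` FST value.

    Returns ``{"below": RegressionFit|None, "above": ..., "omitted": [...]}``;
    a side with fewer than 3 demes is omitted and flagged.
    """
    conn = np.array([connectedness(fst, d) for d in range(fst.d)])
    psc = np.array([psc_by_deme[d] for d in range(fst.d)])
    out: dict = {"below": None, "above": None, "omitted": []}
    for name, mask in (("below", conn < split), ("above", conn >= split)):
        if mask.sum() < 3:
            out["omitted"].append(name)
            continue
        res = stats.linregress(conn[mask], psc[mask])
        out[name] = RegressionFit(
            slope=float(res.slope), intercept=float(res.intercept),
            r=float(res.rvalue), n=int(mask.sum()),
        )
    return out
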