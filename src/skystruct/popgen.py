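"""Population-genetic statistics: Hudson FST from sequences, island-model
equilibrium theory, migration inversion and connectedness scores.

All formulas use the haploid / maternally-inherited (mtDNA) scaling, where
``Nm`` counts female migrants per deme per generation.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .seqsim import Alignment


class UndefinedFstError(ArithmeticError):
    """FST is undefined (no divergence between the demes)."""


@dataclasses.dataclass(frozen=True)
class FstMatrix:
    """Symmetric pairwise FST among demes with a zero diagonal."""

    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        d = v.shape[0]
        if v.shape != (d, d):
            raise ValueError("FST matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("FST matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("FST matrix diagonal must be exactly zero")
        off = v[~np.eye(d, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() >= 1):
            raise ValueError("off-diagonal FST values must lie in [0, 1)")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(f"deme{i}" for i in range(d)))

    @property
    def d(self) -> int:
        return int(self.values.shape[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FstMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), labels=tuple(map(str, df.columns)))


# ---------------------------------------------------------------------------
# Pairwise distances and the Hudson estimator

def _pair_counts(codes_a: np.ndarray, codes_b: np.ndarray):
    """Mean per-site transition (P) and transversion (Q) proportions over all
    cross pairs of rows between the two code arrays."""
    diff = codes_a[:, None, :] != codes_b[None, :, :]
    # a transition keeps the purine/pyrimidine class
    purine_a = np.isin(codes_a, (0, 2))
    same_class = purine_a[:, None, :] == np.isin(codes_b, (0, 2))[None, :, :]
    P = (diff & same_class).mean(axis=2)
    Q = (diff & ~same_class).mean(axis=2)
    return P, Q


def _within_pairs(codes: np.ndarray):
    n = codes.shape[0]
    iu = np.triu_indices(n, k=1)
    P, Q = _pair_counts(codes, codes)
    return P[iu], Q[iu]


def k2p_gamma_distance(P, Q, alpha: float | None = 0.5):
    """Kimura two-parameter distance with optional gamma rate correction.

    ``P`` and ``Q`` are per-site transition and transversion proportions.
    With ``alpha=None`` the standard (homogeneous-rate) K2P log formula is
    used; otherwise the Jin–Nei gamma generalisation with shape ``alpha``.
    Saturated pairs (``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``) yield ``nan``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    with np.errstate(invalid="ignore", divide="ignore"):
        if alpha is None:
            d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
        else:
            d = (alpha / 2.0) * (a1 ** (-1.0 / alpha) - 1.0) + (alpha / 4.0) * (
                a2 ** (-1.0 / alpha) - 1.0
            )
    bad = (a1 <= 0) | (a2 <= 0)
    if np.ndim(d) == 0:
        return float("nan") if bad else float(d)
    d = np.where(bad, np.nan, d)
    return d


def hudson_fst_components(
    alignment: Alignment,
    deme_a: int,
    deme_b: int,
    *,
    correction: str | None = None,
    gamma_shape: float = 0.5,
) -> tuple[float, float]:
    """Mean within-deme (``pi_w``) and between-deme (``pi_b``) pairwise
    distance per site for one deme pair.

    ``correction=None`` uses raw proportions of differing sites;
    ``correction="k2p_gamma"`` applies the gamma-corrected Kimura
    two-parameter distance (appropriate for transition-biased, rate-
    heterogeneous mtDNA where multiple hits are common).
    """
    codes_a = alignment.codes[alignment.tip_demes == deme_a]
    codes_b = alignment.codes[alignment.tip_demes == deme_b]
    if codes_a.shape[0] < 2 or codes_b.shape[0] < 2:
        raise ValueError("need at least 2 sequences per deme for within diversity")

    def dist(P, Q):
        if correction is None:
            return P + Q
        if correction == "k2p_gamma":
            return k2p_gamma_distance(P, Q, gamma_shape)
        raise ValueError(f"unknown correction {correction!r}")

    pw = 0.5 * (np.mean(dist(*_within_pairs(codes_a))) + np.mean(dist(*_within_pairs(codes_b))))
    Pb, Qb = _pair_counts(codes_a, codes_b)
    pb = float(np.mean(dist(Pb, Qb)))
    return float(pw), pb


def hudson_fst_pair(
    alignment: Alignment,
    deme_a: int,
    deme_b: int,
    *,
    correction: str | None = None,
    gamma_shape: float = 0.5,
) -> float:
    """Hudson's FST estimate ``1 - pi_w / pi_b`` for one deme pair.

    Negative estimates are returned as computed (not clamped) so that
    averages over replicates stay unbiased. ``pi_b == 0`` raises
    :class:`UndefinedFstError`.
    """
    pw, pb = hudson_fst_components(
        alignment, deme_a, deme_b, correction=correction, gamma_shape=gamma_shape
    )
    if pb == 0.0:
        raise UndefinedFstError("no divergence between demes: FST undefined")
    return 1.0 - pw / pb


def hudson_fst_matrix(alignment: Alignment, **kwargs) -> FstMatrix:
    """Pairwise Hudson FST over every pair of demes present in the alignment.

    Negative point estimates are floored at 0 so the result is a valid
    :class:`FstMatrix`; use :func:`hudson_fst_pair` for unclamped values.
    """
    demes = sorted(set(alignment.tip_demes.tolist()))
    d = len(demes)
    out = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            f = hudson_fst_pair(alignment, demes[i], demes[j], **kwargs)
            out[i, j] = out[j, i] = max(f, 0.0)
    return FstMatrix(values=out, labels=tuple(f"deme{k}" for k in demes))


# ---------------------------------------------------------------------------
# Island-model equilibrium theory

def equilibrium_fst(Nm: float, d: float | None = None) -> float:
    """Equilibrium FST of a haploid maternally inherited marker in an island
    model: ``1 / (1 + 2 Nm d/(d-1))``; ``d=None`` (or inf) gives the
    infinite-island limit ``1 / (1 + 2 Nm)``."""
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if d is None or math.isinf(d):
        return 1.0 / (1.0 + 2.0 * Nm)
    if d < 2:
        raise ValueError("d must be at least 2")
    return 1.0 / (1.0 + 2.0 * Nm * d / (d - 1.0))


def fst_to_nm(F: float, d: float | None = None) -> float:
    """Invert :func:`equilibrium_fst`: migrant number from an FST value.

    ``Nm = (1/F - 1) (d-1)/(2d)``; ``d=None`` gives the infinite-island
    variant ``(1/F - 1)/2``.
    """
    if not 0.0 < F < 1.0:
        raise ValueError("F must lie strictly in (0, 1)")
    if d is None or math.isinf(d):
        return (1.0 / F - 1.0) / 2.0
    if d < 2:
        raise ValueError("d must be at least 2")
    return (1.0 / F - 1.0) * (d - 1.0) / (2.0 * d)


def connectedness(fst: FstMatrix, deme: int) -> float:
    """Mean of all pairwise FST values involving ``deme``."""
    if fst.d < 2:
        raise ValueError("need at least 2 demes")
    row = np.delete(fst.values[deme], deme)
    return float(row.mean())


def expected_mrd(Nm: float) -> float:
    """Expected mean relative departure of the collecting-phase effective
    size from the census size: ``1 / (2 Nm)``."""
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    return 1.0 / (2.0 * Nm)
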