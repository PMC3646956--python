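"""Skyline-plot inference on genealogies.

Two estimators of the female effective population size through time:

* the classic (deterministic) skyline, one segment per coalescent interval;
* a Bayesian piecewise-constant skyline with a posterior over the *number*
  of population-size change points (PSC). Change points are restricted to
  the coalescence times of the (pooled) genealogies; the change-point count
  carries a Poisson(ln 2) prior, so zero change points and "some change"
  are a priori equally likely; segment sizes carry a scale-invariant 1/N
  prior truncated to [N_min, N_max].

The sampler works on the true genealogy (node times known), so its state is
just the change-point indicator vector plus per-segment sizes; birth moves
draw the new segment size from its prior, which makes the trans-dimensional
acceptance ratio free of Jacobian terms.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .coalescent import Genealogy


@dataclasses.dataclass(frozen=True)
class SkylineFunction:
    """Piecewise-constant N(t): ``sizes[i]`` applies on
    ``(boundaries[i], boundaries[i+1]]`` (times in generations before present)."""

    boundaries: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        s = np.asarray(self.sizes, dtype=float)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "sizes", s)
        if b.ndim != 1 or s.ndim != 1 or len(s) != len(b) - 1:
            raise ValueError("need len(sizes) == len(boundaries) - 1")
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must increase strictly from 0")
        if np.any(s <= 0):
            raise ValueError("sizes must be positive")

    @property
    def n_changepoints(self) -> int:
        return int(np.sum(self.sizes[1:] != self.sizes[:-1]))

    def at(self, t) -> np.ndarray:
        """Evaluate N(t); times beyond the last boundary get the last size."""
        idx = np.clip(np.searchsorted(self.boundaries[1:-1], t, side="left"),
                      0, len(self.sizes) - 1)
        return self.sizes[idx]


@dataclasses.dataclass(frozen=True)
class PscPrior:
    """Poisson prior on the number of change points (default mean ln 2)."""

    mean: float = math.log(2.0)

    def logpmf(self, k: int) -> float:
        return k * math.log(self.mean) - self.mean - math.lgamma(k + 1)


@dataclasses.dataclass(frozen=True)
class ChainSettings:
    n_steps: int = 100_000
    burn_in: float = 0.1
    thin: int = 100
    prior_only: bool = False
    size_bounds: tuple[float, float] = (1.0, 1e8)
    scale_width: float = 0.8
    grid_points: int = 100


@dataclasses.dataclass
class SkylinePosterior:
    """Thinned posterior draws with grid summaries."""

    samples: list[tuple[np.ndarray, np.ndarray]]  # (active change times, sizes)
    psc_samples: np.ndarray
    grid: np.ndarray
    median_curve: np.ndarray
    hpd_lo: np.ndarray
    hpd_hi: np.ndarray
    ess_log_posterior: float
    warn_low_ess: bool
    acceptance_rate: float


def classic_skyline(genealogy: Genealogy) -> SkylineFunction:
    """Classic skyline: while ``k`` lineages persist for ``tau``, estimate
    ``N = tau * k (k-1) / 2`` on that interval (haploid females)."""
    if genealogy.n_tips < 2:
        raise ValueError("need at least 2 tips")
    if np.any(genealogy.node_times[: genealogy.n_tips] != 0):
        raise ValueError("classic skyline requires contemporaneous tips")
    times = genealogy.coalescence_times()
    n = genealogy.n_tips
    ks = np.arange(n, 1, -1)
    tau = np.diff(np.concatenate([[0.0], times]))
    sizes = tau * ks * (ks - 1) / 2.0
    return SkylineFunction(boundaries=np.concatenate([[0.0], times]), sizes=sizes)


# ---------------------------------------------------------------------------
# Coalescent likelihood via sufficient statistics

class _CoalData:
    """Pooled sufficient statistics of one or more genealogies.

    ``A(t) = integral_0^t sum_g C(k_g(u), 2) du`` is piecewise linear with
    breaks at coalescence times, so the likelihood of any piecewise-constant
    N reduces to interpolating A at segment boundaries plus counting
    coalescences per segment.
    """

    def __init__(self, genealogies: Sequence[Genealogy]):
        events = []  # (time, is_coalescence) — k drops by 1 at each coalescence
        self.n_total = 0
        for g in genealogies:
            events.extend(g.coalescence_times().tolist())
            self.n_total += g.n_tips
        self.coal_times = np.sort(np.asarray(events))
        self.t_max = float(self.coal_times[-1])
        # lineage count of each genealogy between pooled event times
        ks = []
        counts = {id(g): g.n_tips for g in genealogies}
        per_g = sorted(
            [(t, id(g)) for g in genealogies for t in g.coalescence_times()]
        )
        lam = sum(n * (n - 1) / 2.0 for n in counts.values())
        bp = [0.0]
        lams = [lam]
        for t, gid in per_g:
            k = counts[gid]
            counts[gid] = k - 1
            lam += ((k - 1) * (k - 2) - k * (k - 1)) / 2.0
            bp.append(t)
            lams.append(lam)
        self.breakpoints = np.asarray(bp)
        cumA = np.concatenate([[0.0], np.cumsum(np.diff(self.breakpoints) * np.asarray(lams[:-1]))])
        self.cumA = cumA
        # log prod C(k, 2) over coalescences — constant in N, part of the density
        counts2 = {id(g): g.n_tips for g in genealogies}
        self.log_binom_const = 0.0
        for _, gid in per_g:
            k = counts2[gid]
            self.log_binom_const += math.log(k * (k - 1) / 2.0)
            counts2[gid] = k - 1

    def A(self, t) -> np.ndarray:
        return np.interp(t, self.breakpoints, self.cumA)

    def loglik(self, boundaries: np.ndarray, sizes: np.ndarray) -> float:
        """Log coalescent density for piecewise-constant N given by
        ``boundaries`` (0 ... >= t_max) and ``sizes``."""
        dA = np.diff(self.A(boundaries))
        counts = np.diff(np.searchsorted(self.coal_times, boundaries, side="right"))
        return float(np.sum(-dA / sizes - counts * np.log(sizes))) + self.log_binom_const


def coalescent_loglik(genealogy: Genealogy, fn: SkylineFunction) -> float:
    """Log-density of ``genealogy`` under the piecewise-constant ``fn``."""
    data = _CoalData([genealogy])
    if fn.boundaries[-1] < data.t_max * (1 - 1e-9):
        raise ValueError("skyline function does not cover the tree depth")
    b = fn.boundaries.copy()
    b[-1] = max(b[-1], data.t_max)
    return data.loglik(b, fn.sizes)


# ---------------------------------------------------------------------------
# MCMC

def bayesian_skyline(
    genealogies: Genealogy | Sequence[Genealogy],
    rng: np.random.Generator,
    prior: PscPrior = PscPrior(),
    chain: ChainSettings = ChainSettings(),
) -> SkylinePosterior:
    """Sample piecewise-constant demographic functions for one or more
    genealogies sharing a single demography (multi-locus mode).

    Returns thinned draws, the PSC posterior, and per-grid-point median and
    central 95% HPD summaries on a grid from 0 to the 95th percentile of the
    input root heights.
    """
    if isinstance(genealogies, Genealogy):
        genealogies = [genealogies]
    genealogies = list(genealogies)
    data = _CoalData(genealogies)
    lo, hi = chain.size_bounds
    log_range = math.log(hi / lo)

    # candidate change-point locations: pooled coalescence times except the last
    candidates = data.coal_times[:-1]
    M = len(candidates)
    active = np.zeros(M, dtype=bool)
    n_events = len(data.coal_times)
    init = float(np.clip(data.A([data.t_max])[0] / n_events, lo * 1.001, hi * 0.999))
    sizes = np.array([init])

    def boundaries_of(active_mask: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], candidates[active_mask], [data.t_max]])

    def loglik(active_mask: np.ndarray, sz: np.ndarray) -> float:
        if chain.prior_only:
            return 0.0
        return data.loglik(boundaries_of(active_mask), sz)

    def log_config_prior(k: int) -> float:
        # Poisson(k) spread uniformly over the C(M, k) indicator configurations
        return prior.logpmf(k) - (gammaln(M + 1) - gammaln(k + 1) - gammaln(M - k + 1))

    cur_ll = loglik(active, sizes)
    cur_k = 0
    n_keep = chain.n_steps - int(chain.n_steps * chain.burn_in)
    samples: list[tuple[np.ndarray, np.ndarray]] = []
    psc: list[int] = []
    trace: list[float] = []
    accepted = 0
    proposed = 0

    for step in range(chain.n_steps):
        u = rng.uniform()
        proposed += 1
        if u < 0.4 and M > 0:
            # indicator birth/death: toggle one candidate
            j = int(rng.integers(M))
            new_active = active.copy()
            new_active[j] = not new_active[j]
            seg = int(np.count_nonzero(active[:j]))  # segment young of candidate j
            if new_active[j]:  # birth: split segment, ancient part gets a prior draw
                new_size = lo * math.exp(rng.uniform() * log_range)
                new_sizes = np.insert(sizes, seg + 1, new_size)
                new_k = cur_k + 1
            else:  # death: merge, keep the young side's size
                new_sizes = np.delete(sizes, seg + 1)
                new_k = cur_k - 1
            new_ll = loglik(new_active, new_sizes)
            log_alpha = (new_ll - cur_ll) + (log_config_prior(new_k) - log_config_prior(cur_k))
            if math.log(rng.uniform()) < log_alpha:
                active, sizes, cur_ll, cur_k = new_active, new_sizes, new_ll, new_k
                accepted += 1
        elif u < 0.9 or len(sizes) < 2:
            # scale one segment size on the log scale (prior and Jacobian cancel)
            seg = int(rng.integers(len(sizes)))
            factor = math.exp(chain.scale_width * (rng.uniform() - 0.5))
            new_size = sizes[seg] * factor
            if lo <= new_size <= hi:
                new_sizes = sizes.copy()
                new_sizes[seg] = new_size
                new_ll = loglik(active, new_sizes)
                if math.log(rng.uniform()) < new_ll - cur_ll:
                    sizes, cur_ll = new_sizes, new_ll
                    accepted += 1
        else:
            # swap the sizes of two adjacent segments
            seg = int(rng.integers(len(sizes) - 1))
            new_sizes = sizes.copy()
            new_sizes[[seg, seg + 1]] = new_sizes[[seg + 1, seg]]
            new_ll = loglik(active, new_sizes)
            if math.log(rng.uniform()) < new_ll - cur_ll:
                sizes, cur_ll = new_sizes, new_ll
                accepted += 1
        if step >= chain.n_steps - n_keep and (step % chain.thin) == 0:
            samples.append((candidates[active].copy(), sizes.copy()))
            psc.append(cur_k)
            trace.append(cur_ll + log_config_prior(cur_k) - np.log(sizes).sum())

    psc_arr = np.asarray(psc, dtype=int)
    roots = [g.root_time for g in genealogies]
    grid_max = float(np.percentile(roots, 95)) if len(roots) > 1 else roots[0]
    grid = np.linspace(0.0, grid_max, chain.grid_points)
    curves = np.empty((len(samples), len(grid)))
    for i, (times, sz) in enumerate(samples):
        idx = np.searchsorted(times, grid, side="left")
        curves[i] = sz[idx]
    median_curve = np.median(curves, axis=0)
    hpd_lo, hpd_hi = _hpd_columns(curves, 0.95)
    ess = _ess(np.asarray(trace))
    return SkylinePosterior(
        samples=samples,
        psc_samples=psc_arr,
        grid=grid,
        median_curve=median_curve,
        hpd_lo=hpd_lo,
        hpd_hi=hpd_hi,
        ess_log_posterior=ess,
        warn_low_ess=bool(ess < 50),
        acceptance_rate=accepted / max(proposed, 1),
    )


def psc_mean(posterior: SkylinePosterior) -> float:
    """Posterior mean number of population-size change points."""
    if len(posterior.psc_samples) == 0:
        raise ValueError("empty posterior")
    return float(np.mean(posterior.psc_samples))


def _hpd_columns(curves: np.ndarray, mass: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-column shortest interval containing ``mass`` of the draws."""
    n, g = curves.shape
    m = max(int(math.ceil(mass * n)), 1)
    srt = np.sort(curves, axis=0)
    if m >= n:
        return srt[0], srt[-1]
    widths = srt[m - 1 :] - srt[: n - m + 1]
    start = np.argmin(widths, axis=0)
    cols = np.arange(g)
    return srt[start, cols], srt[start + m - 1, cols]


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial positive autocorrelation sum."""
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    acf = acf / acf[0]
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1.0 + 2.0 * s))
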