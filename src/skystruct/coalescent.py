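"""Structured-coalescent genealogy simulation with migration and
piecewise-exponential deme sizes, plus analytic expectations for validation.

Internal time is measured in generations before the present (tips at 0);
conversion to years happens only at I/O boundaries via the model's
generation time.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .scenarios import SamplingScheme, StructuredModel

#: number of piecewise-constant steps used to discretise an exponential phase
EXP_PHASE_STEPS = 32


class SimulationError(RuntimeError):
    """The coalescent process cannot terminate (e.g. disconnected demes)."""


@dataclasses.dataclass
class Genealogy:
    """Rooted strictly bifurcating coalescent tree with contemporaneous tips.

    Nodes ``0 .. n_tips-1`` are tips (time 0); nodes ``n_tips .. 2*n_tips-2``
    are internal, created in coalescence order so node times are
    non-decreasing with node index. ``parent[root] == -1``.
    """

    n_tips: int
    tip_demes: np.ndarray
    parent: np.ndarray
    node_times: np.ndarray
    #: coalescences that happened before every remaining lineage occupied a
    #: distinct deme — the scattering-phase part of the tree (diagnostic)
    scattering_coalescences: int | None = None

    def __post_init__(self) -> None:
        self.tip_demes = np.asarray(self.tip_demes, dtype=int)
        self.parent = np.asarray(self.parent, dtype=int)
        self.node_times = np.asarray(self.node_times, dtype=float)
        n = self.n_tips
        if self.tip_demes.shape != (n,):
            raise ValueError("tip_demes must have one entry per tip")
        if self.parent.shape != (2 * n - 1,) or self.node_times.shape != (2 * n - 1,):
            raise ValueError("parent/node_times must cover 2*n_tips - 1 nodes")
        internal = self.node_times[n:]
        if n > 1 and not np.all(np.diff(internal) >= 0):
            raise ValueError("internal node times must be non-decreasing in index")
        for v in range(2 * n - 2):
            p = self.parent[v]
            if p < 0 or self.node_times[p] <= self.node_times[v] - 1e-12:
                raise ValueError("every internal node must be older than its children")

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def root_time(self) -> float:
        return float(self.node_times[self.root])

    tmrca = root_time

    def coalescence_times(self) -> np.ndarray:
        """Sorted internal node times (generations)."""
        return np.sort(self.node_times[self.n_tips:])

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(2 * self.n_tips - 1)]
        for v in range(2 * self.n_tips - 2):
            kids[self.parent[v]].append(v)
        return kids

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        bl = np.zeros(2 * self.n_tips - 1)
        for v in range(2 * self.n_tips - 2):
            bl[v] = self.node_times[self.parent[v]] - self.node_times[v]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


# ---------------------------------------------------------------------------
# Deme-size trajectories

def _size_phases(model: StructuredModel) -> list[tuple[float, float, float, float]]:
    """Resolve exponential_change events into phases.

    Returns ``(t_start, t_end, mult_start, mult_end)`` tuples in generations,
    where ``mult`` multiplies the present-day deme sizes; the final tuple has
    ``t_end = inf`` and a constant multiplier.
    """
    g = model.generation_time
    phases = []
    t_prev, s_prev = 0.0, 1.0
    for ev in model.events:
        if ev.kind != "exponential_change":
            continue
        t_ev = ev.time_years / g
        s_ev = s_prev * ev.factor
        phases.append((t_prev, t_ev, s_prev, s_ev))
        t_prev, s_prev = t_ev, s_ev
    phases.append((t_prev, math.inf, s_prev, s_prev))
    return phases


def size_multiplier(model: StructuredModel, t: float) -> float:
    """Deme-size multiplier relative to the present at ``t`` generations ago."""
    if t < 0:
        raise ValueError("t must be non-negative")
    for t0, t1, s0, s1 in _size_phases(model):
        if t <= t1 or math.isinf(t1):
            if s0 == s1 or math.isinf(t1):
                return s0
            frac = (t - t0) / (t1 - t0)
            return s0 * (s1 / s0) ** frac
    raise AssertionError("unreachable")


def deme_size_at(model: StructuredModel, deme: int, t: float) -> float:
    """Size (females) of ``deme`` at ``t`` generations before present."""
    if not 0 <= deme < model.d:
        raise IndexError(f"deme {deme} out of range for {model.d} demes")
    return float(model.deme_sizes[deme]) * size_multiplier(model, t)


def census_size(model: StructuredModel, t: float = 0.0) -> float:
    """Total female count across demes at ``t`` generations before present."""
    return float(model.deme_sizes.sum()) * size_multiplier(model, t)


def expected_structured_ne(Nm: float, census: float) -> float:
    """Collecting-phase effective size of a many-deme island model:
    ``census * (1 + 1/(2*Nm))`` for a haploid maternally inherited marker.

    ``Nm = 0`` (complete isolation) makes the effective size infinite and
    returns ``math.inf``.
    """
    if Nm < 0:
        raise ValueError("Nm must be non-negative")
    if Nm == 0:
        return math.inf
    return census * (1.0 + 1.0 / (2.0 * Nm))


# ---------------------------------------------------------------------------
# Simulation

def _epochs(model: StructuredModel) -> list[tuple[float, float, float]]:
    """Piecewise-constant approximation of the size trajectory.

    Exponential phases are discretised into ``EXP_PHASE_STEPS`` equal steps,
    each using the size at the step midpoint. Returns ``(t0, t1, mult)``
    tuples covering ``[0, inf)``; a subdivision event time is inserted as an
    extra boundary.
    """
    epochs: list[tuple[float, float, float]] = []
    for t0, t1, s0, s1 in _size_phases(model):
        if s0 == s1 or math.isinf(t1):
            epochs.append((t0, t1, s0))
            continue
        edges = np.linspace(t0, t1, EXP_PHASE_STEPS + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        frac = (mids - t0) / (t1 - t0)
        mults = s0 * (s1 / s0) ** frac
        epochs.extend(zip(edges[:-1], edges[1:], mults))
    t_sub = _subdivision_time(model)
    if t_sub is not None:
        split: list[tuple[float, float, float]] = []
        for t0, t1, mult in epochs:
            if t0 < t_sub < t1:
                split.append((t0, t_sub, mult))
                split.append((t_sub, t1, mult))
            else:
                split.append((t0, t1, mult))
        epochs = split
    return epochs


def _subdivision_time(model: StructuredModel) -> float | None:
    for ev in model.events:
        if ev.kind == "subdivision":
            return ev.time_years / model.generation_time
    return None


def _check_reachable(model: StructuredModel, demes: Sequence[int]) -> bool:
    """True if all sampled demes communicate through the migration graph."""
    d = model.d
    adj = (model.migration > 0) | (model.migration.T > 0)
    seen = {int(demes[0])}
    stack = [int(demes[0])]
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return all(int(x) in seen for x in demes)


def simulate_genealogy(
    model: StructuredModel,
    scheme: SamplingScheme,
    rng: np.random.Generator,
    *,
    max_generations: float = 1e10,
) -> Genealogy:
    """Simulate a genealogy under the continuous-time structured coalescent.

    While more than one lineage remains, deme ``i`` holding ``k_i`` lineages
    coalesces at rate ``k_i (k_i - 1) / 2 / N_i(t)`` (haploid, per generation)
    and each lineage in deme ``i`` migrates to ``j`` at rate
    ``migration[i, j]``. Exponential size phases are handled by piecewise-
    constant discretisation; a subdivision event merges all lineages into a
    single panmictic pool of the summed deme size.
    """
    for deme in scheme.counts:
        if not 0 <= deme < model.d:
            raise InvalidSampleError(f"sampled deme {deme} not in model")
    n = scheme.n_total
    if n < 2:
        raise InvalidSampleError("need at least 2 sampled lineages")

    tip_demes = np.concatenate(
        [np.full(cnt, deme, dtype=int) for deme, cnt in sorted(scheme.counts.items())]
    )
    t_sub = _subdivision_time(model)
    if t_sub is None and len(scheme.counts) > 1:
        if not _check_reachable(model, list(scheme.counts)):
            raise SimulationError(
                "sampled demes are not connected by migration and no subdivision "
                "event exists: the coalescent cannot terminate"
            )

    parent = np.full(2 * n - 1, -1, dtype=int)
    node_times = np.zeros(2 * n - 1)
    lineage_nodes = list(range(n))
    lineage_demes = tip_demes.tolist()
    next_node = n
    row_rates = model.migration.sum(axis=1)
    base_sizes = model.deme_sizes
    total_base = float(base_sizes.sum())

    scattering_over = len(set(lineage_demes)) == len(lineage_demes)
    scattering_coal = 0

    t = 0.0
    for t0, t1, mult in _epochs(model):
        panmictic = t_sub is not None and t0 >= t_sub - 1e-12
        while len(lineage_nodes) > 1:
            k = len(lineage_nodes)
            if panmictic:
                coal_rates = np.array([k * (k - 1) / 2.0 / (total_base * mult)])
                mig_total = 0.0
            else:
                counts = np.bincount(lineage_demes, minlength=model.d)
                coal_rates = counts * (counts - 1) / 2.0 / (base_sizes * mult)
                mig_total = float(sum(row_rates[dm] for dm in lineage_demes))
            coal_total = float(coal_rates.sum())
            rate = coal_total + mig_total
            if rate == 0.0:
                break  # nothing can happen until the next epoch
            wait = rng.exponential(1.0 / rate)
            if t + wait > t1:
                break
            t += wait
            if t > max_generations:
                raise SimulationError(
                    f"coalescent did not terminate within {max_generations:g} generations"
                )
            if rng.uniform() * rate < coal_total:
                if panmictic:
                    ia, ib = rng.choice(k, size=2, replace=False)
                else:
                    deme = rng.choice(model.d, p=coal_rates / coal_total)
                    members = [ix for ix, dm in enumerate(lineage_demes) if dm == deme]
                    ia, ib = rng.choice(len(members), size=2, replace=False)
                    ia, ib = members[ia], members[ib]
                ia, ib = max(ia, ib), min(ia, ib)
                node_times[next_node] = t
                parent[lineage_nodes[ia]] = next_node
                parent[lineage_nodes[ib]] = next_node
                lineage_nodes[ib] = next_node
                lineage_demes[ib] = lineage_demes[ib]
                del lineage_nodes[ia]
                del lineage_demes[ia]
                next_node += 1
                if not scattering_over:
                    scattering_coal += 1
            else:
                u = rng.uniform() * mig_total
                acc = 0.0
                for ix, dm in enumerate(lineage_demes):
                    acc += row_rates[dm]
                    if u < acc:
                        probs = model.migration[dm] / row_rates[dm]
                        lineage_demes[ix] = int(rng.choice(model.d, p=probs))
                        break
            if not scattering_over and (
                panmictic or len(set(lineage_demes)) == len(lineage_demes)
            ):
                scattering_over = True
        if len(lineage_nodes) == 1:
            break
        if math.isinf(t1):
            raise SimulationError(
                "no events possible in the final epoch with more than one lineage"
            )
        t = t1
    return Genealogy(
        n_tips=n,
        tip_demes=tip_demes,
        parent=parent,
        node_times=node_times,
        scattering_coalescences=scattering_coal,
    )


class InvalidSampleError(ValueError):
    """The sampling scheme is incompatible with the model."""


# ---------------------------------------------------------------------------
# Analytic expectations: first-step linear system for two lineages

def expected_pair_coalescence_times(model: StructuredModel) -> np.ndarray:
    """Expected coalescence time (generations) of two lineages, by starting demes.

    Solves the first-step linear equations of the two-lineage structured
    coalescent on the (unordered) pair-of-demes state space; requires a
    constant-size model (no demographic events).

    Returns a ``d x d`` symmetric matrix; entry ``(i, j)`` is the expectation
    for one lineage sampled in deme ``i`` and one in deme ``j``.
    """
    if any(e.kind == "exponential_change" for e in model.events):
        raise ValueError("analytic pair times require a constant-size model")
    d = model.d
    states = [(i, j) for i in range(d) for j in range(i, d)]
    index = {s: ix for ix, s in enumerate(states)}
    ns = len(states)
    A = np.zeros((ns, ns))
    b = np.ones(ns)
    M = model.migration
    row = M.sum(axis=1)
    for (i, j), ix in index.items():
        rate = row[i] + row[j] + (1.0 / model.deme_sizes[i] if i == j else 0.0)
        if rate == 0.0:
            raise SimulationError("absorbing non-coalescing pair state: disconnected demes")
        A[ix, ix] = rate
        for dest in range(d):
            if M[i, dest] > 0:
                A[ix, index[tuple(sorted((dest, j)))]] -= M[i, dest]
            if M[j, dest] > 0:
                A[ix, index[tuple(sorted((i, dest)))]] -= M[j, dest]
    sol = np.linalg.solve(A, b)
    out = np.zeros((d, d))
    for (i, j), ix in index.items():
        out[i, j] = out[j, i] = sol[ix]
    return out
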