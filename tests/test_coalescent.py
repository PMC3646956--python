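import math

import numpy as np
import pytest
from scipy import stats

from skystruct import (
    SamplingScheme,
    add_events,
    build_island_model,
    census_size,
    deme_size_at,
    expected_pair_coalescence_times,
    expected_structured_ne,
    simulate_genealogy,
)
from skystruct.coalescent import SimulationError
from skystruct.scenarios import decline, expansion, subdivision


def mean_tmrca(model, scheme, n_reps, seed):
    rng = np.random.default_rng(seed)
    times = np.array([simulate_genealogy(model, scheme, rng).root_time
                      for _ in range(n_reps)])
    return times.mean(), times.std(ddof=1) / math.sqrt(n_reps), times


class TestSizeTrajectories:
    def test_constant_model(self):
        model = build_island_model(40, 500, 1.25)
        assert deme_size_at(model, 0, 0.0) == 500
        assert deme_size_at(model, 39, 12345.0) == 500
        assert census_size(model, 0.0) == 20000

    def test_boom_bust_anchors(self):
        # x10 decline from 4200 ya plus x10 expansion from 25200 ya (g = 7)
        model = add_events(build_island_model(40, 500, 1.25),
                           [decline(4200, 10), expansion(25200, 10)])
        assert deme_size_at(model, 0, 600.0) == pytest.approx(5000)
        assert deme_size_at(model, 0, 3600.0) == pytest.approx(500)
        assert deme_size_at(model, 0, 10000.0) == pytest.approx(500)
        # exponential interpolation is continuous and monotone within a phase
        mid = deme_size_at(model, 0, 300.0)
        assert 500 < mid < 5000

    def test_census_sizes(self):
        assert census_size(build_island_model(10, 2000, 1.25)) == 20000
        assert census_size(build_island_model(34, 500, 1.25)) == 17000

    def test_deme_index_checked(self):
        model = build_island_model(4, 500, 1.25)
        with pytest.raises(IndexError):
            deme_size_at(model, 4, 0.0)


class TestStructuredNe:
    @pytest.mark.parametrize(
        "Nm, expected, departure",
        [(0.125, 100_000, 4.00), (1.25, 28_000, 0.40), (12.5, 20_800, 0.04)],
    )
    def test_collecting_phase_size(self, Nm, expected, departure):
        ne = expected_structured_ne(Nm, 20_000)
        assert ne == pytest.approx(expected)
        assert ne / 20_000 - 1 == pytest.approx(departure)

    def test_isolation_gives_infinity(self):
        assert math.isinf(expected_structured_ne(0.0, 20_000))


class TestPairOracle:
    """First-step linear system vs the island-model closed forms."""

    @pytest.mark.parametrize("d", [2, 3])
    @pytest.mark.parametrize("Nm", [0.25, 2.0])
    def test_island_closed_forms(self, d, Nm):
        N = 120.0
        model = build_island_model(d, N, Nm)
        E = expected_pair_coalescence_times(model)
        m = Nm / N
        assert E[0, 0] == pytest.approx(d * N, rel=1e-10)
        if d > 1:
            assert E[0, 1] == pytest.approx(d * N + (d - 1) / (2 * m), rel=1e-10)

    def test_disconnected_pair_rejected(self):
        model = build_island_model(2, 100, 0.0)
        with pytest.raises(SimulationError):
            expected_pair_coalescence_times(model)


class TestSimulator:
    def test_single_deme_pair_tmrca(self, panmictic_model):
        scheme = SamplingScheme("local", {0: 2}, 2)
        model = build_island_model(2, 500, 1.0)
        single = type(panmictic_model)(deme_sizes=np.array([500.0]),
                                       migration=np.zeros((1, 1)))
        mean, se, _ = mean_tmrca(single, scheme, 2000, seed=1)
        assert abs(mean - 500) < 3.5 * se

    @pytest.mark.parametrize("d", [2, 3])
    def test_monte_carlo_matches_linear_oracle(self, d):
        model = build_island_model(d, 100, 0.5)
        E = expected_pair_coalescence_times(model)
        same = SamplingScheme("local", {0: 2}, 2)
        diff = SamplingScheme("scattered", {0: 1, 1: 1}, 2)
        for scheme, truth in ((same, E[0, 0]), (diff, E[0, 1])):
            mean, se, _ = mean_tmrca(model, scheme, 700, seed=2 + d)
            assert abs(mean - truth) < 3.5 * se

    def test_zero_migration_local_equals_panmictic(self):
        """A local sample from an isolated deme follows the single-population
        coalescent of that deme's size only."""
        iso = build_island_model(2, 300, 0.0)
        single = iso.__class__(deme_sizes=np.array([300.0]), migration=np.zeros((1, 1)))
        scheme = SamplingScheme("local", {0: 5}, 5)
        _, _, t_iso = mean_tmrca(iso, scheme, 400, seed=5)
        _, _, t_single = mean_tmrca(single, scheme, 400, seed=6)
        assert stats.ks_2samp(t_iso, t_single).pvalue > 0.005

    def test_scattering_coalescences_decrease_with_migration(self):
        scheme = SamplingScheme("local", {0: 40}, 40)
        means = []
        for Nm in (0.125, 1.25, 12.5):
            model = build_island_model(40, 500, Nm)
            rng = np.random.default_rng(8)
            scat = [simulate_genealogy(model, scheme, rng).scattering_coalescences
                    for _ in range(20)]
            means.append(np.mean(scat))
        assert means[0] > means[1] > means[2]

    def test_deme_exchangeability(self):
        """Island demes are exchangeable: local TMRCA distribution does not
        depend on which deme is sampled."""
        model = build_island_model(5, 200, 1.0)
        _, _, t0 = mean_tmrca(model, SamplingScheme("local", {0: 4}, 4), 300, seed=9)
        _, _, t3 = mean_tmrca(model, SamplingScheme("local", {3: 4}, 4), 300, seed=10)
        assert stats.ks_2samp(t0, t3).pvalue > 0.005

    def test_disconnected_multi_deme_sample_raises(self, pair_scheme):
        model = build_island_model(2, 100, 0.0)
        with pytest.raises(SimulationError):
            simulate_genealogy(model, pair_scheme, np.random.default_rng(0))

    def test_subdivision_rescues_disconnected_demes(self, pair_scheme):
        # structure arose T generations ago; before that one panmictic pool
        t_sub_gen = 1000.0
        model = add_events(build_island_model(4, 500, 0.0),
                           [subdivision(t_sub_gen * 7)])
        rng = np.random.default_rng(11)
        times = np.array([simulate_genealogy(model, pair_scheme, rng).root_time
                          for _ in range(400)])
        assert np.all(times >= t_sub_gen)
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert abs(times.mean() - (t_sub_gen + 2000.0)) < 3.5 * se

    def test_genealogy_invariants(self):
        model = build_island_model(4, 300, 2.0)
        scheme = SamplingScheme("pooled", {0: 3, 1: 3, 2: 3, 3: 3}, 12)
        g = simulate_genealogy(model, scheme, np.random.default_rng(12))
        assert g.n_tips == 12
        internal = g.node_times[12:]
        assert np.all(np.diff(internal) >= 0)
        assert np.all(internal > 0)
        for v in range(g.root):
            assert g.node_times[g.parent[v]] >= g.node_times[v]


def test_decline_interpolates_between_present_and_ancient_sizes():
    """Under a 10-fold decline ending at the present, early coalescences are
    slower than in a constant population of the present-day size but faster
    than in one of the ancient size."""
    present = build_island_model(2, 5000, 5.0)
    ancient = build_island_model(2, 50_000, 5.0)
    declining = add_events(present, [decline(4200, 10)])
    scheme = SamplingScheme("local", {0: 10}, 10)
    rng = np.random.default_rng(13)

    def mean_first(model):
        return np.mean([simulate_genealogy(model, scheme, rng).coalescence_times()[0]
                        for _ in range(150)])

    assert mean_first(present) < mean_first(declining) < mean_first(ancient)


def test_cross_validation_against_msprime():
    """Independent oracle: msprime's structured coalescent gives the same mean
    TMRCA for a two-deme sample in a small island model."""
    msprime = pytest.importorskip("msprime")
    d, N, Nm = 3, 200.0, 0.5
    model = build_island_model(d, N, Nm)
    scheme = SamplingScheme("pooled", {0: 2, 1: 2}, 4)
    mean_ours, se_ours, _ = mean_tmrca(model, scheme, 500, seed=14)

    demography = msprime.Demography()
    for i in range(d):
        demography.add_population(name=f"p{i}", initial_size=N)
    demography.set_symmetric_migration_rate([f"p{i}" for i in range(d)],
                                            (Nm / N) / (d - 1))
    times = []
    for ts in msprime.sim_ancestry(
        samples={"p0": 2, "p1": 2},
        demography=demography,
        ploidy=1,
        num_replicates=500,
        random_seed=99,
    ):
        times.append(ts.max_root_time)
    times = np.array(times)
    se_ms = times.std(ddof=1) / math.sqrt(len(times))
    assert abs(mean_ours - times.mean()) < 3.5 * math.hypot(se_ours, se_ms)
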