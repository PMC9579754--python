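import numpy as np
import pandas as pd
import pytest

from duoscan import (
    MarkerCatalog,
    RecombinationMap,
    SimConfig,
    build_genetic_map,
    deterministic_trajectory,
    init_population,
    make_gamete,
    simulate_null,
    simulate_replicate,
)
from duoscan.simulate import (
    ChromosomeCopy,
    SimulationError,
    build_linkage_groups,
    null_rng,
)
from duoscan.windows import assign_windows


def line_catalog(n: int, arm: str = "2L", chrom: str = "2", spacing: int = 1000):
    return MarkerCatalog(
        pd.DataFrame(
            {
                "chromosome": chrom,
                "arm": arm,
                "position": np.arange(1, n + 1) * spacing,
                "focal_allele": "A",
                "other_allele": "C",
            }
        )
    )


def uniform_map(arm="2L", rate=2.0, length=2_000_000):
    return RecombinationMap.uniform({arm: rate}, {arm: length})


class TestInitPopulation:
    def test_founder_counts_and_frequency(self):
        cat = line_catalog(5)
        pop = init_population(cat, uniform_map(), SimConfig(census=1500, p_geno=0.3))
        assert pop.n_focal == 450
        assert np.allclose(pop.marker_frequencies(), 0.3)

    def test_small_census_rounding(self):
        cat = line_catalog(3)
        pop = init_population(cat, uniform_map(), SimConfig(census=10, p_geno=0.3))
        assert np.allclose(pop.marker_frequencies(), 0.3)  # 3/10 flies = 6/20 copies

    def test_absorbing_state_without_focal_founders(self):
        cat = line_catalog(3)
        cfg = SimConfig(census=50, p_geno=0.0, generations=5)
        freqs = simulate_replicate(cat, uniform_map(), cfg, np.random.default_rng(0))
        assert np.all(freqs == 0.0)

    def test_both_sexes_in_both_founder_classes(self):
        cat = line_catalog(2)
        pop = init_population(cat, uniform_map(), SimConfig(census=100, p_geno=0.3))
        focal_sex = pop.sex[: pop.n_focal]
        other_sex = pop.sex[pop.n_focal :]
        assert {0, 1} <= set(focal_sex) and {0, 1} <= set(other_sex)

    def test_x_frequency_counts_copies(self):
        """On the X, females carry two copies and males one."""
        cat = line_catalog(4, arm="X", chrom="X")
        pop = init_population(cat, uniform_map("X"), SimConfig(census=100, p_geno=0.3))
        # 30 focal flies: 15 female (2 copies) + 15 male (1 copy) = 45
        # total copies: 50 female * 2 + 50 male = 150
        assert np.allclose(pop.marker_frequencies(), 45 / 150)


class TestMakeGamete:
    def _gmap(self, rate, length=10_000_000):
        return build_genetic_map(uniform_map(rate=rate, length=length), ["2L"])

    def test_zero_rate_map_transmits_unmodified_copies(self):
        gmap = self._gmap(0.0)
        rng = np.random.default_rng(1)
        a = ChromosomeCopy(1, np.array([1000.0, 5000.0]))
        b = ChromosomeCopy(0, np.array([]))
        for _ in range(50):
            g = make_gamete([a, b], gmap, rng)
            assert (g.anc0, list(g.breakpoints)) in [
                (1, [1000.0, 5000.0]),
                (0, []),
            ]

    def test_male_gametes_never_recombine(self):
        """Achiasmatic males: a gamete is always one whole parental copy."""
        gmap = self._gmap(10.0)  # 1 Morgan
        rng = np.random.default_rng(2)
        a = ChromosomeCopy(1, np.array([]))
        b = ChromosomeCopy(0, np.array([]))
        for _ in range(2000):
            g = make_gamete([a, b], gmap, rng, male=True)
            assert g.n_switches == 0

    def test_female_crossover_count_is_poisson_of_map_length(self):
        gmap = self._gmap(10.0)  # 1 Morgan total
        rng = np.random.default_rng(3)
        a = ChromosomeCopy(1, np.array([]))
        b = ChromosomeCopy(0, np.array([]))
        n = 10_000
        switches = [make_gamete([a, b], gmap, rng).n_switches for _ in range(n)]
        # ancestry switches at crossovers between opposite-ancestry copies
        se = np.sqrt(1.0 / n)
        assert abs(np.mean(switches) - 1.0) < 3 * se

    def test_hemizygous_parent_transmits_single_copy(self):
        gmap = self._gmap(5.0)
        g = make_gamete(
            [ChromosomeCopy(1, np.array([123.0]))], gmap, np.random.default_rng(4)
        )
        assert g.anc0 == 1 and list(g.breakpoints) == [123.0]


class TestNextGeneration:
    def test_sex_extinction_raises_named_generation(self):
        cat = line_catalog(2)
        pop = init_population(cat, uniform_map(), SimConfig(census=10, p_geno=0.5))
        pop.sex[:] = 0  # all female
        with pytest.raises(SimulationError, match="generation 0"):
            pop.next_generation(np.random.default_rng(0))

    def test_extreme_selection_fixes_focal_allele(self):
        """A surrogate for s -> infinity: focal homozygotes monopolize parentage."""
        from duoscan import SelectionTarget

        cat = line_catalog(3, spacing=100_000)
        cfg = SimConfig(
            census=200,
            p_geno=0.3,
            generations=6,
            targets=(SelectionTarget("2", 200_000.0, s18=1e6, s29=1e6, h=0.5),),
        )
        freqs = simulate_replicate(
            cat, uniform_map(rate=0.0), cfg, np.random.default_rng(5), temperature=29
        )
        assert freqs.min() > 0.99

    def test_wright_fisher_drift_variance(self):
        """Neutral variance after t generations matches p0 q0 (1-(1-1/2N)^t)."""
        cat = line_catalog(1)
        n, t, runs = 100, 10, 500
        cfg = SimConfig(census=n, p_geno=0.3, generations=t)
        vals = np.array(
            [
                simulate_replicate(cat, uniform_map(rate=0.0), cfg, null_rng(11, r, 0))[0]
                for r in range(runs)
            ]
        )
        expected = 0.3 * 0.7 * (1 - (1 - 1 / (2 * n)) ** t)
        assert abs(vals.var(ddof=1) / expected - 1) < 0.2

    def test_tightly_linked_markers_stay_correlated(self):
        """Two-founder linkage: markers a few kb apart drift as one unit."""
        cat = line_catalog(2, spacing=5000)
        cfg = SimConfig(census=300, p_geno=0.3, generations=10)
        pairs = np.array(
            [
                simulate_replicate(cat, uniform_map(rate=2.4), cfg, null_rng(13, r, 0))
                for r in range(60)
            ]
        )
        assert np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1] > 0.95

    def test_determinism_under_same_stream(self):
        cat = line_catalog(10, spacing=10_000)
        cfg = SimConfig(census=80, p_geno=0.3, generations=5)
        f1 = simulate_replicate(cat, uniform_map(), cfg, null_rng(7, 0, 0))
        f2 = simulate_replicate(cat, uniform_map(), cfg, null_rng(7, 0, 0))
        assert np.array_equal(f1, f2)


class TestSimulateNull:
    def _setup(self, n_markers=60, w=20):
        cat = line_catalog(n_markers, spacing=10_000)
        rmap = uniform_map()
        windex = assign_windows(cat, w)
        return cat, rmap, windex

    def test_run_and_window_bookkeeping(self):
        cat, rmap, windex = self._setup()
        cfg = SimConfig(census=60, p_geno=0.3, generations=3, replicates=2)
        null = simulate_null(cat, rmap, cfg, windex, n_runs=4, seed=3)
        assert len(null.values("2")) == 4 * len(windex)
        assert set(null.frame["run"]) == {0, 1, 2, 3}

    def test_zero_generations_gives_zero_afc(self):
        cat, rmap, windex = self._setup()
        cfg = SimConfig(census=100, p_geno=0.3, generations=0, replicates=2)
        null = simulate_null(cat, rmap, cfg, windex, n_runs=2, seed=1)
        assert np.allclose(null.values("2"), 0.0)  # 30/100 flies = exactly 0.3

    def test_neutral_mean_is_zero(self):
        cat, rmap, windex = self._setup()
        cfg = SimConfig(census=100, p_geno=0.3, generations=5, replicates=3)
        null = simulate_null(cat, rmap, cfg, windex, n_runs=40, seed=5)
        v = null.values("2")
        assert abs(v.mean()) < 3 * v.std(ddof=1) / np.sqrt(len(v) / len(windex))

    def test_rejects_selection_and_bad_run_counts(self):
        from duoscan import SelectionTarget

        cat, rmap, windex = self._setup()
        cfg = SimConfig(census=60, generations=2)
        with pytest.raises(ValueError):
            simulate_null(cat, rmap, cfg, windex, n_runs=0)
        sel = SimConfig(
            census=60, targets=(SelectionTarget("2", 100.0, 0.1, 0.1),)
        )
        with pytest.raises(ValueError, match="neutral"):
            simulate_null(cat, rmap, sel, windex, n_runs=2)


class TestDeterministicTrajectory:
    def test_matches_hand_iteration(self):
        # one step by hand: p=0.3, s=0.3, h=0.5
        p = deterministic_trajectory(0.3, 0.3, 1)[-1]
        wbar = 1 + 0.3 * (0.09 + 0.5 * 2 * 0.3 * 0.7)
        expected = 0.3 * (0.3 * 1.3 + 0.7 * 1.15) / wbar
        assert p == pytest.approx(expected)

    def test_neutral_is_constant(self):
        assert np.allclose(deterministic_trajectory(0.3, 0.0, 10), 0.3)


def test_markers_outside_map_support_rejected():
    cat = line_catalog(3, spacing=1_000_000)
    small = RecombinationMap.uniform({"2L": 2.0}, {"2L": 100})
    with pytest.raises(Exception, match="support"):
        build_linkage_groups(cat, small)
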