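import numpy as np
import pandas as pd
import pytest

from duoscan import (
    concat_samples,
    downsample_coverage,
    focal_allele_frequency,
    intersect_samples,
)
from duoscan.syncio import CountTable

from conftest import random_counts


def make_counts(toy_catalog, per_marker):
    """Counts from a list of dicts {nucleotide: count} per marker (1 sample)."""
    from duoscan.syncio import NUC_INDEX

    counts = np.zeros((len(toy_catalog), 1, 6), dtype=np.int64)
    for i, d in enumerate(per_marker):
        for nuc, c in d.items():
            counts[i, 0, NUC_INDEX[nuc]] = c
    return CountTable(toy_catalog, counts, ["s1"])


class TestFocalAlleleFrequency:
    def test_basic_arithmetic_and_boundaries(self, toy_catalog):
        # markers: (2L:100 A/C), (2L:250 C/T), others empty
        table = make_counts(
            toy_catalog,
            [{"A": 9, "C": 3}, {"C": 0, "T": 7}, {}, {}, {}, {}],
        )
        freqs = focal_allele_frequency(table, temperature=18)
        assert freqs.freq[0, 0] == pytest.approx(0.75)
        assert freqs.freq[1, 0] == 0.0
        assert np.isnan(freqs.freq[2, 0])  # zero informative coverage -> missing

    def test_third_allele_reads_ignored(self, toy_catalog):
        # marker 0 is A/C; T reads are off-ladder
        table = make_counts(toy_catalog, [{"A": 5, "T": 1, "C": 4}, {}, {}, {}, {}, {}])
        freqs = focal_allele_frequency(table, temperature=18)
        assert freqs.freq[0, 0] == pytest.approx(5 / 9)
        assert freqs.depth[0, 0] == 9
        assert freqs.ignored_reads[0] == 1

    def test_missingness_never_becomes_zero(self, toy_catalog):
        table = make_counts(toy_catalog, [{} for _ in range(6)])
        freqs = focal_allele_frequency(table, temperature=18)
        assert np.isnan(freqs.freq).all()
        assert not (freqs.freq == 0).any()


class TestIntersectSamples:
    def _freq_tables(self, toy_catalog, rng, n18=3, n29=3):
        t18 = focal_allele_frequency(random_counts(toy_catalog, n18, rng), 18)
        t29 = focal_allele_frequency(random_counts(toy_catalog, n29, rng), 29)
        return t18, t29

    def test_complete_tables_identity(self, toy_catalog):
        rng = np.random.default_rng(0)
        t18, t29 = self._freq_tables(toy_catalog, rng)
        # Poisson(20) coverage: tiny chance of zero; force non-missing
        t18.freq[np.isnan(t18.freq)] = 0.5
        t29.freq[np.isnan(t29.freq)] = 0.5
        combined = intersect_samples(t18, t29)
        assert len(combined.catalog) == len(toy_catalog)
        assert combined.n_samples == 6

    def test_marker_missing_in_one_sample_dropped_everywhere(self, toy_catalog):
        rng = np.random.default_rng(1)
        t18, t29 = self._freq_tables(toy_catalog, rng)
        t18.freq[np.isnan(t18.freq)] = 0.5
        t29.freq[np.isnan(t29.freq)] = 0.5
        t18.freq[2, 1] = np.nan  # one marker, one 18-degree replicate
        combined = intersect_samples(t18, t29)
        assert len(combined.catalog) == len(toy_catalog) - 1
        assert 40 not in combined.catalog.frame["position"].values  # row 2 gone

    def test_random_missingness_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(42)
        n = 1000
        frame = pd.DataFrame(
            {
                "chromosome": "2",
                "arm": "2L",
                "position": np.arange(1, n + 1),
                "focal_allele": "A",
                "other_allele": "C",
            }
        )
        from duoscan import MarkerCatalog

        catalog = MarkerCatalog(frame)
        tables = []
        missing_sets = []
        for j, temp in enumerate([18, 18, 29, 29]):
            freq = rng.random((n, 1))
            miss = rng.random(n) < 0.1
            freq[miss, 0] = np.nan
            missing_sets.append(set(np.flatnonzero(miss)))
            from duoscan.frequencies import AlleleFrequencyTable

            tables.append(
                AlleleFrequencyTable(
                    catalog,
                    freq,
                    np.where(np.isnan(freq), 0, 20).astype(int),
                    pd.DataFrame(
                        {"sample": [f"s{j}"], "temperature": [temp], "replicate": [j % 2 + 1]}
                    ),
                )
            )
        combined = intersect_samples(*tables)
        # brute-force oracle: a marker survives iff missing in no sample
        expected = set(range(n)) - set().union(*missing_sets)
        got = set(combined.catalog.frame["position"] - 1)
        assert got == expected

    def test_empty_intersection_raises(self, toy_catalog):
        rng = np.random.default_rng(3)
        t18 = focal_allele_frequency(random_counts(toy_catalog, 1, rng), 18)
        t18.freq[:] = np.nan
        with pytest.raises(ValueError, match="no marker"):
            intersect_samples(t18)


class TestDownsampleCoverage:
    def _big_table(self, n=100_000, p=0.3, seed=5):
        from duoscan import MarkerCatalog
        from duoscan.frequencies import AlleleFrequencyTable

        frame = pd.DataFrame(
            {
                "chromosome": "2",
                "arm": "2L",
                "position": np.arange(1, n + 1),
                "focal_allele": "A",
                "other_allele": "C",
            }
        )
        catalog = MarkerCatalog(frame)
        freq = np.full((n, 1), p)
        return AlleleFrequencyTable(
            catalog,
            freq,
            np.full((n, 1), 100),
            pd.DataFrame({"sample": ["s1"], "temperature": [29], "replicate": [1]}),
        )

    def test_poisson_mean_coverage(self):
        table = self._big_table()
        down = downsample_coverage(table, target_mean=12, seed=1)
        n = len(table.catalog)
        se = np.sqrt(12 / n)
        assert abs(down.depth[:, 0].mean() - 12) < 3 * se

    def test_frequency_unbiased(self):
        """Binomial resampling preserves the expected frequency (3 SE)."""
        table = self._big_table(p=0.3)
        down = downsample_coverage(table, target_mean=12, seed=2)
        vals = down.freq[:, 0]
        vals = vals[~np.isnan(vals)]
        se = np.sqrt(0.3 * 0.7 / 12 / len(vals))
        assert abs(vals.mean() - 0.3) < 3 * se

    def test_zero_frequency_stays_zero(self):
        table = self._big_table(n=1000, p=0.0)
        down = downsample_coverage(table, target_mean=12, seed=3)
        vals = down.freq[:, 0]
        assert np.nanmax(vals) == 0.0

    def test_zero_coverage_becomes_missing(self):
        table = self._big_table(n=5000, p=0.5)
        down = downsample_coverage(table, target_mean=0.5, seed=4)
        zero = down.depth[:, 0] == 0
        assert zero.any()
        assert np.isnan(down.freq[zero, 0]).all()

    def test_reproducible_under_same_seed(self):
        table = self._big_table(n=2000)
        a = downsample_coverage(table, 12, seed=9)
        b = downsample_coverage(table, 12, seed=9)
        assert np.array_equal(a.depth, b.depth)
        assert np.array_equal(a.freq, b.freq, equal_nan=True)

    def test_rejects_nonpositive_target(self):
        table = self._big_table(n=10)
        with pytest.raises(ValueError):
            downsample_coverage(table, 0, seed=0)


def test_concat_requires_shared_catalog(toy_catalog):
    rng = np.random.default_rng(8)
    t1 = focal_allele_frequency(random_counts(toy_catalog, 1, rng), 18)
    other = toy_catalog.subset(np.array([True] * 5 + [False]))
    t2 = focal_allele_frequency(random_counts(other, 1, rng), 29)
    with pytest.raises(ValueError, match="catalogue"):
        concat_samples(t1, t2)
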