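import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duoscan import (
    CLASS_LABELS,
    bh_adjust,
    class_summary,
    classify_windows,
    empirical_pvalue,
    fit_window_lm,
)
from duoscan.scan import (
    CLASS_18_ONLY,
    CLASS_29_ONLY,
    CLASS_DIRECTION,
    CLASS_DRIFT,
    CLASS_MAGNITUDE,
    CLASS_NO_TEMP,
    NullDistribution,
    ScanResult,
)


class TestEmpiricalPvalue:
    NULL = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])

    def test_enumeration_examples(self):
        assert empirical_pvalue(0.05, self.NULL) == pytest.approx(2 / 5)
        assert empirical_pvalue(-0.15, self.NULL) == pytest.approx(1 / 5)

    def test_boundaries(self):
        assert empirical_pvalue(0.5, self.NULL) == 0.0  # beyond every null value
        assert empirical_pvalue(0.0, self.NULL) == 1.0  # convention at exactly zero

    def test_strict_inequality_no_pseudocount(self):
        # observed equal to a null value is not counted as more extreme
        assert empirical_pvalue(0.2, self.NULL) == 0.0
        assert empirical_pvalue(0.1, self.NULL) == pytest.approx(1 / 5)

    def test_matches_exhaustive_counting(self):
        rng = np.random.default_rng(0)
        null = rng.normal(0, 0.1, size=200)
        obs = rng.normal(0, 0.1, size=50)
        got = empirical_pvalue(obs, null)
        for o, p in zip(obs, got):
            if o > 0:
                assert p == (null > o).sum() / 200
            elif o < 0:
                assert p == (null < o).sum() / 200

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10))
    @settings(deadline=None)
    def test_monotone_in_positive_observations(self, obs):
        null = np.linspace(-0.3, 0.3, 101)
        obs = np.sort(np.asarray(obs))
        p = empirical_pvalue(obs, null)
        assert np.all(np.diff(p) <= 0)


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_stepup_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 7), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @staticmethod
    def _brute_force(p):
        """Textbook step-up: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        adj_sorted = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            adj_sorted[rank - 1] = running
        out = np.empty(m)
        out[order] = adj_sorted
        return out

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(deadline=None)
    def test_matches_bruteforce_stepup(self, pvals):
        assert np.allclose(bh_adjust(pvals), self._brute_force(pvals), atol=1e-12)


class TestFitWindowLm:
    def test_hand_example(self):
        lm = fit_window_lm([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert lm.alpha_intercept[0] == pytest.approx(0.2)
        assert lm.alpha_temperature[0] == pytest.approx(0.3)
        assert lm.t[0] == pytest.approx(0.3 / (0.1 * np.sqrt(2 / 3)))
        assert lm.df == 4
        assert lm.p[0] == pytest.approx(0.02131, abs=1e-4)

    def test_intercept_is_reference_level_mean_exactly(self):
        rng = np.random.default_rng(1)
        a18, a29 = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        lm = fit_window_lm(a18, a29)
        assert np.array_equal(lm.alpha_intercept, a18.mean(axis=1))
        assert np.allclose(lm.alpha_intercept + lm.alpha_temperature, a29.mean(axis=1))

    def test_zero_variance_conventions(self):
        same = fit_window_lm([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert same.p[0] == 1.0
        diff = fit_window_lm([0.2, 0.2, 0.2], [0.5, 0.5, 0.5])
        assert diff.p[0] == 0.0

    def test_equals_statsmodels_ols_contrast(self):
        """The pooled-variance computation must reproduce OLS with a
        two-level categorical factor (independent implementation)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        for _ in range(25):
            a18, a29 = rng.normal(size=3), rng.normal(size=3)
            lm = fit_window_lm(a18, a29)
            x = sm.add_constant(np.r_[np.zeros(3), np.ones(3)])
            fit = sm.OLS(np.r_[a18, a29], x).fit()
            assert lm.alpha_intercept[0] == pytest.approx(fit.params[0], abs=1e-12)
            assert lm.alpha_temperature[0] == pytest.approx(fit.params[1], abs=1e-12)
            assert lm.p[0] == pytest.approx(fit.pvalues[1], abs=1e-10)


class TestClassifyWindows:
    @staticmethod
    def _classify_point(sig18, sig29, sig_lm, sign18, sign29, fdr=0.1):
        padj = lambda sig: fdr / 2 if sig else 0.9
        labels = classify_windows(
            np.array([padj(sig18)]),
            np.array([padj(sig29)]),
            np.array([padj(sig_lm)]),
            np.array([0.2 * sign18]),
            np.array([0.4 * sign29]),
            fdr,
        )
        return labels[0]

    def test_factorial_is_exhaustive_and_exclusive(self):
        """Every combination of the five predicates yields exactly one of
        the six labels, matching the decision tree."""
        for sig18, sig29, sig_lm, sign18, sign29 in itertools.product(
            [False, True], [False, True], [False, True], [-1, 1], [-1, 1]
        ):
            label = self._classify_point(sig18, sig29, sig_lm, sign18, sign29)
            if not sig18 and not sig29:
                assert label == CLASS_DRIFT
            elif sig18 and not sig29:
                assert label == CLASS_18_ONLY
            elif sig29 and not sig18:
                assert label == CLASS_29_ONLY
            elif not sig_lm:
                assert label == CLASS_NO_TEMP
            elif sign18 == sign29:
                assert label == CLASS_MAGNITUDE
            else:
                assert label == CLASS_DIRECTION
            assert label in CLASS_LABELS

    def test_nan_adjusted_lm_never_significant(self):
        label = classify_windows(
            np.array([0.01]), np.array([0.01]), np.array([np.nan]),
            np.array([0.2]), np.array([0.4]), 0.1,
        )[0]
        assert label == CLASS_NO_TEMP

    def test_decision_tree_examples(self):
        assert self._classify_point(False, False, False, 1, 1) == CLASS_DRIFT
        assert self._classify_point(True, True, False, 1, 1) == CLASS_NO_TEMP
        assert self._classify_point(True, True, True, 1, 1) == CLASS_MAGNITUDE
        assert self._classify_point(True, True, True, -1, 1) == CLASS_DIRECTION

    def test_temperature_relabel_swaps_single_classes(self):
        """Swapping the two temperatures swaps the change-only labels and
        leaves drift / no-temperature-effect invariant."""
        rng = np.random.default_rng(3)
        n = 200
        padj18 = rng.random(n)
        padj29 = rng.random(n)
        padj_lm = rng.random(n)
        afc18 = rng.normal(0, 0.2, n)
        afc29 = rng.normal(0, 0.2, n)
        fwd = classify_windows(padj18, padj29, padj_lm, afc18, afc29, 0.1)
        rev = classify_windows(padj29, padj18, padj_lm, afc29, afc18, 0.1)
        swap = {CLASS_18_ONLY: CLASS_29_ONLY, CLASS_29_ONLY: CLASS_18_ONLY}
        assert all(swap.get(a, a) == b for a, b in zip(fwd, rev))


class TestClassSummary:
    def _scan_result(self):
        frame = pd.DataFrame(
            {
                "chromosome": ["2"] * 4 + ["X"] * 2,
                "window": [0, 1, 2, 3, 0, 1],
                "label": [
                    CLASS_DRIFT,
                    CLASS_DRIFT,
                    CLASS_MAGNITUDE,
                    CLASS_MAGNITUDE,
                    CLASS_DRIFT,
                    CLASS_DRIFT,
                ],
                "afc18": [0, 0, 0.1, 0.3, 0, 0],
                "afc29": [0, 0, 0.4, 0.2, 0, 0],
            }
        )
        return ScanResult(frame, fdr=0.1)

    def test_fractions_sum_to_one_per_chromosome(self):
        summary = class_summary(self._scan_result())
        assert np.allclose(summary.fractions.sum(axis=1), 1.0)

    def test_genome_wide_is_unweighted_chromosome_mean(self):
        summary = class_summary(self._scan_result())
        assert summary.fractions.loc["GW", CLASS_DRIFT] == pytest.approx(
            (0.5 + 1.0) / 2
        )
        weighted = class_summary(self._scan_result(), weighted=True)
        assert weighted.fractions.loc["GW", CLASS_DRIFT] == pytest.approx(4 / 6)

    def test_share_more_extreme_at_29(self):
        summary = class_summary(self._scan_result())
        # magnitude windows: |0.4|>|0.1| yes, |0.2|>|0.3| no
        assert summary.more_extreme_at_29 == pytest.approx(1 / 2)


def test_null_distribution_roundtrip(tmp_path):
    frame = pd.DataFrame(
        {"chromosome": ["2"] * 4, "run": [0, 0, 1, 1], "window": [0, 1, 0, 1],
         "afc": [0.01, -0.02, 0.03, 0.0]}
    )
    null = NullDistribution(frame)
    path = tmp_path / "null.tsv"
    null.to_tsv(path)
    again = NullDistribution.from_tsv(path)
    assert np.allclose(again.values("2"), np.sort(frame["afc"]))
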