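import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cervikit.core_io import SampleDesign
from cervikit.quantify import TPMMatrix
from cervikit.stats import anova_three_stage, fold_change, pairwise_t
from cervikit.stats import test_gene_set as run_gene_tests


class TestAnova:
    def test_hand_computed_f(self):
        # SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3.0
        f, p = anova_three_stage([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert f == pytest.approx(3.0, abs=1e-9)
        assert p == pytest.approx(float(sps.f.sf(3.0, 2, 6)), abs=1e-12)

    def test_identical_group_means_give_f_zero(self):
        f, p = anova_three_stage([1, 3], [1, 3], [1, 3])
        assert f == 0.0
        assert p == 1.0

    def test_all_constant_is_degenerate_not_fatal(self):
        assert anova_three_stage([2, 2], [2, 2], [2, 2]) == (0.0, 1.0)

    def test_p_is_upper_tail_of_reference_distribution(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=4) for _ in range(3)]
        f, p = anova_three_stage(*groups)
        assert p == pytest.approx(float(sps.f.sf(f, 2, 9)), rel=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(loc=i, size=n) for i, n in enumerate((3, 3, 4))]
        f, p = anova_three_stage(*groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(float(ref.statistic), rel=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            anova_three_stage([1.0], [2, 3], [4, 5])


class TestPairwiseT:
    def test_hand_computed_pooled_t(self):
        # pooled s^2 = 1, SE = sqrt(2/3): t = -2/0.8165 = -2.449, df = 4
        t, p = pairwise_t([1, 2, 3], [3, 4, 5])
        assert t == pytest.approx(-2.449, abs=1e-3)
        assert p == pytest.approx(0.0705, abs=1e-3)

    def test_identical_groups(self):
        assert pairwise_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_swap_negates_t_keeps_p(self):
        t1, p1 = pairwise_t([1, 2, 3], [3, 4, 5])
        t2, p2 = pairwise_t([3, 4, 5], [1, 2, 3])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_unequal_means(self):
        t, p = pairwise_t([2, 2], [5, 5])
        assert t == -np.inf and p == 0.0

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=4), rng.normal(loc=1, size=5)
        f, p_f = anova_three_stage(a, b)
        t, p_t = pairwise_t(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_welch_differs_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.0]
        b = [0.0, 4.0, -2.0, 6.0]
        t_pooled, _ = pairwise_t(a, b)
        t_welch, _ = pairwise_t(a, b, welch=True)
        assert t_pooled == pytest.approx(float(sps.ttest_ind(a, b).statistic))
        assert t_welch == pytest.approx(
            float(sps.ttest_ind(a, b, equal_var=False).statistic))


class TestFoldChange:
    @pytest.mark.parametrize("late,early,expected", [
        (9.0, 122.0, 0.07),      # reported at 2 decimals
        (10.0, 10.0, 1.0),
        (181.0, 14.0, 12.93),
    ])
    def test_reported_ratios(self, late, early, expected):
        assert round(fold_change(late, early), 2) == pytest.approx(expected)

    def test_zero_early_mean_is_undefined(self):
        assert np.isnan(fold_change(5.0, 0.0))


def _tpm_matrix(values, design):
    frame = pd.DataFrame(values, columns=design.sample_ids)
    frame.index = [f"g{i}" for i in range(len(frame))]
    return TPMMatrix(tpm=frame, design=design)


class TestTestGeneSet:
    @pytest.fixture()
    def design(self):
        return SampleDesign({"n1": "NP", "n2": "NP", "n3": "NP",
                             "m1": "MT", "m2": "MT", "m3": "MT",
                             "l1": "LT", "l2": "LT", "l3": "LT", "l4": "LT"})

    def test_constant_gene_has_all_p_one(self, design):
        tpm = _tpm_matrix([[4.0] * 10], design)
        res = run_gene_tests(tpm, design).table
        assert res.loc["g0", "p_anova"] == 1.0
        assert res.loc["g0", ["p_NP_MT", "p_NP_LT", "p_MT_LT"]].eq(1.0).all()

    def test_row_count_and_columns(self, design):
        rng = np.random.default_rng(0)
        tpm = _tpm_matrix(rng.uniform(1, 100, size=(7, 10)), design)
        res = run_gene_tests(tpm, design).table
        assert len(res) == 7
        for col in ("F", "p_anova", "t_MT_LT", "p_MT_LT", "fc_MT_LT"):
            assert col in res.columns

    def test_invariant_to_sample_order_within_stage(self, design):
        rng = np.random.default_rng(1)
        values = rng.uniform(1, 100, size=(5, 10))
        tpm = _tpm_matrix(values, design)
        shuffled_ids = ["n3", "n1", "n2", "m2", "m3", "m1", "l4", "l1", "l3", "l2"]
        tpm2 = TPMMatrix(tpm=tpm.tpm[shuffled_ids], design=design)
        a = run_gene_tests(tpm, design).table
        b = run_gene_tests(tpm2, design).table
        pd.testing.assert_frame_equal(a, b)

    def test_planted_shift_detected_at_study_sample_sizes(self, design):
        """A 5-within-SD mean shift at n = 3/3/4 should reach p < 0.05 in
        at least 95% of simulations (Monte Carlo power check)."""
        rng = np.random.default_rng(42)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            base = rng.normal(10.0, 1.0, size=10)
            base[6:] += 5.0  # LT shifted by 5 SD
            tpm = _tpm_matrix([base ** 2], design)  # squared: sqrt undoes it
            res = run_gene_tests(tpm, design).table
            hits += res.loc["g0", "p_MT_LT"] < 0.05
        assert hits / n_sim >= 0.95
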