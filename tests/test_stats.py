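import numpy as np
import pytest
from scipy import stats as sps

from nirtaste.errors import ConfigError, DegenerateInputError
from nirtaste.stats import levene, one_way_anova, tukey_lsd, two_sample_t


def _groups(seed, k=3, n=50, scale=1.0, shift=0.0):
    rng = np.random.default_rng(seed)
    return [shift * g + scale * rng.normal(size=n) for g in range(k)]


def _brute_anova(groups):
    """From-definition sums of squares (independent of the implementation)."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((np.asarray(g) - np.mean(g)) ** 2)) for g in groups)
    sst = float(np.sum((allv - grand) ** 2))
    return ssb, ssw, sst


class TestAnova:
    def test_three_by_fifty_degrees_of_freedom(self):
        table = one_way_anova(_groups(0))
        assert (table.df_between, table.df_within, table.df_total) == (2, 147, 149)

    def test_all_means_equal_gives_zero_f(self):
        groups = [np.array([1.0, 2.0, 3.0])] * 3
        table = one_way_anova(groups)
        assert table.f == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_scipy(self, seed):
        groups = _groups(seed, n=20, shift=0.5)
        table = one_way_anova(groups)
        ssb, ssw, sst = _brute_anova(groups)
        assert table.ss_between == pytest.approx(ssb, rel=1e-9)
        assert table.ss_within == pytest.approx(ssw, rel=1e-9)
        assert table.ss_total == pytest.approx(sst, rel=1e-9)
        f_ref, p_ref = sps.f_oneway(*groups)
        assert table.f == pytest.approx(float(f_ref), rel=1e-9)
        assert table.p == pytest.approx(float(p_ref), rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_decomposition_identities(self, seed):
        table = one_way_anova(_groups(seed, n=15, shift=1.0))
        assert table.ss_between + table.ss_within == pytest.approx(
            table.ss_total, rel=1e-9)
        assert table.df_between + table.df_within == table.df_total
        assert table.ss_contrast + table.ss_deviation == pytest.approx(
            table.ss_between, rel=1e-9)

    def test_linear_contrast_formula(self):
        groups = _groups(3, n=10, shift=2.0)
        table = one_way_anova(groups)
        means = [np.mean(g) for g in groups]
        ns = [len(g) for g in groups]
        c = [-1.0, 0.0, 1.0]
        expected = (sum(ci * m for ci, m in zip(c, means)) ** 2
                    / sum(ci**2 / n for ci, n in zip(c, ns)))
        assert table.ss_contrast == pytest.approx(expected, rel=1e-9)

    def test_more_than_three_groups_contrast_not_implemented(self):
        with pytest.raises(NotImplementedError):
            one_way_anova(_groups(0, k=4, n=10))

    def test_small_group_rejected(self):
        with pytest.raises(ConfigError):
            one_way_anova([np.array([1.0]), np.array([1.0, 2.0])])


class TestTukeyLsd:
    def test_identical_groups_not_significant(self):
        g = np.random.default_rng(0).normal(size=30)
        rows = tukey_lsd([g, g.copy(), g + 1e-9])
        first = rows[0]
        assert first.mean_difference == pytest.approx(0.0, abs=1e-6)
        assert first.p_tukey > 0.99 and first.p_lsd > 0.99

    def test_equal_n_shares_standard_error(self):
        rows = tukey_lsd(_groups(1, n=50, shift=0.3))
        ses = {round(r.std_error, 12) for r in rows}
        assert len(ses) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_lsd_no_more_conservative_than_tukey(self, seed):
        rows = tukey_lsd(_groups(seed, n=12, shift=0.8))
        for r in rows:
            assert r.p_lsd <= r.p_tukey + 1e-12

    def test_antisymmetric_differences(self):
        rows = tukey_lsd(_groups(2, n=10))
        lookup = {(r.group_i, r.group_j): r for r in rows}
        for (i, j), r in lookup.items():
            assert r.mean_difference == pytest.approx(
                -lookup[(j, i)].mean_difference, rel=1e-12)

    def test_matches_statsmodels_tukey(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        groups = _groups(4, n=25, shift=0.6)
        rows = tukey_lsd(groups)
        data = np.concatenate(groups)
        labels = np.repeat([1, 2, 3], [len(g) for g in groups])
        ref = statsmodels.pairwise_tukeyhsd(data, labels)
        mine = {frozenset((r.group_i, r.group_j)): r.p_tukey for r in rows}
        for (a, b), p in zip([(1, 2), (1, 3), (2, 3)], ref.pvalues):
            assert mine[frozenset((a, b))] == pytest.approx(float(p), abs=1e-6)


class TestLevene:
    def test_identical_samples_give_zero(self):
        a = np.random.default_rng(0).normal(size=20)
        f, p = levene(a, a.copy())
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_unequal_spread_detected(self):
        a = np.random.default_rng(1).normal(size=40)
        f, p = levene(a, 3.0 * a)
        assert f > 0 and p < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_mean_centred(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=30), 1.5 * rng.normal(size=25)
        f, p = levene(a, b)
        f_ref, p_ref = sps.levene(a, b, center="mean")
        assert f == pytest.approx(float(f_ref), rel=1e-9)
        assert p == pytest.approx(float(p_ref), rel=1e-9)


class TestTwoSampleT:
    def test_pooled_df_for_150_vs_150(self):
        rng = np.random.default_rng(0)
        res = two_sample_t(rng.normal(size=150), rng.normal(size=150), equal_var=True)
        assert res.df == 298

    def test_identical_samples(self):
        a = np.random.default_rng(1).normal(size=20)
        res = two_sample_t(a, a.copy())
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.ci_lower == pytest.approx(-res.ci_upper, rel=1e-9)

    def test_welch_df_at_most_pooled_and_equal_when_balanced(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=30), 2.0 * rng.normal(size=30)
        pooled = two_sample_t(a, b, equal_var=True)
        welch = two_sample_t(a, b, equal_var=False)
        assert welch.df <= pooled.df
        # equal variances and equal n: Satterthwaite df equals n1+n2-2
        c = rng.normal(size=30)
        d = np.concatenate([c[15:], c[:15]])  # same values, same variance
        assert two_sample_t(c, d, equal_var=False).df == pytest.approx(58, rel=1e-9)

    @pytest.mark.parametrize("equal_var", [True, False])
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy(self, seed, equal_var):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=25), 0.5 + 1.4 * rng.normal(size=35)
        res = two_sample_t(a, b, equal_var=equal_var)
        ref = sps.ttest_ind(a, b, equal_var=equal_var)
        assert res.t == pytest.approx(float(ref.statistic), rel=1e-9)
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-9)
        lo, hi = ref.confidence_interval(0.95)
        assert res.ci_lower == pytest.approx(float(lo), rel=1e-9)
        assert res.ci_upper == pytest.approx(float(hi), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            two_sample_t(np.ones(10), np.ones(10))
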