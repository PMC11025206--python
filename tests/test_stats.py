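"""Clinical formulas, summary-statistic tests, partial correlation, GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plexus.errors import ParameterError
from plexus.stats import (
    GroupSummary,
    anova_from_summary,
    bpr,
    chisq_contingency,
    glm_group_comparison,
    partial_correlation,
    qalb,
    ttest_from_summary,
)


def _raw_from_summary(rng, summary):
    """Construct raw data whose sample mean/SD match a summary exactly
    (affine reconstruction of a random draw)."""
    x = rng.standard_normal(summary.n)
    x = (x - x.mean()) / x.std(ddof=1)
    return summary.mean + summary.sd * x


class TestClinicalFormulas:
    def test_qalb_values_and_units(self):
        assert qalb(236.0, 40.0) == pytest.approx(5.9)
        assert qalb(60.0, 60.0) == pytest.approx(1.0)
        out = qalb(np.array([100.0, 200.0]), np.array([50.0, 40.0]))
        assert np.allclose(out, [2.0, 5.0])

    def test_qalb_guards(self):
        with pytest.raises(ParameterError):
            qalb(100.0, 0.0)
        with pytest.raises(ParameterError):
            qalb(-1.0, 40.0)

    def test_bpr_values(self):
        assert bpr(48.0, 10.0) == 0.0
        assert bpr(40.3, 13.6) == pytest.approx(0.5662, abs=1e-4)
        assert bpr(36.0, 12.0) == pytest.approx(1.0)

    def test_bpr_guards(self):
        with pytest.raises(ParameterError):
            bpr(40.0, 0.0)
        with pytest.raises(ParameterError):
            bpr(50.0, 10.0)


class TestSummaryAnova:
    def test_reconstructs_published_cp_volume_f(self):
        """The three-group CP-volume summaries give F ~= 13.09 (the printed
        13.3 reflects rounding of the printed inputs)."""
        f, df1, df2, p = anova_from_summary([
            GroupSummary(12, 3161.8, 735.1),
            GroupSummary(143, 2911.3, 735.1),
            GroupSummary(105, 2454.5, 781.3),
        ])
        assert (df1, df2) == (2, 257)
        assert f == pytest.approx(13.0902, abs=2e-3)
        assert p < 0.001

    def test_identical_means_give_zero_f(self):
        f, *_ = anova_from_summary([GroupSummary(10, 5.0, 1.0),
                                    GroupSummary(20, 5.0, 2.0)])
        assert f == 0.0

    def test_matches_raw_data_anova(self, rng):
        summaries = [GroupSummary(14, 3.0, 1.2), GroupSummary(25, 4.5, 0.8),
                     GroupSummary(19, 2.2, 2.0)]
        raw = [_raw_from_summary(rng, s) for s in summaries]
        f, df1, df2, p = anova_from_summary(summaries)
        ref = sps.f_oneway(*raw)
        assert f == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_group_f_equals_squared_pooled_t(self):
        a, b = GroupSummary(12, 38.1, 6.1), GroupSummary(143, 40.5, 3.4)
        f, *_ = anova_from_summary([a, b])
        t, *_ = ttest_from_summary(a, b)
        assert f == pytest.approx(t * t, rel=1e-10)


class TestSummaryTtest:
    def test_reconstructs_published_alsfrs_t(self):
        t, df, p = ttest_from_summary(GroupSummary(12, 38.1, 6.1),
                                      GroupSummary(143, 40.5, 3.4))
        assert df == 153
        assert abs(t) == pytest.approx(2.1802, abs=2e-3)
        assert p < 0.05

    def test_equal_means_give_zero_t(self):
        t, _, p = ttest_from_summary(GroupSummary(10, 5.0, 1.0),
                                     GroupSummary(10, 5.0, 2.0))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_raw_data_ttest(self, rng):
        a, b = GroupSummary(15, 10.0, 2.0), GroupSummary(22, 11.5, 3.0)
        xa, xb = _raw_from_summary(rng, a), _raw_from_summary(rng, b)
        t, df, p = ttest_from_summary(a, b)
        ref = sps.ttest_ind(xa, xb)
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        tw, dfw, pw = ttest_from_summary(a, b, pooled=False)
        refw = sps.ttest_ind(xa, xb, equal_var=False)
        assert tw == pytest.approx(refw.statistic, rel=1e-9)
        assert pw == pytest.approx(refw.pvalue, rel=1e-9)


class TestChiSquare:
    def test_reconstructs_published_sex_table(self):
        chi2, df, p = chisq_contingency([[9, 3], [85, 58], [55, 50]])
        assert df == 2
        assert chi2 == pytest.approx(2.84, abs=0.005)
        assert p > 0.05

    def test_independent_table_gives_zero(self):
        chi2, _, p = chisq_contingency([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_two_by_two(self):
        chi2, df, _ = chisq_contingency([[10, 0], [0, 10]])
        assert (chi2, df) == (pytest.approx(20.0), 1)

    def test_zero_margin_raises(self):
        with pytest.raises(ParameterError):
            chisq_contingency([[0, 0], [5, 5]])


class TestPartialCorrelation:
    def test_single_covariate_closed_form(self, rng):
        """Matches (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        n = 200
        z = rng.standard_normal(n)
        x = 0.5 * z + rng.standard_normal(n)
        y = -0.3 * z + 0.4 * x + rng.standard_normal(n)
        res = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert res.r == pytest.approx(closed, abs=1e-10)
        assert res.df == n - 3

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 150
        c = rng.standard_normal((n, 2))
        x = c @ [0.3, -0.2] + rng.standard_normal(n)
        y = c @ [0.1, 0.4] + 0.5 * x + rng.standard_normal(n)
        res = partial_correlation(x, y, c)
        df = pd.DataFrame({"x": x, "y": y, "c1": c[:, 0], "c2": c[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_identity_gives_r_one(self, rng):
        x = rng.standard_normal(50)
        c = rng.standard_normal((50, 2))
        res = partial_correlation(x, x, c)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_reduces_to_pearson_with_irrelevant_covariates(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        c = rng.standard_normal((n, 3))
        res = partial_correlation(x, y, c)
        plain = np.corrcoef(x, y)[0, 1]
        assert abs(res.r - plain) < 0.02

    def test_zero_variance_residual_raises(self, rng):
        z = rng.standard_normal(30)
        with pytest.raises(ParameterError):
            partial_correlation(2.0 * z, rng.standard_normal(30), z)


def _toy_cohort(rng, n_per_group=40, shift=0.0):
    rows = []
    for gi, g in enumerate(["A", "B", "C"]):
        n = n_per_group
        rows.append(pd.DataFrame({
            "group": g,
            "cp_volume_mm3": rng.normal(2500 + shift * gi, 300, n),
            "age": rng.normal(55, 8, n),
            "sex": rng.choice(["M", "F"], n),
            "tiv_mm3": rng.normal(1.45e6, 1.2e5, n),
        }))
    return pd.concat(rows, ignore_index=True)


class TestGLM:
    def test_constant_outcome_gives_zero_f_and_unit_p(self, rng):
        df = _toy_cohort(rng)
        df["cp_volume_mm3"] = 1234.5
        res = glm_group_comparison(df)
        assert res.f_omnibus == 0.0
        assert res.p_omnibus == pytest.approx(1.0)
        assert all(c.p_adjusted == pytest.approx(1.0) for c in res.contrasts)

    def test_covariate_free_two_group_f_equals_t_squared(self, rng):
        df = _toy_cohort(rng, shift=150.0)
        df = df[df["group"] != "C"]
        res = glm_group_comparison(df, covariates=())
        a = df[df.group == "A"]["cp_volume_mm3"]
        b = df[df.group == "B"]["cp_volume_mm3"]
        t = sps.ttest_ind(a, b).statistic
        assert res.f_omnibus == pytest.approx(t * t, rel=1e-9)

    def test_bonferroni_triples_raw_p(self, rng):
        res = glm_group_comparison(_toy_cohort(rng, shift=100.0))
        assert len(res.contrasts) == 3
        for c in res.contrasts:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted <= 1.0

    def test_holm_never_exceeds_bonferroni(self, rng):
        df = _toy_cohort(rng, shift=120.0)
        bonf = glm_group_comparison(df, fwe="bonferroni")
        holm = glm_group_comparison(df, fwe="holm")
        for cb, ch in zip(bonf.contrasts, holm.contrasts):
            assert ch.p_adjusted <= cb.p_adjusted + 1e-12

    def test_rank_deficient_design_raises(self, rng):
        df = _toy_cohort(rng)
        df["age"] = 50.0  # constant covariate collides with intercept
        with pytest.raises(ParameterError):
            glm_group_comparison(df)

    def test_single_group_raises(self, rng):
        df = _toy_cohort(rng)
        with pytest.raises(ParameterError):
            glm_group_comparison(df[df.group == "A"])
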