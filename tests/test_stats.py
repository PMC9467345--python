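"""Cohort statistics: closed-form oracles, published-table checks, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from ccflow.stats import (
    SummaryStat,
    chisq_2x2,
    partial_correlation,
    pearson_r,
    render_report_markdown,
    run_table_reports,
    ttest_two_sample,
)
from ccflow.synthetic import CohortParams, generate_cohort


class TestTTest:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ttest_two_sample(x, x.copy())
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_published_age_comparison(self):
        """Group ages 62.5±8.6 (n=32) vs 65.2±9.9 (n=30): p ≈ 0.254."""
        res = ttest_two_sample(SummaryStat(32, 62.5, 8.6), SummaryStat(30, 65.2, 9.9))
        assert res.p_value == pytest.approx(0.254, abs=0.01)

    def test_published_total_void_area_comparison(self):
        """1.16±0.18 (n=32) vs 0.91±0.16 (n=30) separates at p < 0.001."""
        res = ttest_two_sample(SummaryStat(32, 1.16, 0.18), SummaryStat(30, 0.91, 0.16))
        assert res.p_value < 0.001

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_summary_and_raw_paths_agree_exactly(self, variant):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.4, 1.3, 25)
        raw = ttest_two_sample(a, b, variant)
        summ = ttest_two_sample(SummaryStat.from_values(a), SummaryStat.from_values(b), variant)
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, rel=1e-12)

    @pytest.mark.parametrize("variant,equal_var", [("student", True), ("welch", False)])
    def test_against_scipy(self, variant, equal_var):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 18)
        res = ttest_two_sample(a, b, variant)
        ref = sps.ttest_ind(a, b, equal_var=equal_var)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            ttest_two_sample([1.0, 1.0, 1.0], [1.0, 1.0])


class TestChiSquare:
    def test_identical_proportions(self):
        res = chisq_2x2([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_published_sex_ratio_table(self):
        """25/7 vs 18/12 males/females: chi-square p ≈ 0.122 (no correction)."""
        res = chisq_2x2([[25, 7], [18, 12]])
        assert res.p_value == pytest.approx(0.122, abs=0.005)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 40, (2, 2))
        res = chisq_2x2(table)
        # direct Σ(O−E)²/E with margins computed by explicit loops
        n = table.sum()
        chi2 = 0.0
        for i in range(2):
            for j in range(2):
                e = table[i].sum() * table[:, j].sum() / n
                chi2 += (table[i, j] - e) ** 2 / e
        assert res.statistic == pytest.approx(chi2)

    def test_yates_matches_scipy(self):
        table = [[25, 7], [18, 12]]
        res = chisq_2x2(table, yates=True)
        chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2([[0, 0], [5, 3]])


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, -2 * x + 7)
        assert r == pytest.approx(-1.0)

    def test_against_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r, p = pearson_r(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_simulation_is_centred_and_calibrated(self):
        """Independent draws (n=25): mean r near 0, α=0.05 size in [0.03, 0.07]."""
        rng = np.random.default_rng(3)
        rs, rejects = [], 0
        n_rep = 500
        for _ in range(n_rep):
            x, y = rng.normal(size=25), rng.normal(size=25)
            r, p = pearson_r(x, y)
            rs.append(r)
            rejects += p < 0.05
        assert abs(np.mean(rs)) < 0.05
        assert 0.03 <= rejects / n_rep <= 0.07

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = partial_correlation(x, y)
        r, p = pearson_r(x, y)
        assert res.statistic == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_orthogonal_covariate_leaves_r_unchanged(self):
        n = 64
        x = np.tile([1.0, -1.0], n // 2)
        y = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        z = np.ones(n)
        z[n // 2:] = -1.0  # orthogonal to both x and y by construction
        res = partial_correlation(x, y, z)
        r, _ = pearson_r(x, y)
        assert res.statistic == pytest.approx(r, abs=1e-10)

    def test_recursive_formula_oracle_two_covariates(self):
        """Matches the textbook recursion on the pairwise correlation matrix."""
        rng = np.random.default_rng(5)
        n = 50
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        x = 0.5 * z1 + rng.normal(size=n)
        y = -0.3 * z1 + 0.4 * z2 + rng.normal(size=n)

        def r_of(a, b):
            return np.corrcoef(a, b)[0, 1]

        def partial1(rxy, rxz, ryz):
            return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))

        # r_xy.z1 z2 by recursion: partial out z1, then z2
        rxy_1 = partial1(r_of(x, y), r_of(x, z1), r_of(y, z1))
        rxz2_1 = partial1(r_of(x, z2), r_of(x, z1), r_of(z2, z1))
        ryz2_1 = partial1(r_of(y, z2), r_of(y, z1), r_of(z2, z1))
        expected = partial1(rxy_1, rxz2_1, ryz2_1)
        res = partial_correlation(x, y, np.column_stack([z1, z2]))
        assert res.statistic == pytest.approx(expected, abs=1e-10)
        assert res.df == n - 4

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        n = 40
        df = pd.DataFrame({
            "x": rng.normal(size=n), "y": rng.normal(size=n),
            "a": rng.normal(size=n), "b": rng.integers(0, 2, n).astype(float),
        })
        res = partial_correlation(df.x, df.y, df[["a", "b"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.p_value == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-9)

    def test_y_identical_to_covariate_rejected(self):
        rng = np.random.default_rng(7)
        x, z = rng.normal(size=20), rng.normal(size=20)
        with pytest.raises(ValueError, match="zero"):
            partial_correlation(x, z, z)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(8)
        x, y, z = rng.normal(size=20), rng.normal(size=20), rng.normal(size=20)
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))


class TestTableReports:
    def test_single_group_cohort_notes_missing_comparisons(self):
        import dataclasses

        p = CohortParams(seed=0)
        p = dataclasses.replace(p, control=dataclasses.replace(p.control, n=0))
        report = run_table_reports(generate_cohort(p))
        assert report["characteristics"] == {}
        assert any("one group" in n for n in report["notices"])

    def test_report_is_deterministic(self):
        cohort = generate_cohort(CohortParams(seed=3))
        a = render_report_markdown(run_table_reports(cohort))
        b = render_report_markdown(run_table_reports(cohort.copy()))
        assert a == b

    def test_group_comparisons_match_direct_tests(self):
        cohort = generate_cohort(CohortParams(seed=4))
        report = run_table_reports(cohort)
        a = cohort.loc[cohort.group == "PPE", "sfct_um"]
        b = cohort.loc[cohort.group == "control", "sfct_um"]
        assert report["characteristics"]["sfct_um"]["p"] == \
            pytest.approx(ttest_two_sample(a, b).p_value)
        assert "pachyvessel_split" in report
        assert "rpe_vein_distance_um" in report["pachyvessel_split"]

    def test_adjusted_p_uses_age_sex_partial_correlation(self):
        cohort = generate_cohort(CohortParams(seed=5))
        report = run_table_reports(cohort)
        ind = (cohort.group == "PPE").to_numpy(float)
        covs = np.column_stack([cohort.age.to_numpy(),
                                (cohort.sex == "M").to_numpy(float)])
        expected = partial_correlation(ind, cohort.total_void_area_mm2.to_numpy(), covs)
        assert report["flow_voids"]["total_void_area_mm2"]["p_adj"] == \
            pytest.approx(expected.p_value)

    def test_missing_columns_named(self):
        cohort = generate_cohort(CohortParams(seed=6)).drop(columns=["sfct_um"])
        with pytest.raises(ValueError, match="sfct_um"):
            run_table_reports(cohort)
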