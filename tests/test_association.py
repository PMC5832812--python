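import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from uratepath import (
    DEFAULT_PANEL,
    fisher_allelic_test,
    hwe_report,
    hwe_test,
    linear_snp_assoc,
    logistic_snp_assoc,
    run_association_scan,
)
from uratepath.association import (
    MonomorphicError,
    SCAN_CELLS,
    SeparationError,
    cochran_armitage_trend,
)
from .conftest import make_cohort
from .oracles import fisher_two_sided_enumeration, ols_normal_equations


class TestHwe:
    @pytest.mark.parametrize(
        "counts, stat, p",
        [
            ((25, 50, 25), 0.0, 1.0),          # exact HWE proportions
            ((0, 0, 50), 0.0, 1.0),            # monomorphic path
            ((50, 0, 0), 0.0, 1.0),
        ],
    )
    def test_degenerate_and_exact_cases(self, counts, stat, p):
        got_stat, got_p = hwe_test(counts)
        assert got_stat == pytest.approx(stat, abs=1e-12)
        assert got_p == pytest.approx(p)

    def test_hand_computed_deviation(self):
        # q=0.5 -> expected (7.5, 15, 7.5); chi2 = 2*(2.5^2/7.5) + 5^2/15
        stat, p = hwe_test((10, 10, 10))
        assert stat == pytest.approx(10 / 3, rel=1e-12)
        assert p == pytest.approx(st.chi2.sf(10 / 3, 1), rel=1e-12)
        assert 0.06 < p < 0.08

    def test_report_covers_panel(self, small_cohort):
        rep = hwe_report(small_cohort, DEFAULT_PANEL)
        assert len(rep) == len(DEFAULT_PANEL)
        assert (rep["p"] > 0.001).all()  # generated under HWE


class TestLinearAssoc:
    def test_noiseless_recovery_is_exact(self):
        dosage = np.tile([0, 1, 2], 20)
        cohort = make_cohort({"rs1": dosage}, urate=300.0 + 10.0 * dosage)
        res = linear_snp_assoc(cohort, "rs1")
        assert res.beta == pytest.approx(10.0, abs=1e-9)
        assert res.p < 1e-30

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 12
        dosage = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2], dtype=float)
        age = np.array([40, 45, 50, 55, 60, 65, 42, 47, 52, 57, 62, 67], dtype=float)
        urate = 300 + 8 * dosage + 0.4 * age + rng.normal(0, 20, n)
        cohort = make_cohort({"rs1": dosage.astype(int)}, urate=urate, age=age)
        res = linear_snp_assoc(cohort, "rs1")

        coefs_full, rss_full, df_full = ols_normal_equations([dosage, age], urate)
        _, rss_red, _ = ols_normal_equations([age], urate)
        f = (rss_red - rss_full) / (rss_full / df_full)
        assert res.beta == pytest.approx(coefs_full[1], rel=1e-10)
        assert res.p == pytest.approx(float(st.f.sf(f, 1, df_full)), rel=1e-10)

    def test_monomorphic_stratum_raises(self):
        cohort = make_cohort({"rs1": np.ones(20, dtype=int)},
                             urate=np.linspace(250, 450, 20))
        with pytest.raises(MonomorphicError, match="monomorphic in stratum"):
            linear_snp_assoc(cohort, "rs1")

    def test_collinear_covariate_named(self):
        dosage = np.tile([0, 1, 2], 8)
        cohort = make_cohort({"rs1": dosage}, urate=300.0 + dosage,
                             age=np.full(24, 50.0),
                             sex=["male", "female"] * 12)
        # age is constant -> collinear with the intercept
        with pytest.raises(ValueError, match="age"):
            linear_snp_assoc(cohort, "rs1")

    def test_deviance_p_equals_squared_t_p(self):
        """1-df nested F-test == squared-t test from the coefficient table."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 200
        dosage = rng.binomial(2, 0.3, n)
        age = rng.uniform(30, 70, n)
        urate = 320 + 5 * dosage + 0.5 * age + rng.normal(0, 60, n)
        cohort = make_cohort({"rs1": dosage}, urate=urate, age=age)
        res = linear_snp_assoc(cohort, "rs1")
        x = sm.add_constant(pd.DataFrame({"dosage": dosage, "age": age}))
        fit = sm.OLS(urate, x).fit()
        assert res.p == pytest.approx(float(fit.pvalues["dosage"]), rel=1e-10)

    def test_beta_sign_flips_under_allele_recoding(self):
        rng = np.random.default_rng(3)
        dosage = rng.binomial(2, 0.4, 100)
        urate = 330 + 6.0 * dosage + rng.normal(0, 40, 100)
        a = make_cohort({"rs1": dosage}, urate=urate)
        b = make_cohort({"rs1": 2 - dosage}, urate=urate)
        ra, rb = linear_snp_assoc(a, "rs1"), linear_snp_assoc(b, "rs1")
        assert ra.beta == pytest.approx(-rb.beta, rel=1e-9)
        assert ra.p == pytest.approx(rb.p, rel=1e-9)


def _case_control_cohort(case_doses, comp_doses):
    dosage = list(case_doses) + list(comp_doses)
    status = ["gout"] * len(case_doses) + ["control"] * len(comp_doses)
    return make_cohort({"rs1": dosage}, urate=np.full(len(dosage), 300.0), status=status)


class TestFisherAllelic:
    def test_or_16_against_enumeration(self):
        # 5 cases with 8 effect/2 other alleles; 5 comparisons reversed
        cohort = _case_control_cohort([2, 2, 2, 1, 1], [0, 0, 0, 1, 1])
        res = fisher_allelic_test(cohort, "rs1", "gout_vs_control")
        assert res.odds_ratio == pytest.approx(16.0)
        p_oracle, num, den = fisher_two_sided_enumeration([[8, 2], [2, 8]])
        assert (num, den) == (4252, 184756)
        assert res.p == pytest.approx(p_oracle, rel=1e-10)

    def test_symmetric_groups_give_or_1_p_1(self):
        cohort = _case_control_cohort([2, 2, 1, 0, 0], [2, 2, 1, 0, 0])
        res = fisher_allelic_test(cohort, "rs1", "gout_vs_control")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_cell_gets_haldane_correction(self):
        # cases 10 effect/0 other vs comparisons 5/5
        cohort = _case_control_cohort([2] * 5, [2, 2, 1, 0, 0])
        res = fisher_allelic_test(cohort, "rs1", "gout_vs_control")
        assert res.flag == "haldane"
        assert res.odds_ratio == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))
        p_oracle, _, _ = fisher_two_sided_enumeration([[10, 0], [5, 5]])
        assert res.p == pytest.approx(p_oracle, rel=1e-10)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        gout = rng.binomial(2, 0.35, 30)
        ctrl = rng.binomial(2, 0.25, 40)
        a = _case_control_cohort(gout, ctrl)
        # swap: controls as "cases" via the reversed contrast table
        dosage = list(ctrl) + list(gout)
        status = ["gout"] * len(ctrl) + ["control"] * len(gout)
        b = make_cohort({"rs1": dosage}, urate=np.full(len(dosage), 300.0), status=status)
        ra = fisher_allelic_test(a, "rs1", "gout_vs_control")
        rb = fisher_allelic_test(b, "rs1", "gout_vs_control")
        assert ra.p == pytest.approx(rb.p, rel=1e-12)
        assert ra.odds_ratio == pytest.approx(1.0 / rb.odds_ratio, rel=1e-12)

    def test_degenerate_identical_alleles_flagged(self):
        cohort = _case_control_cohort([0, 0, 0], [0, 0, 0])
        res = fisher_allelic_test(cohort, "rs1", "gout_vs_control")
        assert res.p == 1.0 and res.odds_ratio is None and res.flag == "degenerate"

    def test_empty_group_is_error(self):
        cohort = make_cohort({"rs1": [1, 2]}, urate=[300.0, 310.0],
                             status=["gout", "gout"])
        with pytest.raises(ValueError, match="empty"):
            fisher_allelic_test(cohort, "rs1", "gout_vs_control")


class TestLogistic:
    def test_collapses_to_allele_cross_product_on_two_point_dosage(self):
        rng = np.random.default_rng(8)
        dosage = np.repeat([0, 2], 400)
        p_case = np.where(dosage == 2, 0.45, 0.25)
        status = np.where(rng.random(800) < p_case, "gout", "control")
        cohort = make_cohort({"rs1": dosage}, urate=np.full(800, 300.0), status=status)
        res = logistic_snp_assoc(cohort, "rs1", "gout_vs_control", covariates=())
        # genotype-level 2x2 cross-product on dosage/2 scale
        case2 = np.sum((dosage == 2) & (status == "gout"))
        case0 = np.sum((dosage == 0) & (status == "gout"))
        ctrl2 = np.sum((dosage == 2) & (status == "control"))
        ctrl0 = np.sum((dosage == 0) & (status == "control"))
        or_table = (case2 * ctrl0) / (case0 * ctrl2)
        assert res.odds_ratio**2 == pytest.approx(or_table, rel=0.01)

    def test_separation_is_reported_with_direction(self):
        dosage = np.repeat([0, 2], 10)
        status = ["control"] * 10 + ["gout"] * 10
        cohort = make_cohort({"rs1": dosage}, urate=np.full(20, 300.0), status=status)
        with pytest.raises(SeparationError, match="positive"):
            logistic_snp_assoc(cohort, "rs1", "gout_vs_control", covariates=())

    def test_null_wald_p_is_calibrated(self):
        """Type-I error of the Wald test near nominal under the null."""
        rng = np.random.default_rng(17)
        n, reps = 800, 200
        pvals = []
        for _ in range(reps):
            dosage = rng.binomial(2, 0.3, n)
            status = np.where(rng.random(n) < 0.3, "gout", "control")
            cohort = make_cohort({"rs1": dosage}, urate=np.full(n, 300.0), status=status)
            pvals.append(logistic_snp_assoc(cohort, "rs1", "gout_vs_control",
                                            covariates=()).p)
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.01 <= rate <= 0.10
        assert st.kstest(pvals, "uniform").pvalue > 0.01


class TestTrendAlternative:
    def test_agrees_with_fisher_direction_on_strong_signal(self):
        rng = np.random.default_rng(4)
        gout = rng.binomial(2, 0.45, 200)
        ctrl = rng.binomial(2, 0.25, 200)
        cohort = _case_control_cohort(gout, ctrl)
        trend = cochran_armitage_trend(cohort, "rs1", "gout_vs_control")
        fisher = fisher_allelic_test(cohort, "rs1", "gout_vs_control")
        assert trend.p < 0.01 and fisher.p < 0.01


class TestScan:
    def test_grid_shape_and_fdr_population(self, small_cohort, config):
        results = run_association_scan(small_cohort, DEFAULT_PANEL, config)
        assert len(results) == len(SCAN_CELLS) * len(DEFAULT_PANEL)
        ok = [r for r in results if not r.flag or r.flag in ("haldane", "degenerate")]
        assert all(r.p_fdr is not None for r in ok)
        # a well-populated cohort should test every cell bar sparse BMI bins
        flagged = [r for r in results if r.flag not in ("", "haldane", "degenerate")]
        assert len(flagged) < len(results) * 0.25

    def test_single_snp_panel_fdr_is_identity(self, small_cohort, config):
        results = run_association_scan(small_cohort, DEFAULT_PANEL[:1], config)
        for r in results:
            if r.p is not None and not r.flag:
                assert r.p_fdr == pytest.approx(r.p)
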