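"""Univariate ACE engine: covariance assembly, FIML, CIs, boundary tests."""

import numpy as np
import pytest
from scipy import stats

from twinvolve import (
    CohortDesign,
    TraitSpec,
    VarianceComponents,
    fit_ace,
    generate_cohort,
    lrt,
    profile_ci,
    simulate_phenotypes,
    standardize,
)
from twinvolve.ace_uni import expected_family_cov, family_loglik
from twinvolve.reshape import RelatednessCoefficients, to_family_records
from tests.conftest import make_cohort


def _pair_rel(rA_off):
    rA = np.array([[1.0, rA_off], [rA_off, 1.0]])
    return RelatednessCoefficients(rA=rA, rC=np.ones((2, 2)))


class TestExpectedFamilyCov:
    def test_mz_pair(self):
        cov = expected_family_cov(VarianceComponents(2, 1, 1), _pair_rel(1.0))
        np.testing.assert_allclose(cov, [[4, 3], [3, 4]])

    def test_dz_pair_off_diagonal(self):
        cov = expected_family_cov(VarianceComponents(2, 1, 1), _pair_rel(0.5))
        assert cov[0, 1] == pytest.approx(2.0)

    def test_no_familial_variance_is_diagonal(self):
        cov = expected_family_cov(VarianceComponents(0, 0, 3), _pair_rel(0.5))
        np.testing.assert_allclose(cov, 3 * np.eye(2))


class TestFamilyLoglik:
    def test_complete_data_matches_scipy_density(self, small_records):
        comp = VarianceComponents(2e5, 5e4, 1e5)
        beta = np.array([5500.0, 10.0, -5.0])
        rec = next(r for r in small_records if r.n_members == 2)
        mine = family_loglik(rec, comp, beta)
        sigma = expected_family_cov(comp, rec.relatedness)
        oracle = stats.multivariate_normal.logpdf(rec.y, mean=rec.X @ beta, cov=sigma)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_missing_member_marginalizes(self, small_records):
        comp = VarianceComponents(2e5, 5e4, 1e5)
        beta = np.array([5500.0, 10.0, -5.0])
        rec = next(r for r in small_records if r.n_members == 2)
        y = rec.y.copy()
        y[1] = np.nan
        from dataclasses import replace

        partial = replace(rec, y=y)
        marginal = stats.norm.logpdf(
            rec.y[0], loc=(rec.X @ beta)[0], scale=np.sqrt(comp.V)
        )
        assert family_loglik(partial, comp, beta) == pytest.approx(marginal, abs=1e-10)

    def test_likelihood_peaks_near_generating_parameters(self, vermis_trait):
        cohort = make_cohort(CohortDesign(400, 250, 300), [vermis_trait], seed=21)
        records = to_family_records(cohort, ["Cbm_Vermis"])
        v = vermis_trait.total_sd**2
        truth = VarianceComponents(vermis_trait.a2 * v, vermis_trait.c2 * v,
                                   vermis_trait.e2 * v)
        beta = np.array([vermis_trait.mean, 0.0, 0.0])
        ll_truth = sum(family_loglik(r, truth, beta) for r in records)
        perturbed = VarianceComponents(0.3 * v, 0.5 * v, 0.2 * v)
        ll_pert = sum(family_loglik(r, perturbed, beta) for r in records)
        assert ll_truth > ll_pert


class TestFitACE:
    def test_recovers_generating_proportions(self, vermis_trait):
        cohort = make_cohort(CohortDesign(500, 300, 300), [vermis_trait], seed=31)
        fit = fit_ace(to_family_records(cohort, ["Cbm_Vermis"]), n_starts=3)
        assert fit.converged
        assert fit.a2 == pytest.approx(vermis_trait.a2, abs=0.12)
        assert fit.e2 == pytest.approx(vermis_trait.e2, abs=0.06)

    def test_boundary_a2_zero(self):
        trait = TraitSpec("x", 0, 1, a2=0.0, c2=0.5, e2=0.5)
        cohort = make_cohort(CohortDesign(200, 150, 100), [trait], seed=32)
        records = to_family_records(cohort, ["x"])
        ace = fit_ace(records, "ACE", n_starts=3)
        ce = fit_ace(records, "CE", n_starts=3)
        assert ace.a2 < 0.15
        assert ce.minus2lnl == pytest.approx(ace.minus2lnl, abs=0.5)

    def test_ae_submodel_forces_c_zero(self, small_records):
        fit = fit_ace(small_records, "AE", n_starts=2)
        assert fit.components.C == 0.0
        assert fit.c2 == 0.0

    def test_nesting_monotonicity(self, small_records):
        fits = {m: fit_ace(small_records, m, n_starts=3) for m in ("ACE", "AE", "CE", "E")}
        tol = 1e-6
        assert fits["ACE"].minus2lnl <= fits["AE"].minus2lnl + tol
        assert fits["ACE"].minus2lnl <= fits["CE"].minus2lnl + tol
        assert fits["AE"].minus2lnl <= fits["E"].minus2lnl + tol
        assert fits["CE"].minus2lnl <= fits["E"].minus2lnl + tol

    def test_proportions_sum_to_one(self, small_records):
        fit = fit_ace(small_records, n_starts=2)
        assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-8)

    def test_scale_invariance_of_proportions(self, small_cohort):
        scaled = small_cohort.copy()
        scaled["Cbm_Vermis"] = scaled["Cbm_Vermis"] * 1000.0
        f1 = fit_ace(to_family_records(small_cohort, ["Cbm_Vermis"]), n_starts=2)
        f2 = fit_ace(to_family_records(scaled, ["Cbm_Vermis"]), n_starts=2)
        assert f1.a2 == pytest.approx(f2.a2, abs=2e-3)
        assert f1.c2 == pytest.approx(f2.c2, abs=2e-3)

    def test_family_order_invariance(self, small_records):
        rev = list(reversed(small_records))
        f1 = fit_ace(small_records, n_starts=2)
        f2 = fit_ace(rev, n_starts=2)
        assert f1.minus2lnl == pytest.approx(f2.minus2lnl, abs=1e-4)
        assert f1.a2 == pytest.approx(f2.a2, abs=1e-3)

    def test_mar_missingness_consistent_with_complete(self, vermis_trait):
        full_spec = vermis_trait
        miss_spec = TraitSpec("Cbm_Vermis", full_spec.mean, full_spec.total_sd,
                              full_spec.a2, full_spec.c2, full_spec.e2,
                              missing_rate=0.2)
        design = CohortDesign(600, 400, 400)
        cohort_full = make_cohort(design, [full_spec], seed=41)
        cohort_miss = simulate_phenotypes(
            generate_cohort(design, 41), [miss_spec], seed=42
        )
        f_full = fit_ace(to_family_records(cohort_full, ["Cbm_Vermis"]), n_starts=3)
        f_miss = fit_ace(to_family_records(cohort_miss, ["Cbm_Vermis"]), n_starts=3)
        assert f_miss.a2 == pytest.approx(f_full.a2, abs=0.1)

    def test_implied_mz_minus_dz_covariance_nonnegative(self, small_records):
        fit = fit_ace(small_records, n_starts=2)
        comp = fit.components
        mz = expected_family_cov(comp, _pair_rel(1.0))[0, 1]
        dz = expected_family_cov(comp, _pair_rel(0.5))[0, 1]
        assert mz - dz == pytest.approx(0.5 * comp.A, abs=1e-9)
        assert mz - dz >= 0

    def test_unknown_model_rejected(self, small_records):
        with pytest.raises(ValueError):
            fit_ace(small_records, "ADE")


class TestStandardize:
    def test_arithmetic(self):
        assert standardize(VarianceComponents(8.4, 0.4, 1.2))[0] == pytest.approx(0.84)

    def test_zero_a(self):
        a2, c2, e2 = standardize(VarianceComponents(0.0, 2.0, 3.0))
        assert a2 == 0.0 and c2 == pytest.approx(0.4)

    def test_e_only(self):
        assert standardize(VarianceComponents(0, 0, 5.0))[2] == 1.0


class TestProfileCI:
    def test_interval_brackets_estimate(self, small_records):
        fit = fit_ace(small_records, n_starts=3)
        ci = profile_ci(small_records, fit, "a2")
        assert ci.lower <= fit.a2 <= ci.upper
        assert 0.0 <= ci.lower and ci.upper <= 1.0

    def test_boundary_lower_bound_is_zero(self):
        trait = TraitSpec("x", 0, 1, a2=0.0, c2=0.5, e2=0.5)
        cohort = make_cohort(CohortDesign(120, 80, 60), [trait], seed=55)
        records = to_family_records(cohort, ["x"])
        fit = fit_ace(records, n_starts=3)
        ci = profile_ci(records, fit, "a2")
        assert ci.lower == pytest.approx(0.0, abs=1e-6)

    def test_width_shrinks_with_sample_size(self, vermis_trait):
        widths = []
        for scale in (1, 2):
            design = CohortDesign(120 * scale, 80 * scale, 60 * scale)
            cohort = make_cohort(design, [vermis_trait], seed=60 + scale)
            records = to_family_records(cohort, ["Cbm_Vermis"])
            fit = fit_ace(records, n_starts=3)
            ci = profile_ci(records, fit, "a2")
            widths.append(ci.upper - ci.lower)
        assert widths[1] < widths[0]


class TestLRT:
    def test_mixture_p_at_critical_value(self, small_records):
        # synthetic fits carrying the deviances of interest
        full = fit_ace(small_records, "ACE", n_starts=2)
        from dataclasses import replace

        reduced = fit_ace(small_records, "CE", n_starts=2)
        reduced = replace(reduced, minus2lnl=full.minus2lnl + 3.841)
        res = lrt(full, reduced)
        assert res.p_value == pytest.approx(0.025, abs=5e-4)

    def test_zero_deviance_gives_p_one(self, small_records):
        from dataclasses import replace

        full = fit_ace(small_records, "ACE", n_starts=2)
        reduced = replace(fit_ace(small_records, "AE", n_starts=2),
                          minus2lnl=full.minus2lnl)
        assert lrt(full, reduced).p_value == 1.0

    def test_two_df_mixture(self, small_records):
        from dataclasses import replace

        full = fit_ace(small_records, "ACE", n_starts=2)
        reduced = replace(fit_ace(small_records, "E", n_starts=1),
                          minus2lnl=full.minus2lnl + 5.0)
        expected = 0.5 * stats.chi2.sf(5.0, 1) + 0.25 * stats.chi2.sf(5.0, 2)
        assert lrt(full, reduced).p_value == pytest.approx(expected, abs=1e-10)

    def test_non_nested_rejected(self, small_records):
        ae = fit_ace(small_records, "AE", n_starts=1)
        ce = fit_ace(small_records, "CE", n_starts=1)
        with pytest.raises(ValueError):
            lrt(ae, ce)
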