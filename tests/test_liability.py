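import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from twinliab import (
    PairContingencyTable,
    Zygosity,
    compare_models,
    contingency_from_records,
    fit_variance_model,
    orthant_probabilities,
    tetrachoric_mle,
    threshold_from_prevalence,
)
from twinliab.liability import (
    VarianceModelFit,
    bivariate_normal_cdf,
    tetrachoric_grid_search,
)

from conftest import records_from_counts


def expected_table(zygosity, rho, t, n):
    """Exact-expected-count 3-cell table under the liability model."""
    pb, po1, po2, pn = orthant_probabilities(t, t, rho)
    return PairContingencyTable(
        zygosity, round(pb * n), round((po1 + po2) * n), round(pn * n)
    )


class TestThreshold:
    def test_median_prevalence_gives_zero(self):
        assert threshold_from_prevalence(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_rare_disease_threshold(self):
        # inverse-normal oracle: upper tail 0.37% sits near 2.678 SD
        assert threshold_from_prevalence(0.0037) == pytest.approx(2.678, abs=1e-3)

    @pytest.mark.parametrize("K", [0.5, 0.1, 0.0037, 0.9])
    def test_round_trip(self, K):
        assert norm.sf(threshold_from_prevalence(K)) == pytest.approx(K, abs=1e-12)

    @pytest.mark.parametrize("K", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_prevalence_rejected(self, K):
        with pytest.raises(ValueError):
            threshold_from_prevalence(K)


class TestBivariateNormal:
    def test_matches_scipy_mvn(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            h, k = rng.normal(scale=2, size=2)
            rho = rng.uniform(-0.99, 0.99)
            ref = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert bivariate_normal_cdf(h, k, rho) == pytest.approx(ref, abs=1e-10)

    def test_zero_thresholds_closed_form(self):
        for rho in (-0.8, -0.3, 0.0, 0.5, 0.95):
            assert bivariate_normal_cdf(0.0, 0.0, rho) == pytest.approx(
                0.25 + np.arcsin(rho) / (2 * np.pi), abs=1e-10)

    def test_comonotone_and_antithetic_limits(self):
        assert bivariate_normal_cdf(1.0, 2.0, 1.0) == pytest.approx(norm.cdf(1.0))
        assert bivariate_normal_cdf(-1.0, 0.5, -1.0) == pytest.approx(
            max(norm.cdf(-1.0) + norm.cdf(0.5) - 1, 0.0))


class TestOrthantProbabilities:
    def test_independence_factorizes(self):
        t1, t2 = 1.2, 0.4
        pb, po1, po2, pn = orthant_probabilities(t1, t2, 0.0)
        assert pb == pytest.approx(norm.sf(t1) * norm.sf(t2), abs=1e-12)

    def test_perfect_correlation_concentrates_mass(self):
        t = 2.678
        pb, po1, po2, pn = orthant_probabilities(t, t, 1.0)
        assert pb == pytest.approx(norm.sf(t), abs=1e-12)
        assert po1 == pytest.approx(0.0, abs=1e-12)
        assert po2 == pytest.approx(0.0, abs=1e-12)

    def test_against_brute_force_quadrature(self):
        # direct 2-D integration of the bivariate normal density
        t, rho = 2.678, 0.6
        det = 1 - rho**2

        def density(y, x):
            return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * det)) / (
                2 * np.pi * np.sqrt(det))

        ref, err = integrate.dblquad(density, t, 8.0, t, 8.0, epsabs=1e-12)
        pb = orthant_probabilities(t, t, rho)[0]
        assert pb == pytest.approx(ref, abs=1e-8)

    def test_probabilities_sum_to_one_on_rho_grid(self):
        for rho in np.linspace(-0.99, 0.99, 41):
            probs = orthant_probabilities(1.5, -0.3, rho)
            assert sum(probs) == pytest.approx(1.0, abs=1e-10)

    def test_p_both_strictly_increasing_in_rho(self):
        rhos = np.linspace(-0.95, 0.95, 39)
        pb = np.array([orthant_probabilities(2.0, 2.0, r)[0] for r in rhos])
        assert np.all(np.diff(pb) >= 0)
        # strict once above double-precision underflow of the deep tail
        visible = pb[pb > 1e-12]
        assert np.all(np.diff(visible) > 0)
        assert len(visible) > 30

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            orthant_probabilities(1.0, 1.0, 1.5)


class TestTetrachoricMLE:
    def test_independence_recovery(self):
        t = threshold_from_prevalence(0.1)
        table = expected_table(Zygosity.MZ, 0.0, t, 10**6)
        est = tetrachoric_mle(table)
        assert est.rho == pytest.approx(0.0, abs=1e-5)
        assert est.ci_low < 0 < est.ci_high

    def test_self_consistent_recovery_at_rare_prevalence(self):
        t = threshold_from_prevalence(0.0037)
        table = expected_table(Zygosity.MZ, 0.60, t, 10**6)
        est = tetrachoric_mle(table)
        assert est.rho == pytest.approx(0.60, abs=0.01)
        assert est.threshold == pytest.approx(t, abs=0.01)
        assert est.ci_low <= est.rho <= est.ci_high

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = int(rng.integers(100, 3000))
            p = rng.dirichlet([2.0, 5.0, 20.0])
            nb, no, nn = rng.multinomial(n, p)
            if nn == 0 or nb + no == 0:
                continue
            table = PairContingencyTable(Zygosity.MZ, int(nb), int(no), int(nn))
            est = tetrachoric_mle(table)
            rho_grid, t_grid, ll_grid = tetrachoric_grid_search(table)
            assert est.rho == pytest.approx(rho_grid, abs=1e-4)
            assert est.loglik >= ll_grid - 1e-6

    def test_fixed_prevalence_threshold(self):
        t = threshold_from_prevalence(0.05)
        table = expected_table(Zygosity.MZ, 0.4, t, 10**5)
        est = tetrachoric_mle(table, prevalence=0.05)
        assert est.threshold == pytest.approx(t)
        assert est.rho == pytest.approx(0.4, abs=0.01)

    def test_degenerate_all_concordant_reports_boundary(self):
        table = PairContingencyTable(Zygosity.MZ, 10, 0, 0)
        with pytest.warns(UserWarning, match="degenerate"):
            est = tetrachoric_mle(table)
        assert est.rho == 1.0

    def test_no_unaffected_pairs_needs_prevalence(self):
        table = PairContingencyTable(Zygosity.MZ, 5, 5, 0)
        with pytest.raises(ValueError, match="prevalence"):
            tetrachoric_mle(table)


class TestVarianceModels:
    def test_equal_correlations_zero_additive(self):
        t = threshold_from_prevalence(0.05)
        tables = [expected_table(Zygosity.MZ, 0.5, t, 10**5),
                  expected_table(Zygosity.DZss, 0.5, t, 10**5)]
        fit = fit_variance_model(tables, "ACE", compute_ci=False)
        assert fit.a2 == pytest.approx(0.0, abs=1e-3)
        assert fit.c2 == pytest.approx(0.5, abs=0.01)

    def test_uncorrelated_liability_is_pure_e(self):
        t = threshold_from_prevalence(0.05)
        tables = [expected_table(Zygosity.MZ, 0.0, t, 10**5),
                  expected_table(Zygosity.DZss, 0.0, t, 10**5)]
        ace = fit_variance_model(tables, "ACE", compute_ci=False)
        e_only = fit_variance_model(tables, "E", compute_ci=False)
        assert ace.e2 == pytest.approx(1.0, abs=1e-3)
        assert ace.loglik == pytest.approx(e_only.loglik, abs=1e-3)

    def test_component_recovery_from_expected_tables(self):
        a2, c2 = 0.12, 0.50
        t = threshold_from_prevalence(0.0037)
        tables = [expected_table(Zygosity.MZ, a2 + c2, t, 10**6),
                  expected_table(Zygosity.DZss, 0.5 * a2 + c2, t, 10**6),
                  expected_table(Zygosity.DZos, 0.5 * a2 + c2, t, 10**6)]
        fit = fit_variance_model(tables, "ACE", compute_ci=False)
        assert fit.a2 == pytest.approx(0.12, abs=0.02)
        assert fit.c2 == pytest.approx(0.50, abs=0.02)
        assert fit.e2 == pytest.approx(0.38, abs=0.02)
        assert fit.components()["a2"] + fit.c2 + fit.d2 + fit.e2 == pytest.approx(1.0)

    def test_profile_ci_brackets_estimate_and_hits_boundary(self):
        # desk-scale data: wide CIs reaching the boundary are expected
        t = threshold_from_prevalence(0.01)
        tables = [expected_table(Zygosity.MZ, 0.6, t, 20000),
                  expected_table(Zygosity.DZss, 0.55, t, 20000)]
        fit = fit_variance_model(tables, "ACE", compute_ci=True)
        lo, hi = fit.component_ci["a2"]
        assert lo <= fit.a2 <= hi
        assert lo == 0.0  # weak identification of A at this scale
        lo_e, hi_e = fit.component_ci["e2"]
        assert lo_e <= fit.e2 <= hi_e

    def test_per_sex_thresholds(self, small_cohort):
        _, records, _ = small_cohort
        tables = []
        for z in Zygosity:
            tables.extend(contingency_from_records(records, z, by_sex=True))
        fit = fit_variance_model(tables, "ACE", sex_layout="per-sex", compute_ci=False)
        assert set(fit.thresholds) == {"F", "M"}
        assert fit.n_free_params == 4

    def test_invalid_structure_rejected(self):
        t = threshold_from_prevalence(0.05)
        tables = [expected_table(Zygosity.MZ, 0.5, t, 1000),
                  expected_table(Zygosity.DZss, 0.4, t, 1000)]
        with pytest.raises(ValueError, match="structure"):
            fit_variance_model(tables, "ACDE")

    def test_requires_both_zygosity_classes(self):
        t = threshold_from_prevalence(0.05)
        with pytest.raises(ValueError, match="MZ"):
            fit_variance_model([expected_table(Zygosity.DZss, 0.4, t, 1000)], "ACE")


class TestModelComparison:
    def _fit(self, structure, loglik, k):
        return VarianceModelFit(structure=structure, a2=0.1, c2=0.2, d2=0.0, e2=0.7,
                                thresholds={"common": 2.0}, loglik=loglik,
                                aic=-2 * loglik + 2 * k, n_free_params=k)

    def test_identical_fits_have_zero_delta(self):
        cmp_ = compare_models([self._fit("ACE", -100.0, 3), self._fit("CE", -100.0, 2)])
        assert cmp_.delta_aic["CE"] == 0.0
        assert cmp_.delta_aic["ACE"] == pytest.approx(2.0)
        assert cmp_.selected == "CE"

    def test_equal_loglik_nested_pair(self):
        cmp_ = compare_models([self._fit("ACE", -50.0, 3), self._fit("AE", -50.0, 2)])
        lrt = cmp_.lrt[("ACE", "AE")]
        assert lrt["stat"] == 0.0
        assert lrt["p_naive"] == pytest.approx(1.0)
        assert lrt["p_boundary"] == pytest.approx(1.0)
        # dropping a parameter at no likelihood cost lowers AIC by 2
        assert cmp_.delta_aic["ACE"] - cmp_.delta_aic["AE"] == pytest.approx(2.0)

    def test_aic_ranking_invariant_to_loglik_shift(self):
        fits_a = [self._fit("ACE", -100.0, 3), self._fit("CE", -104.0, 2)]
        fits_b = [self._fit("ACE", -600.0, 3), self._fit("CE", -604.0, 2)]
        assert compare_models(fits_a).selected == compare_models(fits_b).selected
        assert compare_models(fits_a).delta_aic == compare_models(fits_b).delta_aic

    def test_boundary_mixture_halves_naive_p(self):
        from scipy.stats import chi2
        cmp_ = compare_models([self._fit("ACE", -50.0, 3), self._fit("AE", -52.0, 2)])
        lrt = cmp_.lrt[("ACE", "AE")]
        assert lrt["stat"] == pytest.approx(4.0)
        assert lrt["p_boundary"] == pytest.approx(0.5 * chi2.sf(4.0, 1))

    def test_duplicate_structures_rejected(self):
        with pytest.raises(ValueError):
            compare_models([self._fit("ACE", -1.0, 3), self._fit("ACE", -1.0, 3)])
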