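"""Bivariate correlated-factors model: equivalence, recovery, decomposition."""

import math

import numpy as np
import pytest

from liabtwin.bivariate import (CorrelatedFactorsParams, PairTraitTable4x4,
                                _cell_probabilities, _table_nll, cf_to_cholesky,
                                cholesky_to_cf, ctct_expected, decompose_rph,
                                fit_bivariate, implied_pair_correlation,
                                pair_trait_table, profile_ci, two_stage_estimate)
from liabtwin.liability import sobol_points, threshold_from_prevalence


def expected_tables(params, n_mz=20000, n_dz=20000, n_points=1 << 14):
    u3, u4 = sobol_points(2, n_points), sobol_points(3, n_points)
    t = np.array([params.t1, params.t2, params.t1, params.t2])
    tabs = {}
    for z, n in (("MZ", n_mz), ("DZ", n_dz)):
        p = _cell_probabilities(t, implied_pair_correlation(params, z), u3, u4)
        tabs[z] = PairTraitTable4x4(z, n * p / p.sum())
    return tabs["MZ"], tabs["DZ"]


def epilepsy_autism_like_truth():
    """a1^2=0.90, a2^2=0.61, ra=0.5, re set so rPH=0.40."""
    a1, a2 = math.sqrt(0.90), math.sqrt(0.61)
    e1, e2 = math.sqrt(0.10), math.sqrt(0.39)
    re = (0.40 - a1 * a2 * 0.5) / (e1 * e2)
    return CorrelatedFactorsParams(
        t1=threshold_from_prevalence(0.016).t, t2=threshold_from_prevalence(0.012).t,
        a1=a1, c1=0.0, a2=a2, c2=0.0, ra=0.5, rc=0.0, re=re)


@pytest.fixture(scope="module")
def ea_fit_and_tables():
    truth = epilepsy_autism_like_truth()
    mz, dz = expected_tables(truth, 50000, 50000)
    fit = fit_bivariate(mz, dz, method="full")
    return truth, fit, mz, dz


class TestParameterizationEquivalence:
    def test_maps_round_trip_and_matrices_agree(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a1, c1 = rng.uniform(0.1, 0.7, 2)
            a2, c2 = rng.uniform(0.1, 0.7, 2)
            p = CorrelatedFactorsParams(
                t1=rng.uniform(0.5, 2), t2=rng.uniform(0.5, 2),
                a1=a1, c1=c1, a2=a2, c2=c2,
                ra=rng.uniform(-0.9, 0.9), rc=rng.uniform(-0.9, 0.9),
                re=rng.uniform(-0.9, 0.9))
            back = cholesky_to_cf(cf_to_cholesky(p))
            for field in ("a1", "c1", "a2", "c2", "ra", "rc", "re"):
                assert getattr(back, field) == pytest.approx(getattr(p, field),
                                                             abs=1e-12)
            for z in ("MZ", "DZ"):
                np.testing.assert_allclose(
                    implied_pair_correlation(cf_to_cholesky(p), z),
                    implied_pair_correlation(p, z), atol=1e-12)

    def test_identical_likelihood_under_both_parameterizations(self):
        truth = epilepsy_autism_like_truth()
        mz, dz = expected_tables(truth, 5000, 5000, n_points=1 << 12)
        u3, u4 = sobol_points(2, 1 << 12), sobol_points(3, 1 << 12)
        nll_cf = _table_nll(truth, mz, dz, u3, u4)
        nll_ch = _table_nll(cholesky_to_cf(cf_to_cholesky(truth)), mz, dz, u3, u4)
        assert abs(nll_cf - nll_ch) < 1e-6


class TestRecovery:
    def test_independent_traits_give_null_correlations(self):
        p = CorrelatedFactorsParams(t1=1.2, t2=1.5, a1=0.8, c1=0.2, a2=0.7,
                                    c2=0.3, ra=0.0, rc=0.0, re=0.0)
        mz, dz = expected_tables(p, 10000, 10000)
        est = two_stage_estimate(mz, dz)
        assert est.ra == pytest.approx(0.0, abs=0.02)
        assert est.rph == pytest.approx(0.0, abs=0.02)

    def test_self_consistency_on_expected_tables(self, ea_fit_and_tables):
        truth, fit, _, _ = ea_fit_and_tables
        p = fit.params
        assert p.a1**2 == pytest.approx(0.90, abs=1e-3)
        assert p.a2**2 == pytest.approx(0.61, abs=1e-3)
        assert p.ra == pytest.approx(0.5, abs=1e-3)
        assert fit.rph == pytest.approx(0.40, abs=1e-3)

    def test_genetic_share_of_rph_matches_published_pattern(self, ea_fit_and_tables):
        _, fit, _, _ = ea_fit_and_tables
        assert fit.bivariate_heritability == pytest.approx(0.93, abs=0.01)

    def test_profile_ci_tightens_with_n(self):
        truth = epilepsy_autism_like_truth()
        cis = {}
        for n in (4000, 16000):
            mz, dz = expected_tables(truth, n, n, n_points=1 << 11)
            fit = fit_bivariate(mz, dz, method="full", n_points=1 << 11,
                                maxiter=1200)
            u3, u4 = sobol_points(2, 1 << 11), sobol_points(3, 1 << 11)
            cis[n] = profile_ci(fit, mz, dz, "ra", u3=u3, u4=u4)
        width = {n: ci[1] - ci[0] for n, ci in cis.items()}
        assert width[16000] < width[4000]
        for n in cis:
            assert cis[n][0] < 0.5 < cis[n][1]


class TestDecomposition:
    def test_published_style_genetic_proportion(self):
        # genetic contribution 0.372 of rPH 0.40 -> proportion 0.93
        p = epilepsy_autism_like_truth()
        gen = p.a1 * p.a2 * p.ra
        assert gen == pytest.approx(0.372, abs=0.002)
        assert gen / p.rph == pytest.approx(0.93, abs=0.005)

    def test_pure_genetic_overlap_gives_unit_proportion(self):
        p = CorrelatedFactorsParams(t1=1.0, t2=1.0, a1=0.8, c1=0.0, a2=0.8,
                                    c2=0.0, ra=0.6, rc=0.0, re=0.0)
        mz, dz = expected_tables(p, 3000, 3000, n_points=1 << 11)
        fit = fit_bivariate(mz, dz, method="two_stage")
        dec = decompose_rph(fit)
        assert dec["bivariate_heritability"] == pytest.approx(1.0, abs=0.02)

    def test_contributions_match_implied_matrix_entries(self, ea_fit_and_tables):
        _, fit, _, _ = ea_fit_and_tables
        # within-person cross-trait entry of the implied matrix equals rPH
        R = implied_pair_correlation(fit.params, "MZ")
        assert sum(fit.contributions) == pytest.approx(R[0, 1], abs=1e-10)
        assert sum(fit.proportions) == pytest.approx(1.0, abs=1e-10)

    def test_near_zero_rph_flagged_undefined(self):
        p = CorrelatedFactorsParams(t1=1.0, t2=1.0, a1=0.7, c1=0.0, a2=0.7,
                                    c2=0.0, ra=0.0, rc=0.0, re=0.0)
        mz, dz = expected_tables(p, 1000, 1000, n_points=1 << 10)
        fit = fit_bivariate(mz, dz, method="two_stage")
        assert not decompose_rph(fit)["defined"] or abs(fit.rph) < 0.02


class TestCtctExpected:
    def test_path_arithmetic(self):
        p = CorrelatedFactorsParams(t1=1.0, t2=1.0, a1=0.8, c1=0.0, a2=0.8,
                                    c2=0.0, ra=0.5, rc=0.0, re=0.0)
        fit = _fake_fit(p)
        assert ctct_expected(fit, "MZ") == pytest.approx(0.32, abs=1e-12)
        assert ctct_expected(fit, "DZ") == pytest.approx(0.16, abs=1e-12)

    def test_null_correlations_give_zero(self):
        p = CorrelatedFactorsParams(t1=1.0, t2=1.0, a1=0.8, c1=0.3, a2=0.8,
                                    c2=0.3, ra=0.0, rc=0.0, re=0.2)
        fit = _fake_fit(p)
        assert ctct_expected(fit, "MZ") == 0.0
        assert ctct_expected(fit, "DZ") == 0.0

    def test_mz_at_least_dz_for_nonnegative_ra(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = CorrelatedFactorsParams(
                t1=1.0, t2=1.0, a1=rng.uniform(0, 0.9), c1=0.1,
                a2=rng.uniform(0, 0.9), c2=0.1, ra=rng.uniform(0, 1),
                rc=rng.uniform(-1, 1), re=0.0)
            fit = _fake_fit(p)
            assert ctct_expected(fit, "MZ") >= ctct_expected(fit, "DZ") - 1e-12


def _fake_fit(params):
    from liabtwin.bivariate import BivariateFit

    contributions = (params.a1 * params.a2 * params.ra,
                     params.c1 * params.c2 * params.rc,
                     params.e1 * params.e2 * params.re)
    return BivariateFit(params=params, rph=params.rph,
                        contributions=contributions, proportions=None,
                        bivariate_heritability=None, minus2LL=0.0, aic=0.0,
                        converged=True, method="two_stage", n_mz=0, n_dz=0)


class TestPairTraitTable:
    def test_built_from_cohort_and_collapse(self, comorbid_cohort):
        tab = pair_trait_table(comorbid_cohort, "exposure", "outcome", "MZ")
        n_pairs = comorbid_cohort[comorbid_cohort.zygosity == "MZ"]["pair_id"].nunique()
        assert tab.total == n_pairs
        margin = tab.collapse(0, 2)  # exposure twin1 x exposure twin2
        assert margin.total == n_pairs
        # margin prevalence matches the column mean
        mz = comorbid_cohort[comorbid_cohort.zygosity == "MZ"]
        assert margin.row_margin == pytest.approx(
            mz[mz.twin_index == 1]["exposure"].mean(), abs=1e-12)
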