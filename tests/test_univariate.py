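"""Univariate ACE/AE/E liability fits, Falconer oracle, likelihood-ratio tests."""

import numpy as np
import pytest

from liabtwin.liability import Table2x2, implied_table
from liabtwin.univariate import (compare_models, falconer_oracle,
                                 fit_univariate, fit_with_boundary_refit)

N_MZ, N_DZ = 4767, 5580


def expected_tables(K, r_mz, r_dz, n_mz=N_MZ, n_dz=N_DZ):
    return implied_table(K, K, r_mz, n_mz), implied_table(K, K, r_dz, n_dz)


def multinomial_tables(rng, K, a2, c2, n_mz=N_MZ, n_dz=N_DZ):
    """Sampled zygosity tables under the liability model (for null simulations)."""
    out = []
    for r, n in ((a2 + c2, n_mz), (a2 / 2 + c2, n_dz)):
        exp = implied_table(K, K, r, n)
        p = np.array([exp.n11, exp.n10, exp.n01, exp.n00]) / n
        out.append(Table2x2(*rng.multinomial(n, p)))
    return out


class TestFalconerOracle:
    def test_asthma_row_arithmetic(self):
        assert falconer_oracle(0.83, 0.49) == pytest.approx((0.68, 0.15, 0.17))

    def test_equal_correlations_imply_no_additive(self):
        a2, c2, e2 = falconer_oracle(0.4, 0.4)
        assert (a2, c2, e2) == pytest.approx((0.0, 0.4, 0.6))

    def test_coeliac_like_row(self):
        a2, c2, _ = falconer_oracle(0.96, 0.71)
        assert a2 == pytest.approx(0.50, abs=1e-12)
        assert c2 == pytest.approx(0.46, abs=1e-12)


class TestFitUnivariate:
    def test_no_familial_resemblance_is_pure_e(self):
        mz, dz = expected_tables(0.1, 0.0, 0.0)
        vc = fit_univariate(mz, dz, "ACE", compute_ci=False)
        assert vc.a2 == pytest.approx(0.0, abs=1e-3)
        assert vc.c2 == pytest.approx(0.0, abs=1e-3)
        assert vc.e2 == pytest.approx(1.0, abs=1e-3)

    def test_asthma_like_components_and_cis(self):
        mz, dz = expected_tables(0.134, 0.83, 0.49)
        vc = fit_univariate(mz, dz, "ACE", compute_ci=True)
        assert vc.a2 == pytest.approx(0.68, abs=0.01)
        assert vc.c2 == pytest.approx(0.15, abs=0.01)
        # published-style profile intervals
        assert vc.a2_ci[0] == pytest.approx(0.57, abs=0.02)
        assert vc.a2_ci[1] == pytest.approx(0.79, abs=0.02)

    def test_epilepsy_like_boundary_then_ae_refit(self):
        mz, dz = expected_tables(0.012, 0.62, 0.25)
        ace, ae = fit_with_boundary_refit(mz, dz)
        assert ace.c2_at_boundary
        assert ace.c2 == 0.0
        assert ae is not None
        assert ae.a2 == pytest.approx(0.61, abs=0.03)

    def test_falconer_consistency_inside_parameter_space(self):
        for a2, c2 in [(0.6, 0.1), (0.3, 0.3), (0.4, 0.0), (0.2, 0.5)]:
            mz, dz = expected_tables(0.13, a2 + c2, a2 / 2 + c2)
            vc = fit_univariate(mz, dz, "ACE", compute_ci=False)
            fa2, fc2, fe2 = falconer_oracle(a2 + c2, a2 / 2 + c2)
            assert vc.a2 == pytest.approx(fa2, abs=0.02)
            assert vc.c2 == pytest.approx(fc2, abs=0.02)

    def test_degenerate_table_names_stratum(self):
        mz = Table2x2(0, 0, 0, 100)
        dz = implied_table(0.1, 0.1, 0.2, 100)
        with pytest.raises(ValueError, match="MZ"):
            fit_univariate(mz, dz)

    def test_likelihood_ordering_of_nested_models(self):
        rng = np.random.default_rng(12)
        for _ in range(3):
            mz, dz = multinomial_tables(rng, 0.1, 0.5, 0.2, 2000, 2500)
            fits = {m: fit_univariate(mz, dz, m, compute_ci=False)
                    for m in ("ACE", "AE", "E")}
            assert fits["ACE"].minus2LL <= fits["AE"].minus2LL + 1e-6
            assert fits["AE"].minus2LL <= fits["E"].minus2LL + 1e-6


class TestProfileCICoverage:
    def test_a2_interval_covers_truth_near_nominal_rate(self):
        """95% profile intervals for a2 cover the truth 90-99% of the time."""
        rng = np.random.default_rng(31)
        a2, c2, K = 0.5, 0.2, 0.13
        n_reps, covered = 100, 0
        for _ in range(n_reps):
            mz, dz = multinomial_tables(rng, K, a2, c2, 4000, 4000)
            vc = fit_univariate(mz, dz, "ACE", compute_ci=True,
                                ci_components=("a2",))
            if vc.a2_ci is not None and vc.a2_ci[0] <= a2 <= vc.a2_ci[1]:
                covered += 1
        assert 0.90 <= covered / n_reps <= 0.99


class TestModelComparison:
    def test_identical_fits_give_null_statistic(self):
        mz, dz = expected_tables(0.1, 0.5, 0.25)
        ae = fit_univariate(mz, dz, "AE", compute_ci=False)
        res = compare_models(ae, ae_copy := fit_univariate(mz, dz, "AE", compute_ci=False))
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_not_nested_rejected(self):
        mz, dz = expected_tables(0.1, 0.5, 0.25)
        ace = fit_univariate(mz, dz, "ACE", compute_ci=False)
        ae = fit_univariate(mz, dz, "AE", compute_ci=False)
        with pytest.raises(ValueError, match="not nested"):
            compare_models(ae, ace)

    def test_ae_vs_e_power_at_strong_heritability(self):
        # a2=0.6 at 5,000 pairs per zygosity: the E model should be rejected
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(5):
            mz, dz = multinomial_tables(rng, 0.1, 0.6, 0.0, 5000, 5000)
            ae = fit_univariate(mz, dz, "AE", compute_ci=False)
            e = fit_univariate(mz, dz, "E", compute_ci=False)
            rejections += compare_models(ae, e).p_value < 0.05
        assert rejections == 5
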