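"""Liability kernel: thresholds, MVN rectangles, tetrachorics, implied tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import dblquad
from scipy.special import ndtr

from liabtwin.liability import (RectangleQuery, Table2x2, bvn_upper,
                                implied_table, mvn_rectangle, tetrachoric_fit,
                                threshold_from_prevalence)


def bvn_quadrature_oracle(h, k, r):
    """Brute-force adaptive 2-D quadrature over the bivariate normal density."""
    det = 1.0 - r * r

    def density(y, x):
        return math.exp(-(x * x - 2 * r * x * y + y * y) / (2 * det)) / (
            2 * math.pi * math.sqrt(det))

    val, _ = dblquad(density, h, 8.5, lambda _: k, lambda _: 8.5, epsabs=1e-12)
    return val


class TestThreshold:
    @pytest.mark.parametrize("K,expected,tol", [
        (0.5, 0.0, 1e-15),
        (0.134, 1.107, 1e-3),   # asthma-like prevalence
        (0.012, 2.257, 1e-3),   # epilepsy-like prevalence
    ])
    def test_known_cutpoints(self, K, expected, tol):
        thr = threshold_from_prevalence(K)
        assert thr.t == pytest.approx(expected, abs=tol)
        # defining property: upper-tail area beyond t equals K
        assert ndtr(-thr.t) == pytest.approx(K, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error_names_value(self, bad):
        with pytest.raises(ValueError, match=str(bad)):
            threshold_from_prevalence(bad)


class TestRectangle:
    def test_independence_factorizes(self):
        q = RectangleQuery(np.array([0.7, -0.3]), np.eye(2))
        expected = float(ndtr(-0.7) * ndtr(0.3))
        assert mvn_rectangle(q) == pytest.approx(expected, abs=1e-14)

    def test_perfect_correlation_degenerates(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        q = RectangleQuery(np.array([0.9, 0.9]), corr)
        assert mvn_rectangle(q) == pytest.approx(float(ndtr(-0.9)), abs=1e-14)

    def test_matches_quadrature_oracle(self):
        assert bvn_upper(1.0, 1.0, 0.5) == pytest.approx(
            bvn_quadrature_oracle(1.0, 1.0, 0.5), abs=1e-8)

    @pytest.mark.parametrize("t1,t2", [(-1.0, 0.5), (0.0, 0.0), (1.5, 2.0)])
    @pytest.mark.parametrize("r", [-0.8, -0.3, 0.0, 0.45, 0.95])
    def test_quadrants_sum_to_one(self, t1, t2, r):
        corr = np.array([[1.0, r], [r, 1.0]])
        total = 0.0
        for s1, s2 in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
            # flip variables to express each quadrant as an upper orthant
            R = np.array([[1.0, s1 * s2 * r], [s1 * s2 * r, 1.0]])
            total += mvn_rectangle(RectangleQuery(np.array([s1 * t1, s2 * t2]), R))
        assert total == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(t=st.floats(-2.0, 2.5),
           r1=st.floats(-0.99, 0.99), r2=st.floats(-0.99, 0.99))
    def test_monotone_in_correlation(self, t, r1, r2):
        lo, hi = sorted([r1, r2])
        assert bvn_upper(t, t, hi) >= bvn_upper(t, t, lo) - 1e-12

    def test_higher_dims_consistent_with_marginalization(self):
        # dropping a coordinate via an infinite bound reproduces the 2-D value
        R = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]])
        q3 = RectangleQuery(np.array([0.5, 1.0, -np.inf]), R)
        assert mvn_rectangle(q3) == pytest.approx(bvn_upper(0.5, 1.0, 0.4), abs=1e-12)
        # finite 3-D value against a fine independent evaluation
        q = RectangleQuery(np.array([0.5, 1.0, 0.2]), R)
        coarse = mvn_rectangle(q)
        fine = mvn_rectangle(q, n_points=1 << 16, seed=99)
        assert coarse == pytest.approx(fine, abs=1e-6)

    def test_non_psd_reports_eigenvalue(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            mvn_rectangle(RectangleQuery(np.array([0.0, 0.0, 0.0]), R))


class TestTetrachoric:
    def test_independence_table_gives_zero(self):
        est = tetrachoric_fit(Table2x2(25, 25, 25, 25))
        assert est.r == pytest.approx(0.0, abs=1e-6)
        assert not est.at_boundary

    def test_perfect_concordance_hits_boundary(self):
        est = tetrachoric_fit(Table2x2(30, 0, 0, 70))
        assert est.at_boundary
        assert est.r == 1.0

    @pytest.mark.parametrize("K,r,N", [
        (0.012, 0.62, 4767),   # epilepsy-like MZ row
        (0.134, 0.83, 4767),
        (0.062, -0.40, 5000),
        (0.3, 0.25, 2000),
    ])
    def test_round_trip_recovers_r(self, K, r, N):
        est = tetrachoric_fit(implied_table(K, K, r, N))
        assert est.r == pytest.approx(r, abs=1e-4)

    def test_zero_margin_flagged_undefined(self):
        est = tetrachoric_fit(Table2x2(0, 0, 40, 60))
        assert not est.defined
        assert math.isnan(est.r)

    def test_se_shrinks_like_sqrt_n(self):
        se1 = tetrachoric_fit(implied_table(0.1, 0.1, 0.5, 4000)).se
        se2 = tetrachoric_fit(implied_table(0.1, 0.1, 0.5, 8000)).se
        assert 0.65 <= se2 / se1 <= 0.75


class TestImpliedTable:
    def test_independent_even_margins(self):
        t = implied_table(0.5, 0.5, 0.0, 100)
        assert np.allclose([t.n11, t.n10, t.n01, t.n00], 25.0, atol=1e-10)

    def test_perfect_correlation_concentrates(self):
        t = implied_table(0.134, 0.134, 1.0, 4767)
        assert t.n11 == pytest.approx(4767 * 0.134, abs=1e-6)
        assert t.n10 == pytest.approx(0.0, abs=1e-9)
        assert t.n01 == pytest.approx(0.0, abs=1e-9)

    def test_cells_sum_to_n_and_match_oracle(self):
        t = implied_table(0.134, 0.134, 0.83, 4767)
        assert t.total == pytest.approx(4767, abs=1e-9)
        p11 = bvn_quadrature_oracle(
            threshold_from_prevalence(0.134).t, threshold_from_prevalence(0.134).t, 0.83)
        assert t.n11 == pytest.approx(4767 * p11, abs=1e-4 * 4767)
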