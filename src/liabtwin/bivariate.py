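"""Bivariate liability-threshold twin models (correlated-factors solution).

Two binary traits per twin give 16 observable response patterns per pair;
per zygosity these counts are the sufficient statistic.  The model places a
4-dimensional normal over the pair's liabilities (twin1 trait1, twin1 trait2,
twin2 trait1, twin2 trait2) with correlation structure

    within twin, cross trait :  rPH = a1*a2*ra + c1*c2*rc + e1*e2*re
    cross twin, within trait :  g*ai^2 + ci^2        (g = 1 MZ, 1/2 DZ)
    cross twin, cross trait  :  g*a1*a2*ra + c1*c2*rc

where (ai, ci, ei) are the per-trait standardized paths (ai^2+ci^2+ei^2 = 1)
and ra/rc/re the additive-genetic, shared- and nonshared-environment
correlations between the traits.  This correlated-factors parameterization is
mathematically equivalent to the bivariate Cholesky decomposition; both maps
are provided and yield identical implied matrices and likelihoods.

Full ML maximizes the 16-cell multinomial likelihood per zygosity with cell
probabilities computed as 4-D normal rectangles (deterministic Sobol kernel,
fixed points reused across iterations so the objective is smooth).  A fast
two-stage mode — tetrachoric correlations from the collapsed margins followed
by the moment solution of the correlation structure — serves as starting
values, as a cross-check, and as the estimator for printed-correlation
inputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import ndtr, ndtri
from scipy.stats import chi2

from .liability import (Table2x2, _orthant_qmc, bvn_upper, sobol_points,
                        tetrachoric_fit)

__all__ = [
    "CorrelatedFactorsParams",
    "CholeskyParams",
    "PairTraitTable4x4",
    "BivariateFit",
    "cf_to_cholesky",
    "cholesky_to_cf",
    "implied_pair_correlation",
    "pair_trait_table",
    "fit_bivariate",
    "two_stage_estimate",
    "decompose_rph",
    "ctct_expected",
    "profile_ci",
]

_CHI2_95 = chi2.ppf(0.95, 1)
_FIT_POINTS = 1 << 12


@dataclasses.dataclass(frozen=True)
class CorrelatedFactorsParams:
    """Per-trait paths plus etiologic correlations; paths nonnegative."""

    t1: float
    t2: float
    a1: float
    c1: float
    a2: float
    c2: float
    ra: float
    rc: float
    re: float

    def __post_init__(self):
        for label in ("a1", "c1", "a2", "c2"):
            if getattr(self, label) < 0:
                raise ValueError(f"path {label} must be nonnegative")
        for label in ("ra", "rc", "re"):
            v = getattr(self, label)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{label} must lie in [-1, 1], got {v}")
        for i in (1, 2):
            if getattr(self, f"a{i}") ** 2 + getattr(self, f"c{i}") ** 2 > 1.0 + 1e-9:
                raise ValueError(f"a{i}^2 + c{i}^2 exceeds 1")

    @property
    def e1(self) -> float:
        return math.sqrt(max(1.0 - self.a1**2 - self.c1**2, 0.0))

    @property
    def e2(self) -> float:
        return math.sqrt(max(1.0 - self.a2**2 - self.c2**2, 0.0))

    @property
    def rph(self) -> float:
        return (self.a1 * self.a2 * self.ra + self.c1 * self.c2 * self.rc
                + self.e1 * self.e2 * self.re)


@dataclasses.dataclass(frozen=True)
class CholeskyParams:
    """Lower-triangular paths per component: trait2 loads on trait1's factors."""

    t1: float
    t2: float
    a11: float
    a21: float
    a22: float
    c11: float
    c21: float
    c22: float
    e11: float
    e21: float
    e22: float


def cf_to_cholesky(p: CorrelatedFactorsParams) -> CholeskyParams:
    return CholeskyParams(
        t1=p.t1, t2=p.t2,
        a11=p.a1, a21=p.a2 * p.ra, a22=p.a2 * math.sqrt(max(1 - p.ra**2, 0.0)),
        c11=p.c1, c21=p.c2 * p.rc, c22=p.c2 * math.sqrt(max(1 - p.rc**2, 0.0)),
        e11=p.e1, e21=p.e2 * p.re, e22=p.e2 * math.sqrt(max(1 - p.re**2, 0.0)))


def cholesky_to_cf(p: CholeskyParams) -> CorrelatedFactorsParams:
    a2 = math.hypot(p.a21, p.a22)
    c2 = math.hypot(p.c21, p.c22)
    e2 = math.hypot(p.e21, p.e22)
    return CorrelatedFactorsParams(
        t1=p.t1, t2=p.t2, a1=abs(p.a11), c1=abs(p.c11),
        a2=a2, c2=c2,
        ra=p.a21 / a2 if a2 > 0 else 0.0,
        rc=p.c21 / c2 if c2 > 0 else 0.0,
        re=p.e21 / e2 if e2 > 0 else 0.0)


def implied_pair_correlation(params, zygosity: str) -> np.ndarray:
    """4x4 liability correlation: (twin1 t1, twin1 t2, twin2 t1, twin2 t2)."""
    if isinstance(params, CholeskyParams):
        params = cholesky_to_cf(params)
    p = params
    g = {"MZ": 1.0, "DZ": 0.5}[zygosity]
    rph = p.rph
    r11 = g * p.a1**2 + p.c1**2
    r22 = g * p.a2**2 + p.c2**2
    ctct = g * p.a1 * p.a2 * p.ra + p.c1 * p.c2 * p.rc
    R = np.array([
        [1.0, rph, r11, ctct],
        [rph, 1.0, ctct, r22],
        [r11, ctct, 1.0, rph],
        [ctct, r22, rph, 1.0],
    ])
    return R


@dataclasses.dataclass(frozen=True)
class PairTraitTable4x4:
    """16-cell pattern counts; bit order (t1 trait1, t1 trait2, t2 trait1, t2 trait2)."""

    zygosity: str
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (16,):
            raise ValueError("counts must have 16 cells")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def collapse(self, coord_x: int, coord_y: int) -> Table2x2:
        """2x2 margin over two of the four coordinates (0..3, bit order)."""
        idx = np.arange(16)
        x = (idx >> (3 - coord_x)) & 1
        y = (idx >> (3 - coord_y)) & 1
        c = self.counts
        return Table2x2(
            n11=float(c[(x == 1) & (y == 1)].sum()),
            n10=float(c[(x == 1) & (y == 0)].sum()),
            n01=float(c[(x == 0) & (y == 1)].sum()),
            n00=float(c[(x == 0) & (y == 0)].sum()))


def pair_trait_table(cohort: pd.DataFrame, trait_a: str, trait_b: str,
                     zygosity: str) -> PairTraitTable4x4:
    from .descriptives import pair_wide

    wide = pair_wide(cohort, sorted({trait_a, trait_b}), zygosity)
    bits = (8 * wide[f"{trait_a}_1"].astype(int)
            + 4 * wide[f"{trait_b}_1"].astype(int)
            + 2 * wide[f"{trait_a}_2"].astype(int)
            + wide[f"{trait_b}_2"].astype(int))
    counts = np.bincount(bits, minlength=16).astype(float)
    return PairTraitTable4x4(zygosity=zygosity, counts=counts)


@dataclasses.dataclass(frozen=True)
class BivariateFit:
    params: CorrelatedFactorsParams
    rph: float
    contributions: tuple[float, float, float]
    proportions: tuple[float, float, float] | None
    bivariate_heritability: float | None
    minus2LL: float
    aic: float
    converged: bool
    method: str
    n_mz: float
    n_dz: float
    ra_ci: tuple[float, float] | None = None
    rc_ci: tuple[float, float] | None = None
    re_ci: tuple[float, float] | None = None
    rph_ci: tuple[float, float] | None = None
    ra_se: float | None = None


# ---------------------------------------------------------------------------
# 16-cell probabilities
# ---------------------------------------------------------------------------

_SUBSETS = [tuple(M) for size in range(5) for M in itertools.combinations(range(4), size)]
_AFFECTED = [tuple(i for i in range(4) if (s >> (3 - i)) & 1) for s in range(16)]
_UNAFFECTED = [tuple(i for i in range(4) if not (s >> (3 - i)) & 1) for s in range(16)]


def _cell_probabilities(t: np.ndarray, R: np.ndarray,
                        u3: np.ndarray | None = None,
                        u4: np.ndarray | None = None) -> np.ndarray:
    """All 16 pattern probabilities by Moebius inversion of lower-orthant CDFs."""
    F: dict[tuple[int, ...], float] = {(): 1.0}
    for M in _SUBSETS[1:]:
        tm = t[list(M)]
        if len(M) == 1:
            F[M] = float(ndtr(tm[0]))
        elif len(M) == 2:
            F[M] = bvn_upper(-tm[0], -tm[1], float(R[M[0], M[1]]))
        else:
            Rm = R[np.ix_(M, M)]
            u = u3 if len(M) == 3 else u4
            F[M] = _orthant_qmc(-tm, Rm, 0, 0, u=u)
    cells = np.empty(16)
    for s in range(16):
        acc = 0.0
        base = _UNAFFECTED[s]
        for k in range(len(_AFFECTED[s]) + 1):
            for S in itertools.combinations(_AFFECTED[s], k):
                acc += (-1.0) ** k * F[tuple(sorted(base + S))]
        cells[s] = acc
    return np.clip(cells, 1e-12, 1.0)


def _nearest_psd_penalty(R: np.ndarray) -> tuple[np.ndarray, float]:
    eig = np.linalg.eigvalsh(R)
    mn = float(eig.min())
    if mn >= -1e-10:
        return R, 0.0
    vals, vecs = np.linalg.eigh(R)
    Rp = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
    d = np.sqrt(np.diag(Rp))
    Rp = Rp / np.outer(d, d)
    return Rp, 1e6 * mn * mn


def _table_nll(params: CorrelatedFactorsParams, mz: PairTraitTable4x4,
               dz: PairTraitTable4x4, u3: np.ndarray, u4: np.ndarray) -> float:
    nll = 0.0
    for tab in (mz, dz):
        R = implied_pair_correlation(params, tab.zygosity)
        R, penalty = _nearest_psd_penalty(R)
        t = np.array([params.t1, params.t2, params.t1, params.t2])
        p = _cell_probabilities(t, R, u3, u4)
        nll += penalty - float(tab.counts @ np.log(p))
    return nll


# ---------------------------------------------------------------------------
# two-stage moment estimator
# ---------------------------------------------------------------------------


def _margin_threshold(tab: PairTraitTable4x4, coords: tuple[int, int]) -> float:
    idx = np.arange(16)
    aff = ((idx >> (3 - coords[0])) & 1) + ((idx >> (3 - coords[1])) & 1)
    k = float((tab.counts * aff).sum()) / (2.0 * tab.total)
    k = min(max(k, 1e-6), 1 - 1e-6)
    return float(-ndtri(k))


def _double_entered(t: Table2x2) -> Table2x2:
    return Table2x2(n11=2 * t.n11, n10=t.n10 + t.n01, n01=t.n10 + t.n01, n00=2 * t.n00)


def two_stage_estimate(mz: PairTraitTable4x4, dz: PairTraitTable4x4,
                       ) -> CorrelatedFactorsParams:
    """Moment solution: tetrachorics from collapsed margins, then path algebra.

    Falconer-style identities give the per-trait variance shares from the
    within-trait cross-twin correlations, and the MZ/DZ contrast of the
    cross-twin cross-trait correlations splits the cross-trait covariance
    into its A and C parts; the within-person cross-trait correlation then
    pins down the E part.  All quantities are clipped into the admissible
    parameter space.
    """
    r = {}
    for tab, z in ((mz, "MZ"), (dz, "DZ")):
        # double entry over twin orderings; trait1 = coords 0/2, trait2 = 1/3.
        # Both orderings keep trait1 on the rows, so the merge is a plain sum
        # (for the within-trait tables the second collapse is the transpose,
        # which symmetrizes them).
        def tet(first, second):
            t_a = tab.collapse(*first)
            t_b = tab.collapse(*second)
            merged = Table2x2(n11=t_a.n11 + t_b.n11, n10=t_a.n10 + t_b.n10,
                              n01=t_a.n01 + t_b.n01, n00=t_a.n00 + t_b.n00)
            return tetrachoric_fit(merged, n_effective=tab.total).r

        r[f"ct1_{z}"] = tet((0, 2), (2, 0))     # cross-twin within trait1
        r[f"ct2_{z}"] = tet((1, 3), (3, 1))     # cross-twin within trait2
        r[f"ctct_{z}"] = tet((0, 3), (2, 1))    # cross-twin cross-trait
        r[f"rph_{z}"] = tet((0, 1), (2, 3))     # within person cross-trait

    def shares(rmz, rdz):
        a2 = min(max(2.0 * (rmz - rdz), 0.0), 1.0)
        c2 = min(max(2.0 * rdz - rmz, 0.0), 1.0 - a2)
        return a2, c2

    a1s, c1s = shares(r["ct1_MZ"], r["ct1_DZ"])
    a2s, c2s = shares(r["ct2_MZ"], r["ct2_DZ"])
    a1, c1 = math.sqrt(a1s), math.sqrt(c1s)
    a2, c2 = math.sqrt(a2s), math.sqrt(c2s)
    e1 = math.sqrt(max(1 - a1s - c1s, 0.0))
    e2 = math.sqrt(max(1 - a2s - c2s, 0.0))

    cov_a = 2.0 * (r["ctct_MZ"] - r["ctct_DZ"])
    cov_c = 2.0 * r["ctct_DZ"] - r["ctct_MZ"]
    w_mz, w_dz = mz.total, dz.total
    rph = (w_mz * r["rph_MZ"] + w_dz * r["rph_DZ"]) / (w_mz + w_dz)
    ra = np.clip(cov_a / (a1 * a2), -1, 1) if a1 * a2 > 1e-6 else 0.0
    rc = np.clip(cov_c / (c1 * c2), -1, 1) if c1 * c2 > 1e-6 else 0.0
    cov_e = rph - a1 * a2 * ra - c1 * c2 * rc
    re = np.clip(cov_e / (e1 * e2), -1, 1) if e1 * e2 > 1e-6 else 0.0

    t1 = 0.5 * (_margin_threshold(mz, (0, 2)) + _margin_threshold(dz, (0, 2)))
    t2 = 0.5 * (_margin_threshold(mz, (1, 3)) + _margin_threshold(dz, (1, 3)))
    return CorrelatedFactorsParams(t1=t1, t2=t2, a1=a1, c1=c1, a2=a2, c2=c2,
                                   ra=float(ra), rc=float(rc), re=float(re))


# ---------------------------------------------------------------------------
# full ML
# ---------------------------------------------------------------------------


def _pack(p: CorrelatedFactorsParams) -> np.ndarray:
    def z(v):
        return math.atanh(min(max(v, -1 + 1e-9), 1 - 1e-9))

    return np.array([p.t1, p.t2, p.a1, p.c1, p.a2, p.c2,
                     z(p.ra), z(p.rc), z(p.re)])


def _unpack(x: np.ndarray) -> CorrelatedFactorsParams:
    t1, t2, a1, c1, a2, c2, zra, zrc, zre = x
    a1, c1, a2, c2 = abs(a1), abs(c1), abs(a2), abs(c2)
    s1 = a1 * a1 + c1 * c1
    if s1 > 1 - 1e-9:
        f = math.sqrt((1 - 1e-9) / s1)
        a1, c1 = a1 * f, c1 * f
    s2 = a2 * a2 + c2 * c2
    if s2 > 1 - 1e-9:
        f = math.sqrt((1 - 1e-9) / s2)
        a2, c2 = a2 * f, c2 * f
    return CorrelatedFactorsParams(t1=t1, t2=t2, a1=a1, c1=c1, a2=a2, c2=c2,
                                   ra=math.tanh(zra), rc=math.tanh(zrc),
                                   re=math.tanh(zre))


def fit_bivariate(mz: PairTraitTable4x4, dz: PairTraitTable4x4,
                  method: str = "full", n_points: int = _FIT_POINTS,
                  compute_ci: bool = False, maxiter: int = 2500) -> BivariateFit:
    """Fit the bivariate model to MZ and DZ 16-cell tables.

    ``method="full"`` maximizes the multinomial likelihood (two-stage moment
    estimates as start values); ``method="two_stage"`` stops at the moment
    solution and evaluates its likelihood.  ``compute_ci`` adds
    profile-likelihood intervals for ra, rc, re (full method only).
    """
    if mz.total <= 0 or dz.total <= 0:
        raise ValueError("both zygosity tables must be nonempty")
    start = two_stage_estimate(mz, dz)
    u3 = sobol_points(2, n_points)
    u4 = sobol_points(3, n_points)

    if method == "two_stage":
        params = start
        nll = _table_nll(params, mz, dz, u3, u4)
        converged = True
        res_x = _pack(params)
    elif method == "full":
        def obj(x):
            return _table_nll(_unpack(x), mz, dz, u3, u4)

        res = minimize(obj, _pack(start), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": maxiter,
                                "adaptive": True})
        params = _unpack(res.x)
        nll = float(res.fun)
        converged = bool(res.success)
        res_x = res.x
    else:
        raise ValueError(f"method must be 'full' or 'two_stage', got {method!r}")

    contributions = (params.a1 * params.a2 * params.ra,
                     params.c1 * params.c2 * params.rc,
                     params.e1 * params.e2 * params.re)
    rph = params.rph
    if abs(rph) > 1e-6:
        proportions = tuple(c / rph for c in contributions)
        biv_h2 = proportions[0]
    else:
        proportions = None
        biv_h2 = None

    k = 9
    fit = BivariateFit(params=params, rph=rph, contributions=contributions,
                       proportions=proportions, bivariate_heritability=biv_h2,
                       minus2LL=2 * nll, aic=2 * nll + 2 * k, converged=converged,
                       method=method, n_mz=mz.total, n_dz=dz.total)
    if compute_ci and method == "full":
        cis = {}
        for name, idx in (("ra", 6), ("rc", 7), ("re", 8)):
            cis[name] = profile_ci(fit, mz, dz, name, u3=u3, u4=u4)
        fit = dataclasses.replace(fit, ra_ci=cis["ra"], rc_ci=cis["rc"],
                                  re_ci=cis["re"])
    return fit


def _profile_nll(value: float, which: str, start: CorrelatedFactorsParams,
                 mz, dz, u3, u4, maxiter: int = 500) -> float:
    zfix = math.atanh(min(max(value, -1 + 1e-9), 1 - 1e-9))
    idx = {"ra": 6, "rc": 7, "re": 8}[which]

    def obj(xfree):
        x = np.empty(9)
        x[:idx] = xfree[:idx]
        x[idx] = zfix
        x[idx + 1:] = xfree[idx:]
        return _table_nll(_unpack(x), mz, dz, u3, u4)

    x0 = np.delete(_pack(start), idx)
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": maxiter})
    return float(res.fun)


def profile_ci(fit: BivariateFit, mz: PairTraitTable4x4, dz: PairTraitTable4x4,
               which: str = "ra", u3: np.ndarray | None = None,
               u4: np.ndarray | None = None) -> tuple[float, float]:
    """Profile-likelihood 95% interval for one etiologic correlation."""
    if u3 is None:
        u3 = sobol_points(2, _FIT_POINTS)
    if u4 is None:
        u4 = sobol_points(3, _FIT_POINTS)
    hat = getattr(fit.params, which)
    nll_hat = fit.minus2LL / 2.0

    def dev(v):
        return 2.0 * (_profile_nll(v, which, fit.params, mz, dz, u3, u4)
                      - nll_hat) - _CHI2_95

    lo, hi = -1.0, 1.0
    try:
        if dev(-1 + 1e-6) > 0:
            lo = brentq(dev, -1 + 1e-6, hat, xtol=5e-4)
        if dev(1 - 1e-6) > 0:
            hi = brentq(dev, hat, 1 - 1e-6, xtol=5e-4)
    except ValueError:
        return (float("nan"), float("nan"))
    return (float(lo), float(hi))


def decompose_rph(fit: BivariateFit) -> dict:
    """Genetic / shared / nonshared contributions to rPH, and as proportions."""
    gen, sha, non = fit.contributions
    out = {"genetic": gen, "shared_env": sha, "nonshared_env": non,
           "rph": fit.rph, "defined": abs(fit.rph) > 1e-6}
    if out["defined"]:
        out["proportions"] = (gen / fit.rph, sha / fit.rph, non / fit.rph)
        out["bivariate_heritability"] = gen / fit.rph
    else:
        out["proportions"] = None
        out["bivariate_heritability"] = None
    return out


def ctct_expected(fit: BivariateFit, zygosity: str) -> float:
    """Model-implied cross-twin cross-trait correlation for one zygosity."""
    g = {"MZ": 1.0, "DZ": 0.5}[zygosity]
    p = fit.params
    return g * p.a1 * p.a2 * p.ra + p.c1 * p.c2 * p.rc
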