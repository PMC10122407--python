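"""Univariate liability-threshold twin models (ACE, AE, E).

A binary trait is the indicator of a standard-normal liability exceeding a
threshold.  The liability variance splits into additive-genetic (A), shared-
environment (C) and nonshared (E) proportions a2 + c2 + e2 = 1, which imply
cross-twin liability correlations

    rMZ = a2 + c2        rDZ = a2/2 + c2

because MZ co-twins share all segregating DNA and DZ co-twins on average
half.  With no covariates the zygosity-wise 2x2 concordance tables are
sufficient statistics, so the fit maximizes the joint multinomial likelihood
over both tables with a single threshold shared across zygosities and twins.
Path coefficients (a, c) are estimated directly and squared for reporting,
which enforces nonnegativity; 95% confidence intervals are profile-likelihood
based.  Nested models are compared with likelihood-ratio tests against a
chi-square reference, which is conservative when a component sits on its
zero bound.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar
from scipy.special import ndtri
from scipy.stats import chi2

from .liability import Table2x2, _cell_probs, threshold_from_prevalence

__all__ = [
    "VarianceComponents",
    "LRTResult",
    "fit_univariate",
    "fit_with_boundary_refit",
    "compare_models",
    "falconer_oracle",
]

_MODELS = {"ACE": ("a", "c"), "AE": ("a",), "E": ()}
_CHI2_95 = chi2.ppf(0.95, 1)


@dataclasses.dataclass(frozen=True)
class VarianceComponents:
    model: str
    a2: float
    c2: float
    e2: float
    threshold: float
    minus2LL: float
    aic: float
    df: int
    a2_ci: tuple[float, float] | None = None
    c2_ci: tuple[float, float] | None = None
    e2_ci: tuple[float, float] | None = None
    converged: bool = True
    c2_at_boundary: bool = False
    a2_at_boundary: bool = False

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2


@dataclasses.dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    full_model: str
    nested_model: str


def falconer_oracle(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Moment estimators a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ.

    Raw values, no bounding — used as an independent cross-check on the
    likelihood fit wherever all three land inside [0, 1].
    """
    for label, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{label} must lie in [-1, 1], got {r}")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    return a2, c2, 1.0 - r_mz


def _counts(table: Table2x2) -> np.ndarray:
    c = np.array([table.n11, table.n10, table.n01, table.n00], dtype=float)
    if (c < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if c.sum() <= 0:
        raise ValueError("table total must be positive")
    return c


def _nll(t: float, a: float, c: float, mz: np.ndarray, dz: np.ndarray) -> float:
    a2, c2 = a * a, c * c
    if a2 + c2 > 1.0 - 1e-9:
        # smooth penalty keeps the optimizer inside the unit simplex
        excess = a2 + c2 - (1.0 - 1e-9)
        scale = math.sqrt((1.0 - 1e-9) / (a2 + c2))
        a, c = a * scale, c * scale
        a2, c2 = a * a, c * c
        penalty = 1e4 * excess * excess
    else:
        penalty = 0.0
    nll = 0.0
    for counts, r in ((mz, a2 + c2), (dz, 0.5 * a2 + c2)):
        p = np.clip(_cell_probs(t, t, r), 1e-12, 1.0)
        nll -= float(counts @ np.log(p))
    return nll + penalty


def _start_values(mz: np.ndarray, dz: np.ndarray) -> tuple[float, float, float]:
    n = mz.sum() + dz.sum()
    k = (2 * (mz[0] + dz[0]) + mz[1] + mz[2] + dz[1] + dz[2]) / (2 * n)
    k = min(max(k, 1e-4), 1 - 1e-4)
    return float(-ndtri(k)), 0.6, 0.3


def fit_univariate(mz_table: Table2x2, dz_table: Table2x2, model: str = "ACE",
                   compute_ci: bool = True,
                   ci_components: tuple[str, ...] = ("a2", "c2", "e2"),
                   ) -> VarianceComponents:
    """ML variance components from MZ and DZ 2x2 cross-twin tables.

    Tables may hold fractional expected counts (two-stage fits from printed
    prevalence and correlations) or observed integer counts.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {sorted(_MODELS)}, got {model!r}")
    mz, dz = _counts(mz_table), _counts(dz_table)
    for label, counts in (("MZ", mz), ("DZ", dz)):
        margin = (2 * counts[0] + counts[1] + counts[2]) / (2 * counts.sum())
        if margin <= 0 or margin >= 1:
            raise ValueError(f"{label} table is degenerate: trait "
                             f"{'never' if margin <= 0 else 'always'} present")

    t0, a0, c0 = _start_values(mz, dz)
    free = _MODELS[model]

    def unpack(x):
        t = x[0]
        a = x[1] if "a" in free else 0.0
        c = x[2 if "a" in free else 1] if "c" in free else 0.0
        return t, a, c

    def obj(x):
        return _nll(*unpack(x), mz, dz)

    x0 = [t0] + ([a0] if "a" in free else []) + ([c0] if "c" in free else [])
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 5000})
    t, a, c = unpack(res.x)
    a2, c2 = a * a, c * c
    # mirror solutions: paths reported nonnegative
    a2 = min(a2, 1.0)
    c2 = min(c2, 1.0 - a2)
    e2 = max(1.0 - a2 - c2, 0.0)
    minus2ll = 2.0 * res.fun
    k = 1 + len(free)
    c2_bound = model == "ACE" and c2 < 1e-6
    a2_bound = "a" in free and a2 < 1e-6
    if c2_bound:
        c2 = 0.0
    if a2_bound:
        a2 = 0.0
    e2 = 1.0 - a2 - c2

    ci_a = ci_c = ci_e = None
    if compute_ci:
        ci_a, ci_c, ci_e = _profile_cis(model, mz, dz, t, a2, c2, res.fun,
                                        ci_components)

    return VarianceComponents(
        model=model, a2=float(a2), c2=float(c2), e2=float(e2), threshold=float(t),
        minus2LL=float(minus2ll), aic=float(minus2ll + 2 * k), df=k,
        a2_ci=ci_a, c2_ci=ci_c, e2_ci=ci_e,
        converged=bool(res.success), c2_at_boundary=c2_bound,
        a2_at_boundary=a2_bound)


def _profile_nll(component: str, value: float, model: str,
                 mz: np.ndarray, dz: np.ndarray, t_hat: float,
                 a2_hat: float, c2_hat: float) -> float:
    """Minimized nll with one variance share fixed at ``value``."""
    free = _MODELS[model]

    if component == "a2":
        a = math.sqrt(value)

        def obj(x):
            t = x[0]
            c = x[1] if "c" in free else 0.0
            return _nll(t, a, c, mz, dz)

        x0 = [t_hat] + ([math.sqrt(max(c2_hat, 1e-6))] if "c" in free else [])
    elif component == "c2":
        c = math.sqrt(value)

        def obj(x):
            t = x[0]
            a = x[1] if "a" in free else 0.0
            return _nll(t, a, c, mz, dz)

        x0 = [t_hat] + ([math.sqrt(max(a2_hat, 1e-6))] if "a" in free else [])
    elif component == "e2":
        # constrain a2 + c2 = 1 - value via an angle parameter
        rad = math.sqrt(max(1.0 - value, 0.0))

        def obj(x):
            t = x[0]
            if "c" in free and "a" in free:
                th = x[1]
                a, c = rad * math.cos(th), rad * math.sin(th)
            elif "a" in free:
                a, c = rad, 0.0
            else:
                a, c = 0.0, 0.0
            return _nll(t, a, c, mz, dz)

        th0 = math.atan2(math.sqrt(max(c2_hat, 1e-8)), math.sqrt(max(a2_hat, 1e-8)))
        x0 = [t_hat] + ([th0] if ("a" in free and "c" in free) else [])
    else:  # pragma: no cover
        raise ValueError(component)

    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return float(res.fun)


def _profile_cis(model, mz, dz, t_hat, a2_hat, c2_hat, nll_hat,
                 components=("a2", "c2", "e2")):
    estimates = {"a2": a2_hat, "c2": c2_hat, "e2": 1.0 - a2_hat - c2_hat}
    free = _MODELS[model]
    out = {"a2": None, "c2": None, "e2": None}
    for comp, hat in estimates.items():
        if comp not in components:
            continue
        if (comp == "a2" and "a" not in free) or (comp == "c2" and "c" not in free):
            continue

        def dev(v):
            return 2.0 * (_profile_nll(comp, v, model, mz, dz, t_hat,
                                       a2_hat, c2_hat) - nll_hat) - _CHI2_95

        lo, hi = 0.0, 1.0
        try:
            if hat > 1e-6 and dev(1e-9) > 0:
                lo = brentq(dev, 1e-9, hat, xtol=1e-5)
            if hat < 1.0 - 1e-6 and dev(1.0 - 1e-9) > 0:
                hi = brentq(dev, hat, 1.0 - 1e-9, xtol=1e-5)
        except ValueError:
            out[comp] = None
            continue
        out[comp] = (float(lo), float(hi))
    return out["a2"], out["c2"], out["e2"]


def fit_with_boundary_refit(mz_table: Table2x2, dz_table: Table2x2,
                            compute_ci: bool = False,
                            ) -> tuple[VarianceComponents, VarianceComponents | None]:
    """ACE fit; when C hits its zero bound, also return the AE refit.

    Mirrors the reporting convention where a boundary C is printed as 0 and
    the genetic share is taken from the AE solution.
    """
    ace = fit_univariate(mz_table, dz_table, "ACE", compute_ci=compute_ci)
    if ace.c2_at_boundary:
        ae = fit_univariate(mz_table, dz_table, "AE", compute_ci=compute_ci)
        return ace, ae
    return ace, None


def compare_models(full: VarianceComponents, nested: VarianceComponents) -> LRTResult:
    """Likelihood-ratio test of a nested model against the fuller one."""
    if nested.df > full.df:
        raise ValueError(f"{nested.model} is not nested in {full.model}")
    stat = nested.minus2LL - full.minus2LL
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic ({stat:.3g}): optimizer failure in the "
            f"{full.model} fit")
    stat = max(stat, 0.0)
    df = full.df - nested.df
    # identical parameterizations: statistic 0 by construction, p = 1
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), df=df, p_value=p,
                     full_model=full.model, nested_model=nested.model)
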