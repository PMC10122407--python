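"""A-TAC scoring, subclinical classification, and item emission.

The Autism-Tics, ADHD and Other Comorbidities inventory (A-TAC) is a parent
interview whose items are scored 0 ("No"), 0.5 ("Yes, to some extent") or
1 ("Yes").  The autism module has 17 items (subclinical cutoff: total >= 4.5)
and the ADHD module 19 items (cutoff: total >= 6.0); at these lower screening
cutoffs roughly 3.6% and 10.5% of the general child population screen
positive.

Item emission for synthetic cohorts is a graded-response device: item i of an
individual with liability ``l`` is a three-level discretization of
``loading * l + sqrt(1 - loading^2) * eps_i`` at thresholds tau1 < tau2, with
independent standard-normal item noise ``eps_i``.  ``calibrate_atac_settings``
solves for tau1 so the population screen-positive rate matches a target
exactly (computed analytically, no simulation).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, roots_hermitenorm

__all__ = [
    "ATAC_MODULES",
    "ATAC_CUTOFFS",
    "SCREEN_RATES",
    "AtacSettings",
    "score_module",
    "classify_subclinical",
    "apply_sensitivity_exclusion",
    "emit_atac_items",
    "atac_screen_rate",
    "calibrate_atac_settings",
    "assign_phenotypes",
]

ATAC_MODULES = {"autism": 17, "adhd": 19}
ATAC_CUTOFFS = {"autism": 4.5, "adhd": 6.0}
# general-population screen-positive rates at the lower cutoffs
SCREEN_RATES = {"autism": 0.036, "adhd": 0.105}
_ITEM_LEVELS = frozenset({0.0, 0.5, 1.0})


@dataclasses.dataclass(frozen=True)
class AtacSettings:
    """Item-emission parameters per module: (tau1, tau2, loading)."""

    params: dict[str, tuple[float, float, float]]
    module_traits: dict[str, str] = dataclasses.field(
        default_factory=lambda: {"autism": "subclinical_autism",
                                 "adhd": "subclinical_adhd"})


def _check_module(module: str) -> int:
    if module not in ATAC_MODULES:
        raise ValueError(f"unknown A-TAC module {module!r}; "
                         f"expected one of {sorted(ATAC_MODULES)}")
    return ATAC_MODULES[module]


def score_module(items, module: str | None = None, row_id=None) -> float:
    """Total score of one module: the sum of its 0/0.5/1 item scores.

    If any item is missing (NaN), the total is missing and the individual is
    excluded from subclinical classification downstream.
    """
    arr = np.asarray(items, dtype=float)
    if module is not None:
        m = _check_module(module)
        if arr.shape[-1] != m:
            raise ValueError(f"{module} module has {m} items, got {arr.shape[-1]}")
    if np.isnan(arr).any():
        return float("nan")
    bad = ~np.isin(arr, [0.0, 0.5, 1.0])
    if bad.any():
        where = f" (row {row_id})" if row_id is not None else ""
        raise ValueError(
            f"item scores must be 0, 0.5 or 1; offending values "
            f"{np.unique(arr[bad])}{where}")
    return float(arr.sum())


def classify_subclinical(total: float, module: str) -> bool:
    """Screen-positive flag at the module's lower cutoff (inclusive)."""
    m = _check_module(module)
    if np.isnan(total):
        return False
    if not 0.0 <= total <= m:
        raise ValueError(f"total {total} outside [0, {m}] for module {module!r}")
    return bool(total >= ATAC_CUTOFFS[module])


def apply_sensitivity_exclusion(assignments) -> "object":
    """Zero out subclinical flags for individuals with the clinical diagnosis.

    Accepts a DataFrame with columns clinical_autism / subclinical_autism /
    clinical_adhd / subclinical_adhd (any subset of the pairs present); all
    other columns are untouched.  Used by the sensitivity analysis that
    checks subclinical results are not driven by clinical cases.
    """
    out = assignments.copy()
    for pheno in ("autism", "adhd"):
        clin, sub = f"clinical_{pheno}", f"subclinical_{pheno}"
        if clin in out.columns and sub in out.columns:
            out.loc[out[clin] == 1, sub] = 0
    return out


# ---------------------------------------------------------------------------
# item emission and exact calibration
# ---------------------------------------------------------------------------


def emit_atac_items(liability, module: str, settings: AtacSettings,
                    rng: np.random.Generator) -> np.ndarray:
    """Item-score matrix (n, n_items) for liabilities under the graded model."""
    m = _check_module(module)
    tau1, tau2, loading = settings.params[module]
    liab = np.atleast_1d(np.asarray(liability, dtype=float))
    noise_sd = np.sqrt(max(1.0 - loading**2, 0.0))
    u = loading * liab[:, None] + noise_sd * rng.standard_normal((liab.shape[0], m))
    return np.where(u >= tau2, 1.0, np.where(u >= tau1, 0.5, 0.0))


def _total_tail_prob(tau1: float, tau2: float, loading: float, m: int,
                     cutoff: float, gh_order: int = 64) -> float:
    """P(total >= cutoff) in the population, exactly.

    Conditional on liability l the items are iid three-level variables; the
    total (in half-point units) is an m-fold convolution, integrated over
    l ~ N(0,1) with Gauss-Hermite quadrature.
    """
    nodes, weights = roots_hermitenorm(gh_order)
    weights = weights / weights.sum()
    s = np.sqrt(max(1.0 - loading**2, 1e-12))
    k_cut = int(np.ceil(cutoff * 2 - 1e-9))  # half-point units
    out = 0.0
    for l, w in zip(nodes, weights):
        p1 = float(ndtr((loading * l - tau2) / s))
        p_ge1 = float(ndtr((loading * l - tau1) / s))
        probs = np.array([1.0 - p_ge1, p_ge1 - p1, p1])
        dist = np.array([1.0])
        for _ in range(m):
            dist = np.convolve(dist, probs)
        out += w * float(dist[k_cut:].sum())
    return out


def atac_screen_rate(settings: AtacSettings, module: str) -> float:
    m = _check_module(module)
    tau1, tau2, loading = settings.params[module]
    return _total_tail_prob(tau1, tau2, loading, m, ATAC_CUTOFFS[module])


def calibrate_atac_settings(loading: float = 0.8, spread: float = 1.0,
                            targets: dict[str, float] | None = None) -> AtacSettings:
    """Solve tau1 per module so the screen-positive rate hits its target.

    ``spread`` is tau2 - tau1, the width of the "to some extent" band in
    item-scale standard deviations.
    """
    targets = dict(SCREEN_RATES if targets is None else targets)
    params = {}
    for module, target in targets.items():
        m = _check_module(module)
        cutoff = ATAC_CUTOFFS[module]

        def f(tau1):
            return _total_tail_prob(tau1, tau1 + spread, loading, m, cutoff) - target

        params[module] = (float(brentq(f, -3.0, 6.0, xtol=1e-10)), None, loading)
        tau1 = params[module][0]
        params[module] = (tau1, tau1 + spread, loading)
    return AtacSettings(params=params)


def assign_phenotypes(cohort, exclude_clinical_from_subclinical: bool = False):
    """Phenotype assignment table from a cohort frame.

    Clinical flags come straight from the diagnosis columns; subclinical
    flags are recomputed from per-item columns when present (individuals with
    any missing item are left unclassified and counted), otherwise existing
    subclinical columns are passed through.
    """
    cols = ["pair_id", "twin_index"]
    out = cohort[cols].copy()
    n_excluded = 0
    for module, pheno in (("autism", "autism"), ("adhd", "adhd")):
        clin = f"clinical_{pheno}"
        if clin in cohort.columns:
            out[clin] = cohort[clin].astype(int)
        item_cols = [c for c in cohort.columns
                     if c.startswith(f"atac_{module}_i")]
        sub = f"subclinical_{pheno}"
        if item_cols:
            items = cohort[item_cols].to_numpy(dtype=float)
            totals = np.where(np.isnan(items).any(axis=1), np.nan, items.sum(axis=1))
            n_excluded += int(np.isnan(totals).sum())
            # listwise: any missing item leaves the individual unclassified
            out[sub] = np.where(np.isnan(totals), 0,
                                (totals >= ATAC_CUTOFFS[module])).astype(int)
            out[f"{sub}_missing"] = np.isnan(totals).astype(int)
        elif sub in cohort.columns:
            out[sub] = cohort[sub].astype(int)
    out.attrs["n_excluded_missing_items"] = n_excluded
    if exclude_clinical_from_subclinical:
        out = apply_sensitivity_exclusion(out)
    return out
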