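"""Twin-pair-clustered association tests between phenotype groups and conditions.

Odds ratios come from a population-averaged logistic model fitted by
generalized estimating equations with an independence working correlation;
standard errors use the pair-level robust (sandwich) covariance, which
accounts for the non-independence of co-twins.  Sex and age group enter as
adjustment factors.  Significance across a panel of outcomes uses a
Bonferroni-corrected threshold.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "fit_clustered_logistic",
    "bonferroni_threshold",
    "exclusive_groups",
    "association_table",
]

_SEPARATION_COEF = 15.0  # |log OR| beyond this is treated as separation


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    exposure: str
    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    significant_bonferroni: bool | None = None
    separation: bool = False

    def with_flag(self, threshold: float) -> "AssociationResult":
        return dataclasses.replace(
            self, significant_bonferroni=bool(self.p_value < threshold))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"test count must be >= 1, got {m}")
    return alpha / m


def fit_clustered_logistic(cohort: pd.DataFrame, exposure: str, outcome: str,
                           covariates: tuple[str, ...] = ("sex", "age"),
                           ) -> AssociationResult:
    """OR of ``outcome`` on ``exposure`` with cluster-robust inference.

    ``covariates`` are entered as categorical factors (reference level = first
    observed).  Complete separation is flagged, with an infinite-bound CI,
    rather than failing silently; an exposure or outcome without variation is
    an error.
    """
    cols = [exposure, outcome, "pair_id", *covariates]
    data = cohort[cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    x = data[exposure].to_numpy(dtype=float)
    for label, v in ((exposure, x), (outcome, y)):
        if not set(np.unique(v)) <= {0.0, 1.0}:
            raise ValueError(f"{label!r} must be binary 0/1")
        if v.min() == v.max():
            raise ValueError(f"{label!r} has no variation (all {v.min():g})")

    X = [np.ones_like(x), x]
    names = ["const", exposure]
    for cov in covariates:
        dummies = pd.get_dummies(data[cov], prefix=cov, drop_first=True)
        for c in dummies.columns:
            X.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(X)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=data["pair_id"].to_numpy(),
                       family=sm.families.Binomial(),
                       cov_struct=sm.cov_struct.Independence())
        try:
            fit = model.fit(maxiter=100)
        except Exception:  # noqa: BLE001 - convergence/separation paths vary
            inf = float("inf")
            return AssociationResult(exposure, outcome, inf, 0.0, inf,
                                     float("nan"), len(data), separation=True)

    beta = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > _SEPARATION_COEF:
        return AssociationResult(exposure, outcome,
                                 float(np.exp(np.clip(beta, -700, 700))),
                                 0.0, float("inf"), float("nan"), len(data),
                                 separation=True)
    z = 1.959963984540054
    return AssociationResult(
        exposure=exposure, outcome=outcome,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(fit.pvalues[1]),
        n_used=int(len(data)))


def exclusive_groups(assignments: pd.DataFrame,
                     autism_col: str = "clinical_autism",
                     adhd_col: str = "clinical_adhd") -> pd.Series:
    """Partition individuals into autism-only / adhd-only / both / neither."""
    a = assignments[autism_col].astype(bool)
    d = assignments[adhd_col].astype(bool)
    labels = np.select(
        [a & d, a & ~d, ~a & d],
        ["autism+adhd", "autism_only", "adhd_only"],
        default="neither")
    return pd.Series(labels, index=assignments.index, name="group")


def association_table(cohort: pd.DataFrame, exposures: list[str],
                      outcomes: list[str], alpha: float = 0.05,
                      bonferroni_m: int | None = None,
                      covariates: tuple[str, ...] = ("sex", "age"),
                      ) -> pd.DataFrame:
    """OR/CI/p grid over exposures x outcomes with Bonferroni flags.

    ``bonferroni_m`` defaults to the number of outcomes (one correction per
    exposure column of the output table).
    """
    m = len(outcomes) if bonferroni_m is None else bonferroni_m
    thr = bonferroni_threshold(alpha, m)
    rows = []
    for outcome in outcomes:
        for exposure in exposures:
            res = fit_clustered_logistic(cohort, exposure, outcome,
                                         covariates=covariates).with_flag(thr)
            rows.append(dataclasses.asdict(res))
    table = pd.DataFrame(rows)
    table.attrs["bonferroni_threshold"] = thr
    return table
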