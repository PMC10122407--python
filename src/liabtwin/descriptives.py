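"""Cohort descriptives: prevalences, cross-twin correlations, concordances.

Cross-twin (cross-trait) tables are double-entered — each pair contributes
both (twin1 trait A, twin2 trait B) and (twin2 trait A, twin1 trait B) — so
estimates are invariant to the arbitrary within-pair twin ordering; the
tetrachoric standard error is corrected by halving the doubled count back to
the number of pairs.  Proportion confidence intervals use the Wilson score
method, which behaves at the small counts typical of rare conditions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .liability import Table2x2, TetrachoricEstimate, tetrachoric_fit

__all__ = [
    "ConcordanceResult",
    "prevalence",
    "pair_wide",
    "cross_twin_table",
    "cross_twin_correlation",
    "proband_cross_concordance",
]


@dataclasses.dataclass(frozen=True)
class ConcordanceResult:
    proband_trait: str
    target_trait: str
    zygosity: str
    n_probands: int
    n_affected_cotwins: int
    proportion: float
    ci_low: float
    ci_high: float
    defined: bool = True


def prevalence(cohort: pd.DataFrame, trait: str,
               by: list[str] | None = None) -> pd.DataFrame:
    """Affected counts, proportions and Wilson 95% CIs, optionally stratified."""
    if trait not in cohort.columns:
        raise KeyError(f"trait column {trait!r} not in cohort")
    groups = cohort.groupby(by, observed=True) if by else [((), cohort)]
    rows = []
    for key, g in groups:
        n = int(g[trait].notna().sum())
        k = int(g[trait].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson") if n else (np.nan,) * 2
        row = dict(zip(by or [], key if isinstance(key, tuple) else (key,)))
        row.update(trait=trait, n_affected=k, n_total=n,
                   prevalence=k / n if n else np.nan, ci_low=lo, ci_high=hi)
        rows.append(row)
    return pd.DataFrame(rows)


def pair_wide(cohort: pd.DataFrame, traits: list[str],
              zygosity: str | None = None) -> pd.DataFrame:
    """One row per complete pair with {trait}_1 / {trait}_2 columns."""
    df = cohort if zygosity is None else cohort[cohort["zygosity"] == zygosity]
    wide = df.pivot_table(index="pair_id", columns="twin_index", values=traits,
                          aggfunc="first")
    wide.columns = [f"{t}_{i}" for t, i in wide.columns]
    need = [f"{t}_{i}" for t in traits for i in (1, 2)]
    return wide.dropna(subset=[c for c in need if c in wide.columns])


def cross_twin_table(cohort: pd.DataFrame, trait_a: str, trait_b: str,
                     zygosity: str) -> tuple[Table2x2, int]:
    """Double-entered cross-twin 2x2 (trait_a in one twin x trait_b in co-twin).

    Returns the table plus the number of contributing pairs.  With
    trait_a == trait_b this is the within-trait cross-twin table.
    """
    wide = pair_wide(cohort, sorted({trait_a, trait_b}), zygosity)
    a1 = wide[f"{trait_a}_1"].to_numpy(dtype=int)
    a2 = wide[f"{trait_a}_2"].to_numpy(dtype=int)
    b1 = wide[f"{trait_b}_1"].to_numpy(dtype=int)
    b2 = wide[f"{trait_b}_2"].to_numpy(dtype=int)
    # entries (a of twin i, b of co-twin), both orderings
    x = np.concatenate([a1, a2])
    y = np.concatenate([b2, b1])
    return Table2x2(
        n11=float(((x == 1) & (y == 1)).sum()),
        n10=float(((x == 1) & (y == 0)).sum()),
        n01=float(((x == 0) & (y == 1)).sum()),
        n00=float(((x == 0) & (y == 0)).sum()),
    ), len(wide)


def cross_twin_correlation(cohort: pd.DataFrame, trait_a: str, trait_b: str,
                           zygosity: str) -> TetrachoricEstimate:
    """Tetrachoric cross-twin (cross-trait) correlation for one zygosity group."""
    table, n_pairs = cross_twin_table(cohort, trait_a, trait_b, zygosity)
    if n_pairs == 0:
        raise ValueError(f"no complete {zygosity} pairs for "
                         f"({trait_a!r}, {trait_b!r})")
    return tetrachoric_fit(table, n_effective=n_pairs)


def proband_cross_concordance(cohort: pd.DataFrame, proband_trait: str,
                              target_trait: str, zygosity: str,
                              ) -> ConcordanceResult:
    """Probability that the co-twin of an affected proband has the target trait.

    Proband-wise counting: every affected individual is a proband, so pairs
    concordant for the proband trait contribute twice.
    """
    wide = pair_wide(cohort, sorted({proband_trait, target_trait}), zygosity)
    p1 = wide[f"{proband_trait}_1"].to_numpy(dtype=int)
    p2 = wide[f"{proband_trait}_2"].to_numpy(dtype=int)
    t1 = wide[f"{target_trait}_1"].to_numpy(dtype=int)
    t2 = wide[f"{target_trait}_2"].to_numpy(dtype=int)
    n_probands = int(p1.sum() + p2.sum())
    if n_probands == 0:
        return ConcordanceResult(proband_trait, target_trait, zygosity, 0, 0,
                                 float("nan"), float("nan"), float("nan"),
                                 defined=False)
    # proband = twin 1 -> co-twin carries trait value t2, and vice versa
    n_affected = int((t2[p1 == 1]).sum() + (t1[p2 == 1]).sum())
    lo, hi = proportion_confint(n_affected, n_probands, alpha=0.05, method="wilson")
    return ConcordanceResult(proband_trait, target_trait, zygosity,
                             n_probands, n_affected, n_affected / n_probands,
                             float(lo), float(hi))
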