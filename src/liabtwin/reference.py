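"""Published summary inputs for the two-stage reproduction.

A nationwide Swedish child-and-adolescent twin cohort (10,347 nine- and
twelve-year-old pairs; 4,767 MZ and 5,580 same-sex DZ pairs) reports, for 13
physical health conditions, the prevalence in the twin-model sample and the
MZ/DZ cross-twin tetrachoric correlations.  Individual-level registry data
are access-restricted, but those printed summaries are sufficient statistics
for the univariate liability model: expected zygosity tables built from
(K, rMZ, N) and (K, rDZ, N) reproduce the published variance components.

These dictionaries are *inputs* to that computation; nothing here stores a
fitted result.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .liability import implied_table
from .univariate import VarianceComponents, fit_with_boundary_refit

__all__ = ["CohortSummary", "CONDITION_SUMMARIES", "N_MZ_PAIRS", "N_DZ_PAIRS",
           "PHENOTYPE_PREVALENCES", "two_stage_variance_components",
           "variance_components_table"]

N_MZ_PAIRS = 4767
N_DZ_PAIRS = 5580


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Printed prevalence (twin-model sample) and cross-twin correlations."""

    K: float
    r_mz: float
    r_dz: float


CONDITION_SUMMARIES: dict[str, CohortSummary] = {
    "epilepsy": CohortSummary(K=0.012, r_mz=0.62, r_dz=0.25),
    "migraine": CohortSummary(K=0.017, r_mz=0.45, r_dz=0.13),
    "other_headache": CohortSummary(K=0.008, r_mz=0.54, r_dz=0.18),
    "mixed_headache": CohortSummary(K=0.023, r_mz=0.49, r_dz=0.12),
    "allergic_rhinitis": CohortSummary(K=0.059, r_mz=0.76, r_dz=0.40),
    "asthma": CohortSummary(K=0.134, r_mz=0.83, r_dz=0.49),
    "atopic_dermatitis": CohortSummary(K=0.051, r_mz=0.79, r_dz=0.43),
    "specific_allergy": CohortSummary(K=0.019, r_mz=0.90, r_dz=0.54),
    "coeliac_disease": CohortSummary(K=0.011, r_mz=0.96, r_dz=0.71),
    "constipation": CohortSummary(K=0.062, r_mz=0.51, r_dz=0.25),
    "functional_diarrhea": CohortSummary(K=0.006, r_mz=0.93, r_dz=0.54),
    "irritable_bowel_syndrome": CohortSummary(K=0.004, r_mz=0.69, r_dz=0.57),
    "mixed_fgids": CohortSummary(K=0.069, r_mz=0.55, r_dz=0.27),
}

# neurodevelopmental phenotype prevalences in the same twin-model sample
PHENOTYPE_PREVALENCES = {
    "clinical_autism": 0.016,
    "subclinical_autism": 0.040,
    "clinical_adhd": 0.043,
    "subclinical_adhd": 0.113,
}


def two_stage_variance_components(summary: CohortSummary,
                                  n_mz: int = N_MZ_PAIRS,
                                  n_dz: int = N_DZ_PAIRS,
                                  compute_ci: bool = False,
                                  ) -> VarianceComponents:
    """ACE fit to the expected tables implied by printed (K, rMZ, rDZ).

    When C sits on its zero bound, the reported genetic share comes from the
    AE refit, matching the convention of printing C = 0.
    """
    mz = implied_table(summary.K, summary.K, summary.r_mz, n_mz)
    dz = implied_table(summary.K, summary.K, summary.r_dz, n_dz)
    ace, ae = fit_with_boundary_refit(mz, dz, compute_ci=compute_ci)
    return ae if ae is not None else ace


def variance_components_table(conditions: list[str] | None = None,
                              compute_ci: bool = False) -> pd.DataFrame:
    """Two-stage A/V, C/V, E/V for each condition with printed summaries."""
    names = list(CONDITION_SUMMARIES) if conditions is None else conditions
    rows = []
    for name in names:
        s = CONDITION_SUMMARIES[name]
        vc = two_stage_variance_components(s, compute_ci=compute_ci)
        rows.append({
            "condition": name, "K": s.K, "r_mz": s.r_mz, "r_dz": s.r_dz,
            "model": vc.model, "a2": vc.a2,
            "c2": 0.0 if vc.model == "AE" else vc.c2, "e2": vc.e2,
            "a2_ci_low": vc.a2_ci[0] if vc.a2_ci else None,
            "a2_ci_high": vc.a2_ci[1] if vc.a2_ci else None,
        })
    return pd.DataFrame(rows)
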