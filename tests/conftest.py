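import numpy as np
import pytest

from liabtwin.simulate import CohortSpec, CrossTraitSpec, TraitSpec, simulate_cohort

SEED = 20230421


@pytest.fixture(scope="session")
def comorbid_cohort():
    """Mid-size cohort with a heritable exposure-outcome pair (ra = 0.5).

    Trait parameters mirror an asthma-like condition (a2=0.68, c2=0.15,
    K=0.134) and a rarer, highly heritable exposure (a2=0.8, K=0.05).
    """
    spec = CohortSpec(
        traits=[
            TraitSpec("exposure", a2=0.8, c2=0.0, e2=0.2, K=0.05),
            TraitSpec("outcome", a2=0.68, c2=0.15, e2=0.17, K=0.134),
        ],
        cross={("exposure", "outcome"): CrossTraitSpec(ra=0.5)},
        n_mz=6000, n_dz=6000, seed=SEED)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """Two independent traits; no familial or cross-trait structure."""
    spec = CohortSpec(
        traits=[
            TraitSpec("exposure", a2=0.0, c2=0.0, e2=1.0, K=0.10),
            TraitSpec("outcome", a2=0.0, c2=0.3, e2=0.7, K=0.10),
        ],
        n_mz=5000, n_dz=5000, seed=SEED + 1)
    return simulate_cohort(spec)
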