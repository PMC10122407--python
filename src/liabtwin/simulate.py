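"""Synthetic twin-cohort generation.

Simulates classical-twin-design cohorts of MZ and same-sex DZ pairs with
binary phenotypes produced by thresholding multivariate-normal liabilities.
Per trait, liability decomposes into additive-genetic (A), shared-environment
(C) and nonshared-environment (E) standard components with variance shares
a2/c2/e2; A correlates 1.0 between MZ co-twins and 0.5 between DZ co-twins,
C is fully shared, E is twin-specific.  Cross-trait structure is generated in
the correlated-factors parameterization: the A factors of two traits
correlate ra, the C factors rc and the E factors re, giving a within-person
phenotypic liability correlation rPH = a1*a2*ra + c1*c2*rc + e1*e2*re.

Defaults mirror a nationwide Swedish child-and-adolescent twin cohort of
10,347 nine- and twelve-year-old pairs: 4,767 MZ and 5,580 same-sex DZ pairs,
age split 8,125 : 2,222 (ages 9 : 12), and an even sex ratio.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atac import AtacSettings, ATAC_MODULES, emit_atac_items
from .liability import threshold_from_prevalence

__all__ = [
    "TraitSpec",
    "CrossTraitSpec",
    "CohortSpec",
    "simulate_cohort",
    "pair_liability_correlation",
    "write_cohort_csv",
    "read_cohort_csv",
]

N_MZ_DEFAULT = 4767
N_DZ_DEFAULT = 5580
AGE_LEVELS_DEFAULT = {9: 8125 / 10347, 12: 2222 / 10347}


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """One binary trait: variance shares of liability and population prevalence."""

    name: str
    a2: float
    c2: float
    e2: float
    K: float

    def __post_init__(self):
        for label, v in (("a2", self.a2), ("c2", self.c2), ("e2", self.e2)):
            if v < -1e-12:
                raise ValueError(f"{label} must be nonnegative, got {v}")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ValueError(
                f"variance shares must sum to 1, got {self.a2 + self.c2 + self.e2}")
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence must lie in (0, 1), got {self.K}")

    @property
    def paths(self) -> tuple[float, float, float]:
        return (np.sqrt(max(self.a2, 0.0)), np.sqrt(max(self.c2, 0.0)),
                np.sqrt(max(self.e2, 0.0)))


@dataclasses.dataclass(frozen=True)
class CrossTraitSpec:
    """Etiologic correlations between the component factors of two traits."""

    ra: float = 0.0
    rc: float = 0.0
    re: float = 0.0

    def __post_init__(self):
        for label, v in (("ra", self.ra), ("rc", self.rc), ("re", self.re)):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{label} must lie in [-1, 1], got {v}")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    traits: Sequence[TraitSpec]
    cross: Mapping[tuple[str, str], CrossTraitSpec] = dataclasses.field(default_factory=dict)
    n_mz: int = N_MZ_DEFAULT
    n_dz: int = N_DZ_DEFAULT
    n_dzos: int = 0  # opposite-sex DZ pairs, descriptives only; excluded from twin models
    sex_ratio: float = 0.5
    age_levels: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(AGE_LEVELS_DEFAULT))
    atac: AtacSettings | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_mz < 0 or self.n_dz < 0 or self.n_dzos < 0:
            raise ValueError("pair counts must be nonnegative")
        if abs(sum(self.age_levels.values()) - 1.0) > 1e-9:
            raise ValueError("age-level proportions must sum to 1")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("trait names must be unique")
        for key in self.cross:
            for nm in key:
                if nm not in names:
                    raise ValueError(f"cross-trait spec references unknown trait {nm!r}")
        # fail fast on an inconsistent correlation structure
        for zyg in ("MZ", "DZ"):
            pair_liability_correlation(list(self.traits), dict(self.cross), zyg)

    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]


def _cross_lookup(cross: Mapping[tuple[str, str], CrossTraitSpec],
                  a: str, b: str) -> CrossTraitSpec:
    if (a, b) in cross:
        return cross[(a, b)]
    if (b, a) in cross:
        return cross[(b, a)]
    return CrossTraitSpec()


def pair_liability_correlation(traits: Sequence[TraitSpec],
                               cross: Mapping[tuple[str, str], CrossTraitSpec],
                               zygosity: str) -> np.ndarray:
    """Implied 2T x 2T liability correlation matrix for one twin pair.

    Row order: twin 1 traits 1..T, then twin 2 traits 1..T.  Raises if the
    implied matrix is not positive semi-definite.
    """
    g = {"MZ": 1.0, "DZ": 0.5, "DZOS": 0.5}[zygosity]
    T = len(traits)
    R = np.eye(2 * T)
    for j, k in itertools.product(range(T), range(T)):
        tj, tk = traits[j], traits[k]
        aj, cj, ej = tj.paths
        ak, ck, ek = tk.paths
        cs = _cross_lookup(cross, tj.name, tk.name)
        if j != k:
            within = aj * ak * cs.ra + cj * ck * cs.rc + ej * ek * cs.re
            R[j, k] = R[T + j, T + k] = within
        across = (g * aj * ak * (1.0 if j == k else cs.ra)
                  + cj * ck * (1.0 if j == k else cs.rc))
        R[j, T + k] = R[T + k, j] = across
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"implied liability correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigmin:.3e}); check variance shares and "
            f"etiologic correlations")
    return R


def _sample_group(rng: np.random.Generator, n_pairs: int, R: np.ndarray,
                  thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent liabilities (n_pairs, 2T) and binary phenotypes per twin."""
    T = thresholds.shape[0]
    eigvals, eigvecs = np.linalg.eigh(R)
    L = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    z = rng.standard_normal((n_pairs, 2 * T)) @ L.T
    y = (z > thresholds[np.concatenate([np.arange(T), np.arange(T)])]).astype(np.int8)
    return z, y


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a twin cohort; one row per individual, fully seeded.

    Columns: pair_id, twin_index (1/2), zygosity, sex (F/M), age, one 0/1
    column per trait, and (when A-TAC emission is configured) per-item scores
    plus module totals.
    """
    rng = np.random.default_rng(spec.seed)
    traits = list(spec.traits)
    thresholds = np.array([threshold_from_prevalence(t.K).t for t in traits])
    names = [t.name for t in traits]
    T = len(traits)

    frames = []
    pair_offset = 0
    for zyg, n_pairs in (("MZ", spec.n_mz), ("DZ", spec.n_dz), ("DZOS", spec.n_dzos)):
        if n_pairs == 0:
            continue
        R = pair_liability_correlation(traits, spec.cross, zyg)
        z, y = _sample_group(rng, n_pairs, R, thresholds)
        pair_ids = pair_offset + np.arange(n_pairs)
        pair_offset += n_pairs
        if zyg == "DZOS":
            sex1 = np.where(rng.random(n_pairs) < spec.sex_ratio, "F", "M")
            sex2 = np.where(sex1 == "F", "M", "F")
        else:
            sex1 = sex2 = np.where(rng.random(n_pairs) < spec.sex_ratio, "F", "M")
        ages = rng.choice(list(spec.age_levels), size=n_pairs,
                          p=list(spec.age_levels.values()))
        for twin in (1, 2):
            cols = {
                "pair_id": pair_ids,
                "twin_index": twin,
                "zygosity": zyg,
                "sex": sex1 if twin == 1 else sex2,
                "age": ages,
            }
            sl = slice(0, T) if twin == 1 else slice(T, 2 * T)
            for j, nm in enumerate(names):
                cols[nm] = y[:, sl][:, j]
            df = pd.DataFrame(cols)
            if spec.atac is not None:
                _attach_atac(df, z[:, sl], names, spec.atac, rng)
            frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["pair_id", "twin_index"], inplace=True, kind="stable")
    out.reset_index(drop=True, inplace=True)
    return out


def _attach_atac(df: pd.DataFrame, liab: np.ndarray, names: list[str],
                 settings: AtacSettings, rng: np.random.Generator) -> None:
    for module, trait in settings.module_traits.items():
        if trait not in names:
            raise ValueError(f"A-TAC module {module!r} maps to unknown trait {trait!r}")
        m = ATAC_MODULES[module]
        items = emit_atac_items(liab[:, names.index(trait)], module, settings, rng)
        prefix = f"atac_{module}"
        for i in range(m):
            df[f"{prefix}_i{i + 1}"] = items[:, i]
        df[f"{prefix}_total"] = items.sum(axis=1)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"pair_id", "twin_index", "zygosity", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {sorted(missing)}")
    return df
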