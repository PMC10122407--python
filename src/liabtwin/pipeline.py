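"""Configuration-driven orchestration of the full analysis.

One run takes a cohort (CSV on disk or a simulation spec), and emits the
standard table set:

* table1.tsv  — prevalences, overall and by zygosity,
* table2.tsv  — pair-clustered, sex/age-adjusted odds ratios with a
  Bonferroni significance flag,
* table3.tsv  — univariate ACE/AE/E variance components with LRTs,
* table4.tsv  — proband-wise cross-concordances for significant pairs,
* bivariate/<exposure>__<outcome>.json and fig1_contributions.tsv — the
  correlated-factors decomposition for pairs passing the Bonferroni gate,
* manifest.json — seed, versions, counts, per-stage runtimes.

Only exposure-outcome pairs significant at the Bonferroni-corrected level
advance to the bivariate stage, and only MZ and same-sex DZ rows enter the
twin-model stages; the association stage uses every configured row.
Structured per-stage log lines go to stderr; results never do.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import association_table
from .atac import apply_sensitivity_exclusion, calibrate_atac_settings
from .bivariate import decompose_rph, fit_bivariate, pair_trait_table
from .descriptives import prevalence, proband_cross_concordance
from .liability import Table2x2
from .descriptives import cross_twin_table
from .simulate import (CohortSpec, CrossTraitSpec, TraitSpec, read_cohort_csv,
                       simulate_cohort)
from .univariate import compare_models, fit_univariate

__all__ = ["RunConfig", "load_config", "run_pipeline"]

logger = logging.getLogger("liabtwin")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

TWIN_MODEL_ZYGOSITIES = ("MZ", "DZ")  # same-sex pairs only


@dataclasses.dataclass
class RunConfig:
    exposures: list[str]
    outcomes: list[str]
    cohort_csv: str | None = None
    cohort_spec: CohortSpec | None = None
    alpha: float = 0.05
    bonferroni_m: int | None = None
    models: tuple[str, ...] = ("ACE", "AE", "E")
    sensitivity_exclusion: bool = False
    bivariate_method: str = "full"
    seed: int = 0
    out_dir: str = "liabtwin_out"

    def __post_init__(self):
        if self.cohort_csv is None and self.cohort_spec is None:
            raise ValueError("config needs either a cohort CSV or a cohort spec")


def _spec_from_mapping(d: dict, seed: int) -> CohortSpec:
    traits = []
    for t in d["traits"]:
        a2 = float(t.get("a2", 0.0))
        c2 = float(t.get("c2", 0.0))
        e2 = float(t.get("e2", 1.0 - a2 - c2))
        traits.append(TraitSpec(name=t["name"], a2=a2, c2=c2, e2=e2, K=float(t["K"])))
    cross = {}
    for c in d.get("cross", []):
        cross[(c["a"], c["b"])] = CrossTraitSpec(
            ra=float(c.get("ra", 0.0)), rc=float(c.get("rc", 0.0)),
            re=float(c.get("re", 0.0)))
    atac = None
    atac_cfg = d.get("atac")
    if atac_cfg and atac_cfg.get("enabled", True):
        atac = calibrate_atac_settings(
            loading=float(atac_cfg.get("loading", 0.8)),
            spread=float(atac_cfg.get("spread", 1.0)))
    kwargs = {k: d[k] for k in ("n_mz", "n_dz", "n_dzos", "sex_ratio") if k in d}
    if "age_levels" in d:
        kwargs["age_levels"] = {int(k): float(v) for k, v in d["age_levels"].items()}
    return CohortSpec(traits=traits, cross=cross, atac=atac, seed=seed, **kwargs)


def load_config(path) -> RunConfig:
    """Read a YAML (or JSON — YAML is a superset) run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    seed = int(raw.get("seed", 0))
    cohort = raw.get("cohort", {})
    spec = None
    if "spec" in cohort:
        spec = _spec_from_mapping(cohort["spec"], seed)
    return RunConfig(
        exposures=list(raw["exposures"]), outcomes=list(raw["outcomes"]),
        cohort_csv=cohort.get("csv"), cohort_spec=spec,
        alpha=float(raw.get("alpha", 0.05)),
        bonferroni_m=raw.get("bonferroni_m"),
        models=tuple(raw.get("models", ("ACE", "AE", "E"))),
        sensitivity_exclusion=bool(raw.get("sensitivity_exclusion", False)),
        bivariate_method=str(raw.get("bivariate_method", "full")),
        seed=seed, out_dir=str(raw.get("out_dir", "liabtwin_out")))


def _stage(manifest: dict, name: str, t0: float, **info) -> None:
    dt = time.time() - t0
    manifest["stages"].append({"stage": name, "runtime_s": round(dt, 3), **info})
    logger.info("stage=%s runtime=%.2fs %s", name, dt,
                " ".join(f"{k}={v}" for k, v in info.items()))


def _halved(table: Table2x2) -> Table2x2:
    # double-entered table back to one entry per pair (fractional is fine)
    return Table2x2(table.n11 / 2, table.n10 / 2, table.n01 / 2, table.n00 / 2)


def run_pipeline(config: RunConfig) -> dict:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "bivariate").mkdir(exist_ok=True)
    manifest: dict = {"seed": config.seed, "liabtwin_version": __version__,
                      "pandas_version": pd.__version__, "stages": []}

    t0 = time.time()
    if config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv)
        source = config.cohort_csv
    else:
        cohort = simulate_cohort(config.cohort_spec)
        source = "simulated"
    if config.sensitivity_exclusion:
        cohort = apply_sensitivity_exclusion(cohort)
    all_traits = config.exposures + config.outcomes
    missing = [c for c in all_traits if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks configured columns: {missing}")
    manifest["n_individuals"] = int(len(cohort))
    manifest["n_pairs"] = int(cohort["pair_id"].nunique())
    _stage(manifest, "load_cohort", t0, source=source, n=len(cohort))

    # --- table 1: prevalences --------------------------------------------
    t0 = time.time()
    frames = [prevalence(cohort, t) for t in all_traits]
    frames += [prevalence(cohort, t, by=["zygosity"]) for t in all_traits]
    table1 = pd.concat(frames, ignore_index=True)
    table1.to_csv(out_dir / "table1.tsv", sep="\t", index=False)
    _stage(manifest, "table1_prevalence", t0, traits=len(all_traits))

    # --- table 2: associations -------------------------------------------
    t0 = time.time()
    try:
        table2 = association_table(cohort, config.exposures, config.outcomes,
                                   alpha=config.alpha,
                                   bonferroni_m=config.bonferroni_m)
    except Exception as exc:
        raise RuntimeError(f"stage association failed: {exc}") from exc
    table2.to_csv(out_dir / "table2.tsv", sep="\t", index=False)
    threshold = table2.attrs["bonferroni_threshold"]
    manifest["bonferroni_threshold"] = round(threshold, 4)
    _stage(manifest, "table2_association", t0, tests=len(table2))

    twin = cohort[cohort["zygosity"].isin(TWIN_MODEL_ZYGOSITIES)]
    manifest["n_pairs_twin_models"] = int(twin["pair_id"].nunique())

    # --- table 3: univariate variance components --------------------------
    t0 = time.time()
    rows = []
    for trait in config.outcomes:
        try:
            fits = {}
            tables = {}
            for zyg in TWIN_MODEL_ZYGOSITIES:
                tab, _ = cross_twin_table(twin, trait, trait, zyg)
                tables[zyg] = _halved(tab)
            for model in config.models:
                fits[model] = fit_univariate(tables["MZ"], tables["DZ"], model,
                                             compute_ci=(model == "ACE"))
        except Exception as exc:
            raise RuntimeError(f"stage univariate failed for {trait!r}: {exc}") from exc
        full = fits.get("ACE")
        for model, vc in fits.items():
            lrt_p = None
            if full is not None and model != "ACE":
                lrt_p = compare_models(full, vc).p_value
            rows.append({
                "trait": trait, "model": model, "a2": vc.a2, "c2": vc.c2,
                "e2": vc.e2,
                "a2_ci_low": vc.a2_ci[0] if vc.a2_ci else None,
                "a2_ci_high": vc.a2_ci[1] if vc.a2_ci else None,
                "c2_ci_low": vc.c2_ci[0] if vc.c2_ci else None,
                "c2_ci_high": vc.c2_ci[1] if vc.c2_ci else None,
                "minus2LL": vc.minus2LL, "aic": vc.aic,
                "lrt_p_vs_ACE": lrt_p, "c2_at_boundary": vc.c2_at_boundary,
                "ci_method": "profile" if vc.a2_ci else None,
            })
    pd.DataFrame(rows).to_csv(out_dir / "table3.tsv", sep="\t", index=False)
    _stage(manifest, "table3_univariate", t0, traits=len(config.outcomes))

    # --- Bonferroni gate ---------------------------------------------------
    sig = table2[table2["significant_bonferroni"] == True]  # noqa: E712
    sig_pairs = list(zip(sig["exposure"], sig["outcome"]))
    manifest["significant_pairs"] = [list(p) for p in sig_pairs]

    # --- table 4: concordances --------------------------------------------
    t0 = time.time()
    rows = []
    for exposure, outcome in sig_pairs:
        for zyg in TWIN_MODEL_ZYGOSITIES:
            res = proband_cross_concordance(twin, exposure, outcome, zyg)
            rows.append({"proband_trait": exposure, "target_trait": outcome,
                         "zygosity": zyg, "n_probands": res.n_probands,
                         "proportion": res.proportion, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "ci_method": "wilson",
                         "defined": res.defined})
    pd.DataFrame(rows, columns=["proband_trait", "target_trait", "zygosity",
                                "n_probands", "proportion", "ci_low",
                                "ci_high", "ci_method", "defined"]
                 ).to_csv(out_dir / "table4.tsv", sep="\t", index=False)
    _stage(manifest, "table4_concordance", t0, pairs=len(sig_pairs))

    # --- bivariate models --------------------------------------------------
    t0 = time.time()
    contrib_rows = []
    for exposure, outcome in sig_pairs:
        try:
            mz = pair_trait_table(twin, exposure, outcome, "MZ")
            dz = pair_trait_table(twin, exposure, outcome, "DZ")
            fit = fit_bivariate(mz, dz, method=config.bivariate_method)
        except Exception as exc:
            raise RuntimeError(
                f"stage bivariate failed for ({exposure!r}, {outcome!r}): {exc}"
            ) from exc
        dec = decompose_rph(fit)
        payload = {
            "exposure": exposure, "outcome": outcome,
            "method": fit.method, "converged": fit.converged,
            "a2": fit.params.a1**2, "c2": fit.params.c1**2, "e2": fit.params.e1**2,
            "outcome_a2": fit.params.a2**2, "outcome_c2": fit.params.c2**2,
            "ra": fit.params.ra, "rc": fit.params.rc, "re": fit.params.re,
            "rph": fit.rph,
            "contributions": {"genetic": dec["genetic"],
                              "shared_env": dec["shared_env"],
                              "nonshared_env": dec["nonshared_env"]},
            "bivariate_heritability": dec["bivariate_heritability"],
            "minus2LL": fit.minus2LL, "aic": fit.aic,
            "thresholds": [fit.params.t1, fit.params.t2],
            "seed": config.seed,
        }
        name = f"{exposure}__{outcome}.json"
        with open(out_dir / "bivariate" / name, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        contrib_rows.append({
            "exposure": exposure, "outcome": outcome, "rph": fit.rph,
            "genetic": dec["genetic"], "shared_env": dec["shared_env"],
            "nonshared_env": dec["nonshared_env"]})
    pd.DataFrame(contrib_rows, columns=["exposure", "outcome", "rph", "genetic",
                                        "shared_env", "nonshared_env"]
                 ).to_csv(out_dir / "fig1_contributions.tsv", sep="\t", index=False)
    _stage(manifest, "bivariate", t0, fits=len(sig_pairs))

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"out_dir": str(out_dir), "manifest": manifest}
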