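"""Orchestration of the full comparative workflow.

The comparative analysis fits a *ladder* of models with nested covariate
sets on the same cohort — for the multilevel backend a null model, then
individual covariates, then each area covariate, then the full model
(Models 1-5); for the spatial backend the same sequence plus the two
reduced variants that drop the spatial or the unstructured effect
(Models 7-13) — and tabulates the area-level variance summaries (MOR,
variance components, spatial fraction) per rung together with a
side-by-side comparison of the two backends' exponentiated fixed effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adjacency import AdjacencyStructure
from .data import Cohort, aggregate_strata, expand_person_period
from .multilevel import DiscreteTimeMultilevel, MultilevelResults
from .spatial import SpatialPoissonModel, SpatialResults

__all__ = ["LadderConfig", "run_ladder", "compare_fixed_effects", "default_ladder"]


@dataclass
class LadderConfig:
    """Ordered model ladders for both backends.

    ``multilevel_models`` / ``spatial_models`` map model id to a covariate
    list; spatial entries may carry ``include_u`` / ``include_v`` flags as a
    ``(covariates, include_u, include_v)`` tuple.
    """

    multilevel_models: dict[str, list[str]] = field(default_factory=dict)
    spatial_models: dict[str, tuple[list[str], bool, bool]] = field(default_factory=dict)
    mcmc_multilevel: dict = field(default_factory=dict)
    mcmc_spatial: dict = field(default_factory=dict)
    seed: int = 0
    max_years: int = 5

    def __post_init__(self) -> None:
        ids = list(self.multilevel_models) + list(self.spatial_models)
        if len(ids) != len(set(ids)):
            raise ValueError("model ids must be unique")


def default_ladder(
    individual: list[str],
    area: list[str],
    seed: int = 0,
    mcmc_multilevel: dict | None = None,
    mcmc_spatial: dict | None = None,
) -> LadderConfig:
    """The standard three-step strategy: null, +individual covariates, +each
    area covariate separately, full; spatial side adds the two single-effect
    variants of the full model."""
    ml = {"1_null": [], "2_individual": list(individual)}
    sp = {"7_null": ([], True, True), "8_individual": (list(individual), True, True)}
    for i, a in enumerate(area):
        ml[f"{3 + i}_{a}"] = list(individual) + [a]
        sp[f"{9 + i}_{a}"] = (list(individual) + [a], True, True)
    full = list(individual) + list(area)
    ml["5_full"] = full
    sp["11_full"] = (full, True, True)
    sp["12_no_spatial"] = (full, False, True)
    sp["13_no_unstructured"] = (full, True, False)
    return LadderConfig(
        multilevel_models=ml,
        spatial_models=sp,
        seed=seed,
        mcmc_multilevel=mcmc_multilevel or {},
        mcmc_spatial=mcmc_spatial or {},
    )


def run_ladder(
    cohort: Cohort,
    adj: AdjacencyStructure,
    ladder: LadderConfig,
    out_dir: str | None = None,
) -> dict:
    """Fit every model in both ladders and build the report bundle.

    Returns a dict with ``area_effects_multilevel`` (variance, Wald p, MOR
    per rung), ``area_effects_spatial`` (variance components and spatial
    fraction per rung), ``fixed_effects`` (OR vs RR for the full models),
    per-model results objects, and a run log.  A model failure is recorded
    in the log and the remaining rungs still run.
    """
    pp = expand_person_period(cohort, ladder.max_years)
    log: dict = {"seed": ladder.seed, "mcmc_multilevel": ladder.mcmc_multilevel,
                 "mcmc_spatial": ladder.mcmc_spatial, "errors": {}}
    ml_results: dict[str, MultilevelResults] = {}
    rows4 = []
    for mid, covs in ladder.multilevel_models.items():
        try:
            model = DiscreteTimeMultilevel(pp, covs, n_areas=adj.n_areas, max_years=ladder.max_years)
            res = model.fit(seed=ladder.seed, **ladder.mcmc_multilevel)
        except Exception as exc:
            log["errors"][mid] = str(exc)
            continue
        ml_results[mid] = res
        s2 = res.sigma2_u
        mor, (mlo, mhi) = res.mor()
        _, wald_p = res.wald_area_test()
        dic_val, p_d = res.dic()
        rows4.append(
            {
                "model": mid,
                "sigma2_u": float(np.median(s2)),
                "cri_2.5": float(np.percentile(s2, 2.5)),
                "cri_97.5": float(np.percentile(s2, 97.5)),
                "wald_p": wald_p,
                "mor": mor,
                "mor_2.5": mlo,
                "mor_97.5": mhi,
                "dic": dic_val,
                "pd": p_d,
            }
        )

    sp_results: dict[str, SpatialResults] = {}
    rows5 = []
    for mid, (covs, inc_u, inc_v) in ladder.spatial_models.items():
        try:
            strata_covs = covs if covs else ["_const"]
            frame = cohort.frame
            if not covs:
                frame = frame.assign(_const=0)
                cohort_m = Cohort(frame, covariates=cohort.covariates + ["_const"])
            else:
                cohort_m = cohort
            strata = aggregate_strata(cohort_m, strata_covs, ladder.max_years)
            model = SpatialPoissonModel(
                strata, adj, covs, include_u=inc_u, include_v=inc_v, max_years=ladder.max_years
            )
            res = model.fit(seed=ladder.seed, **ladder.mcmc_spatial)
        except Exception as exc:
            log["errors"][mid] = str(exc)
            continue
        sp_results[mid] = res
        vc = res.variance_components()
        row = {
            "model": mid,
            "sigma2_u_marginal": vc.loc["sigma2_u_marginal", "median"] if inc_u else np.nan,
            "sigma2_v": vc.loc["sigma2_v", "median"] if inc_v else np.nan,
            "total": vc.loc["total", "median"] if (inc_u and inc_v) else np.nan,
        }
        if inc_u and inc_v:
            psi, (plo, phi) = res.spatial_fraction()
            row.update({"psi": psi, "psi_2.5": plo, "psi_97.5": phi})
        dic_val, p_d = res.dic()
        row.update({"dic": dic_val, "pd": p_d})
        rows5.append(row)

    report = {
        "area_effects_multilevel": pd.DataFrame(rows4),
        "area_effects_spatial": pd.DataFrame(rows5),
        "multilevel_results": ml_results,
        "spatial_results": sp_results,
        "log": log,
    }
    # pick the full models (last fitted) for the fixed-effect comparison
    ml_full = ml_results.get("5_full") or (list(ml_results.values())[-1] if ml_results else None)
    sp_full = sp_results.get("11_full")
    if sp_full is None:
        both = [r for r in sp_results.values() if r.model.include_u and r.model.include_v]
        sp_full = both[-1] if both else None
    if ml_full is not None and sp_full is not None and ml_full.model.covariates:
        report["fixed_effects"] = compare_fixed_effects(ml_full, sp_full, cohort)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report["area_effects_multilevel"].to_csv(out / "area_effects_multilevel.csv", index=False)
        report["area_effects_spatial"].to_csv(out / "area_effects_spatial.csv", index=False)
        if "fixed_effects" in report:
            report["fixed_effects"].to_csv(out / "fixed_effects.csv")
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)
    return report


def compare_fixed_effects(
    ml: MultilevelResults,
    sp: SpatialResults,
    cohort: Cohort,
    high_share_threshold: float = 0.5,
) -> pd.DataFrame:
    """Side-by-side OR (multilevel) vs RR (spatial) per covariate level, the
    OR/RR ratio, and a flag for levels whose event share exceeds
    ``high_share_threshold`` — there the rare-event approximation breaks and
    OR is expected to exceed RR."""
    ors = ml.odds_ratios()
    rrs = sp.relative_risks()
    if set(ors.index) != set(rrs.index):
        raise ValueError("covariate coding differs between the two fitted models")
    shares = {}
    df = cohort.frame
    for nm in ors.index:
        cov, level = nm[:-1].split("[", 1)
        sub = df[df[cov].astype(str) == level]
        shares[nm] = float(sub["event"].mean()) if len(sub) else np.nan
    out = pd.DataFrame(
        {
            "or": ors["or"],
            "rr": rrs.loc[ors.index, "rr"],
            "ratio": ors["or"] / rrs.loc[ors.index, "rr"],
            "event_share": pd.Series(shares),
        }
    )
    out["high_event_share"] = out["event_share"] > high_share_threshold
    return out
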