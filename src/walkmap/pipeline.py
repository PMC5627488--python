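"""End-to-end analysis pipeline.

Runs simulate -> walkability index -> outcome derivation -> stage-1
adjustment -> BYM model ladder -> variance partition / disease maps ->
post-stratification weighting check from a single YAML-configurable
:class:`PipelineConfig`, writing every artifact (CSV/GeoJSON/JSON) plus a run
log and a config snapshot into one output directory.  All randomness is
routed through a single seed expanded into per-stage substreams, so reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bym, individual, outcomes, variance, weighting
from .covariates import CovariateSpec
from .synthetic import GeneratorConfig, simulate_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "walkmap_run"
    generator: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=lambda: {
        "iterations": 8000, "thin": 4, "n_chains": 2})
    outcomes: list = field(default_factory=lambda: ["sufficient_walking"])
    models: list = field(default_factory=lambda: ["M1", "M2", "M3"])
    weighting_rate: float = 0.1
    environment_csv: str = None   # optional: load instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - report stage and cause
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return result, time.perf_counter() - t0
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns in-memory results per stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"seed": config.seed, "stages": {}, "warnings": []}
    results = {}

    gen_kwargs = dict(config.generator)
    gen_kwargs["seed"] = config.seed
    gcfg = GeneratorConfig(**gen_kwargs)

    @_stage("simulate")
    def do_simulate():
        study = simulate_study(gcfg)
        study["lattice"].to_geojson(out / "lattice.geojson")
        study["lattice"].write_edgelist(out / "adjacency.csv")
        study["environment"].to_csv(out / "environment.csv", index=False)
        study["cohort"].to_csv(out / "cohort.csv", index=False)
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in study["truth"].items()}
        (out / "truth.json").write_text(json.dumps(truth))
        return study

    study, dt = do_simulate()
    log["stages"]["simulate"] = dt
    results["study"] = study

    @_stage("walkability_index")
    def do_index():
        scores = study["scores"]
        scores.to_csv(out / "walkability_scores.csv", index=False)
        variance.export_choropleth(
            scores.assign(total=scores["total"].astype(float)),
            study["lattice"], "total", path=out / "walkability.geojson")
        return scores

    scores, dt = do_index()
    log["stages"]["walkability_index"] = dt

    @_stage("outcomes")
    def do_outcomes():
        flags = outcomes.classify(study["cohort"])
        merged = pd.concat(
            [study["cohort"][["area_id"]],
             study["area_covariates"].set_index("area_id")
             .loc[study["cohort"]["area_id"]].reset_index(drop=True),
             flags], axis=1)
        prev = outcomes.cohort_prevalence(merged, strata="walkability")
        prev.to_csv(out / "prevalence_by_walkability.csv", index=False)
        return flags

    flags, dt = do_outcomes()
    log["stages"]["outcomes"] = dt
    results["flags"] = flags

    structure = bym.ICARStructure.from_lattice(study["lattice"])
    spec = CovariateSpec()
    results["stage1"] = {}
    results["stage2"] = {}
    results["maps"] = {}

    for outcome_name in config.outcomes:
        @_stage(f"stage1[{outcome_name}]")
        def do_stage1(oc=outcome_name):
            cohort = pd.concat([study["cohort"], flags], axis=1) \
                if oc not in study["cohort"] else study["cohort"]
            s1 = individual.stage1(cohort, oc, spec)
            s1["odds_ratios"].to_csv(out / f"{oc}_odds_ratios.csv", index=False)
            s1["expected"].to_csv(out / f"{oc}_expected_adjusted.csv", index=False)
            y = cohort[oc].to_numpy().astype(float)
            unadj = individual.expected_counts(cohort, y, mode="unadjusted")
            unadj.to_csv(out / f"{oc}_expected_unadjusted.csv", index=False)
            return {"s1": s1, "unadjusted": unadj, "cohort": cohort, "y": y}

        st1, dt = do_stage1()
        log["stages"][f"stage1[{outcome_name}]"] = dt
        results["stage1"][outcome_name] = st1

        @_stage(f"stage2[{outcome_name}]")
        def do_stage2(oc=outcome_name, st=st1):
            mcfg = bym.MCMCConfig(seed=config.seed, **config.mcmc)
            ladder = bym.fit_ladder(
                st["unadjusted"], st["s1"]["expected"], scores,
                study["environment"][["area_id", "disadvantage"]],
                structure, mcfg, models=config.models)
            ladder["comparison"].to_csv(out / f"{oc}_ladder.csv", index=False)
            for mdl, fit in ladder["fits"].items():
                fit["summary"].to_csv(out / f"{oc}_{mdl}_summary.csv", index=False)
            return ladder

        ladder, dt = do_stage2()
        log["stages"][f"stage2[{outcome_name}]"] = dt
        results["stage2"][outcome_name] = ladder

        @_stage(f"maps[{outcome_name}]")
        def do_maps(oc=outcome_name, lad=ladder):
            rows = []
            for mdl, fit in lad["fits"].items():
                frac = variance.spatial_fraction(fit["draws"])
                epr = variance.excess_pr(fit["draws"])
                variance.export_choropleth(
                    epr, study["lattice"], "excess_pr",
                    path=out / f"{oc}_{mdl}_excess_pr.geojson")
                rows.append({"model": mdl, **{k: v for k, v in frac.items()
                                              if k != "method"}})
            tbl = pd.DataFrame(rows)
            base = lad["fits"].get("M1")
            if base is not None:
                tbl["spatial_variance_reduction_vs_M1"] = [
                    variance.variance_reduction(base["draws"], lad["fits"][m]["draws"])
                    for m in tbl["model"]]
            tbl.to_csv(out / f"{oc}_variance.csv", index=False)
            return tbl

        vtbl, dt = do_maps()
        log["stages"][f"maps[{outcome_name}]"] = dt
        results["maps"][outcome_name] = vtbl

    @_stage("weighting")
    def do_weighting():
        cohort = pd.concat([study["cohort"]], axis=1)
        oc = config.outcomes[0]
        y = cohort[oc].to_numpy().astype(float)
        bench = weighting.uniform_benchmark(cohort, rate=config.weighting_rate)
        wtbl = weighting.compute_weights(cohort, bench)
        wtbl.to_csv(out / "weights.csv", index=False)
        w = weighting.attach_weights(cohort, wtbl)
        pr_u = weighting.weighted_area_pr(cohort, y, mode="unadjusted")
        pr_w = weighting.weighted_area_pr(cohort, y, mode="unadjusted", weights=w)
        r, scatter = weighting.compare_pr(pr_u, pr_w)
        scatter.to_csv(out / "pr_weighting_comparison.csv", index=False)
        return {"pearson_r": r, "scatter": scatter}

    wres, dt = do_weighting()
    log["stages"]["weighting"] = dt
    results["weighting"] = wres

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    (out / "config_snapshot.yaml").write_text(yaml.safe_dump(asdict(config)))
    results["log"] = log
    return results
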