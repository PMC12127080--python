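"""End-to-end analysis pipeline.

Runs the full evaluation in the order the study design sequences it:
simulate (or load) the cohort -> per-site DID loop -> pan-cancer DID
(demographic and full covariate models) -> event-study parallel-trend
check -> permutation placebo -> entropy-balancing / matching robustness
re-estimates -> moderation by pollution index and depression score ->
subgroup fits with Chow tests.  Each stage writes CSV/JSON/PNG
artifacts into the output directory and a manifest records seeds,
versions and settings; a stage failure aborts with the stage name while
preserving completed artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .balance import balance_table, entropy_balance_panel, fit_propensity, \
    nearest_neighbor_match
from .cohort import (CohortConfig, PAN_CANCER_SITES, default_cancer_catalog,
                     generate_panel, generate_policy_schedule,
                     generate_pollution_indicators)
from .did import (ModerationSpec, build_pan_cancer_outcome, estimate_did,
                  estimate_event_study, estimate_moderation,
                  estimate_per_outcome, forest_frame, plot_forest,
                  subgroup_analysis)
from .linear import ModelSpec
from .panel import PolicySchedule, build_treatment_indicator
from .placebo import placebo_distribution
from .pollution import CompositeIndexModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]

#: demographic-only ("Model 1") and full ("Model 2") covariate sets
MODEL1_COVARIATES = ("female", "age", "bmi")
MODEL2_COVARIATES = ("female", "age", "bmi", "education", "rural", "sleep",
                     "smoke", "drink", "hypertension", "diabetes")


@dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: str = "staggerdid_output"
    placebo_b: int = 500
    seed: int = 0
    subgroups: tuple[tuple[str, tuple[float, ...] | None], ...] = (
        ("female", None), ("bmi", (18.5, 25.0)), ("smoke", None),
    )
    impute_bmi: bool = False
    level: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        if "subgroups" in raw:
            raw["subgroups"] = tuple(
                (g, tuple(c) if c else None) for g, c in raw["subgroups"]
            )
        return cls(cohort=cohort, **raw)


def _impute_median(panel: pd.DataFrame, column: str) -> pd.DataFrame:
    """Median imputation for a missing covariate — a simple, clearly
    labeled stand-in for a full multiple-imputation robustness check."""
    panel = panel.copy()
    panel[column] = panel[column].fillna(panel[column].median())
    return panel


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dictionary."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "cohort_seed": config.cohort.seed,
        "settings": {
            "placebo_b": config.placebo_b,
            "subgroups": [list(s) for s in config.subgroups],
            "level": config.level,
        },
        "artifacts": [],
        "stages": [],
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        manifest["artifacts"].extend(str(p) for p in paths)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    stage = "simulate"
    try:
        cohort = config.cohort
        if cohort.cancer_catalog is None:
            cohort = cohort.replace(cancer_catalog=default_cancer_catalog())
        schedule = generate_policy_schedule(cohort)
        panel = generate_panel(cohort, schedule)
        if config.impute_bmi:
            panel = _impute_median(panel, "bmi")
        indicators = generate_pollution_indicators(schedule, seed=cohort.seed)
        panel = build_treatment_indicator(panel, schedule)
        schedule_path = outdir / "policy_schedule.csv"
        schedule.to_csv(schedule_path)
        record(stage, schedule_path)

        stage = "per_cancer"
        sites = list(cohort.cancer_catalog)
        spec2 = ModelSpec(covariates=MODEL2_COVARIATES, level=config.level)
        per_site = estimate_per_outcome(panel, schedule, spec2, sites)
        forest = forest_frame(per_site, sites)
        forest_csv = outdir / "forest.csv"
        forest.to_csv(forest_csv, index=False)
        ax = plot_forest(forest)
        forest_png = outdir / "forest.png"
        ax.figure.savefig(forest_png, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        record(stage, forest_csv, forest_png)

        stage = "pan_cancer"
        term = spec2.treatment_terms[0]
        significant = [
            s for s, r in zip(sites, per_site)
            if r.pvalues[term] < 0.05 and r.params[term] < 0
        ] or list(PAN_CANCER_SITES)
        panel = build_pan_cancer_outcome(panel, significant)
        spec_m1 = ModelSpec(outcome="pan_cancer", covariates=MODEL1_COVARIATES,
                            level=config.level)
        spec_m2 = spec_m1.replace(covariates=MODEL2_COVARIATES)
        fit_m1 = estimate_did(panel, schedule, spec_m1)
        fit_m2 = estimate_did(panel, schedule, spec_m2)
        main_frame = fit_m1.to_frame().add_prefix("model1_").join(
            fit_m2.to_frame().add_prefix("model2_"), how="outer")
        main_csv = outdir / "main_table.csv"
        main_frame.to_csv(main_csv)
        main_txt = outdir / "main_table.txt"
        with open(main_txt, "w") as fh:
            fh.write(fit_m1.summary(title="Model 1 (demographics)"))
            fh.write("\n\n")
            fh.write(fit_m2.summary(title="Model 2 (full covariates)"))
        record(stage, main_csv, main_txt)

        stage = "event_study"
        curve = estimate_event_study(panel, schedule, spec_m2)
        es_csv = outdir / "event_study.csv"
        curve.to_frame().to_csv(es_csv, index=False)
        ax = curve.plot()
        es_png = outdir / "event_study.png"
        ax.figure.savefig(es_png, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        record(stage, es_csv, es_png)

        stage = "placebo"
        dist = placebo_distribution(panel, schedule, spec_m2,
                                    B=config.placebo_b, seed=config.seed)
        pl_csv = outdir / "placebo_draws.csv"
        dist.to_frame().to_csv(pl_csv, index=False)
        ax = dist.plot()
        pl_png = outdir / "placebo.png"
        ax.figure.savefig(pl_png, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        record(stage, pl_csv, pl_png)

        stage = "balancing"
        weights = entropy_balance_panel(panel, MODEL2_COVARIATES)
        bt = balance_table(panel, weights, MODEL2_COVARIATES)
        bt_csv = outdir / "balance_table.csv"
        bt.to_csv(bt_csv, index=False)
        panel_w = panel.copy()
        panel_w["weight"] = weights.to_numpy()
        fit_eb = estimate_did(panel_w, schedule, spec_m2.replace(weight="weight"))
        prop = fit_propensity(panel, MODEL2_COVARIATES)
        pairs = nearest_neighbor_match(prop.scores, panel["treated"],
                                       with_replacement=True)
        keep = pd.Index(pairs["treated_id"]).append(
            pd.Index(pairs["control_id"].dropna()))
        fit_psm = estimate_did(panel.loc[panel.index.isin(keep)], schedule, spec_m2)
        re_frame = pd.concat({
            "entropy_balanced": fit_eb.to_frame().loc[[term]],
            "psm_matched": fit_psm.to_frame().loc[[term]],
        })
        re_csv = outdir / "robustness_reestimates.csv"
        re_frame.to_csv(re_csv)
        record(stage, bt_csv, re_csv)

        stage = "moderation"
        index_model = CompositeIndexModel.from_table(indicators)
        idx_csv = outdir / "pollution_index.csv"
        index_model.index_frame().to_csv(idx_csv, index=False)
        panel_m = index_model.merge_into_panel(panel)
        fit_pollution = estimate_moderation(
            panel_m, schedule,
            ModerationSpec("pollution_index", spec_m2))
        fit_cesd = estimate_moderation(
            panel, schedule, ModerationSpec("cesd", spec_m2))
        mod_frame = pd.concat({
            "pollution_index": fit_pollution.to_frame(),
            "cesd": fit_cesd.to_frame(),
        })
        mod_csv = outdir / "moderation_table.csv"
        mod_frame.to_csv(mod_csv)
        record(stage, idx_csv, mod_csv)

        stage = "subgroups"
        rows = []
        for grouping, cutpoints in config.subgroups:
            comp = subgroup_analysis(panel, schedule, spec_m2, grouping,
                                     cutpoints)
            tab = comp.table()
            tab.insert(0, "grouping", grouping)
            tab["chow_f"] = comp.chow_f
            tab["chow_p"] = comp.chow_p
            rows.append(tab)
        sub_csv = outdir / "subgroup_table.csv"
        pd.concat(rows, ignore_index=True).to_csv(sub_csv, index=False)
        record(stage, sub_csv)
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["key_results"] = {
        "pan_cancer_did_model1": fit_m1.treatment_effect(),
        "pan_cancer_did_model2": fit_m2.treatment_effect(),
        "placebo_p": dist.pvalue,
        "entropy_balanced_did": fit_eb.treatment_effect(),
        "cesd_triple_interaction": float(
            fit_cesd.params[f"{term}:cesd"]),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
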