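"""End-to-end run: simulate -> cv -> split -> fit -> score -> validate.

A single seeded run writes all artifacts (CSV tables, JSON models, a YAML
config echo) plus a manifest recording the configuration, the seed, package
versions and the SHA-256 of every output, so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .impute import ImputationConfig, fcs_impute
from .model import backward_select, univariable_screen
from .points import build_risk_table
from .simulate import GeneratorConfig, simulate_cohort, simulate_visits
from .validation import (
    horizon_auc,
    horizon_calibration,
    hosmer_lemeshow,
    split_cohort,
)
from .variation import CUTPOINT_PRESETS, adjusted_cv_table, assign_tertiles

log = logging.getLogger("pointrisk")

ALL_STAGES = ("simulate", "cv", "split", "fit", "score", "risktable", "validate")


@dataclass
class RunConfig:
    """Settings for one reproducible pipeline run."""

    outdir: str = "run"
    seed: int = 0
    n_subjects: int = 24104
    stages: tuple[str, ...] = ALL_STAGES
    horizons: tuple[float, ...] = (3.0, 5.0, 8.0)
    split_ratio: tuple[int, int] = (2, 1)
    cutpoint_preset: str = "table3"
    n_visits_range: tuple[int, int] = (3, 8)
    screen_alpha: float = 0.25
    stay_alpha: float = 0.05
    risktable_bin_width: int = 3
    bootstrap_reps: int = 0
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        for k in ("stages", "horizons", "split_ratio", "n_visits_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Every artifact lands under ``config.outdir``; stage failures halt the
    run with the stage name attached.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    def save_json(obj, name: str):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        written.append(p)
        return p

    state: dict = {}
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            gcfg = GeneratorConfig(
                n_subjects=config.n_subjects, seed=config.seed, **config.generator
            )
            cohort = simulate_cohort(gcfg)
            state["cohort"] = cohort
            (out / "generator.yaml").write_text(gcfg.to_yaml())
            written.append(out / "generator.yaml")
            save_df(cohort, "cohort.csv")
            log.info("simulated %d subjects, %.2f%% events", len(cohort), 100 * cohort["event"].mean())

        if "cv" in config.stages:
            stage = "cv"
            cohort = state["cohort"]
            visits = simulate_visits(
                cohort, n_visits_range=config.n_visits_range, seed=config.seed + 1
            )
            save_df(visits, "visits.csv")
            cvtab = adjusted_cv_table(visits)
            save_df(cvtab, "cv.csv")
            wide = cvtab.pivot(index="subject_id", columns="measure", values="adjusted_cv")
            for measure, col in (("hba1c", "hba1c_cv"), ("sbp", "sbp_cv")):
                vals = cohort["id"].map(wide[measure])
                cohort[f"{col}_value"] = vals
                cuts = CUTPOINT_PRESETS[(measure, config.cutpoint_preset)]
                cohort[col] = assign_tertiles(vals, cuts)
            state["cohort"] = cohort
            save_df(cohort, "cohort.csv")

        if "split" in config.stages:
            stage = "split"
            der, val = split_cohort(state["cohort"], config.split_ratio, seed=config.seed + 2)
            state["derivation"], state["validation"] = der, val
            save_df(der, "derivation.csv")
            save_df(val, "validation.csv")

        if "fit" in config.stages:
            stage = "fit"
            der = state.get("derivation", state["cohort"])
            retained, screen_tab = univariable_screen(
                der, alpha=config.screen_alpha, horizons=config.horizons
            )
            sel = backward_select(
                der, retained, alpha_stay=config.stay_alpha, horizons=config.horizons
            )
            if sel.empty:
                raise RuntimeError("backward elimination emptied the model")
            state["fit"] = sel.results
            save_json(
                {
                    "screen": screen_tab.to_dict(orient="records"),
                    "dropped": [{"factor": f, "p": p} for f, p in sel.dropped],
                    "retained": [t.factor for t in sel.retained],
                },
                "selection.json",
            )
            (out / "fit.json").write_text(sel.results.to_json())
            written.append(out / "fit.json")

        if "score" in config.stages:
            stage = "score"
            system = state["fit"].point_system()
            state["system"] = system
            (out / "system.json").write_text(system.to_json())
            written.append(out / "system.json")

        if "risktable" in config.stages:
            stage = "risktable"
            save_df(build_risk_table(state["system"], bins=config.risktable_bin_width), "risktable.csv")

        if "validate" in config.stages:
            stage = "validate"
            val = state.get("validation", state["cohort"])
            system = state["system"]
            scores = system.score_dataframe(val)
            report: dict = {"n": len(val), "horizons": {}}
            for t in config.horizons:
                risks = system.risk(scores.to_numpy(), t)
                disc = horizon_auc(risks, val["follow_time"], val["event"], t)
                hl = hosmer_lemeshow(risks, time=val["follow_time"], event=val["event"], t=t)
                intercept, slope = horizon_calibration(risks, val["follow_time"], val["event"], t)
                report["horizons"][f"{t:g}"] = {
                    "auc": disc.auc,
                    "auc_ci": [disc.ci_lower, disc.ci_upper],
                    "n_evaluable": disc.n,
                    "n_cases": disc.n_cases,
                    "hl_chi2": hl.chi2,
                    "hl_p": hl.p,
                    "calibration_intercept": intercept,
                    "calibration_slope": slope,
                }
                save_df(hl.table.assign(horizon=t), f"calibration_{t:g}y.csv")
            if config.bootstrap_reps > 0:
                from .validation import bootstrap_optimism

                der = state.get("derivation", state["cohort"])
                bo = bootstrap_optimism(
                    der,
                    state["fit"].terms,
                    t=5.0,
                    b_reps=config.bootstrap_reps,
                    seed=config.seed + 3,
                )
                report["bootstrap"] = asdict(bo)
            save_json(report, "report.json")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {**asdict(config), "stages": list(config.stages)},
        "artifacts": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n")
    return manifest


def impute_and_save(cohort_path, outdir, m=5, seed=None, **cfg_kw):
    """Impute missing CV values and write the m completed cohorts."""
    data = pd.read_csv(cohort_path)
    cfg = ImputationConfig(m=m, seed=seed, **cfg_kw)
    completed = fcs_impute(data, cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, df in enumerate(completed, 1):
        p = out / f"imputed_{i}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths
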