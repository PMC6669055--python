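"""End-to-end orchestration: simulate/load -> clean -> classify -> seasons
-> prevalence -> growth -> risk -> lag, with reproducible artifacts.

Each stage writes its outputs before the next starts; a run manifest
records the seed, package version and a hash of the configuration so any
output directory is traceable to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cleaning as cleaning_mod
from . import growth as growth_mod
from . import lag as lag_mod
from . import lms as lms_mod
from . import prevalence as prev_mod
from . import risk as risk_mod
from . import seasons as seasons_mod
from .simulate import SyntheticConfig, generate_cohort
from .visits import read_visits_csv

__all__ = ["RunConfig", "run_pipeline", "StageError"]

log = logging.getLogger("wastunt")

ALL_STAGES = ("clean", "prevalence", "seasons", "growth", "risk", "lag")


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with documented defaults.

    Either ``visits_csv`` (plus optionally ``lms_csv``) points at real
    inputs, or a synthetic cohort is generated from ``synthetic``.
    """

    output_dir: str = "results/run"
    seed: int = 0
    visits_csv: Optional[str] = None
    lms_csv: Optional[str] = None
    stages: tuple = ALL_STAGES
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # stage-level decisions (defaults = the documented design choices)
    outcome_rule: str = "mean"  # 20-24-month stunting outcome rule
    include_birth_visit: bool = True  # seasonal episode windows
    classification_threshold: float = 0.5
    lag_target_months: float = 3.0
    lag_window_months: tuple = (2.5, 3.5)
    growth_interior_knots: Optional[tuple] = None  # None -> age quartiles
    growth_by_sex: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        syn = d.pop("synthetic", {})
        for key in ("birth_start", "birth_end"):
            if key in syn:
                syn[key] = pd.Timestamp(syn[key]).date()
        syn = {k: tuple(v) if isinstance(v, list) else v for k, v in syn.items()}
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)} - {"synthetic"}})
        cfg.synthetic = SyntheticConfig(**syn)
        for name in ("stages", "lag_window_months", "growth_interior_knots"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in order; return the artifact dictionary.

    Artifacts are also written under ``config.output_dir`` as plain
    CSV/JSON.  A stage failure raises :class:`StageError` naming the
    stage; artifacts already written are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    artifacts: dict = {}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "timings_s": {},
    }
    config.to_yaml(out / "config.yaml")

    # ---- inputs -------------------------------------------------------
    if config.lms_csv:
        refs = lms_mod.read_lms_csv(config.lms_csv)
        lfa, wfl = refs["age_days"], refs["length_cm"]
    else:
        lfa, wfl = lms_mod.toy_reference()
    if config.visits_csv:
        visits = read_visits_csv(config.visits_csv)
        truth = None
    else:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        visits, truth = generate_cohort(syn, refs=(lfa, wfl))
        visits.to_csv(out / "visits_raw.csv", index=False)
    visits = lms_mod.add_zscores(visits, lfa, wfl)
    artifacts["visits_raw"] = visits
    artifacts["truth"] = truth

    def stage(name):
        return name in config.stages

    def record(name, t0):
        manifest["timings_s"][name] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1fs", name, time.time() - t0)

    clean = visits
    try:
        if stage("clean"):
            t0 = time.time()
            clean, excluded, report = cleaning_mod.clean_cohort(visits)
            report.to_json(out / "cleaning_report.json")
            excluded.to_csv(out / "excluded_visits.csv", index=False)
            log.info("\n%s", report.log_block())
            artifacts["clean"] = clean
            artifacts["cleaning_report"] = report
            record("clean", t0)

        monthly = prev_mod.monthly_classification(clean)
        outcome = prev_mod.outcome_stunted_20_24(clean, rule=config.outcome_rule)
        artifacts["monthly"] = monthly
        artifacts["outcome_20_24"] = outcome

        if stage("prevalence"):
            t0 = time.time()
            table1 = prev_mod.prevalence_table(monthly)
            table1.to_csv(out / "prevalence_by_age.csv", index=False)
            grouped = prev_mod.grouped_prevalence(monthly, outcome)
            grouped.to_csv(out / "prevalence_by_outcome_group.csv", index=False)
            artifacts["prevalence"] = table1
            artifacts["prevalence_grouped"] = grouped
            record("prevalence", t0)

        if stage("seasons"):
            t0 = time.time()
            episodes = seasons_mod.summarize_episodes(
                clean, include_birth_visit=config.include_birth_visit
            )
            episodes.to_csv(out / "season_episodes.csv", index=False)
            artifacts["episodes"] = episodes
            record("seasons", t0)

        growth_fit = None
        if stage("growth"):
            t0 = time.time()
            spec = growth_mod.GrowthDesignSpec(
                interior_knots=config.growth_interior_knots
            )
            if config.growth_by_sex:
                fits = {
                    sex: growth_mod.fit_growth_model(
                        growth_mod.build_design(sub, spec)
                    )
                    for sex, sub in clean.groupby("sex")
                }
                re_frames = []
                for sex, f in fits.items():
                    summary = growth_mod.subject_seasonal_summary(f)
                    re_frames.append(summary)
                    with open(out / f"growth_fit_{sex}.json", "w") as fh:
                        json.dump(f.summary_dict(), fh, indent=2)
                re_summary = pd.concat(re_frames).sort_index()
                growth_fit = next(iter(fits.values()))
            else:
                growth_fit = growth_mod.fit_growth_model(
                    growth_mod.build_design(clean, spec)
                )
                with open(out / "growth_fit.json", "w") as fh:
                    json.dump(growth_fit.summary_dict(), fh, indent=2)
                re_summary = growth_mod.subject_seasonal_summary(growth_fit)
            re_summary.to_csv(out / "subject_random_effects.csv")
            trajs = []
            for dob in ("1990-07-01", "1990-10-30", "1990-03-01"):
                trajs.append(
                    growth_mod.predict_trajectory(
                        growth_fit, dob, np.linspace(0, 24, 97)
                    )
                )
            pd.concat(trajs).to_csv(out / "predicted_trajectories.csv", index=False)
            artifacts["growth_fit"] = growth_fit
            artifacts["random_effects"] = re_summary
            record("growth", t0)

        if stage("risk"):
            t0 = time.time()
            season_fit = risk_mod.season_repeat_model(artifacts["episodes"]) if (
                "episodes" in artifacts
            ) else None
            if season_fit is not None:
                season_fit.table().to_csv(out / "season_repeat_model.csv", index=False)
                artifacts["season_repeat_fit"] = season_fit
            if growth_fit is None:
                log.info(
                    "growth stage disabled: stunting models limited to I and II "
                    "(model III needs the random-effect features)"
                )
                artifacts["stunting_models"] = None
            else:
                sex_by_subject = clean.groupby("subject_id")["sex"].first()
                features = risk_mod.build_stunting_features(
                    monthly, artifacts["random_effects"], outcome, sex_by_subject
                )
                models = risk_mod.fit_stunting_models(features)
                tables = []
                diags = {}
                for name, fit in models.items():
                    tab = fit.table()
                    tab.insert(0, "model", name)
                    tables.append(tab)
                    d = risk_mod.classification_diagnostics(
                        fit,
                        features.dropna(
                            subset=[c for c in features.columns if c != "stunted_20_24"]
                        )["stunted_20_24"],
                        threshold=config.classification_threshold,
                    )
                    diags[name] = dataclasses.asdict(d)
                pd.concat(tables).to_csv(out / "stunting_models.csv", index=False)
                with open(out / "stunting_model_diagnostics.json", "w") as fh:
                    json.dump(diags, fh, indent=2)
                artifacts["stunting_models"] = models
                artifacts["stunting_features"] = features
                artifacts["stunting_diagnostics"] = diags
            record("risk", t0)

        if stage("lag"):
            t0 = time.time()
            pairs = lag_mod.match_lagged(
                clean,
                target_lag=config.lag_target_months,
                window=config.lag_window_months,
            )
            pairs.to_csv(out / "lagged_pairs.csv", index=False)
            fits = {}
            for outcome_name in ("stunting", "wasting"):
                fits[outcome_name] = lag_mod.fit_lagged_model(pairs, outcome_name)
            with open(out / "lagged_models.json", "w") as fh:
                json.dump(
                    {
                        k: {
                            "table": f.table().to_dict(orient="records"),
                            "sigma_u": f.sigma_u,
                            "n_obs": f.n_obs,
                            "n_subjects": f.n_subjects,
                            "method": f.method,
                        }
                        for k, f in fits.items()
                    },
                    fh,
                    indent=2,
                )
            scen = lag_mod.predict_scenarios(
                fits["stunting"], ages=np.arange(0.0, 22.0, 3.0)
            )
            scen.to_csv(out / "scenario_probabilities.csv", index=False)
            artifacts["lagged_pairs"] = pairs
            artifacts["lagged_fits"] = fits
            artifacts["scenarios"] = scen
            record("lag", t0)
    except StageError:
        raise
    except Exception as exc:
        stage_name = next(
            (s for s in config.stages if s not in manifest["timings_s"]), "?"
        )
        raise StageError(stage_name, exc) from exc

    manifest["total_s"] = round(time.time() - t_start, 3)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = manifest
    return artifacts
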