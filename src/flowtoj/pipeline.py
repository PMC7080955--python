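"""Pipeline orchestration: simulate/load -> estimate -> screen -> score -> model.

A run is fully determined by a config mapping and a seed; the run log
(seed, config hash, stage row counts) suffices to regenerate every output.
All tables are plain CSV; a sidecar JSON records the seed of simulated data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import lmm
from .psychometrics import estimate_study
from .screening import format_report, screen_estimates
from .staircase import StaircaseConfig
from .study import StudyConfig, generate_study

TRIAL_COLUMNS = [
    "participant", "session", "phase", "condition", "block", "trial",
    "cue_side", "first_side", "signed_soa_ms", "response", "correct",
]
PHASES = ("pre", "post")


class ValidationError(ValueError):
    """Raised when input tables violate the schema; carries all violations."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__("input validation failed:\n  " + "\n  ".join(issues))


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # "simulate" or "load"
    seed: int = 0
    study: dict = field(default_factory=dict)       # StudyConfig overrides
    staircase: dict = field(default_factory=dict)   # StaircaseConfig overrides
    screening: dict = field(default_factory=dict)   # {"k": 2.5, "b": 1.4826}
    trials_path: str | None = None
    questionnaire_path: str | None = None
    column_map: dict = field(default_factory=dict)  # external-name -> schema name
    bayesian: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_study(study, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if study.trials is not None:
        study.trials.to_csv(outdir / "trials.csv", index=False)
    study.questionnaire.to_csv(outdir / "questionnaire.csv", index=False)
    study.latent.to_csv(outdir / "latent.csv", index=False)
    meta = {"seed": study.config.seed, "n_participants": study.config.n_participants,
            "missing_runs": [list(r) for r in study.missing_runs]}
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))


def read_study(trials_path, questionnaire_path=None, column_map: dict | None = None):
    """Load and validate study CSVs; returns (trials, questionnaire, summary).

    Schema violations are collected exhaustively and raised together as a
    ``ValidationError``. Individually invalid questionnaire rows are dropped
    with a logged reason rather than failing the load. The summary reports
    row counts and missing (participant, session, phase) runs relative to
    the full crossing of observed participants x sessions x {pre, post}.
    """
    issues: list[str] = []
    trials = pd.read_csv(trials_path)
    if column_map:
        trials = trials.rename(columns=column_map)
    missing_cols = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing_cols:
        issues.append(f"trials: missing columns {missing_cols}")
    else:
        for col, allowed in (("phase", PHASES),
                             ("condition", ("endogenous", "exogenous")),
                             ("cue_side", ("left", "right")),
                             ("first_side", ("left", "right")),
                             ("response", ("left", "right"))):
            bad = ~trials[col].isin(allowed)
            if bad.any():
                issues.append(f"trials: {int(bad.sum())} rows with invalid {col} "
                              f"(allowed: {allowed})")
        if not np.isfinite(trials["signed_soa_ms"]).all():
            issues.append("trials: non-finite signed_soa_ms values")
        if not trials["correct"].isin((0, 1)).all():
            issues.append("trials: correct must be 0/1")

    questionnaire = None
    dropped_q = []
    if questionnaire_path is not None:
        questionnaire = pd.read_csv(questionnaire_path)
        if column_map:
            questionnaire = questionnaire.rename(columns=column_map)
        item_cols = [f"item_{j}" for j in range(1, flow_mod.N_ITEMS + 1)]
        miss_q = [c for c in ("participant", "session", *item_cols)
                  if c not in questionnaire.columns]
        if miss_q:
            issues.append(f"questionnaire: missing columns {miss_q}")
        else:
            vals = questionnaire[item_cols]
            ok = vals.isin((1, 2, 3, 4, 5)).all(axis=1)
            for idx in questionnaire.index[~ok]:
                dropped_q.append(
                    f"questionnaire row {idx} (participant "
                    f"{questionnaire.loc[idx, 'participant']}): item response "
                    "outside the 1..5 Likert range; row rejected")
            questionnaire = questionnaire[ok].reset_index(drop=True)
    if issues:
        raise ValidationError(issues)

    summary = {"n_trials": int(len(trials)), "rejected_questionnaire_rows": dropped_q}
    present = set(map(tuple, trials[["participant", "session", "phase"]]
                      .drop_duplicates().itertuples(index=False)))
    participants = sorted(trials["participant"].unique())
    sessions = sorted(trials["session"].unique())
    expected = {(p, s, ph) for p in participants for s in sessions for ph in PHASES}
    missing_runs = sorted(expected - present)
    summary["missing_runs"] = missing_runs
    summary["n_missing_runs"] = len(missing_runs)
    return trials, questionnaire, summary


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full chain and write every intermediate table.

    Returns a report bundle: tables, screening report, fitted models and the
    run log. A stage failure raises RuntimeError naming the stage; outputs
    of completed stages remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    runlog = {"seed": config.seed, "config_hash": config.hash(), "stages": {}}

    def stage(name, fn):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        runlog["stages"][name] = "ok"
        (outdir / "runlog.json").write_text(json.dumps(runlog, indent=2, default=str))
        return out

    def _acquire():
        if config.mode == "simulate":
            scfg = StudyConfig(seed=config.seed, **config.study)
            stair = StaircaseConfig(**config.staircase)
            study = generate_study(scfg, simulate_trials=True, staircase_cfg=stair)
            write_study(study, outdir)
            return study.trials, study.questionnaire, {
                "n_missing_runs": len(study.missing_runs)}, study
        trials, questionnaire, summary = read_study(
            config.trials_path, config.questionnaire_path, config.column_map)
        return trials, questionnaire, summary, None

    trials, questionnaire, summary, study = stage("acquire", _acquire)
    runlog["input_summary"] = summary

    estimates = stage("estimate", lambda: estimate_study(trials))
    estimates.to_csv(outdir / "estimates.csv", index=False)

    k = config.screening.get("k", 2.5)
    b = config.screening.get("b", 1.4826)
    screened, report = stage("screen", lambda: screen_estimates(estimates, k=k, b=b))
    screened.to_csv(outdir / "estimates_screened.csv", index=False)
    (outdir / "exclusion_report.txt").write_text(format_report(report) + "\n")
    (outdir / "exclusion_report.json").write_text(
        json.dumps(report, indent=2, default=str))

    scores = stage("score", lambda: flow_mod.score_table(questionnaire))
    scores.to_csv(outdir / "flow_scores.csv", index=False)

    def _model():
        if study is not None:
            domains = study.latent
        elif "domain" in trials.columns:
            domains = trials
        else:
            domains = None
        jnd_tab = lmm.prepare_model_table(screened, scores, "JND", domains)
        pss_tab = lmm.prepare_model_table(screened, scores, "PSS_distance", domains)
        return lmm.fit_moderation_models(jnd_tab, pss_tab)

    models = stage("model", _model)
    report_lines = []
    for kind, res in models.items():
        coef = pd.DataFrame({
            "estimate": res.params, "se": res.bse,
            "ci_lower": res.conf_int["lower"], "ci_upper": res.conf_int["upper"],
            "t": res.tvalues, "p": res.pvalues,
        })
        coef.to_csv(outdir / f"{kind}_coefficients.csv")
        report_lines.append(res.summary())
        report_lines.append("")
    report_lines.append(format_report(report))
    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n")

    bundle.update(trials=trials, questionnaire=questionnaire, estimates=estimates,
                  screened=screened, screening_report=report, flow_scores=scores,
                  models=models, runlog=runlog, input_summary=summary)
    (outdir / "runlog.json").write_text(json.dumps(runlog, indent=2, default=str))
    return bundle
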