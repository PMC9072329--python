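"""End-to-end orchestration: simulate -> adjudicate -> fit -> calibrate ->
evaluate, or evaluate a user-supplied record table / confusion matrix.

All randomness flows from a single seed through named substreams
(cohort, panel, learner) so each stage is independently reproducible;
every run directory records the config hash, seed and calibration
decisions in a log, and identical (config, seed) pairs produce
byte-identical metrics JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (CalibrationFailure, FloorSpec, ThresholdPair,
                         band_metrics, calibrate_thresholds, classify,
                         cross_val_scores, fit_score_model)
from .cohort import (BAND_COUNTS, CohortConfig, ConfigError, assign_age_band,
                     cohort_to_frame, generate_cohort, read_cohort_csv)
from .panel import PanelParams, adjudicate_cohort
from .stats import (Confusion3x3, MetricsReport, build_confusion,
                    indeterminate_composition, metrics_report,
                    table3_markdown)

__all__ = [
    "RunConfig",
    "RunResult",
    "run",
    "read_confusion_csv",
    "write_report",
    "evaluate_confusion",
    "evaluate_records",
]

log = logging.getLogger("abstaindx")

MODES = ("simulate_full", "evaluate_records", "evaluate_confusion")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``simulate_full`` emulates a prospective device validation: the score
    model and abstention thresholds are developed on a separate training
    cohort (labels = true class, standing in for the device developer's
    clinically confirmed corpus), frozen, and then applied to the trial
    cohort, whose reference labels come from the consensus specialist
    panel. ``n_train`` sizes the training cohort.
    """

    mode: str = "simulate_full"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    panel: PanelParams = field(default_factory=PanelParams)
    floors: FloorSpec = field(default_factory=FloorSpec)
    learner_hyperparams: dict = field(default_factory=dict)
    n_train: int = 1000
    input_path: str | None = None  # records/confusion CSV for evaluate modes
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}")
        if self.mode != "simulate_full" and not self.input_path:
            raise ConfigError(f"mode {self.mode!r} requires input_path")
        if self.mode == "simulate_full" and self.cohort.n_subjects == 0:
            raise ConfigError("simulate_full requires n_subjects > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # item bank objects serialize by structural summary, not values
        d["cohort"]["item_bank"] = {
            band: {ch: len(items) for ch, items in chans.items()}
            for band, chans in self.cohort.item_bank.items.items()
        }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)  # YAML is a JSON superset
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "panel" in kwargs:
            kwargs["panel"] = PanelParams(**kwargs["panel"])
        if "floors" in kwargs:
            kwargs["floors"] = FloorSpec(**kwargs["floors"])
        return cls(**kwargs)


@dataclass
class RunResult:
    outdir: Path
    confusion: Confusion3x3
    report: MetricsReport
    thresholds: ThresholdPair | CalibrationFailure | None = None


def read_confusion_csv(path) -> Confusion3x3:
    """Read a labeled 3x3 confusion CSV (row = device output, column =
    reference category)."""
    return Confusion3x3.from_csv(path)


def write_report(path, report: MetricsReport, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2,
                                   sort_keys=True) + "\n")
    elif fmt == "markdown":
        lines = ["| metric | estimate | 95% CI |", "|---|---|---|"]
        for name, d in report.to_dict().items():
            if not isinstance(d, dict):
                continue
            if d["undefined_flag"]:
                lines.append(f"| {name} | undefined | - |")
            else:
                lines.append(
                    f"| {name} | {d['point'] * 100:.1f}% "
                    f"({d['num']}/{d['den']}) | "
                    f"({d['ci_lo'] * 100:.1f}%, {d['ci_hi'] * 100:.1f}%) |")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ConfigError(f"unknown report format {fmt!r}")


def evaluate_confusion(C: Confusion3x3, alpha: float = 0.05) -> MetricsReport:
    return metrics_report(C, alpha)


def evaluate_records(df: pd.DataFrame, alpha: float = 0.05):
    """Metrics from a per-subject record table with device_output and
    ref_category columns."""
    for col in ("device_output", "ref_category"):
        if col not in df.columns:
            raise ConfigError(f"records table missing column {col!r}")
    C = build_confusion(zip(df["device_output"], df["ref_category"]))
    return C, metrics_report(C, alpha)


def _feature_matrix(frame: pd.DataFrame) -> np.ndarray:
    cols = [f"q{j + 1:02d}" for j in range(64)]
    return frame[cols].to_numpy(dtype=float)


def _simulate(config: RunConfig, outdir: Path) -> RunResult:
    seed_seq = np.random.SeedSequence(config.seed)
    train_seed, cohort_seed, panel_seed, learner_seed = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_seq.spawn(4)]

    # --- device development on a separate, cleanly labeled cohort
    train_cfg = dataclasses.replace(config.cohort, n_subjects=config.n_train,
                                    seed=train_seed)
    train_frame = cohort_to_frame(generate_cohort(train_cfg))
    X_tr = _feature_matrix(train_frame)
    y_tr = (train_frame["true_class"] == "ASD").to_numpy().astype(int)
    bands_tr = np.array([assign_age_band(a).band
                         for a in train_frame["age_months"]])
    log.info("training cohort: n=%d (ASD %d)", len(y_tr), int(y_tr.sum()))

    # one score model per age band; out-of-fold scores pooled across
    # bands into a single device-wide abstention band
    from .classifier import OofScores
    oof_scores = np.full(len(y_tr), np.nan)
    models = {}
    for band in BAND_COUNTS:
        sel = bands_tr == band
        if sel.sum() == 0:
            continue
        oof = cross_val_scores(X_tr[sel], y_tr[sel],
                               config.learner_hyperparams,
                               seed=learner_seed, folds=config.floors.cv_folds)
        oof_scores[sel] = oof.scores
        models[band] = fit_score_model(X_tr[sel], y_tr[sel],
                                       config.learner_hyperparams,
                                       seed=learner_seed, band=band)
        log.info("band %s: %d training subjects, %d folds", band,
                 int(sel.sum()), config.floors.cv_folds)

    pooled = OofScores(oof_scores, y_tr, np.zeros(len(y_tr), dtype=int))
    result = calibrate_thresholds(pooled, floors=config.floors)

    # --- prospective trial cohort, adjudicated by the consensus panel
    trial_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)
    subjects = generate_cohort(trial_cfg)
    panel_rng = np.random.default_rng(panel_seed)
    diagnoses = adjudicate_cohort(subjects, config.panel, panel_rng)
    frame = cohort_to_frame(subjects)
    frame["ref_label"] = [d.final_label for d in diagnoses]
    frame["n_reviewers"] = [d.n_reviewers_used for d in diagnoses]
    frame["certainty"] = [d.certainty for d in diagnoses]
    log.info("trial cohort: n=%d", len(subjects))

    X = _feature_matrix(frame)
    bands = np.array([assign_age_band(a).band for a in frame["age_months"]])
    scores = np.full(len(subjects), np.nan)
    for band, model in models.items():
        sel = bands == band
        if sel.any():
            scores[sel] = model.score(X[sel])
    frame["score"] = scores

    if isinstance(result, CalibrationFailure):
        log.warning("calibration failed: %s (grid of %d candidates)",
                    result.reason, result.n_candidates)
        frame["device_output"] = "indeterminate"
        thresholds = result
    else:
        thresholds = result
        achieved = band_metrics(oof_scores, y_tr, thresholds)
        log.info("calibrated thresholds (%.4f, %.4f) on training OOF: "
                 "PPV=%.3f NPV=%.3f determinate=%.3f", thresholds.t_neg,
                 thresholds.t_pos, achieved["ppv"], achieved["npv"],
                 achieved["determinate_rate"])
        frame["device_output"] = classify(scores, thresholds)

    C = build_confusion(zip(frame["device_output"], frame["ref_label"]))
    report = metrics_report(C, config.alpha)

    frame.to_csv(outdir / "cohort.csv", index=False)
    C.to_csv(outdir / "confusion.csv")
    write_report(outdir / "metrics.json", report, "json")
    write_report(outdir / "report.md", report, "markdown")
    comp = indeterminate_composition(C)
    (outdir / "confusion.md").write_text(
        table3_markdown(C) + "\n\nindeterminate neurodevelopmental fraction: "
        + (f"{comp.fraction_neurodevelopmental:.3f}"
           if not comp.undefined else "undefined") + "\n")
    if not isinstance(thresholds, CalibrationFailure):
        (outdir / "thresholds.json").write_text(json.dumps(
            {"t_neg": thresholds.t_neg, "t_pos": thresholds.t_pos,
             "config_hash": config.config_hash()}, indent=2) + "\n")
    return RunResult(outdir, C, report, thresholds)


def run(config: RunConfig, outdir) -> RunResult:
    """Execute a configured run into ``outdir`` (created if missing)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("abstaindx %s | mode=%s seed=%d config_hash=%s",
                 __version__, config.mode, config.seed, config.config_hash())
        if config.mode == "simulate_full":
            result = _simulate(config, outdir)
        elif config.mode == "evaluate_confusion":
            C = read_confusion_csv(config.input_path)
            report = metrics_report(C, config.alpha)
            write_report(outdir / "metrics.json", report, "json")
            write_report(outdir / "report.md", report, "markdown")
            result = RunResult(outdir, C, report)
        else:
            df = read_cohort_csv(config.input_path)
            C, report = evaluate_records(df, config.alpha)
            C.to_csv(outdir / "confusion.csv")
            write_report(outdir / "metrics.json", report, "json")
            write_report(outdir / "report.md", report, "markdown")
            result = RunResult(outdir, C, report)
        log.info("run complete: %s", outdir)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
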