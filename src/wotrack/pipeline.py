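"""End-to-end orchestration: simulate -> binarize -> features -> select ->
train -> evaluate, with dataset bookkeeping.

The default cohort mirrors the study layout: five subjects (three mild,
two severe), three in the training partition and two in the test
partition, each recorded in a pre- and a post-Levodopa session of eight
10-m-walk runs with 150 steps per run (1200 steps per session; a step is
one stride of one leg, both legs are monitored).  Training-partition
subjects alone feed feature selection and model fitting; the test
partition is held out end to end.

Every stage derives its random stream from the master seed and a stage
key, so a rerun with the same seed is bit-identical.  The EEG stream key
omits the condition, which makes the ground-truth cortical features of a
subject's pre and post sessions identical by construction.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._utils import MUSCULAR_FEATURES, derive_rng
from .metrics import evaluate
from .models import ModelSpec, complexity, predict_table, train
from .mrp import MRPConfig, session_mrp_features
from .selection import build_report
from .session import write_session
from .strides import session_features
from .synth import NoiseProfile, default_params, simulate_session, subject_params
from .triggers import TriggerConfig, binarize_session

log = logging.getLogger("wotrack")

RUNS_PER_SESSION = 8
STEPS_PER_RUN = 150          # strides summed over both legs
CONDITIONS = ("pre", "post")


@dataclass
class SubjectEntry:
    subject_id: str
    severity: str            # mild | severe
    partition: str           # train | test


@dataclass
class DatasetManifest:
    subjects: list
    runs_per_session: int = RUNS_PER_SESSION
    steps_per_run: int = STEPS_PER_RUN

    @property
    def steps_per_session(self) -> int:
        return self.runs_per_session * self.steps_per_run

    def partition(self, name: str) -> list:
        return [s for s in self.subjects if s.partition == name]

    def expected_steps(self, partition: str) -> int:
        """Steps per condition contributed by one partition."""
        return len(self.partition(partition)) * self.steps_per_session


def default_manifest() -> DatasetManifest:
    return DatasetManifest(subjects=[
        SubjectEntry("S1", "mild", "train"),
        SubjectEntry("S2", "mild", "train"),
        SubjectEntry("S3", "severe", "train"),
        SubjectEntry("S4", "mild", "test"),
        SubjectEntry("S5", "severe", "test"),
    ])


def validate_manifest(manifest: DatasetManifest) -> dict:
    """Check partition disjointness and step-count arithmetic."""
    train = {s.subject_id for s in manifest.partition("train")}
    test = {s.subject_id for s in manifest.partition("test")}
    overlap = train & test
    if overlap:
        raise ValueError(f"subjects in both partitions: {sorted(overlap)}")
    ids = [s.subject_id for s in manifest.subjects]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate subject ids")
    if manifest.steps_per_run % 2:
        raise ValueError("steps per run must be even (two legs)")
    return {
        "n_train_subjects": len(train),
        "n_test_subjects": len(test),
        "steps_per_session": manifest.steps_per_session,
        "steps_per_condition": {
            p: manifest.expected_steps(p) for p in ("train", "test")
        },
    }


@dataclass
class PipelineConfig:
    seed: int = 0
    manifest: DatasetManifest = field(default_factory=default_manifest)
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    trigger: TriggerConfig = field(default_factory=TriggerConfig)
    mrp: MRPConfig = field(default_factory=MRPConfig)
    eeg: bool = False             # EMG-only branch by default (deployment mode)
    alpha: float = 0.05
    selected_only: bool = False   # restrict classifier features to p < alpha ones
    models: tuple = ("tree", "qd", "svm", "knn", "dnn1", "dnn2", "dnn3", "dnn4")
    subject_effects: bool = True
    out_dir: Path | None = None   # persist artifacts when set
    save_signals: bool = False


def _session_table(cfg: PipelineConfig, subject: SubjectEntry, condition: str) -> pd.DataFrame:
    """Simulate and analyse all runs of one (subject, condition) session."""
    params = default_params(condition)
    if cfg.subject_effects:
        params = subject_params(params, cfg.seed, subject.subject_id)
    strides_per_leg = cfg.manifest.steps_per_run // 2
    tables = []
    for run in range(cfg.manifest.runs_per_session):
        emg_seed = int(derive_rng(cfg.seed, "sim", subject.subject_id,
                                  condition, run).integers(2 ** 31))
        eeg_seed = int(derive_rng(cfg.seed, "sim-eeg", subject.subject_id,
                                  run).integers(2 ** 31))
        rec = simulate_session(
            params, strides_per_leg, emg_seed, cfg.noise,
            eeg_seed=eeg_seed, include_eeg=cfg.eeg,
            subject_id=subject.subject_id, run_id=run,
        )
        triggers = binarize_session(rec, cfg.trigger)
        tab = session_features(rec, triggers)
        if cfg.eeg:
            tab = session_mrp_features(rec, tab, cfg.mrp)
        tab["run_id"] = run
        tables.append(tab)
        if cfg.out_dir is not None and cfg.save_signals:
            write_session(rec, Path(cfg.out_dir) / "sessions"
                          / f"{subject.subject_id}_{condition}_run{run}")
    return pd.concat(tables, ignore_index=True)


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Execute the full dataflow; returns a summary dict with all artifacts."""
    cfg = cfg or PipelineConfig()
    validate_manifest(cfg.manifest)
    t0 = time.time()

    tables = {"train": {}, "test": {}}
    for part in ("train", "test"):
        for cond in CONDITIONS:
            parts = []
            for subj in cfg.manifest.partition(part):
                log.info("simulate+extract %s %s %s", part, subj.subject_id, cond)
                parts.append(_session_table(cfg, subj, cond))
            tables[part][cond] = pd.concat(parts, ignore_index=True)
    log.info("feature extraction done in %.1f s", time.time() - t0)

    selection = build_report(tables["train"]["pre"], tables["train"]["post"],
                             alpha=cfg.alpha)
    features = list(MUSCULAR_FEATURES)
    if cfg.selected_only:
        chosen = set(selection[selection["selected"]]["feature"])
        features = [f for f in features if f in chosen]

    train_table = pd.concat(tables["train"].values(), ignore_index=True)
    test_table = pd.concat(tables["test"].values(), ignore_index=True)

    results, trained = {}, {}
    for fam in cfg.models:
        spec = ModelSpec(family=fam, features=tuple(features))
        model = train(spec, train_table, seed=cfg.seed)
        pred = predict_table(model, test_table)
        rep = evaluate(pred["condition"], pred["predicted"], pred["score"])
        d = rep.to_dict()
        d.pop("roc")                      # keep the summary compact
        d["complexity"] = complexity(model)
        if model.history:
            d["epochs_run"] = model.history.get("epochs_run")
        results[fam] = d
        trained[fam] = model
        log.info("%s: accuracy %.2f%%, AUC %.3f", fam, d["accuracy_pct"], d["auc"])

    summary = {
        "seed": cfg.seed,
        "manifest": validate_manifest(cfg.manifest),
        "counts": {
            part: {cond: int(len(tables[part][cond])) for cond in CONDITIONS}
            for part in ("train", "test")
        },
        "eeg_branch": cfg.eeg,
        "classifier_features": features,
        "selection": selection.drop(columns=["alpha", "pairing_scheme"])
                              .to_dict(orient="records"),
        "models": results,
    }
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        train_table.to_csv(out / "train_features.csv", index=False)
        test_table.to_csv(out / "test_features.csv", index=False)
        selection.to_csv(out / "selection_report.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    summary["_tables"] = tables
    summary["_models"] = trained
    return summary
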