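"""End-to-end pipeline: simulate -> featurize -> datasets -> train -> fuse -> evaluate.

The runner reproduces the study layout: per dataset it evaluates the
trivial baseline, the random-forest baselines, the LSTM and the LSTM-SW
variants, each on the EDA descriptor, the facial descriptor, and their
decision fusion, for classification and regression.  All randomness
derives from a single seed; per-model seeds are spawned deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .datasets import DATASET_SPECS, build_dataset, class_counts, get_spec
from .descriptors import WindowSet, featurize_cohort
from .evaluation import (
    EvaluationReport,
    evaluate_classification,
    evaluate_regression,
)
from .fusion import fuse_classifier_scores, fuse_regression
from .models import (
    DEFAULT_ASSIGNMENTS,
    LSTMClassifier,
    LSTMRegressor,
    RandomForestWindowClassifier,
    RandomForestWindowRegressor,
    apply_sample_weighting,
    sample_weight_indices,
    trivial_classifier_scores,
    trivial_regression,
)
from .simulate import GeneratorConfig, generate_cohort, write_cohort

log = logging.getLogger("painmon")

MODALITIES = ("eda", "facial")


@dataclass
class PipelineConfig:
    """Configuration of one full run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    dataset_ids: Sequence[str] = ("RPD",)
    models: Sequence[str] = ("trivial", "rf", "lstm", "lstm_sw")
    tasks: Sequence[str] = ("classification", "regression")
    epochs: int = 50
    lr: float | None = None          # None -> per-dataset default assignment
    batch_size: int = 512
    shift_s: float = 3.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.dataset_ids) - set(DATASET_SPECS)
        if unknown:
            raise ValueError(f"unknown dataset ids: {sorted(unknown)}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(self.generator)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        gen = raw.pop("generator", {})
        if isinstance(gen, dict):
            gen = GeneratorConfig(**gen)
        return cls(generator=gen, **raw)


# Desk-scale profile: a handful of subjects, few repetitions, short training.
SMOKE_PROFILE: dict[str, Any] = {
    "generator": {"n_subjects": 6, "phasic_reps": 2, "seed": 0},
    "dataset_ids": ["RPD"],
    "epochs": 10,
}
# Full-protocol profile (2000-epoch training as in the reference setting).
PAPER_PROFILE: dict[str, Any] = {
    "generator": {"n_subjects": 127, "phasic_reps": 30, "seed": 0},
    "dataset_ids": list(DATASET_SPECS),
    "epochs": 2000,
}


def apply_profile(cfg: PipelineConfig, profile: str) -> PipelineConfig:
    prof = {"smoke": SMOKE_PROFILE, "paper": PAPER_PROFILE}[profile]
    raw = cfg.to_dict()
    raw.update({k: v for k, v in prof.items() if k != "generator"})
    raw["generator"].update(prof.get("generator", {}))
    raw["generator"] = GeneratorConfig(**raw["generator"])
    return PipelineConfig(**raw)


def split_windows(windows: WindowSet, assignment: dict[str, str]) -> dict[str, WindowSet]:
    """Partition a cohort's windows by the subject-level split assignment."""
    out = {}
    splits = np.array([assignment[s] for s in windows.subject_ids])
    for name in ("train", "val", "test"):
        out[name] = windows.subset(splits == name)
    return out


def _spawned_seed(seed: int, *tags: str) -> int:
    h = hashlib.sha256(("|".join(map(str, (seed,) + tags))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _train_predict_classification(model_name, train, test, spec, cfg,
                                  sw_idx=None):
    """Per-modality class scores on the test split for one model family."""
    n_classes = spec.n_classes
    scores = {}
    meta = {}
    arch_c, _, lr_default = DEFAULT_ASSIGNMENTS[spec.id]
    lr = cfg.lr if cfg.lr is not None else lr_default
    for modality in MODALITIES:
        x_tr, y_tr = train.features[modality], train.y_class
        if sw_idx is not None:
            x_tr, y_tr = x_tr[sw_idx], y_tr[sw_idx]
        seed = _spawned_seed(cfg.seed, spec.id, model_name, modality, "c")
        if model_name == "rf":
            est = RandomForestWindowClassifier(random_state=seed)
            est.fit(x_tr, y_tr)
            proba = est.predict_proba(test.features[modality])
            # expand to the full class set if training lacked some classes
            full = np.zeros((proba.shape[0], n_classes))
            full[:, np.asarray(est.classes_, dtype=int)] = proba
            scores[modality] = full
            meta[modality] = {"model": "RFc"}
        else:
            est = LSTMClassifier.from_architecture(
                arch_c, lr=lr, epochs=cfg.epochs, batch_size=cfg.batch_size,
                random_state=seed)
            est.fit(x_tr, y_tr)
            scores[modality] = est.predict_proba(test.features[modality])
            meta[modality] = {"arch": arch_c, "lr": lr, "epochs": cfg.epochs}
    return scores, meta


def _train_predict_regression(model_name, train, test, spec, cfg, sw_idx=None):
    preds = {}
    meta = {}
    _, arch_r, lr_default = DEFAULT_ASSIGNMENTS[spec.id]
    lr = cfg.lr if cfg.lr is not None else lr_default
    for modality in MODALITIES:
        x_tr, y_tr = train.features[modality], train.y_cont
        if sw_idx is not None:
            x_tr, y_tr = x_tr[sw_idx], y_tr[sw_idx]
        seed = _spawned_seed(cfg.seed, spec.id, model_name, modality, "r")
        if model_name == "rf":
            est = RandomForestWindowRegressor(random_state=seed)
            est.fit(x_tr, y_tr)
            preds[modality] = np.clip(est.predict(test.features[modality]), 0, 1)
            meta[modality] = {"model": "RFr"}
        else:
            est = LSTMRegressor.from_architecture(
                arch_r, lr=lr, epochs=cfg.epochs, batch_size=cfg.batch_size,
                random_state=seed)
            est.fit(x_tr, y_tr)
            preds[modality] = est.predict(test.features[modality])
            meta[modality] = {"arch": arch_r, "lr": lr, "epochs": cfg.epochs}
    return preds, meta


def evaluate_dataset(dataset_id: str, train: WindowSet, test: WindowSet,
                     cfg: PipelineConfig, report: EvaluationReport) -> None:
    """All requested model/modality cells for one dataset."""
    spec = get_spec(dataset_id)
    base_meta = {"seed": cfg.seed, "n_train": len(train), "n_test": len(test)}
    if "trivial" in cfg.models:
        if "classification" in cfg.tasks:
            pred = np.argmax(trivial_classifier_scores(len(test), spec.n_classes), axis=1)
            report.add(dataset_id, "Trivial", "-", **base_meta,
                       **evaluate_classification(test.y_class, pred, spec.n_classes))
        if "regression" in cfg.tasks:
            report.add(dataset_id, "Trivial(r)", "-", **base_meta,
                       **evaluate_regression(test.y_cont, trivial_regression(len(test))))

    model_names = [m for m in cfg.models if m != "trivial"]
    sw_idx = None
    if "lstm_sw" in model_names:
        sw_idx = sample_weight_indices(
            train.features["facial"], train.y_class,
            random_state=_spawned_seed(cfg.seed, dataset_id, "sw"))
    for name in model_names:
        idx = sw_idx if name == "lstm_sw" else None
        label = {"rf": "RF", "lstm": "LSTM", "lstm_sw": "LSTM-SW"}[name]
        t0 = time.time()
        if "classification" in cfg.tasks:
            try:
                scores, meta = _train_predict_classification(
                    name, train, test, spec, cfg, idx)
            except ValueError as err:
                log.warning("%s/%s classification skipped: %s", dataset_id, name, err)
                report.add(dataset_id, label + "c", "absent", note=str(err), **base_meta)
            else:
                for modality in MODALITIES:
                    pred = np.argmax(scores[modality], axis=1)
                    report.add(dataset_id, label + "c", modality, **base_meta,
                               **meta[modality],
                               **evaluate_classification(test.y_class, pred, spec.n_classes))
                _, fused_cls = fuse_classifier_scores(scores["eda"], scores["facial"])
                report.add(dataset_id, label + "c", "DF", **base_meta, **meta["eda"],
                           **evaluate_classification(test.y_class, fused_cls, spec.n_classes))
        if "regression" in cfg.tasks:
            try:
                preds, meta = _train_predict_regression(
                    name, train, test, spec, cfg, idx)
            except ValueError as err:
                log.warning("%s/%s regression skipped: %s", dataset_id, name, err)
                report.add(dataset_id, label + "r", "absent", note=str(err), **base_meta)
            else:
                for modality in MODALITIES:
                    report.add(dataset_id, label + "r", modality, **base_meta,
                               **meta[modality],
                               **evaluate_regression(test.y_cont, preds[modality]))
                fused = fuse_regression(preds["eda"], preds["facial"])
                report.add(dataset_id, label + "r", "DF", **base_meta, **meta["eda"],
                           **evaluate_regression(test.y_cont, fused))
        log.info("stage=train dataset=%s model=%s dt=%.1fs",
                 dataset_id, name, time.time() - t0)


def run_all(cfg: PipelineConfig) -> EvaluationReport:
    """Execute the full pipeline and return the metric report.

    If ``cfg.out_dir`` is set, the cohort, the per-dataset class counts and
    the report (CSV + JSON) are written there, each carrying the config
    hash and seed.
    """
    t0 = time.time()
    gen_cfg = dataclasses.replace(cfg.generator, seed=cfg.seed)
    recordings, assignment = generate_cohort(gen_cfg)
    log.info("stage=simulate subjects=%d dt=%.1fs", len(recordings), time.time() - t0)

    windows = featurize_cohort(recordings, shift_s=cfg.shift_s)
    parts = split_windows(windows, assignment)
    log.info("stage=featurize windows=%d dt=%.1fs", len(windows), time.time() - t0)

    report = EvaluationReport()
    dataset_meta = {}
    for dataset_id in cfg.dataset_ids:
        train = build_dataset(parts["train"], dataset_id)
        test = build_dataset(parts["test"], dataset_id)
        dataset_meta[dataset_id] = {
            "train_counts": class_counts(train, dataset_id),
            "test_counts": class_counts(test, dataset_id),
        }
        evaluate_dataset(dataset_id, train, test, cfg, report)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(recordings, assignment, out / "sessions", gen_cfg)
        report.write(out / "report.csv", out / "report.json")
        (out / "run.json").write_text(json.dumps({
            "config": cfg.to_dict(), "config_hash": cfg.config_hash(),
            "seed": cfg.seed, "datasets": dataset_meta,
            "runtime_s": round(time.time() - t0, 1),
        }, indent=2, default=str))
    log.info("stage=done dt=%.1fs", time.time() - t0)
    return report
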