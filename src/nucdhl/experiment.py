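"""End-to-end experiment orchestration.

``run_experiment`` wires the whole two-pipeline system together:

    simulate -> preprocess -> split -> (pipeline 1 || encoder + head)
             -> fuse -> evaluate -> comparison report

Every stage writes its artifacts and a manifest (config, seed fan-out,
package versions, split hash) into an append-only run directory, so a rerun
with the same config reproduces all deterministic artifacts bit-identically.
The single ``seed`` in the config is the root of every random stream.

Data are split once per experiment into train/validation/test partitions
(default 60/15/25 — the 75:25 train:held-out convention with the held-out
quarter kept as an untouched test set and a validation slice carved from the
training side). The scaler, PCA, encoder and heads see only the training
partition; the split hash is written by every stage and compared.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, evaluate, morphometry, preprocessing, synthetic
from .augmentation import AugmentParams
from .encoder import EncoderConfig, TrainConfig, train_encoder
from .exceptions import ConfigurationError
from .preprocessing import PreprocessParams
from .types import RenderStyle, label_code

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pipeline1Config:
    folds: int = 5
    variance_retained: float = 0.95


@dataclass(frozen=True)
class SplitConfig:
    train: float = 0.60
    validation: float = 0.15
    test: float = 0.25

    def fractions(self) -> dict[str, float]:
        return {"train": self.train, "validation": self.validation,
                "test": self.test}


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    stain: str = "laminA"
    n_per_group: int = 1000
    profile: str = "desk"
    style: RenderStyle = field(default_factory=RenderStyle)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    augment: AugmentParams | None = None
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=25))
    pipeline1: Pipeline1Config = field(default_factory=Pipeline1Config)
    split: SplitConfig = field(default_factory=SplitConfig)
    head_algorithm: str = "gradient_boosted_trees"
    fusion_threshold: float = 0.5
    run_baseline: bool = True
    save_images: bool = False

    def __post_init__(self) -> None:
        if self.profile not in ("desk", "study"):
            raise ConfigurationError("profile must be 'desk' or 'study'")
        if abs(self.split.train + self.split.validation + self.split.test - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        if not (0.0 < self.fusion_threshold < 1.0):
            raise ConfigurationError("fusion_threshold must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(_to_plain(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def desk_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Reduced-scale profile: 64x64 inputs, 25 epochs."""
    return ExperimentConfig(seed=seed, profile="desk",
                            train=TrainConfig(epochs=25, seed=seed), **overrides)


def study_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Study-faithful profile: 250 epochs, lr 0.00025, batch 32, ~50k nuclei."""
    return ExperimentConfig(seed=seed, profile="study", n_per_group=25000,
                            train=TrainConfig(epochs=250, seed=seed), **overrides)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment config from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ExperimentConfig:
    def build(cls, data):
        if data is None:
            return None
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        return cls(**data)

    raw = dict(raw)
    nested = {
        "style": RenderStyle, "preprocess": PreprocessParams,
        "augment": AugmentParams, "encoder": EncoderConfig,
        "train": TrainConfig, "pipeline1": Pipeline1Config,
        "split": SplitConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            if key == "encoder" and value is not None:
                value = dict(value)
                for bk in ("incept_blocks", "squeeze_blocks"):
                    if bk in value:
                        value[bk] = tuple(map(tuple, value[bk]))
            kwargs[key] = build(nested[key], value)
        else:
            kwargs[key] = value
    return build(ExperimentConfig, kwargs)


class _Stage:
    """Structured per-stage logging with elapsed time."""

    def __init__(self, name: str, run_dir: Path):
        self.name = name
        self.run_dir = run_dir

    def __enter__(self):
        self.t0 = time.time()
        logger.info("[%s] start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.time() - self.t0
        if exc_type is None:
            logger.info("[%s] done in %.1fs", self.name, elapsed)
        else:
            logger.error("[%s] FAILED after %.1fs: %s", self.name, elapsed, exc)
        return False


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Execute the full experiment; returns the run directory.

    Any stage failure halts the run with the stage name in the log; artifacts
    written so far are preserved.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _to_plain(config),
        "config_hash": config.config_hash(),
        "versions": {"nucdhl": __version__, "numpy": np.__version__},
        "stages": {},
    }
    save_config(config, run_dir / "config.yaml")

    with _Stage("simulate", run_dir):
        images, table, truths = synthetic.generate_dataset(
            config.n_per_group, config.stain, config.style, config.seed,
            out_dir=(run_dir / "dataset") if config.save_images else None)
        frame = morphometry.records_to_frame(table)
        frame.to_csv(run_dir / "morphometrics.csv", index=False)
        labels = np.array([label_code(rec.label) for rec in table])
        manifest["stages"]["simulate"] = {"n": len(images)}

    with _Stage("preprocess", run_dir):
        planes = []
        for img in images:
            pre = preprocessing.preprocess(img, config.preprocess)
            planes.append(pre.pixels)
        x = np.stack(planes).astype(np.float32)
        manifest["stages"]["preprocess"] = {
            "params": _to_plain(config.preprocess), "shape": list(x.shape)}

    with _Stage("split", run_dir):
        parts = classify.stratified_split(labels, config.split.fractions(),
                                          seed=config.seed)
        hashes = {name: classify.split_hash(idx) for name, idx in parts.items()}
        with open(run_dir / "split.json", "w") as fh:
            json.dump({name: idx.tolist() for name, idx in parts.items()}, fh)
        manifest["stages"]["split"] = {
            "sizes": {k: len(v) for k, v in parts.items()}, "hashes": hashes}

    features = frame[list(morphometry.DESCRIPTORS)]
    y = {name: labels[idx] for name, idx in parts.items()}

    with _Stage("pipeline1", run_dir):
        ada, p1_report = classify.train_pipeline1(
            features.iloc[parts["train"]], y["train"],
            folds=config.pipeline1.folds, seed=config.seed,
            variance_retained=config.pipeline1.variance_retained)
        p_ada = {name: ada.predict_proba(features.iloc[idx].to_numpy())[:, 1]
                 for name, idx in parts.items()}
        p1_report.feature_importance.to_csv(run_dir / "feature_importance.csv")
        p1_report.correlation.to_csv(run_dir / "feature_correlation.csv")
        manifest["stages"]["pipeline1"] = {
            "cv_accuracy": p1_report.cv_accuracy,
            "split_hash": hashes["train"]}

    with _Stage("encoder", run_dir):
        trained = train_encoder(
            (x[parts["train"]], y["train"]),
            (x[parts["validation"]], y["validation"]),
            tconfig=config.train, config=config.encoder,
            augment_params=config.augment)
        trained.history.to_csv(run_dir / "encoder_history.csv", index=False)
        feats = {name: trained.extract_features(x[idx])
                 for name, idx in parts.items()}
        manifest["stages"]["encoder"] = {
            **trained.run_manifest(), "split_hash": hashes["train"]}

    with _Stage("dhl_head", run_dir):
        head = classify.train_dhl_head(feats["train"], y["train"],
                                       algorithm=config.head_algorithm,
                                       seed=config.seed)
        p_deep = {name: head.predict_proba(feats[name]) for name in parts}
        manifest["stages"]["dhl_head"] = {
            "algorithm": config.head_algorithm, "split_hash": hashes["train"]}

    with _Stage("fuse", run_dir):
        fused, sources = {}, {}
        for name, idx in parts.items():
            pairs = [classify.ProbPair(p_ada[name][i], p_deep[name][i],
                                       sample_id=int(idx[i]))
                     for i in range(len(idx))]
            decisions = classify.fuse_all(pairs, config.fusion_threshold)
            fused[name] = np.array([d.fused_probability for d in decisions])
            sources[name] = [d.source for d in decisions]
            pd.DataFrame({
                "sample_id": idx,
                "p_ada": p_ada[name], "p_deep": p_deep[name],
                "fused": fused[name],
                "label_pred": [d.predicted_label for d in decisions],
                "label_true": y[name],
            }).to_csv(run_dir / f"predictions_{name}.csv", index=False)
        manifest["stages"]["fuse"] = {"threshold": config.fusion_threshold}

    baseline_probs = None
    if config.run_baseline:
        with _Stage("conventional_dnn", run_dir):
            baseline = classify.train_dense_baseline(
                x[parts["train"]], y["train"], tconfig=config.train,
                config=config.encoder,
                val_data=(x[parts["validation"]], y["validation"]),
                augment_params=config.augment)
            baseline_probs = {name: baseline.predict_proba(x[idx])
                              for name, idx in parts.items()}
            manifest["stages"]["conventional_dnn"] = {
                **baseline.run_manifest(), "split_hash": hashes["train"]}

    with _Stage("evaluate", run_dir):
        def reports(probs: dict[str, np.ndarray]) -> dict[str, evaluate.MetricsReport]:
            return {name: evaluate.compute_metrics(
                        y[name], probs[name], config.fusion_threshold,
                        split=name)
                    for name in parts}

        runs = [
            ("pipeline1_adaboost", reports(p_ada)),
            ("deep_hybrid", reports(p_deep)),
            ("fused_max", reports(fused)),
        ]
        if baseline_probs is not None:
            runs.append(("conventional_dnn", reports(baseline_probs)))
        for name, reps in runs:
            for split_name, rep in reps.items():
                evaluate.write_metrics(rep, run_dir / "metrics",
                                       f"{name}_{split_name}")
        comparison = evaluate.comparison_report(runs, out_dir=run_dir)
        manifest["stages"]["evaluate"] = {
            "models": [name for name, _ in runs],
            "validation_auroc": {
                name: reps["validation"].auroc for name, reps in runs},
        }

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return run_dir


# ---------------------------------------------------------------------------
# canonical benchmark workflows (shared by the test suite, the examples and
# the reproduction script)

def pipeline1_benchmark(stain: str = "laminA", seed: int = 11,
                        folds: int = 5) -> dict[str, float]:
    """Cross-validated accuracy of the three morphometric classifiers on a
    calibrated synthetic table at the inferred study sizes.

    Returns the model -> mean CV accuracy mapping (adaboost, random_forest,
    decision_tree).
    """
    table, _ = synthetic.default_study_dataset(stain=stain, seed=seed)
    frame = morphometry.records_to_frame(table)
    labels = frame["label"].map(label_code).to_numpy()
    _, report = classify.train_pipeline1(
        frame[list(morphometry.DESCRIPTORS)], labels, folds=folds, seed=seed)
    return report.cv_accuracy


def dhl_validation_benchmark(n_per_group: int = 1000, seed: int = 7,
                             epochs: int = 25, stain: str = "laminA",
                             head_algorithm: str = "gradient_boosted_trees",
                             verbose: bool = False) -> dict:
    """Deep-hybrid-learning benchmark at reduced scale.

    Generates ``n_per_group`` pre-processed synthetic images per class at
    64x64, splits 75:25 (train:validation, stratified), trains the 21-layer
    encoder (Adam, cross-entropy, lr 0.00025, batch 32) for ``epochs`` and
    fits the tree-ensemble head on the flattened features. Returns a dict
    with the validation AUROC and accuracy of the deep-hybrid head plus the
    split bookkeeping.
    """
    images, _, _ = synthetic.generate_dataset(n_per_group, stain, seed=seed)
    planes, labels = [], []
    for img in images:
        planes.append(preprocessing.preprocess(img).pixels)
        labels.append(label_code(img.label))
    x = np.stack(planes).astype(np.float32)
    y = np.array(labels)
    parts = classify.stratified_split(y, {"train": 0.75, "validation": 0.25},
                                      seed=seed)
    tconfig = TrainConfig(epochs=epochs, seed=seed)
    trained = train_encoder((x[parts["train"]], y[parts["train"]]),
                            (x[parts["validation"]], y[parts["validation"]]),
                            tconfig=tconfig, verbose=verbose)
    head = classify.train_dhl_head(
        trained.extract_features(x[parts["train"]]), y[parts["train"]],
        algorithm=head_algorithm, seed=seed)
    p_val = head.predict_proba(trained.extract_features(x[parts["validation"]]))
    report = evaluate.compute_metrics(y[parts["validation"]], p_val)
    return {
        "validation_auroc": report.auroc,
        "validation_accuracy": report.accuracy,
        "n_train": len(parts["train"]),
        "n_validation": len(parts["validation"]),
        "split_hash": classify.split_hash(parts["train"]),
        "history": trained.history,
    }
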