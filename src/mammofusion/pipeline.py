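"""End-to-end run orchestration and YAML configuration.

``run_pipeline`` executes: simulate (or ingest a manifest) -> preprocess ->
stratified k-fold cross-validation with train-only augmentation -> per-fold
training and evaluation -> aggregate report, ROC figure, checkpoints and
Grad-CAM samples on disk.  A single global seed drives the phantom
generator, the fold assignment, weight initialisation and the training
shuffles, so a rerun with the same config reproduces the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .augment import AugmentConfig, augment_training_set
from .data import load_records, read_manifest
from .explain import gradcam, overlay
from .metrics import EvaluationReport
from .model import MammoFusionNet, ModelConfig
from .preprocess import PreprocessConfig, preprocess_records
from .synthetic import PhantomSpec, generate_dataset
from .training import TrainConfig, predict, stratified_kfold, train_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Composition of every stage config plus run-level plumbing."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_benign: int = 8
    n_malignant: int = 8
    manifest: str | None = None     # ingest instead of simulate when set
    augment_enabled: bool = True
    gradcam_samples: int = 2
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        # the global seed drives every stochastic component
        self.phantom.seed = self.seed
        self.model.seed = self.seed
        self.train.seed = self.seed

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def tuplify(klass, kw):
            # YAML round-trips tuples as lists; restore tuple-typed fields
            out = {}
            for f in dataclasses.fields(klass):
                if f.name in kw:
                    v = kw[f.name]
                    out[f.name] = tuple(v) if isinstance(v, list) else v
            return klass(**out)

        kw = dict(raw)
        for key, klass in (("phantom", PhantomSpec), ("preprocess", PreprocessConfig),
                           ("augment", AugmentConfig), ("model", ModelConfig),
                           ("train", TrainConfig)):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = tuplify(klass, kw[key])
        return cls(**kw)


def _load_or_simulate(config: RunConfig):
    if config.manifest:
        manifest = read_manifest(config.manifest)
        return load_records(manifest, root=Path(config.manifest).parent)
    records, _ = generate_dataset(config.phantom, config.n_benign, config.n_malignant)
    return records


def run_pipeline(config: RunConfig) -> EvaluationReport:
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    records = _load_or_simulate(config)
    logger.info("pipeline: %d records", len(records))
    samples, exclusions = preprocess_records(records, config.preprocess)
    if exclusions:
        logger.info("pipeline: excluded %d unpaired records", len(exclusions))
    if not samples:
        raise RuntimeError("pipeline: no complete CC/MLO pairs after preprocessing")

    report = EvaluationReport()
    folds = stratified_kfold(samples, k=config.train.n_folds, seed=config.seed)
    split_hash = [[s.case_id for s in val] for _, val in folds]
    for i, (train, val) in enumerate(folds):
        for s in train:
            s.partition = "train"
        for s in val:
            s.partition = "val"
        train_set = augment_training_set(train, config.augment) if config.augment_enabled \
            else list(train)
        logger.info("fold %d: %d train (%d after augmentation), %d val",
                    i, len(train), len(train_set), len(val))
        model, log = train_model(train_set, val, config.model, config.train)
        y_val = [s.label for s in val]
        report.add_fold(y_val, predict(model, val, config.train.batch_size))
        model.save(out / f"fold{i}_checkpoint.npz")
        with open(out / f"fold{i}_log.json", "w") as fh:
            json.dump(log, fh, indent=1)
        if i == 0:
            for s in val[:config.gradcam_samples]:
                sal = gradcam(model, s)
                iio.imwrite(out / f"gradcam_{s.case_id}.png",
                            (overlay(s.cc, sal) * 255).astype(np.uint8))

    result = report.to_dict()
    result["splits"] = split_hash
    with open(out / "report.json", "w") as fh:
        json.dump(result, fh, indent=1)
    report.fold_table().to_csv(out / "fold_metrics.csv", index=False)
    report.plot_roc(out / "roc.png")
    logger.info("pipeline: report written to %s", out / "report.json")
    return report
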