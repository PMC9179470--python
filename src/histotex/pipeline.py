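"""End-to-end pipeline: Gabor preprocessing -> mixed-convolution features
-> stacked-GRU classification -> one-vs-rest metric report, with optional
chaotic-sparrow-search hyperparameter tuning in the loop.

All stage seeds derive deterministically from one master seed, so a fixed
configuration reproduces the identical report.  Inputs are either a
directory of images (one subdirectory per class) or the synthetic texture
fixtures.
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
from PIL import Image, UnidentifiedImageError

from . import cssa, fixtures, gabor, mdconv, metrics, sgru

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "read_image_dir",
           "DEFAULT_TUNING_SPACE"]

logger = logging.getLogger("histotex")

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")

DEFAULT_TUNING_SPACE = (
    cssa.Dimension("learning_rate", 1e-3, 1e-1, "log"),
    cssa.Dimension("dropout", 0.0, 0.7, "continuous"),
    cssa.Dimension("batch_size", 4, 32, "integer"),
    cssa.Dimension("hidden_size", 8, 48, "integer"),
)


@dataclass
class PipelineConfig:
    """One human-editable configuration for the whole pipeline."""

    # data: a class-per-subdirectory image directory, or synthetic fixtures
    data_dir: str | None = None
    fixture_scale: float = 1.0
    image_side: int = 64
    noise_sigma: float = 0.08
    split_fractions: tuple[float, ...] = (0.7, 0.15, 0.15)
    # preprocessing
    gabor_delta: float = 4.0
    gabor_orientations: int = 4
    gabor_gamma: float = 0.5
    gabor_bw: float = 1.0
    # feature extractor
    extractor_widths: tuple[int, ...] = (16, 32, 64)
    extractor_kernel_sizes: tuple[int, ...] = (3, 5)
    # classifier (training defaults: lr 0.01, dropout 0.5, batch 5, 50 epochs)
    learning_rate: float = 0.01
    dropout: float = 0.5
    batch_size: int = 5
    hidden_size: int = 16
    gru_layers: int = 2
    epochs: int = 50
    seq_len: int = 4
    # CSSA tuning
    tune: bool = False
    tune_population: int = 4
    tune_iterations: int = 3
    tune_epochs: int = 15
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("split_fractions", "extractor_widths", "extractor_kernel_sizes"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        data = asdict(self)
        for name in ("split_fractions", "extractor_widths", "extractor_kernel_sizes"):
            data[name] = list(data[name])
        return yaml.safe_dump(data, sort_keys=False)

    def train_config(self, **overrides) -> sgru.TrainConfig:
        base = dict(learning_rate=self.learning_rate, dropout=self.dropout,
                    batch_size=self.batch_size, hidden_size=self.hidden_size,
                    layers=self.gru_layers, epochs=self.epochs,
                    seq_len=self.seq_len)
        base.update(overrides)
        return sgru.TrainConfig(**base)


@dataclass
class PipelineResult:
    report: metrics.MetricsReport
    overall_accuracy: float
    error_rate: float
    history: dict
    best_hyperparameters: dict | None
    tuning_history: np.ndarray | None
    artifacts: dict = field(default_factory=dict)


def read_image_dir(path: str | Path) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Load a class-per-subdirectory image tree in lexicographic order.

    Unreadable files are skipped with a logged warning; empty class
    directories are excluded; no class directory at all is an error.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"data directory not found: {root}")
    images, records = [], []
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    ci = 0
    for cls_dir in class_dirs:
        files = sorted(f for f in cls_dir.iterdir()
                       if f.suffix.lower() in _IMAGE_SUFFIXES)
        loaded = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im)
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping unreadable image %s (%s)", f, exc)
                continue
            images.append(arr)
            records.append({"image_id": f.stem, "label": cls_dir.name,
                            "class_index": ci, "category": ""})
            loaded += 1
        if loaded == 0:
            logger.warning("class directory %s has no readable images; excluded",
                           cls_dir)
        else:
            ci += 1
    if ci == 0:
        raise ValueError(f"no class subdirectories with images under {root}")
    return images, pd.DataFrame.from_records(records)


def _derive_seeds(master: int, n: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def _load_data(config: PipelineConfig):
    if config.data_dir is not None:
        return read_image_dir(config.data_dir)
    spec = fixtures.DatasetSpec(side=config.image_side,
                                noise_sigma=config.noise_sigma,
                                seed=config.seed)
    if config.fixture_scale != 1.0:
        spec = spec.scaled(config.fixture_scale)
    return fixtures.generate_dataset(spec)


def _preprocess_and_extract(images, config: PipelineConfig,
                            extractor_seed: int) -> np.ndarray:
    bank = gabor.GaborBankConfig(
        delta=config.gabor_delta,
        orientations=tuple(k * np.pi / config.gabor_orientations
                           for k in range(config.gabor_orientations)),
        gamma=config.gabor_gamma, bw=config.gabor_bw)
    extractor = mdconv.FeatureExtractor(mdconv.ExtractorConfig(
        blocks=len(config.extractor_widths),
        widths=config.extractor_widths,
        kernel_sizes=config.extractor_kernel_sizes,
        seed=extractor_seed))
    planes = [gabor.denoise(np.asarray(im, dtype=float) / 255.0, bank)
              for im in images]
    return mdconv.extract_features(planes, extractor)


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((arr - mu) / sd for arr in (train, *others))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and (optionally) write report artifacts.

    Stages: data -> Gabor denoise -> feature extraction -> (optional CSSA
    hyperparameter tuning on the validation error rate) -> SGRU training
    -> test-split confusion matrix and Table-style metric report.
    """
    t0 = time.time()
    split_seed, extractor_seed, train_seed, tune_seed = _derive_seeds(config.seed, 4)
    images, manifest = _load_data(config)
    logger.info("stage=data n_images=%d n_classes=%d seed=%d",
                len(images), manifest["class_index"].nunique(), config.seed)

    manifest = fixtures.stratified_split(manifest, config.split_fractions,
                                         seed=split_seed)
    feats = _preprocess_and_extract(images, config, extractor_seed)
    logger.info("stage=features dim=%d duration=%.1fs",
                feats.shape[1], time.time() - t0)

    y = manifest["class_index"].to_numpy()
    n_classes = int(y.max()) + 1
    tr = manifest["split"].to_numpy() == "train"
    va = manifest["split"].to_numpy() == "val"
    te = manifest["split"].to_numpy() == "test"
    if not te.any():          # two-way splits evaluate on the validation part
        te = va
    Xtr, Xva, Xte = _standardize(feats[tr], feats[va], feats[te])

    best_hparams = None
    tuning_history = None
    overrides: dict = {}
    if config.tune:
        def objective(hp: dict) -> float:
            cfg = config.train_config(epochs=config.tune_epochs, **hp)
            model, _ = sgru.train_classifier(Xtr, y[tr], config=cfg,
                                             n_classes=n_classes, seed=train_seed)
            return cssa.fitness_error_rate(model.predict(Xva), y[va])

        warm = {"learning_rate": config.learning_rate, "dropout": config.dropout,
                "batch_size": config.batch_size, "hidden_size": config.hidden_size}
        best_hparams, result = cssa.tune_hyperparameters(
            DEFAULT_TUNING_SPACE, objective,
            config_kwargs=dict(N=config.tune_population, T=config.tune_iterations),
            seed=tune_seed, warm_start=warm)
        tuning_history = result.history
        overrides = dict(best_hparams)
        logger.info("stage=tune best=%s evals=%d", best_hparams,
                    result.n_evaluations)

    model, history = sgru.train_classifier(
        Xtr, y[tr], Xva, y[va], config=config.train_config(**overrides),
        n_classes=n_classes, seed=train_seed)

    y_pred = model.predict(Xte)
    cm = metrics.build_confusion(y[te], y_pred, n_classes)
    labels = None
    if n_classes == len(metrics.CLASS_LABELS):
        labels = metrics.CLASS_LABELS
    report = metrics.per_class_metrics(cm, labels=labels)
    acc = metrics.overall_accuracy(cm)
    err = cssa.fitness_error_rate(y_pred, y[te])
    logger.info("stage=evaluate overall_accuracy=%.2f error_rate=%.2f "
                "duration=%.1fs", acc, err, time.time() - t0)

    artifacts = {}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "confusion_matrix.csv", cm, fmt="%d", delimiter=",")
        report.to_csv(out / "metrics_report.csv")
        with open(out / "metrics_report.json", "w") as fh:
            json.dump({**report.to_dict(),
                       "overall_accuracy": metrics.round_half_up(acc),
                       "error_rate": metrics.round_half_up(err)}, fh, indent=2)
        pd.DataFrame(history).to_csv(out / "training_history.csv", index_label="epoch")
        model.save(out / "model.npz")
        if best_hparams is not None:
            with open(out / "best_hyperparameters.json", "w") as fh:
                json.dump(best_hparams, fh, indent=2)
        artifacts = {name: str(out / name) for name in
                     ("confusion_matrix.csv", "metrics_report.csv",
                      "metrics_report.json", "training_history.csv", "model.npz")}
    return PipelineResult(report=report, overall_accuracy=acc, error_rate=err,
                          history=history, best_hyperparameters=best_hparams,
                          tuning_history=tuning_history, artifacts=artifacts)
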