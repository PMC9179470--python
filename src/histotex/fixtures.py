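"""Deterministic synthetic 8-class texture dataset.

Stands in for a breast-histology image collection with four benign
subtypes (adenosis A, fibroadenoma F, phyllodes tumor PT, tubular adenoma
TA) and four malignant (ductal DC, lobular LC, mucinous MC, papillary PC
carcinoma), with the default per-class counts

    A 106, F 237, PT 115, TA 130  (benign, 588)
    DC 788, LC 137, MC 169, PC 138 (malignant, 1232)   total 1820.

Each class is a parametric texture family — an oriented sinusoidal
grating with class-specific spatial frequency and orientation, overlaid
with a Gaussian-blob field of class-specific density — corrupted by
additive Gaussian pixel noise.  The goal is an 8-way signal with tunable
difficulty, not histological realism: per-image phase, blob placement and
small orientation/frequency jitter provide within-class variability, and
the noise level controls class overlap.

Everything derives from one seed; the same spec always produces
byte-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .metrics import CLASS_LABELS

__all__ = [
    "DatasetSpec",
    "TABLE_COUNTS",
    "generate_dataset",
    "stratified_split",
    "write_dataset",
]

TABLE_COUNTS = {"A": 106, "F": 237, "PT": 115, "TA": 130,
                "DC": 788, "LC": 137, "MC": 169, "PC": 138}
BENIGN = ("A", "F", "PT", "TA")
MALIGNANT = ("DC", "LC", "MC", "PC")

# per-class texture family: orientation (rad), grating frequency
# (cycles/pixel), blob count per 64^2 pixels
_FAMILY = {
    label: (k * math.pi / 8.0, 0.08 + 0.015 * k, 3 + 2 * k)
    for k, label in enumerate(CLASS_LABELS)
}


@dataclass(frozen=True)
class DatasetSpec:
    """Counts, image geometry and noise level of one synthetic dataset."""

    counts: dict = None
    side: int = 64
    noise_sigma: float = 0.08
    seed: int = 0
    tint: bool = False   # optional 3-channel benign/malignant tint

    def __post_init__(self) -> None:
        counts = dict(TABLE_COUNTS if self.counts is None else self.counts)
        if set(counts) != set(CLASS_LABELS):
            raise ValueError(f"counts must cover exactly the classes {CLASS_LABELS}")
        if any(int(c) < 1 for c in counts.values()):
            raise ValueError("all class counts must be positive")
        object.__setattr__(self, "counts", {k: int(counts[k]) for k in CLASS_LABELS})
        if self.side < 8:
            raise ValueError("image side must be >= 8")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def benign_total(self) -> int:
        return sum(self.counts[k] for k in BENIGN)

    @property
    def malignant_total(self) -> int:
        return sum(self.counts[k] for k in MALIGNANT)

    def scaled(self, factor: float, min_count: int = 8) -> "DatasetSpec":
        """Proportionally shrunk spec: floor(count * factor), at least
        ``min_count`` per class."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        new = {k: max(min_count, int(math.floor(c * factor)))
               for k, c in self.counts.items()}
        return replace(self, counts=new)


def _render_image(label: str, side: int, noise_sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    theta0, freq0, blobs_per_64 = _FAMILY[label]
    theta = theta0 + rng.uniform(-math.pi / 36, math.pi / 36)   # +/- 5 degrees
    freq = freq0 * (1.0 + rng.uniform(-0.05, 0.05))
    phase = rng.uniform(0.0, 2.0 * math.pi)
    yy, xx = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    # (row, col) orientation convention matching the Gabor kernel's axes
    carrier = yy * math.cos(theta) + xx * math.sin(theta)
    img = 0.5 + 0.22 * np.sin(2.0 * math.pi * freq * carrier + phase)
    n_blobs = max(1, int(round(blobs_per_64 * (side / 64.0) ** 2)))
    sigma_b = side / 16.0
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, side, size=2)
        amp = rng.uniform(0.10, 0.25)
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_b**2))
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _tint(plane: np.ndarray, label: str) -> np.ndarray:
    # benign leans pink, malignant leans violet - a purely cosmetic cue
    if label in BENIGN:
        weights = (1.0, 0.85, 0.9)
    else:
        weights = (0.9, 0.8, 1.0)
    return np.stack([plane * w for w in weights], axis=2)


def generate_dataset(spec: DatasetSpec | None = None) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render every image of the spec; returns (images, manifest).

    Images are uint8 grayscale (or tinted RGB) arrays; the manifest lists
    image_id, class label, class index and benign/malignant category in a
    fixed deterministic order.  Byte-identical for a fixed spec.
    """
    spec = spec or DatasetSpec()
    images: list[np.ndarray] = []
    records = []
    for ci, label in enumerate(CLASS_LABELS):
        for j in range(spec.counts[label]):
            rng = np.random.default_rng([spec.seed, ci, j])
            plane = _render_image(label, spec.side, spec.noise_sigma, rng)
            if spec.tint:
                plane = _tint(plane, label)
            images.append((plane * 255.0).round().astype(np.uint8))
            records.append({
                "image_id": f"{label}_{j:04d}",
                "label": label,
                "class_index": ci,
                "category": "benign" if label in BENIGN else "malignant",
            })
    return images, pd.DataFrame.from_records(records)


def stratified_split(manifest: pd.DataFrame, fractions, seed: int = 0,
                     names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Assign a per-class proportional split column; disjoint, seeded.

    ``fractions`` must be positive and sum to 1.  The split names default
    to train/val/test (or train/val for two fractions).
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("all split fractions must be positive")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if names is None:
        names = ("train", "val", "test")[: len(fractions)] if len(fractions) <= 3 \
            else tuple(f"split{i}" for i in range(len(fractions)))
    if len(names) != len(fractions):
        raise ValueError("one name per fraction required")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = ""
    for label in out["label"].unique():
        idx = out.index[out["label"] == label].to_numpy()
        idx = idx[rng.permutation(len(idx))]
        edges = np.floor(np.cumsum(fractions) * len(idx)).astype(int)
        edges[-1] = len(idx)
        start = 0
        for name, stop in zip(names, edges):
            out.loc[idx[start:stop], "split"] = name
            start = stop
    return out


def write_dataset(images: list[np.ndarray], manifest: pd.DataFrame,
                  out_dir: str | Path) -> Path:
    """Write one PNG per image under out_dir/<label>/ plus manifest.csv."""
    out = Path(out_dir)
    paths = []
    for img, row in zip(images, manifest.itertuples()):
        cls_dir = out / row.label
        cls_dir.mkdir(parents=True, exist_ok=True)
        path = cls_dir / f"{row.image_id}.png"
        Image.fromarray(img).save(path)
        paths.append(str(path.relative_to(out)))
    mf = manifest.copy()
    mf["path"] = paths
    mf.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"
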