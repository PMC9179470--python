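"""Mixed depthwise convolution (MDConv) building block and cost accounting.

A standard convolution mapping an ``M``-channel ``DF x DF`` feature map to
``N`` output channels with ``Dk x Dk`` kernels costs

    params: Dk^2 * M * N           multiplies: Dk^2 * M * N * DF^2

A depthwise separable convolution factorizes this into per-channel spatial
filtering plus a 1x1 pointwise mix:

    params: Dk^2 * M + M * N       multiplies: Dk^2 * M * DF^2 + M * N * DF^2

so the multiply ratio collapses to ``1/N + 1/Dk^2`` independent of M and DF.
MDConv goes one step further: the M input channels are partitioned into C
groups and each group is depthwise-filtered with its own kernel size, mixing
receptive-field scales at depthwise cost.

The feature extractor here stacks [MDConv -> pointwise 1x1 -> ReLU] blocks
and global-average-pools the last block into a fixed-length feature vector.
Convolutions use stride 1, zero same-padding, and the deep-learning
cross-correlation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ConvSpec",
    "MDConvSpec",
    "ExtractorConfig",
    "FeatureExtractor",
    "standard_conv_params",
    "dsc_params",
    "conv_costs",
    "mdconv_forward",
    "init_mdconv_weights",
    "extract_features",
]


@dataclass(frozen=True)
class ConvSpec:
    """Shape of one convolution: Dk kernel side, M in / N out channels,
    DF output feature-map side."""

    Dk: int
    M: int
    N: int
    DF: int = 1

    def __post_init__(self) -> None:
        for name in ("Dk", "M", "N", "DF"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class MDConvSpec:
    """Channel grouping of a mixed depthwise convolution.

    ``groups[g]`` consecutive channels are depthwise-convolved with an odd
    ``kernel_sizes[g]`` x ``kernel_sizes[g]`` kernel each; groups partition
    the M input channels contiguously in index order.
    """

    M: int
    groups: tuple[int, ...]
    kernel_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(int(g) for g in self.groups))
        object.__setattr__(self, "kernel_sizes", tuple(int(k) for k in self.kernel_sizes))
        if len(self.groups) != len(self.kernel_sizes) or not self.groups:
            raise ValueError("groups and kernel_sizes must be equal-length and nonempty")
        if any(g < 1 for g in self.groups) or sum(self.groups) != self.M:
            raise ValueError(f"groups {self.groups} must be positive and sum to M={self.M}")
        if any(k < 3 or k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError(f"kernel sides must be odd and >= 3, got {self.kernel_sizes}")

    @property
    def C(self) -> int:
        return len(self.groups)


def standard_conv_params(spec: ConvSpec) -> int:
    """Weight count of a standard convolution: Dk^2 * M * N."""
    return spec.Dk * spec.Dk * spec.M * spec.N


def dsc_params(spec: ConvSpec) -> int:
    """Weight count of a depthwise separable convolution:
    Dk^2 * M (depthwise) + 1*1 * M * N (pointwise)."""
    return spec.Dk * spec.Dk * spec.M + spec.M * spec.N


def conv_costs(spec: ConvSpec) -> tuple[int, int, float]:
    """(standard multiplies, depthwise-separable multiplies, their ratio).

    The ratio equals 1/N + 1/Dk^2 exactly, independent of M and DF.
    """
    standard = spec.Dk * spec.Dk * spec.M * spec.N * spec.DF * spec.DF
    dsc = spec.Dk * spec.Dk * spec.M * spec.DF * spec.DF + spec.M * spec.N * spec.DF * spec.DF
    return standard, dsc, dsc / standard


def _depthwise_channel(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # cross-correlation, zero padding, same output size
    return ndimage.correlate(plane, kernel, mode="constant", cval=0.0)


def init_mdconv_weights(spec: MDConvSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """He-style random depthwise kernels, one (group_size, k, k) array per group."""
    weights = []
    for g, k in zip(spec.groups, spec.kernel_sizes):
        scale = np.sqrt(2.0 / (k * k))
        weights.append(rng.normal(0.0, scale, size=(g, k, k)))
    return weights


def mdconv_forward(
    feature_map: np.ndarray, spec: MDConvSpec, weights: list[np.ndarray]
) -> np.ndarray:
    """Mixed depthwise convolution of an (M, H, W) stack.

    Channels are split contiguously by ``spec.groups``; group g is
    depthwise-convolved (one kernel per channel) at its own kernel size.
    Channel order is preserved; with C = 1 this is plain depthwise
    convolution.
    """
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3 or fm.shape[0] != spec.M:
        raise ValueError(f"expected ({spec.M}, H, W) feature map, got shape {fm.shape}")
    if len(weights) != spec.C:
        raise ValueError(f"expected {spec.C} weight groups, got {len(weights)}")
    out = np.empty_like(fm)
    start = 0
    for g, (size, k) in enumerate(zip(spec.groups, spec.kernel_sizes)):
        w = np.asarray(weights[g], dtype=float)
        if w.shape != (size, k, k):
            raise ValueError(
                f"group {g}: expected weights of shape {(size, k, k)}, got {w.shape}"
            )
        for c in range(size):
            out[start + c] = _depthwise_channel(fm[start + c], w[c])
        start += size
    return out


@dataclass(frozen=True)
class ExtractorConfig:
    """Stack of [MDConv -> pointwise 1x1 -> ReLU] blocks with global
    average pooling.

    ``widths`` are the pointwise output channels per block (the last entry
    is the feature-vector length); each block's MDConv splits its input
    channels into equal groups over ``kernel_sizes``, falling back to
    fewer groups when the channel count is too small to split.
    """

    blocks: int = 3
    widths: tuple[int, ...] = (16, 32, 64)
    kernel_sizes: tuple[int, ...] = (3, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.widths) != self.blocks:
            raise ValueError("widths must list one channel count per block")

    @property
    def feature_length(self) -> int:
        return self.widths[-1]


def _split_groups(m: int, kernel_sizes: tuple[int, ...]) -> MDConvSpec:
    c = min(len(kernel_sizes), m)
    base, extra = divmod(m, c)
    groups = tuple(base + (1 if i < extra else 0) for i in range(c))
    return MDConvSpec(M=m, groups=groups, kernel_sizes=kernel_sizes[:c])


class FeatureExtractor:
    """Deterministic random-initialized mixed-convolution feature extractor.

    Weights are drawn once from ``config.seed``; the forward pass is a pure
    function of weights and input, so feature vectors are reproducible.
    An optional ``warm_start_from`` copies weights from another extractor
    (transfer of desk-scale pretrained weights).
    """

    def __init__(self, config: ExtractorConfig | None = None,
                 warm_start_from: "FeatureExtractor | None" = None) -> None:
        self.config = config or ExtractorConfig()
        rng = np.random.default_rng(self.config.seed)
        self.block_specs: list[MDConvSpec] = []
        self.depthwise: list[list[np.ndarray]] = []
        self.pointwise: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        m = 1
        for width in self.config.widths:
            spec = _split_groups(m, self.config.kernel_sizes)
            self.block_specs.append(spec)
            self.depthwise.append(init_mdconv_weights(spec, rng))
            self.pointwise.append(rng.normal(0.0, np.sqrt(2.0 / m), size=(width, m)))
            self.biases.append(np.zeros(width))
            m = width
        if warm_start_from is not None:
            if warm_start_from.config != self.config:
                raise ValueError("warm start requires an identically configured extractor")
            self.depthwise = [[w.copy() for w in blk] for blk in warm_start_from.depthwise]
            self.pointwise = [w.copy() for w in warm_start_from.pointwise]
            self.biases = [b.copy() for b in warm_start_from.biases]

    @property
    def feature_length(self) -> int:
        return self.config.feature_length

    def forward_map(self, image: np.ndarray) -> np.ndarray:
        """Run the block stack on one (H, W) plane; returns (N_last, H, W)."""
        plane = np.asarray(image, dtype=float)
        if plane.ndim != 2 or plane.size == 0:
            raise ValueError(f"expected a nonempty 2-D plane, got shape {plane.shape}")
        fm = plane[None, :, :]
        for spec, dw, pw, b in zip(self.block_specs, self.depthwise, self.pointwise, self.biases):
            fm = mdconv_forward(fm, spec, dw)
            fm = np.tensordot(pw, fm, axes=([1], [0])) + b[:, None, None]
            fm = np.maximum(fm, 0.0)  # ReLU
        return fm

    def __call__(self, image: np.ndarray) -> np.ndarray:
        """Feature vector of one image: global average pool of the last block."""
        return self.forward_map(image).mean(axis=(1, 2))


def extract_features(images: np.ndarray | list[np.ndarray],
                     extractor: FeatureExtractor) -> np.ndarray:
    """Feature matrix (n_images, feature_length) for a uniform-size batch.

    Deterministic for fixed extractor weights; each row depends only on its
    own image, so permuting the batch permutes the rows identically.
    """
    batch = [np.asarray(im, dtype=float) for im in images]
    if not batch:
        raise ValueError("empty image batch")
    shape = batch[0].shape
    if any(im.shape != shape for im in batch):
        raise ValueError("all images in a batch must share one size")
    return np.stack([extractor(im) for im in batch])
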