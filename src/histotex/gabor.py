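"""Gabor-kernel image preprocessing.

The pipeline's first stage suppresses pixel noise by filtering each image
with a small bank of oriented Gabor kernels.  A 2-D Gabor kernel is a
complex sinusoidal carrier modulated by a Gaussian envelope:

    G(a, b) = exp(-(a'^2 + gamma^2 b'^2) / (2 sigma^2))
              * exp(i (2 pi a' / delta + psi))

with the rotated coordinates

    a' =  a cos(theta) + b sin(theta)
    b' = -a sin(theta) + b cos(theta)

where ``delta`` is the carrier wavelength, ``theta`` the orientation,
``psi`` the phase offset, ``sigma`` the envelope standard deviation and
``gamma`` the spatial aspect ratio.  ``psi = 0`` and ``psi = pi/2`` select
the real and imaginary parts.  When a spatial-frequency bandwidth ``bw``
(in octaves) is given instead of ``sigma``, the envelope width follows the
closed form

    sigma = (delta / pi) * sqrt(ln 2 / 2) * (2^bw + 1) / (2^bw - 1).

Note on naming: some descriptions of this preprocessing stage call it
"Gaussian filtering" because of the Gaussian envelope; the kernel is a
Gabor (band-pass, orientation-selective) filter, and :func:`denoise` is
the pipeline-stage alias for the filter-bank application.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GaborParams",
    "sigma_from_bandwidth",
    "make_gabor_kernel",
    "apply_gabor",
    "gabor_bank",
    "denoise",
    "to_luminance",
]

_SIGMA_BW_TOL = 1e-12


def sigma_from_bandwidth(delta: float, bw: float) -> float:
    """Envelope standard deviation implied by a carrier wavelength and a
    spatial-frequency bandwidth in octaves.

    Strictly positive, linear in ``delta`` and strictly decreasing in
    ``bw``; diverges as ``bw -> 0`` (the denominator ``2^bw - 1``
    vanishes) and tends to ``(delta/pi) sqrt(ln 2 / 2)`` as ``bw -> inf``.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if bw <= 0:
        raise ValueError(f"bw must be positive, got {bw}")
    ratio = (2.0**bw + 1.0) / (2.0**bw - 1.0)
    return (delta / math.pi) * math.sqrt(math.log(2.0) / 2.0) * ratio


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single 2-D Gabor kernel.

    ``theta`` is normalized into [0, pi) on construction — orientation is
    a half-turn quantity (the opposite direction is redundant).  Exactly
    one of ``sigma`` / ``bw`` drives the envelope: if ``bw`` is given,
    ``sigma`` is derived from it and both are stored.
    """

    delta: float
    theta: float = 0.0
    psi: float = 0.0
    gamma: float = 0.5
    sigma: float | None = None
    bw: float | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        object.__setattr__(self, "theta", float(self.theta) % math.pi)
        if self.bw is not None:
            derived = sigma_from_bandwidth(self.delta, self.bw)
            if self.sigma is None:
                object.__setattr__(self, "sigma", derived)
            elif abs(self.sigma - derived) > _SIGMA_BW_TOL * max(1.0, abs(derived)):
                raise ValueError(
                    f"sigma={self.sigma} inconsistent with bw={self.bw} "
                    f"(closed form gives {derived})"
                )
        if self.sigma is None:
            raise ValueError("either sigma or bw must be supplied")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def default_half_extent(self) -> int:
        """Kernel half-width covering three envelope standard deviations."""
        return max(1, math.ceil(3.0 * self.sigma))


def make_gabor_kernel(params: GaborParams, half_extent: int) -> np.ndarray:
    """Complex Gabor kernel on the integer grid [-half_extent, half_extent]^2.

    Returns a ``(2*half_extent+1, 2*half_extent+1)`` complex array indexed
    ``kernel[a + half_extent, b + half_extent]`` (first axis = a = row
    offset).  The real part is the psi-phase even filter used throughout
    the pipeline for psi = 0.
    """
    if half_extent < 1:
        raise ValueError(f"half_extent must be >= 1, got {half_extent}")
    offs = np.arange(-half_extent, half_extent + 1, dtype=float)
    a, b = np.meshgrid(offs, offs, indexing="ij")
    a_rot = a * math.cos(params.theta) + b * math.sin(params.theta)
    b_rot = -a * math.sin(params.theta) + b * math.cos(params.theta)
    envelope = np.exp(-(a_rot**2 + params.gamma**2 * b_rot**2) / (2.0 * params.sigma**2))
    carrier = np.exp(1j * (2.0 * math.pi * a_rot / params.delta + params.psi))
    return envelope * carrier


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Collapse a (H, W) or (H, W, C) image to one float64 grayscale plane.

    Color planes are averaged with equal weight.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D or 3-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def apply_gabor(
    image: np.ndarray, params: GaborParams, half_extent: int | None = None
) -> np.ndarray:
    """Convolve an image with the real part of a Gabor kernel.

    True 2-D convolution (kernel flipped), reflect border padding, output
    the same size as the input.  Linear in the input by construction.
    """
    plane = to_luminance(image)
    if half_extent is None:
        half_extent = params.default_half_extent
    if half_extent >= min(plane.shape):
        raise ValueError(
            f"half_extent {half_extent} does not fit image of shape {plane.shape}"
        )
    kernel = make_gabor_kernel(params, half_extent).real
    return ndimage.convolve(plane, kernel, mode="reflect")


@dataclass(frozen=True)
class GaborBankConfig:
    """Filter-bank defaults: four orientations, real-part (psi=0) kernels."""

    delta: float = 4.0
    orientations: tuple[float, ...] = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
    psi: float = 0.0
    gamma: float = 0.5
    bw: float = 1.0
    half_extent: int | None = None


def gabor_bank(config: GaborBankConfig | None = None) -> list[GaborParams]:
    """Build the kernel parameter list for each orientation in the bank."""
    cfg = config or GaborBankConfig()
    return [
        GaborParams(delta=cfg.delta, theta=th, psi=cfg.psi, gamma=cfg.gamma, bw=cfg.bw)
        for th in cfg.orientations
    ]


def denoise(image: np.ndarray, config: GaborBankConfig | None = None) -> np.ndarray:
    """Pipeline preprocessing stage: average the filter-bank responses.

    Each orientation's real-part Gabor response is computed with reflect
    padding; the responses are averaged into a single denoised plane.
    """
    cfg = config or GaborBankConfig()
    bank = gabor_bank(cfg)
    responses = [apply_gabor(image, p, cfg.half_extent) for p in bank]
    return np.mean(responses, axis=0)
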