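"""Controlled synthetic distortions for reference/distorted image pairs.

Five distortion families cover the artifacts a remote-monitoring pipeline
introduces: sensor noise, optical defocus, tone-curve (gamma) shifts,
block-transform compression, and motion smear.  Every distortion is
deterministic for a fixed seed, is the identity at ``level == 0``, and clips
its output to the 0-255 luminance scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft, ndimage

from .io import validate_image

DISTORTION_KINDS = (
    "gaussian_noise",
    "gaussian_blur",
    "contrast_change",
    "blockiness",
    "motion_blur",
)

_BLOCK = 8  # block-DCT size for the blockiness distortion


@dataclass(frozen=True)
class DistortionSpec:
    """One distortion: a kind, a severity level, and a noise seed.

    ``level`` is the physical severity in the units natural to each kind:
    noise standard deviation in gray levels, blur sigma in pixels, the gamma
    exponent for contrast change, the DCT quantization step for blockiness,
    and the smear length in pixels for motion blur.  ``level == 0`` always
    means "no distortion" (for ``contrast_change`` the exponent gamma=1 is
    equivalently the identity).
    """

    kind: str
    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DISTORTION_KINDS:
            raise ValueError(
                f"unknown distortion kind {self.kind!r}; expected one of {DISTORTION_KINDS}"
            )
        if self.level < 0:
            raise ValueError(f"distortion level must be nonnegative, got {self.level}")


def _blockiness(img: np.ndarray, step: float) -> np.ndarray:
    """Quantize 8x8 block-DCT coefficients with a uniform step."""
    h, w = img.shape
    ph = (-h) % _BLOCK
    pw = (-w) % _BLOCK
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    hh, ww = padded.shape
    blocks = padded.reshape(hh // _BLOCK, _BLOCK, ww // _BLOCK, _BLOCK).transpose(0, 2, 1, 3)
    coef = fft.dctn(blocks, axes=(2, 3), norm="ortho")
    coef = np.round(coef / step) * step
    rec = fft.idctn(coef, axes=(2, 3), norm="ortho")
    out = rec.transpose(0, 2, 1, 3).reshape(hh, ww)
    return out[:h, :w]


def apply_distortion(img: np.ndarray, spec: DistortionSpec) -> np.ndarray:
    """Apply ``spec`` to a luminance image, returning a new clipped array.

    A ``level`` of 0 returns a pixel-identical copy for every kind.
    """
    img = validate_image(img)
    if spec.level == 0:
        return img.copy()

    if spec.kind == "gaussian_noise":
        rng = np.random.default_rng(spec.seed)
        out = img + rng.normal(0.0, spec.level, size=img.shape)
    elif spec.kind == "gaussian_blur":
        out = ndimage.gaussian_filter(img, sigma=spec.level)
    elif spec.kind == "contrast_change":
        out = 255.0 * (np.clip(img, 0.0, 255.0) / 255.0) ** spec.level
    elif spec.kind == "blockiness":
        out = _blockiness(img, spec.level)
    elif spec.kind == "motion_blur":
        length = max(1, int(round(spec.level)))
        if length == 1:
            return img.copy()
        kernel = np.full(length, 1.0 / length)
        out = ndimage.correlate1d(img, kernel, axis=1, mode="nearest")
    else:  # pragma: no cover - guarded by DistortionSpec
        raise ValueError(f"unknown distortion kind {spec.kind!r}")

    return np.clip(out, 0.0, 255.0)


__all__ = ["DistortionSpec", "apply_distortion", "DISTORTION_KINDS"]
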