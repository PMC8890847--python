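"""Classical image gradients: template convolution and forward differences.

Coordinate convention, used everywhere in the package: ``x`` is the column
(horizontal) index and ``y`` the row (vertical) index, so ``I[y, x]`` indexes
a luminance array.  The horizontal component ``M_H`` responds to change along
columns, the vertical component ``M_V`` to change along rows.

Two magnitude definitions are provided.  The L2 magnitude
``sqrt(M_H^2 + M_V^2)`` is the classical Euclidean gradient norm, normally
paired with the Prewitt/Sobel/Scharr template operators.  The L1 magnitude
``|M_H| + |M_V|`` paired with one-sided forward differences is the cheap
variant the quality metric in :mod:`gradiq.metric` builds on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import validate_image

# Template kernels stored for mathematical convolution (kernel flipped during
# application), so the horizontal component is positive on a luminance ramp
# that increases with the column index.  Horizontal and vertical kernels are
# transposes of each other and sum to zero.
TEMPLATES: dict[str, np.ndarray] = {
    "prewitt": np.array([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [1.0, 0.0, -1.0]]),
    "sobel": np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]]),
    "scharr": np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]),
}


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient components plus a magnitude map.

    All three arrays share the source image's shape.  ``magnitude_kind``
    records whether ``magnitude`` is the L2 norm of the components or their
    L1 (absolute-sum) norm.
    """

    horizontal: np.ndarray
    vertical: np.ndarray
    magnitude: np.ndarray
    magnitude_kind: str

    @classmethod
    def forward_l1(cls, img: np.ndarray) -> "GradientField":
        """Forward-difference components with the L1 magnitude (metric pipeline)."""
        mh, mv = gradient_components_forward(img)
        return cls(mh, mv, gradient_magnitude_l1(mh, mv), "l1")

    @classmethod
    def template_l2(cls, img: np.ndarray, operator: str) -> "GradientField":
        """Template-operator components with the L2 magnitude (classical path)."""
        mh, mv = gradient_components_template(img, operator)
        return cls(mh, mv, gradient_magnitude_l2(mh, mv), "l2")


def convolve2d(
    img: np.ndarray, kernel: np.ndarray, padding: str = "replicate"
) -> np.ndarray:
    """2-D convolution with edge-replicate padding, preserving shape.

    This is mathematical convolution (the kernel is flipped), matching a
    brute-force nested-loop evaluation of ``sum_k I(p - k) K(k)`` with
    out-of-range pixels replaced by the nearest edge pixel.
    """
    img = np.asarray(img, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2 or img.ndim != 2:
        raise ValueError("image and kernel must both be 2-D")
    if kernel.shape[0] > img.shape[0] or kernel.shape[1] > img.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} is larger than image {img.shape} in some dimension"
        )
    if padding != "replicate":
        raise ValueError(f"unsupported padding mode {padding!r}")
    return ndimage.convolve(img, kernel, mode="nearest")


def gradient_components_template(
    img: np.ndarray, operator: str
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal/vertical components from a named template operator.

    ``operator`` is one of ``prewitt``, ``sobel``, ``scharr`` with the
    classical unnormalized integer coefficients (+/-1; +/-1, +/-2;
    +/-3, +/-10).
    """
    img = validate_image(img)
    if operator not in TEMPLATES:
        raise ValueError(
            f"unknown operator {operator!r}; expected one of {sorted(TEMPLATES)} "
        )
    gh = TEMPLATES[operator]
    return convolve2d(img, gh), convolve2d(img, gh.T)


def gradient_components_forward(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided forward differences.

    ``M_H(y, x) = I(y, x+1) - I(y, x)`` with the last column set to 0;
    ``M_V(y, x) = I(y+1, x) - I(y, x)`` with the last row set to 0.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"forward differences need at least a 2x2 image, got {img.shape}")
    mh = np.zeros_like(img)
    mv = np.zeros_like(img)
    mh[:, :-1] = img[:, 1:] - img[:, :-1]
    mv[:-1, :] = img[1:, :] - img[:-1, :]
    return mh, mv


def _check_same_shape(mh: np.ndarray, mv: np.ndarray) -> None:
    if np.shape(mh) != np.shape(mv):
        raise ValueError(
            f"component shapes differ: {np.shape(mh)} vs {np.shape(mv)}"
        )


def gradient_magnitude_l2(mh: np.ndarray, mv: np.ndarray) -> np.ndarray:
    """Euclidean magnitude ``sqrt(M_H^2 + M_V^2)``."""
    _check_same_shape(mh, mv)
    return np.hypot(np.asarray(mh, dtype=np.float64), np.asarray(mv, dtype=np.float64))


def gradient_magnitude_l1(mh: np.ndarray, mv: np.ndarray) -> np.ndarray:
    """Absolute-sum magnitude ``|M_H| + |M_V|``."""
    _check_same_shape(mh, mv)
    return np.abs(np.asarray(mh, dtype=np.float64)) + np.abs(
        np.asarray(mv, dtype=np.float64)
    )


def gradient_direction_arctan(mh: np.ndarray, mv: np.ndarray) -> np.ndarray:
    """Pointwise ``arctan(M_V / M_H)`` mapped into [0, pi).

    Conventions for the degenerate cases: a purely vertical gradient
    (``M_H = 0``, ``M_V != 0``) maps to pi/2, and a zero gradient maps to 0.
    Negative arctangent values are shifted by pi so orientations are
    reported modulo pi.
    """
    mh = np.asarray(mh, dtype=np.float64)
    mv = np.asarray(mv, dtype=np.float64)
    _check_same_shape(mh, mv)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arctan(np.divide(mv, mh, out=np.zeros_like(mv), where=mh != 0))
    theta = np.where((mh == 0) & (mv != 0), np.pi / 2.0, theta)
    theta = np.where(theta < 0, theta + np.pi, theta)
    return theta


__all__ = [
    "GradientField",
    "TEMPLATES",
    "convolve2d",
    "gradient_components_template",
    "gradient_components_forward",
    "gradient_magnitude_l2",
    "gradient_magnitude_l1",
    "gradient_direction_arctan",
]
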