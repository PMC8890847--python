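"""Gradient-direction quality metric with deviation pooling (DSS/MSS/GSS).

The metric compares a reference and a distorted luminance image through
three per-pixel similarity maps:

* ``DS`` — similarity of quantized gradient *directions*.  Each pixel's
  direction is assigned by convolving the image's L1 forward-difference
  gradient magnitude with a bank of 12 oriented line kernels (rotations of a
  horizontal line detector by i*pi/12, i = 0..11) and taking the angle of
  the strongest response.  Direction values ``D_r``, ``D_d`` of the two
  images are combined SSIM-style:

      DS = (2 D_r D_d + C_d) / (D_r^2 + D_d^2 + C_d),   C_d = 205.

* ``MS`` — similarity of the L1 gradient magnitudes:

      MS = (2 M_r M_d + C_M) / (M_r^2 + M_d^2 + C_M),   C_M = 160.

* ``GS = DS^alpha * MS^beta`` — the joint map, with alpha = beta = 1 by
  default so direction and magnitude carry equal weight; alpha = 0 reduces
  the metric to magnitude-only, beta = 0 to direction-only.

Each map is pooled into a scalar by its *population* standard deviation over
all pixels (deviation pooling): DSS = std(DS), MSS = std(MS), GSS = std(GS).
Identical images give GSS = 0; larger GSS means stronger, more spatially
uneven degradation and hence worse perceived quality.

The stability constants C_d and C_M assume luminance on an 8-bit-like 0-255
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .gradients import GradientField, convolve2d
from .io import validate_image

N_DIRECTIONS = 12
_ANGLE_STEP = np.pi / N_DIRECTIONS


@dataclass(frozen=True)
class MetricParams:
    """Tunable constants of the metric.

    ``c_d`` and ``c_m`` are the stability constants of the direction and
    magnitude similarity maps (defaults 205 and 160, on the 0-255 luminance
    scale); ``alpha`` and ``beta`` weight direction vs magnitude in the
    joint map; ``base_size`` is the side length of the oriented kernels;
    ``circular_direction`` switches the direction comparison to a circular
    (modulo-pi) distance instead of the default raw-value comparison.
    """

    c_d: float = 205.0
    c_m: float = 160.0
    alpha: float = 1.0
    beta: float = 1.0
    base_size: int = 5
    circular_direction: bool = False

    def __post_init__(self) -> None:
        if self.c_d <= 0 or self.c_m <= 0:
            raise ValueError("stability constants c_d and c_m must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")


@dataclass(frozen=True)
class KernelBank:
    """12 oriented line-detector kernels L_0..L_11 at angles i*pi/12."""

    kernels: np.ndarray  # shape (12, k, k)
    base_size: int
    angles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "angles", np.arange(N_DIRECTIONS) * _ANGLE_STEP
        )
        if self.kernels.shape[0] != N_DIRECTIONS:
            raise ValueError(f"kernel bank must hold {N_DIRECTIONS} kernels")


@dataclass(frozen=True)
class DirectionMap:
    """Per-pixel quantized gradient direction.

    ``index`` holds the winning kernel index n in {0..11}; ``direction`` is
    exactly ``index * pi/12``.
    """

    index: np.ndarray

    @property
    def direction(self) -> np.ndarray:
        return self.index * _ANGLE_STEP


@dataclass(frozen=True)
class QualityResult:
    """Similarity maps and pooled scores for one reference/distorted pair."""

    ds_map: np.ndarray
    ms_map: np.ndarray
    gs_map: np.ndarray
    dss: float
    mss: float
    gss: float
    n_pixels: int
    m_ds: float
    m_gs: float


def build_kernel_bank(base_size: int = 5) -> KernelBank:
    """Construct the 12-direction line-kernel bank.

    ``L_0`` is a horizontal line detector: ones along the center row of a
    ``base_size`` x ``base_size`` grid, scaled to unit absolute sum.  Kernel
    ``L_i`` is ``L_0`` rotated counter-clockwise by i*pi/12 with bilinear
    interpolation and renormalized to unit absolute sum; the lattice-aligned
    rotations i = 0 and i = 6 use exact grid rotation.  A line kernel
    responds maximally where a ridge of gradient magnitude aligns with its
    orientation, so the strongest of the 12 responses identifies the local
    edge direction.
    """
    if base_size < 3 or base_size % 2 == 0:
        raise ValueError(f"base_size must be an odd integer >= 3, got {base_size}")
    l0 = np.zeros((base_size, base_size))
    l0[base_size // 2, :] = 1.0 / base_size
    kernels = np.empty((N_DIRECTIONS, base_size, base_size))
    for i in range(N_DIRECTIONS):
        if i == 0:
            k = l0.copy()
        elif i == 6:
            k = np.rot90(l0)  # exact 90-degree grid rotation
        else:
            # ndimage.rotate's positive angle is counter-clockwise for the
            # displayed image (origin at the top-left, y down).
            k = ndimage.rotate(l0, angle=i * 15.0, reshape=False, order=1, cval=0.0)
            k /= np.abs(k).sum()
        kernels[i] = k
    return KernelBank(kernels=kernels, base_size=base_size)


def direction_responses(magnitude: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Convolve the gradient-magnitude map with all 12 oriented kernels.

    Returns a stack of shape ``(12, H, W)`` with replicate-padded
    convolution, layer i being the response to orientation i*pi/12.
    """
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if bank.kernels.shape[0] != N_DIRECTIONS:
        raise ValueError("kernel bank must hold 12 kernels")
    out = np.empty((N_DIRECTIONS,) + magnitude.shape)
    for i in range(N_DIRECTIONS):
        out[i] = convolve2d(magnitude, bank.kernels[i])
    return out


def direction_map(responses: np.ndarray) -> DirectionMap:
    """Pick, per pixel, the orientation with the strongest response.

    Ties are broken toward the smallest kernel index, so an all-equal
    response column yields direction 0.
    """
    responses = np.asarray(responses, dtype=np.float64)
    if responses.ndim != 3 or responses.shape[0] != N_DIRECTIONS:
        raise ValueError(
            f"expected a (12, H, W) response stack, got shape {responses.shape}"
        )
    return DirectionMap(index=np.argmax(responses, axis=0))


def _similarity(a: np.ndarray, b: np.ndarray, c: float) -> np.ndarray:
    return (2.0 * a * b + c) / (a * a + b * b + c)


def direction_similarity(
    d_ref: np.ndarray, d_dist: np.ndarray, c_d: float = 205.0, circular: bool = False
) -> np.ndarray:
    """Per-pixel similarity of two direction maps, values in (0, 1].

    The default compares the raw direction values (so 0 and 11*pi/12 count
    as dissimilar even though the orientations are close modulo pi).  With
    ``circular=True`` the comparison uses the wrap-around angular distance
    ``delta = min(|D_r - D_d|, pi - |D_r - D_d|)`` instead:
    ``DS = C_d / (delta^2 + C_d)``.
    """
    d_ref = np.asarray(d_ref, dtype=np.float64)
    d_dist = np.asarray(d_dist, dtype=np.float64)
    if d_ref.shape != d_dist.shape:
        raise ValueError(f"direction map shapes differ: {d_ref.shape} vs {d_dist.shape}")
    if c_d <= 0:
        raise ValueError("c_d must be positive")
    if circular:
        delta = np.abs(d_ref - d_dist)
        delta = np.minimum(delta, np.pi - delta)
        return c_d / (delta * delta + c_d)
    return _similarity(d_ref, d_dist, c_d)


def magnitude_similarity(
    m_ref: np.ndarray, m_dist: np.ndarray, c_m: float = 160.0
) -> np.ndarray:
    """Per-pixel similarity of two gradient-magnitude maps, values in (0, 1]."""
    m_ref = np.asarray(m_ref, dtype=np.float64)
    m_dist = np.asarray(m_dist, dtype=np.float64)
    if m_ref.shape != m_dist.shape:
        raise ValueError(f"magnitude map shapes differ: {m_ref.shape} vs {m_dist.shape}")
    if c_m <= 0:
        raise ValueError("c_m must be positive")
    return _similarity(m_ref, m_dist, c_m)


def joint_similarity(
    ds_map: np.ndarray, ms_map: np.ndarray, alpha: float = 1.0, beta: float = 1.0
) -> np.ndarray:
    """Combine direction and magnitude similarity: ``GS = DS^alpha * MS^beta``."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    ds_map = np.asarray(ds_map, dtype=np.float64)
    ms_map = np.asarray(ms_map, dtype=np.float64)
    if ds_map.shape != ms_map.shape:
        raise ValueError(f"map shapes differ: {ds_map.shape} vs {ms_map.shape}")
    return ds_map**alpha * ms_map**beta


def deviation_pool(values: np.ndarray) -> float:
    """Population standard deviation of a similarity map over all pixels.

    The pixel set is unordered, so the pooled value is invariant to any
    permutation of the map.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot pool an empty map")
    return float(np.std(values))


def quantized_direction(img: np.ndarray, bank: KernelBank) -> DirectionMap:
    """Full direction pipeline for one image: L1 magnitude -> bank -> argmax."""
    fld = GradientField.forward_l1(validate_image(img))
    return direction_map(direction_responses(fld.magnitude, bank))


def score_pair(
    ref: np.ndarray,
    dist: np.ndarray,
    params: MetricParams | None = None,
    bank: KernelBank | None = None,
) -> QualityResult:
    """Score a distorted image against its reference.

    Runs the full pipeline on both images (forward-difference L1 magnitude,
    kernel-bank direction map, DS/MS/GS similarity maps) and pools each map
    by its standard deviation.  Identical inputs give DSS = MSS = GSS = 0;
    the metric is symmetric in its two arguments.
    """
    params = params or MetricParams()
    ref = validate_image(ref)
    dist = validate_image(dist)
    if ref.shape != dist.shape:
        raise ValueError(
            f"reference shape {ref.shape} does not match distorted shape {dist.shape}"
        )
    if bank is None:
        bank = build_kernel_bank(params.base_size)

    f_ref = GradientField.forward_l1(ref)
    f_dist = GradientField.forward_l1(dist)
    d_ref = direction_map(direction_responses(f_ref.magnitude, bank))
    d_dist = direction_map(direction_responses(f_dist.magnitude, bank))

    ds = direction_similarity(
        d_ref.direction, d_dist.direction, params.c_d, circular=params.circular_direction
    )
    ms = magnitude_similarity(f_ref.magnitude, f_dist.magnitude, params.c_m)
    gs = joint_similarity(ds, ms, params.alpha, params.beta)

    return QualityResult(
        ds_map=ds,
        ms_map=ms,
        gs_map=gs,
        dss=deviation_pool(ds),
        mss=deviation_pool(ms),
        gss=deviation_pool(gs),
        n_pixels=int(ds.size),
        m_ds=float(ds.mean()),
        m_gs=float(gs.mean()),
    )


__all__ = [
    "N_DIRECTIONS",
    "MetricParams",
    "KernelBank",
    "DirectionMap",
    "QualityResult",
    "build_kernel_bank",
    "direction_responses",
    "direction_map",
    "direction_similarity",
    "magnitude_similarity",
    "joint_similarity",
    "deviation_pool",
    "quantized_direction",
    "score_pair",
]
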