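"""Synthetic test imagery.

Two families of fixtures mirror the two statistical regimes the metric is
designed around:

* *screen-content-like* images — computer-rendered pages mixing perfectly
  flat background, glyph-like text strokes with hard edges, filled shapes,
  and one embedded smooth "photographic" patch.  Their gradient amplitudes
  concentrate on a few discrete values.
* *natural-like* images — smoothed Gaussian noise modulated by a smooth
  log-normal contrast envelope (a Gaussian scale mixture, the standard
  statistical model of natural scenes).  Their gradient amplitudes are
  unimodal at zero with heavy, smoothly decaying tails.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import validate_image

#: Luminance of the flat page background in screen fixtures.
_BACKGROUND = 230.0
#: Luminance of glyph strokes; 230 - 20 = 210 gray levels across every text edge.
_GLYPH = 20.0
#: Margin (pixels) kept free of content so a flat background region always survives.
_MARGIN = 4


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a screen-content fixture.

    Attributes
    ----------
    height, width:
        Image dimensions in pixels; at least 32x32.
    n_text_blocks:
        Number of text-like blocks of dark glyph strokes.
    n_shapes:
        Number of filled rectangles with hard edges.
    smooth_patch_fraction:
        Fraction of the image area covered by one low-pass-filtered noise
        patch emulating an embedded natural photograph.
    seed:
        Seed for the generator's random placement and fills.
    """

    height: int
    width: int
    n_text_blocks: int = 6
    n_shapes: int = 4
    smooth_patch_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError(
                f"fixture dimensions must be at least 32x32, got {self.height}x{self.width}"
            )
        if not 0.0 <= self.smooth_patch_fraction <= 1.0:
            raise ValueError("smooth_patch_fraction must lie in [0, 1]")
        if self.n_text_blocks < 0 or self.n_shapes < 0:
            raise ValueError("content counts must be nonnegative")


def make_screen_fixture(spec: FixtureSpec) -> np.ndarray:
    """Render a deterministic screen-content-like page.

    The top-left ``_MARGIN``-wide border strip is never drawn on, so the
    output always contains an exactly constant region; any text block
    guarantees at least one step edge of 210 gray levels.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), _BACKGROUND)

    # Embedded "photograph": one low-pass filtered noise patch.
    if spec.smooth_patch_fraction > 0:
        side = np.sqrt(spec.smooth_patch_fraction)
        ph = max(4, int(round(side * (h - 2 * _MARGIN))))
        pw = max(4, int(round(side * (w - 2 * _MARGIN))))
        ph, pw = min(ph, h - _MARGIN), min(pw, w - _MARGIN)
        r0 = int(rng.integers(_MARGIN, max(_MARGIN + 1, h - ph + 1)))
        c0 = int(rng.integers(_MARGIN, max(_MARGIN + 1, w - pw + 1)))
        noise = ndimage.gaussian_filter(rng.standard_normal((ph, pw)), sigma=2.0)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        img[r0 : r0 + ph, c0 : c0 + pw] = np.clip(128.0 + 40.0 * noise, 0.0, 255.0)

    # Hard-edged filled rectangles ("graphics").
    for _ in range(spec.n_shapes):
        sh = int(rng.integers(h // 8, max(h // 8 + 1, h // 3)))
        sw = int(rng.integers(w // 8, max(w // 8 + 1, w // 3)))
        r0 = int(rng.integers(_MARGIN, max(_MARGIN + 1, h - sh)))
        c0 = int(rng.integers(_MARGIN, max(_MARGIN + 1, w - sw)))
        fill = float(rng.integers(0, 171))  # >= 59 gray levels below the page
        img[r0 : r0 + sh, c0 : c0 + sw] = fill

    # Text blocks: rows of short dark strokes separated by gaps.
    stroke_h = max(2, h // 40)
    for _ in range(spec.n_text_blocks):
        bh = 3 * stroke_h + 2 * stroke_h  # three "lines" with leading
        bw = int(rng.integers(w // 6, max(w // 6 + 1, w // 2)))
        r0 = int(rng.integers(_MARGIN, max(_MARGIN + 1, h - bh)))
        c0 = int(rng.integers(_MARGIN, max(_MARGIN + 1, w - bw)))
        for line in range(3):
            rr = r0 + line * 2 * stroke_h
            cc = c0
            while cc < c0 + bw - 2:
                glyph_w = int(rng.integers(2, 7))
                gap = int(rng.integers(1, 4))
                img[rr : rr + stroke_h, cc : min(cc + glyph_w, c0 + bw)] = _GLYPH
                cc += glyph_w + gap

    return img


def make_natural_fixture(
    height: int, width: int, smoothing_sigma: float, seed: int = 0
) -> np.ndarray:
    """Generate a natural-scene-like luminance field.

    White noise is low-pass filtered at ``smoothing_sigma`` pixels, then
    multiplied by a smooth log-normal envelope (itself filtered noise at
    three times the base scale) before min-max rescaling to 0-255.  The
    envelope makes local contrast vary across the image, which gives the
    derivative distribution the sharp zero peak and heavy tails seen in
    photographic content; plain filtered noise would have Gaussian (zero
    excess kurtosis) derivatives.

    Raises
    ------
    ValueError
        If ``smoothing_sigma`` is not strictly positive.
    """
    if smoothing_sigma <= 0:
        raise ValueError(f"smoothing_sigma must be > 0, got {smoothing_sigma}")
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.standard_normal((height, width)), smoothing_sigma)
    env = ndimage.gaussian_filter(rng.standard_normal((height, width)), 3.0 * smoothing_sigma)
    for field in (base, env):
        sd = field.std()
        if sd > 0:
            field /= sd
    img = base * np.exp(1.2 * env)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.full((height, width), 128.0)
    return (img - lo) / (hi - lo) * 255.0


def make_oriented_edge(
    height: int, width: int, angle: float, contrast: float
) -> np.ndarray:
    """Two half-planes split by a line at ``angle`` through the image center.

    ``angle`` is measured in radians from the horizontal axis,
    counter-clockwise with the y axis pointing up (the usual mathematical
    convention applied to the displayed image); it must lie in [0, pi).
    The two sides sit at 128 +/- contrast/2, clipped to [0, 255].
    """
    if not 0.0 <= angle < np.pi:
        raise ValueError(f"angle must lie in [0, pi), got {angle}")
    rows, cols = np.mgrid[0:height, 0:width].astype(np.float64)
    x = cols - (width - 1) / 2.0
    y_up = (height - 1) / 2.0 - rows
    # Signed distance to the line through the center with direction
    # (cos(angle), sin(angle)); the normal is (-sin(angle), cos(angle)).
    # Tiny trigonometric residues (sin(pi) etc.) are snapped to zero so
    # axis-aligned edges are exactly axis-aligned.
    s, c = np.sin(angle), np.cos(angle)
    s = 0.0 if abs(s) < 1e-12 else s
    c = 0.0 if abs(c) < 1e-12 else c
    signed = -s * x + c * y_up
    img = np.where(signed >= 0, 128.0 + contrast / 2.0, 128.0 - contrast / 2.0)
    return np.clip(img, 0.0, 255.0)


__all__ = [
    "FixtureSpec",
    "make_screen_fixture",
    "make_natural_fixture",
    "make_oriented_edge",
    "validate_image",
]
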