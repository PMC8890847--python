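# Methods

## The quality metric

`gradiq` scores a distorted grayscale image `I_d` against its pristine
reference `I_r` (full-reference IQA). Both images are luminance fields on a
0–255 scale; color input is reduced with the BT.601 weights
0.299/0.587/0.114.

### Gradient stage

The metric pipeline uses one-sided forward differences with the L1 norm:

    M_H(y, x) = I(y, x+1) − I(y, x)      (last column 0)
    M_V(y, x) = I(y+1, x) − I(y, x)      (last row 0)
    M = |M_H| + |M_V|

The classical template operators (Prewitt, Sobel, Scharr, with the standard
unnormalized integer stencils) and the L2 magnitude `sqrt(M_H² + M_V²)` are
also provided, as the conventional alternative gradient path; they are not
part of the default scoring pipeline. Template convolution uses
edge-replicate padding so all maps keep the image's shape; the dangling last
column/row of the forward differences is zero-filled for the same reason.

Coordinate convention throughout: `x` = column, `y` = row, arrays indexed
`I[y, x]`.

### Direction assignment by an oriented kernel bank

Rather than the numerically unstable pointwise `arctan(M_V/M_H)` (which is
still exposed as `gradient_direction_arctan`, mapped into [0, π) with
0 assigned to zero-gradient pixels and π/2 to purely vertical ones), each
pixel's direction is quantized by a bank of 12 oriented line detectors.
`L_0` is a `base_size × base_size` kernel (default 5×5) with ones along its
center row, scaled to unit absolute sum; `L_i` is `L_0` rotated by `i·π/12`
(bilinear interpolation, renormalized to unit absolute sum; the
lattice-aligned cases i = 0 and i = 6 use exact grid rotation). The bank is
convolved with the gradient-magnitude map `M` — a line kernel responds
maximally where a ridge of gradient magnitude aligns with its orientation —
and the pixel's direction is `D = n·π/12` with `n` the index of the
strongest response (ties broken toward the smallest index, so featureless
pixels get direction 0 deterministically).

Angular resolution: the default 5×5 bank cleanly separates orientations at
least 30° from the image axes, but cannot distinguish 15° (and 165°, 75°,
105°) step edges from their axis-aligned neighbours, because at radius 2 the
rotated line is displaced by barely half a pixel. A 7×7 bank resolves all
twelve orientations; `base_size` is exposed for exactly this trade-off, and
the defaults keep the smaller, faster kernel.

### Similarity maps and deviation pooling

With direction maps `D_r, D_d` and magnitude maps `M_r, M_d`:

    DS = (2·D_r·D_d + C_d) / (D_r² + D_d² + C_d),   C_d = 205
    MS = (2·M_r·M_d + C_M) / (M_r² + M_d² + C_M),   C_M = 160
    GS = DS^α · MS^β,                                α = β = 1

The constants keep the ratios stable when both operands are near zero, and
are calibrated to the 0–255 intensity scale; both maps lie in (0, 1] and
equal 1 exactly where the operands agree. `α = 0` reduces the metric to
magnitude-only, `β = 0` to direction-only.

Each map is pooled by its **population** standard deviation over all pixels
(`1/N`, not `1/(N−1)`):

    DSS = std(DS),  MSS = std(MS),  GSS = std(GS)

Identical images give GSS = 0; higher GSS means more spatially uneven
degradation and hence worse perceived quality. Since map values lie in
(0, 1], pooled scores are bounded by 0.5. The metric is symmetric in its two
arguments. No downsampling or multi-scale stage is applied.

Two deliberate design points in the direction comparison:

* `DS` compares the *raw* direction values, so orientations 0 and 11π/12
  count as dissimilar although they are close modulo π. This matches the
  SSIM-style ratio form above taken literally; a circular-distance variant
  `DS = C_d / (δ² + C_d)` with `δ = min(|ΔD|, π − |ΔD|)` is available behind
  the non-default `circular_direction` flag.
* Because direction values are at most 11π/12 ≈ 2.88 while `C_d = 205`, the
  DS map moves in a narrow band below 1; deviation pooling measures its
  spatial *spread*, for which the narrow band is not an obstacle.

## Synthetic fixtures and distortions

No reference corpus ships with the package; fixtures are generated.

* **Screen-content fixture** — a flat page (luminance 230) carrying
  hard-edged filled rectangles, text-like rows of dark strokes (luminance
  20, guaranteeing 210-gray-level step edges), and one low-pass-filtered
  noise patch emulating an embedded photograph. A 4-pixel margin is never
  drawn on, so an exactly constant region always exists. This reproduces
  the defining gradient statistics of computer-rendered content: noise-free
  flat regions, sharp text edges, and amplitudes concentrated on few
  discrete values.
* **Natural fixture** — white noise low-pass filtered at `smoothing_sigma`
  pixels, multiplied by a smooth log-normal contrast envelope
  (`exp(1.2·e)` with `e` filtered noise at 3× the base scale), min-max
  rescaled to 0–255. The envelope turns the field into a Gaussian scale
  mixture — the standard statistical model of natural scenes — giving
  derivative distributions a sharp zero peak and heavy tails (robustly
  positive excess kurtosis across seeds, and a gradient histogram whose
  mode is the zero bin). Plain filtered noise would have Gaussian
  derivatives and fails to show either signature. What the fixture does
  *not* emulate: occlusion boundaries, textures, lighting; conclusions
  about real footage need real footage.
* **Oriented edge** — two half-planes split by a line at a chosen angle
  through the center; the probe used to verify direction selectivity.
* **Distortions** — additive Gaussian noise (σ in gray levels), Gaussian
  blur (σ in pixels), gamma contrast change, 8×8 block-DCT coefficient
  quantization (the codec-agnostic stand-in for blocky compression), and
  horizontal motion blur (box kernel of given length). Level 0 is the
  identity for every kind; for the contrast family the natural identity is
  γ = 1, and level 0 is additionally mapped to the identity so the
  zero-level convention holds uniformly.

## Gradient-amplitude statistics

`gradient_histogram` normalizes a 64-bin (configurable, ≥16) histogram of
the magnitude map over [0, max]; both probabilities and their logs are
returned, since tail structure is read in the log domain.
`fit_generalized_laplace` fits the exponential-power family
`p(v) = k/(2sΓ(1/k))·exp(−|v/s|^k)` by profile maximum likelihood: for
fixed shape `k` the ML scale is closed-form, `s = (k·mean(|v|^k))^{1/k}`,
and a bounded scalar search over `log k ∈ [log 0.05, log 20]` maximizes the
profile likelihood (tolerance 1e−8). Shape 1 is the Laplace distribution,
shape 2 the normal.

`tail_oscillation_index` makes the qualitative screen-vs-natural tail
contrast operational: over the upper `tail_fraction` (default 0.25) of the
bins, empty bins are dropped and the mean absolute second difference of the
log-probabilities is returned. A geometrically decaying tail is log-linear
and scores ≈0; the spiky, gap-ridden tails of screen content score an order
of magnitude higher than natural fixtures (10-seed averages ≈4 vs ≈0.7 at
128×128). The index is a package-defined diagnostic, not a standard
statistic.

## Mediation analysis

The three-step test regresses, on once-standardized columns (mean 0, sd 1,
ddof = 1): outcome on predictor (total effect `c`), mediator on predictor
(path `a`), and outcome on predictor + mediator (direct effect `c'` and
path `b`). Standardized and unstandardized coefficients, SEs, t and p
values, R², adjusted R² (`1 − (1−R²)(n−1)/(n−p−1)`) and F are reported per
step. For OLS on a single sample the decomposition `c = c' + a·b` is an
algebraic identity; the indirect effect `a·b` is reported descriptively
(no Sobel or bootstrap test — the three-step significance logic is the
procedure implemented). Verdict at a two-sided α of 0.05: *none* if any of
`c`, `a`, `b` is nonsignificant (or `|c'| ≥ |c|`); *full* if `c'` loses
significance in step 3; *partial* otherwise.

The simulator draws multivariate normal scores. The default four-variable
correlation structure (basic and functional daily-living ability, health
literacy, depression) encodes the pattern typical of chronic-disease
elderly cohorts — daily-living subscales correlated 0.610 with each other,
0.398/0.563 with health literacy, and −0.200/−0.298/−0.374 with depression
— and a composite-outcome 3×3 matrix is derived from it analytically by
summing the two standardized subscales. The default generating path model
is `a = −0.446`, `b = 0.482`, `c' = −0.388` at n = 382, with noise scaled
so every variable has unit population variance (feasible because the
implied explained variance stays below 1). Since real per-subject data of
this kind are not distributable, the package's claims are about *estimator
behaviour under the generating model* (parameter recovery, identity checks,
verdict logic), not about any particular cohort.

Note that a generating model cannot reproduce every line of a typical
reported table simultaneously: in simple standardized regression the step-1
β must equal the bivariate correlation, so a table whose step-1 β differs
from the correlation matrix it accompanies is internally inconsistent. The
simulator therefore targets the step-2/step-3 path coefficients and the
correlation matrix, which are mutually compatible.

## Problem sizes and numerical choices

Default experiment sizes: 256×256 fixtures and 20 noise seeds for
monotonicity studies; 10⁵ draws for distribution-fit recovery; 500
replicates of n = 382 for mediation recovery (Monte-Carlo SE of the mean
path estimate ≈ 0.002, comfortably inside the ±0.02 check). All generators
take explicit integer seeds and are bit-reproducible. Degenerate inputs
fail loudly: non-PSD correlation matrices report their smallest eigenvalue,
zero-variance samples refuse kurtosis/fits, collinear predictors refuse
OLS, and empty maps refuse pooling.

## Known limitations

* The 5×5 default bank's 15°-from-axis ambiguity (above).
* Deviation pooling is insensitive to a spatially *uniform* quality loss
  (e.g. global contrast scaling that leaves the similarity maps constant).
* GSS saturates at high noise levels: the seed-averaged score remains
  strictly increasing from σ = 10 to σ = 30 but the increments shrink.
* The raw-value direction comparison penalizes the 0 ↔ 11π/12 wrap; use
  `circular_direction=True` if geometric orientation distance is wanted.
* The mediation verdict uses fixed-α significance logic; modern practice
  supplements this with bootstrap indirect-effect intervals, which are out
  of scope here.
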