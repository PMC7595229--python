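# Methods

## The measurement model

`layercaliper` treats a segmented layer as a 2-D boolean raster and its
thickness as the span of the layer perpendicular to its own centerline.
The pipeline is:

1. **Thinning.** The mask is reduced to a single-pixel-wide skeleton by
   topology-preserving (Zhang) thinning; a distance-transform medial axis
   is available behind the `thinning="medial"` flag. The skeleton
   approximates the layer's medial line.
2. **Pruning and path extraction.** The skeleton's pixel graph
   (8-connectivity) is pruned of side branches shorter than
   `min_branch_len` and reduced to the longest geodesic path between
   endpoint pixels (BFS from every endpoint; ties broken
   lexicographically, so output is deterministic). A cyclic skeleton is
   broken at the lexicographically smallest pixel with a warning.
3. **End trimming.** Two mechanisms keep callipers away from skeleton
   ends. *Plateau trimming* (`auto_trim`, default on) removes end pixels
   whose distance-transform value falls more than 2 px below the local
   plateau: thinning a thick band does not stop at the centerline ends
   but runs diagonal tails toward the mask corners (up to roughly half
   the band thickness times √2 long), and a calliper anchored on a tail
   measures along a spurious orientation. The plateau reference is local
   to each end (the maximum over the first/last 30 % of the path), so a
   layer whose thickness genuinely varies along its length — the step
   phantom, a thinning retina — is not eaten into. A fixed `trim_px`
   (default 20) is then removed from each end, the direct analogue of
   trimming the skeleton so that no calliper-to-image-edge measurement
   occurs. For layers that taper smoothly to a point, plateau trimming
   will remove the taper below the end-plateau; disable `auto_trim` and
   set `trim_px` manually in that situation.
4. **Fragmentation and anchoring.** The trimmed path is split into
   `n_calipers` contiguous, near-equal (±1 px) sub-paths. Each fragment's
   anchor is its coordinate mean snapped to the nearest on-path pixel
   (ties to the earlier path index), so anchors always lie on the
   skeleton even for curved fragments.
5. **Orientation.** The local angle θ ∈ [0°, 180°) at an anchor is the
   principal direction (total least squares) of all trimmed-path pixels
   inside an `angle_window` × `angle_window` box (default 15 px) centered
   on the anchor, measured against the horizontal in the y-up sense. TLS
   is used rather than ordinary regression because a near-vertical
   centerline has no well-defined y-on-x slope.
6. **Marching.** Two half-rays leave the anchor along the supplementary
   angle α = 180° − θ, evaluating the mask at integer step counts
   k = 1, 2, … via the rounded-coordinate construction shown in the
   README. Each side stops at its first outside pixel; the calliper
   length is `round(‖final − initial‖) − 1`, clamped at ≥ 1.

### The boundary correction

The two endpoints each sit one pixel beyond the layer, so on an
axis-aligned band of thickness T their separation is exactly T + 1; the
−1 correction makes the calliper read T. The same convention gives exact
readings on the 45°/135° diagonals (endpoint separation 142·√2 ≈ 200.8 on
the 200-px band, which rounds to 201 and corrects to 200). This is the
only constant correction consistent with first-outside endpoints and
exact readings across the whole 10–500 px phantom range, and it is frozen
by the calibration suite.

### Rounding

Coordinates in the marching construction and the final length use
half-up rounding (`floor(x + 0.5)`). For the phantom geometries no
sampled value falls exactly on a half, so the choice is immaterial there;
it is fixed for reproducibility. Lengths are rounded in pixels first and
then scaled to µm (`length_px × scale_um_per_px`).

### Invalid callipers

A half-ray that leaves the canvas before leaving the mask (open boundary)
or exceeds `max_march` (default: image diagonal) flags its calliper
invalid. Invalid callipers are excluded from all statistics rather than
truncated — truncation would bias minima downward.

## Calibration phantoms

The generator reproduces the three calibration datasets exactly as
specified procedurally, with no external data:

- **Increasing thickness:** 50 full-width horizontal bands, 10–500 px in
  10-px steps, vertically centered on a 1344×1024 canvas. Foreground
  count is exactly `width × thickness`.
- **Rotations:** a 1344×200 px band rotated counter-clockwise about the
  canvas center to 0–180° in 10° steps plus 45° and 135° (21 images).
  Rasterization is geometric — a pixel is foreground iff its center lies
  strictly inside the exact rotated rectangle — not image rotation, so
  there is no interpolation and the rasterization is bit-deterministic.
  The canvas is enlarged symmetrically (even-sized, center preserved)
  only when the rotated band would otherwise clip; an exact-fit canvas is
  left untouched so the 0° image equals the axis-aligned band
  bit-for-bit. Rotations in {0, 45, 90, 135, 180}° produce regular
  ("even") edges; all others produce stair-step ("jagged") edges whose
  aliasing the calibration budget allows ±2 px.
- **Step band:** three 448-px segments of 200/150/250 px thickness, each
  vertically centered, with per-column ground truth.

Files are written as 8-bit TIFF/PNG in either foreground dialect
(`inside_is_zero`: layer = pixel value 0, matching the marching
convention; `inside_is_max`: white-on-black).

What the phantoms do **not** emulate: noise, blur, intensity texture,
segmentation error, or anisotropic pixels. Passing the calibration
criteria therefore demonstrates the correctness of the geometry and
marching arithmetic, not robustness to imperfect segmentation — on real
images the measurement is only as good as the supplied mask.

## Calibration criteria and achieved values

With the shipped defaults (50 callipers, 15-px angle window, 20-px trim,
plateau trimming on) all four criteria pass:

1. rotation-set overall mean within 200 ± 1 px (achieved 200.14 ± 0.17;
   the measured value depends on the rasterization dialect, which is why
   the criterion is a tolerance rather than a point value);
2. index of dispersion exactly 0 on every rectangle phantom with regular
   edges (the 50 axis-aligned bands and the 5 even-edge rotations);
   jagged rotations have callipers at 200 ± 1 px and hence a small
   nonzero dispersion (~10⁻³), which is reported but not required to be
   zero;
3. every single calliper on even-edge rotations exactly 200 px;
4. every single calliper on jagged rotations within 200 ± 2 px
   (achieved: ±1 px).

On the increasing set, measured-vs-known bias is 0.00 ± 0.00 and Pearson
r = 1.0; on the step band, callipers anchored more than 15 px from a
transition recover the 200/150/250 schedule exactly. The guard distance
matches the angle window: a calliper whose orientation window straddles a
step is not a point measurement of either segment.

Equivalence testing of the measured means against the hypothesized
200-px mean is replaced by the direct tolerance checks above: the
pipeline is deterministic, within-image variance on even-edge phantoms is
exactly zero, and a TOST procedure degenerates at zero variance.

## Agreement statistics

`bland_altman(a, b)` reports bias = mean(a − b), the sample SD of the
differences, SE = SD/√n, 95 % limits of agreement bias ± 1.96·SD (the
normal-quantile multiplier, consistent with the identity
interval = 3.92·SE·√n), and a matched-pairs t-test p-value (Wilcoxon
signed-rank behind `test="wilcoxon"` for non-normal differences). The
pairwise coefficient of variation is (A − B)/((A + B)/2), antisymmetric
in its arguments; the index of dispersion uses the population variance
(ddof 0 — the zero-iff-constant property holds either way; the choice is
frozen for reproducibility).

## Numerical choices and known limitations

- **Unit-step marching vs a dense ray.** The marching construction
  samples the ray at 1-px parameter steps, producing an 8-connected
  candidate chain. A dense (0.1-px) ray-march crosses every pixel the
  continuous ray touches, including thin background slivers a diagonal
  unit step can hop over. At near-normal incidence — the method's
  operating regime — the two agree within 1 px for ≳98 % of callipers
  and within 2 px always (measured on random curved-band masks); at
  grazing incidence on irregular boundaries the unit-step march can read
  up to ~3 px long. This is inherent to pixel-value marching at integer
  steps, and is the price of implementing the construction exactly.
- **Thinning artifacts.** Zhang thinning is not exactly equivariant
  under transposition/rotation at path tips (a 1–3 px effect); the
  centerline body is, and measured thickness is rotation-consistent.
- **Degenerate inputs.** 1–2 px thick layers are measured correctly (the
  skeleton coincides with the band); an all-foreground canvas has no
  boundary and fails explicitly with every calliper flagged invalid.
- **Stand-in segmenter.** `segment_layer` (threshold → closing → hole
  fill → area filter → largest component) exists so the CLI can run
  end-to-end on grayscale images; it is deliberately simple and is not a
  validated nuclear-layer segmentation method.
- **Scale.** Pixels are assumed square; the default scale of 1.0 µm/px
  reports pixel values unchanged and is logged loudly.

## Problem sizes in the test suite

The test and acceptance runs use the full-scale phantom datasets
(1344×1024 canvases, 72 images, 50 callipers each; about 40 s on one
CPU). Property suites use 200–500 px masks, 450+ oracle comparisons and
10,000 synthetic agreement pairs, sizes at which the brute-force oracles
(column scans, all-pairs BFS, dense ray-march) remain exact and fast.
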