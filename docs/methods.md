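# Methods

## Problem and approach

Cloth facemasks are often sewn from whatever woven or knitted fabric is
locally available, and their filtering behaviour is governed largely by two
surface properties: how tightly the yarns are packed (cover factor /
porosity) and how large the inter-yarn openings (pores) are. Both can be
read off a bright-field transmitted-light micrograph taken with a
smartphone fitted with a ball lens: yarns appear dark, pores bright.

`fabriscope` turns that observation into a measurement pipeline:

1. **Calibration.** A ruled calibration slide of known pitch (10 μm
   minimum inter-grid distance) is imaged, whole grid periods across the
   in-focus central region are counted, and the pixel scale (μm/px) and
   effective field of view follow from `FOV = periods × pitch` and
   `scale = FOV / span_px`.
2. **Segmentation.** The micrograph is cropped to its central in-focus
   region (a ball lens focuses only the image center), optionally
   contrast-stretched, and thresholded into pore (bright) and yarn (dark)
   pixels.
3. **Morphometry.** Pores are 8-connected bright components; each pore's
   size is its longest dimension — the maximum Feret diameter over pixel
   centers — an upper estimate of the opening.
4. **Coverage.** Cover factor `f' = 100 · n_yarn / n_total` (the
   pixel-count estimate of the yarn area fraction
   `f = 100 · A_yarn / A_total`) and porosity `100 − f'`.
5. **Screening.** Per-fabric aggregates (mean ± σ) are ranked — smaller
   pores first, ties to higher cover factor — and flagged against two
   fixed particle scales: bio-aerosols (≤ 5 μm) and respiratory droplets
   (5–100 μm). The report ranks and flags only; it does not estimate
   filtration efficiency, for which pore geometry is a proxy screen, not
   a measurement.

## Synthetic weaves as ground truth

Real mask photographs are not distributed with the package, so every
stage is validated against a synthetic generator with closed-form truth.
The model is an axis-aligned plain weave: warp yarns are vertical strips
of width `w_x` every `p_x` μm, weft yarns horizontal strips (`w_y`,
`p_y`). A pixel is yarn iff its center lies in a strip. From the
geometry alone:

- cover factor `100 · (1 − g_x g_y / (p_x p_y))` with gaps
  `g = p − w`;
- pore longest dimension `sqrt(g_x² + g_y²)` (gap-rectangle diagonal);
- the count of pore cells rasterizing fully inside the frame, by exact
  pixel arithmetic.

Ball-lens artifacts are layered on after the binary rendering and never
touch the truth: isotropic Gaussian blur (defocus), radial quadratic
vignetting (curvature-induced edge falloff), additive Gaussian sensor
noise. Grid images are rendered the same way with line centers recorded
as oracle metadata.

What the generator does **not** emulate: fiber-scale texture inside
yarns, twill/satin or knit loop structure (asymmetric pores are emulated
only via unequal x/y gaps), yarn crimp and 3D shadowing, illumination
gradients other than radial vignetting, and JPEG-style compression. A
passing suite therefore shows the pipeline is correct on ideal plain
weaves under controlled optics; accuracy on heavily textured knits still
depends on thresholding quality in ways only real images can probe.

## Numerical choices

- **Rasterization.** Pixel-center membership; the clean rendering's
  pixel-count cover factor then matches the analytic value to within
  half a pixel per pitch per axis, *when compared over a whole number of
  weave periods*. A frame cut mid-period adds a windowing bias of order
  `pitch / (2 · frame)` that has nothing to do with rasterization; tests
  therefore align the comparison window to whole periods.
- **Focus crop** defaults to 0.6 of each side (linear), the regime where
  vignetted synthetic weaves are classified essentially without bias.
- **Thresholding** defaults to Otsu (exhaustive between-class-variance
  maximization over the 256-bin histogram, via scikit-image) to remove
  operator subjectivity; a manual threshold value is retained as the
  faithful analogue of interactive workflows. A contrast stretch
  (1st/99th percentiles → 0/255) runs automatically only when the
  initial classification finds < 2% pore pixels — the
  pores-barely-visible regime of very dense fabrics — and the result is
  flagged `contrast_adjusted`, as those estimates carry more error.
- **Longest dimension** is computed exactly: convex hull (Qhull) of the
  region's pixel centers, then rotating calipers over antipodal vertex
  pairs, with a pairwise fallback for degenerate hulls and a projection
  formula for collinear regions. Single pixel → 0 by convention. The
  suite checks exact equality with an O(n²) brute force on random blobs.
- **Pore filtering.** Components under 9 px are discarded as noise
  specks (at ~1 μm/px that is far below any plausible pore);
  border-touching pores are excluded from sizing (truncated extents) but
  kept in the cover factor, which is a pixel fraction of the whole
  analyzed area.
- **Aggregation.** Pore mean ± σ pools the interior pores of all region
  images of a fabric and keeps the 10 largest (configurable; one-per-image
  is available via `k_pores`), matching the upper-estimate intent of the
  longest-dimension measurement; cover factor averages the first 5
  region values; σ is the sample standard deviation (n − 1), zero with a
  flag for a single observation.
- **Grid counting** discards dark runs touching the profile ends
  (possibly partial rulings) and counts periods between the outermost
  whole-line centers; the 1D profile is smoothed with a 1 px Gaussian —
  row-averaging already suppresses noise, and heavier smoothing would
  erase the modulation of the finest legal grids (pitch ≥ line width
  + 2 px). Per-axis results and their mean are reported; reporting the
  mean of the two axes is this package's convention.
- **Ranking** uses a fully keyed sort (pore mean, −cover mean, mask id,
  layer), so the order is independent of input order.

## Default study conditions

Synthetic validation runs use 512–800 px frames at 0.5–2.5 μm/px, yarn
pitches of 20–190 μm (gaps 15–150 μm), sensor noise σ ≈ 4–6 intensity
units, blur σ ≤ 1 px and vignetting ≤ 0.75 — the scale regime of a
ball-lens smartphone microscope with a ~760 μm field of view, kept to
problem sizes where the full suite and the acceptance script each finish
in seconds. The acceptance script (`scripts/acceptance.py`) regenerates
all synthetic inputs from its `--seed` and recomputes reference-survey
statistics from the bundled printed aggregates; its measured recovery
errors are ≲ 0.2% for pixel scale, ≲ 0.3 percentage points for cover
factor, ~1% for pore size, and 100% pairwise ranking concordance at the
default conditions.

## Known limitations

- The rectangular-lattice weave keeps ground truth closed-form but
  cannot represent curved or irregular pore outlines; max-Feret accuracy
  on such shapes is tested only indirectly (random-blob equality with
  brute force).
- Otsu assumes a reasonably bimodal histogram. On a dense fabric whose
  faint pores occupy ~1% of pixels with little intensity separation,
  Otsu may split the yarn texture instead; the auto-stretch trigger
  mitigates, but manual thresholds remain the fallback for such images.
- Merged pores (openings connected through inter-yarn channels in loose
  knits) are measured as one region; no watershed splitting is applied.
- The calibration does not correct lens distortion; it assumes the grid
  is imaged flat and the central crop is distortion-free.
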