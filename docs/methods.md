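# Methods

## Coordinate conventions

Rasters are `(row, col)`, 0-based, row increasing downward; the
"inferior edge" of an image is its maximal row. Pixel `(0, 0)` is the
*center* of the top-left pixel, a pixel belongs to a mask iff its
center satisfies the mask predicate, and pixel area is
`pixel_size_um²`. Intervals on rasters and depth bins are half-open
`[lo, hi)` so partitions tile without overlap. Image bit depth and
pixel size are not inferred from files; both are required user inputs.

## Dome model and fit

The dome outline is modelled as `d = a·x²` in a frame rotated by the
tilt angle about the apex: `x` is the signed lateral offset (µm) from
the symmetry axis, `d` the depth (µm) below the apex along it, with
tilt positive clockwise in display orientation. The fit minimizes
squared depth residuals jointly over tilt, apex and curvature: tilt is
searched deterministically on [−45°, 45°] (181-point grid, then a
bounded scalar refinement to 1e-8°), and for each candidate tilt the
quadratic coefficients have a closed-form least-squares solution in the
rotated frame. The procedure is seed-free and reproducible; a
curvature ≤ 0 (collinear trace) or an apex outside the traced lateral
extent raises an error naming the cause.

The parabolic mask covers, in the tilt-corrected frame, lateral offsets
within the traced extent and depths from the parabola down to the depth
of the deeper trace endpoint (`base_depth`); the rectangular mask
continues from `base_depth` to the bottom of the image over the same
lateral extent, so the two tile the tissue without gap or overlap. A
membership tolerance of 1 nm (10⁻⁹ µm, far below any pixel size) is
applied on the parabola-side and lateral boundaries so pixel centers
lying exactly on the curve — the apex in synthetic scenes — are
included; the parabolic/rectangular seam carries no tolerance and stays
exactly disjoint. Rectangular-mask extent follows the parabola-end
x-range rather than the full image width.

`scale_curvature` multiplies `a` by a factor ≥ 1 with apex, tilt,
extent and `base_depth` unchanged; the scaled mask is therefore nested
inside the original. The profile branch uses factor 1.3 by default
(config-overridable and recorded in the run manifest); the appropriate
value depends on how tightly the hybridization signal hugs the dome.

## Zonation

With the apex at the origin: CZ is `|x| ≤ cz_width/2`,
`0 ≤ d < cz_height`; OC is `|x| ≤ oc_width/2`,
`cz_height ≤ d < cz_height + oc_height`; RM is all tissue with
`d ≥ cz_height + oc_height`; PZ is the remaining tissue between CZ/OC
and the parabola. All are intersected with the tissue mask. The CZ box
proxies the CLV3 expression domain and the OC box the WUS domain
(defaults 30×25 µm and 45×25 µm — typical *Arabidopsis* domain sizes,
config-overridable; treat them as assumptions to be calibrated against
marker lines for quantitative zone-level claims). Nuclei are assigned
by the zone of the pixel containing their centroid; centroids outside
the tissue stay in the output as `OUTSIDE` but are excluded from
normalization, summaries and tests, with a logged count.

## Nuclear quantification and statistics

Concentration is total pixel intensity over a nucleus's labelled
pixels divided by its pixel count. Area is deliberately in pixels: the
pixel-size factor is global within a cohort and cancels under
max-normalization, which also removes detector units. No background
subtraction is performed (raw intensities are summed); summaries use
normalized concentrations, with quartiles by linear interpolation (a
fixed, documented choice — the convention matters at n ≤ 4).

Time-point comparisons use the Brunner–Munzel studentized midrank test
on per-meristem medians (one observation per meristem, avoiding
pseudoreplication over nuclei), two-sided, at α = 0.1 by default, with
no multiplicity correction across the baseline-vs-later comparisons
(α and the absence of correction are recorded in the output so users
can correct downstream). When both within-group rank variances vanish
(complete separation or all ties) the t form is undefined; the
implementation then computes the exact permutation two-sided p-value of
the superiority estimate whenever C(N, n1) ≤ 184,756, and reports the
p-value as missing otherwise. At the cohort sizes of interest
(3 vs 4), complete separation gives p = 2/35 ≈ 0.057.

The t-approximation is known to be mildly anticonservative at very
small samples: simulation at n₁ = 3, n₂ = 4 puts the true two-sided
level at α = 0.1 near 0.115 (the exact-permutation branch alone fires
with probability 2/35 under the null). At n = 30 per group the
empirical level is within Monte Carlo noise of nominal — this is the
calibration `scripts/acceptance.py` reports. Users testing many
zone × channel combinations at n ≤ 4 should interpret isolated
rejections accordingly.

## Longitudinal profiles

Z-stacks are sum-projected per channel, masked by the
curvature-increased tissue mask, and the in-mask pixels are binned by
depth from the fitted apex into consecutive `[k·w, (k+1)·w)` sections
(w = 10 µm by default), independent of the pixel grid. Depth is
measured from the apex along the tilt-corrected axis. Each section
reports pixel count, total intensity and concentration; empty sections
are emitted with missing concentration so profiles align across
meristems, and every in-mask pixel contributes to exactly one section
(bin totals conserve the in-mask mass exactly). Per-channel profiles
are normalized to their peak section. Sections are 2D depth slices of
the projection (area-normalized), not volumetric bins.

## Synthetic scenes

The generator exists so that every pipeline stage has exact ground
truth. Default scene: 256×256 px at 0.5 µm/px, dome halfwidth 45 µm,
curvature 0.02 µm⁻¹ (≈ 40 µm deep at the edges), 150 nuclei of radius
2.2 ± 0.3 µm — a realistic mid-transition SAM at confocal scale. Key
design choices:

* **Uniform-intensity disks, not Gaussian blobs.** Total intensity and
  concentration truth are exact, isolating quantification correctness
  from point-spread-function modelling.
* **Dyadic concentrations.** Per-nucleus concentrations are drawn from
  a Gamma law (CV 0.15) around a zone × time-point mean and quantized
  to multiples of 2⁻²⁰, making every pixel sum and total/area division
  exact in float64 — "equals truth" in tests means bit-equality.
* **Rejection-sampled placement** (10,000 attempts per nucleus, then
  error) keeps label masks unambiguous: disks never overlap.
* **Outline traces** are sampled from the true parabola with Gaussian
  pixel jitter (default sd 0.5 px) to exercise fit robustness.
* **Truth zonation** is evaluated with closed-form predicates at the
  continuous centroid, independent of the raster partition, so
  truth-vs-assignment checks compare two genuinely distinct routes.
  Each nucleus also records a conservative lower bound on its distance
  to the nearest zone boundary (distance transform at the centroid
  pixel minus 1 px) used to exclude boundary-straddling nuclei from
  exact-match assertions.
* **Noise** is an additive background plus Gaussian read noise
  (optional Poisson on the background); with noise off, rendered
  images conserve truth exactly. Channel defaults emulate a broadly
  expressed FD-like reporter and an FT-like reporter enriched in RM/OC
  and inducible ×3 at later time points; profile scenes spread a
  depth-dependent signal evenly over the z-slices so the sum projection
  recovers it exactly.
* **Cohorts** follow a (time point, n meristems) design — the nuclear
  time course uses 3/4/4/4 meristems at 10/11/12/13 long days — with
  independent per-meristem sub-seeds spawned from one cohort seed.

What the generator does **not** emulate: optics (PSF, channel
bleed-through, depth attenuation), intensity gradients within nuclei,
segmentation errors (masks are perfect by construction), 3D nuclear
shapes, or meristem-to-meristem biological variability beyond the
per-nucleus Gamma draw. Passing tests therefore certify the
*measurement and statistics machinery* — geometry, masking, zonation,
sums, normalization, rank tests — not robustness to segmentation or
optical artefacts in real data.

## Problem sizes used in tests

Unit and acceptance tests run scenes of 160×160 px (0.7 µm/px, 60
nuclei) for speed, 256–512 px scenes where the assertion concerns
raster resolution (mask-area accuracy, 200-nucleus zonation), 10,000
replicates for the type-I error calibration, and 100 cohort replicates
each for the power and null end-to-end checks. These sizes were chosen
so the full suite exercises every code path at desk scale; the
machinery is size-agnostic.

## Known limitations

* Zone box defaults are literature-scale assumptions, not fitted to
  marker data; quantitative zone-level claims should calibrate them.
* The parabola is fit to depth residuals (not orthogonal distances);
  for strongly asymmetric or non-parabolic domes the residual bound in
  the model invariant is the guard rail.
* The profile branch assumes the projection's signal is depth-resolved
  in-plane; it does not unmix channels or call individual
  hybridization spots.
* `intensity_variation` operates on caller-supplied line profiles; it
  does not detect lines or condensates.
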