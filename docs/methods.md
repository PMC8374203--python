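# Methods

## Problem and model

Actively discharged fungal conidia accumulate on a collection surface. Two
measurements of the same surface are linked by a linear model: the mean
8-bit gray value *g* of a grid cell in a blank-subtracted macroscopic scan
(diffuse reflection grows with the amount of deposited material), and the
conidia density *C* (conidia · cm⁻²) counted microscopically in that cell.
The calibration

    C = a·g + b

is fitted once by ordinary least squares on cells that were both scanned
and counted; afterwards *g* alone quantifies a sample. The model assumes
(i) reflection is proportional to areal conidia density over the working
range, (ii) illumination differences are removed by blank subtraction, and
(iii) the counted cells span the gray range of interest. The usable range
is bounded below by the scanner's noise floor (sparse cells give g ≈ 0)
and above by gray-value saturation; with the default calibration constants
this corresponds to roughly 0.2–2.0 × 10⁵ conidia · cm⁻².

## Counting pipelines

**Automatic (ACC).** rolling-ball background subtraction → threshold →
adjustable watershed → particle analysis.

* *Rolling ball* is implemented literally as its definition: grayscale
  erosion followed by dilation with the ball's upper surface
  b(y) = √(r² − |y|²) (Sternberg's formulation), through
  `scipy.ndimage.grey_erosion/dilation`. Radii above 16 px run on a
  bilinearly downscaled copy (factor 2/4/8 by radius) with a
  proportionally smaller ball, then upscale; the result is clamped below
  the input so `background ≤ image` holds exactly. Default radius: 3× the
  expected conidium major axis in px — large enough not to erode
  particles.
* *Threshold*: Otsu by default (recorded in the result), pluggable as
  `fixed:t` or `percentile:p`. Because automatic thresholds always "find"
  a split even on particle-free noise, a threshold below
  `min_threshold` (default 25 gray, above the corrected noise band of
  common scanners and of the synthetic scenes) declares the patch
  background-only.
* *Adjustable watershed*: Euclidean distance transform flooded from its
  prominent maxima. The single sensitivity knob `merge_tolerance` (default
  0.5 px) suppresses distance-map maxima whose dynamics (height above the
  saddle toward a deeper basin) fall below it. Maxima are computed as
  regional maxima of the morphological reconstruction of `dist − h` under
  `dist`, *not* via the residue rule (`h_maxima`), because the residue rule
  leaves equal-height twin maxima — ubiquitous on quantized distance
  ridges — split at any tolerance, fragmenting single particles. A
  tolerance above every peak height degenerates to one deterministic
  marker (top-left-most distance argmax) per connected blob: merging
  everything still means one basin per blob. Watershed-line pixels carry
  no label, matching common binary-watershed output.
* *Particle analysis*: per-label area (px² and µm²), centroid, equivalent
  diameter, circularity 4πA/P² capped at 1.0 (discrete perimeters
  overshoot on small blobs). Default filters: min area 25 % of the
  expected conidium area, max 10×, no circularity cut, edge particles
  kept (patches are cropped cell interiors, so border clipping is the
  caller's choice).

**Semi-automatic (SACC).** threshold *t* → prominence-filtered intensity
maxima → marker-controlled watershed on the inverted intensity → the same
particle analysis. A maximum's prominence is its height above the highest
saddle connecting it to higher terrain, evaluated within the
above-threshold region (below-threshold pixels count as level 0); the top
of each connected region rises above nothing, so its prominence is its own
height. Pixel values are integers, so running the reconstruction at
`h = prominence − 0.5` realises an inclusive (≥) criterion exactly.
Plateau maxima contribute one representative point: the plateau centroid
rounded toward the top-left (deterministic). `count_semi` applies a light
Gaussian pre-smooth (σ = 1 px, disable with `smooth_sigma=0`) so
single-pixel sensor-noise maxima do not swamp a prominence chosen for the
particles' structure — the batch stand-in for an operator visually tuning
the prominence per image. Batch runs take *t* and prominence per patch
from a CSV; there is no GUI.

## Prediction bands

`predict_band` uses worst-case error combination, half-width
E(g) = E_a·g + E_b: in `fit` mode the central line is a·g + b with
(E_a, E_b) = (σ_a, σ_b), the OLS standard errors; in `expanded` mode the
central line is a·g — the intercept, small against the band width, is
dropped, matching the conventional printed form of such expanded
calibrations — with (E_a, E_b) = (Δ_a, Δ_b). `expand_band` chooses the
smallest single multiplier k ≥ 1 of (σ_a, σ_b) reaching a target coverage
(bisection to 10⁻³ relative tolerance; coverage is a step function of k,
so the upper bisection end is returned). Explicit (Δ_a, Δ_b) overrides are
accepted for bands whose two errors do not share one multiplier. Negative
lower bounds are floored at 0 and flagged: densities are physical counts.
A conventional OLS prediction interval (`prediction_interval`) is offered
as an alternative; the worst-case band is the default because it is the
arithmetic the calibration constants are printed in.

## Synthetic scenes

`generate_micro_scene` emulates what the pipelines must cope with, not
photorealism:

* Conidia are filled ellipses (default 20 × 14 µm at 1 µm/px — the species
  is pear-shaped, but an ellipse suffices for counting) with a parabolic
  *dome* profile, brightest at the centre (`dome_falloff = 0.4` relative
  drop to the rim). The dome mimics the lensing of a roughly spherical
  spore in bright field; it matters because max-blended flat ellipses
  would render touching clusters as featureless plateaus that no
  prominence criterion could resolve, which contradicts how fused conidia
  actually image.
* Clusters: satellites placed around a seed conidium with pairwise overlap
  drawn from 20–50 % of the minor axis (support-function contact
  distance), deep enough to fuse the binary mask, shallow enough that a
  saddle exists. Placement is rejection sampling with bounding-circle
  separation; an explicit `PlacementError` fires when the requested count
  cannot fit (retry budget 2000 per particle).
* Germ tubes: rectangles, width 0.25× minor axis, length 1–2× major axis,
  at 0.9× the conidium intensity, grown from a pole — reproducing the
  known failure mode in which the watershed splits tubes into extra
  particles.
* Secondary conidia leave an adjacent remnant ellipse at 0.2× their
  intensity (remnants are strictly fainter; a mid-range threshold excludes
  them). Remnants appear in the truth table but never in `true_count`.
* Rendering: max-blend (no additive saturation inside clusters), Gaussian
  optical blur (σ = 1 px), additive Gaussian sensor noise (sd 5 gray,
  added after the blur, as sensor noise is), clip and quantize to uint8.
  Intensities: background 10, conidium mean 180 ± 15. The paper trail for
  these levels does not exist — they are conventions chosen to give
  bright-field-like contrast — so every one is a parameter.
* Determinism: one integer seed drives a single `numpy` Generator; equal
  seeds give bit-identical images and truth tables.

`generate_macro_zone` inverts the calibration: each grid cell of a density
field is painted uniformly at g = (C − b)/a plus per-cell Gaussian noise
(clipping beyond 5 % of cells logs a warning). `generate_calibration_set`
draws (g, C) pairs with g ~ U[50, 175] and C scattered (sd 15 000
conidia · cm⁻²) around slope 1250, intercept −100 — the regime of a
realistic counted set of 25 grid cells.

What passing on these scenes does **not** show: robustness to uneven
illumination beyond what rolling ball removes, mucus halos, debris and
scratches, focus variation, or real conidium shape variation. The
generator's clusters are geometric worst cases of a single mechanism
(overlap), not biological aggregates.

## Validation conditions and observed behaviour

The acceptance suite regresses pipeline counts on ground truth over 51
patches spanning 5–250 conidia. With 10 % of conidia in clusters, ACC sits
a few percent below unity slope at R² ≈ 0.999: overlaps approaching half
the minor axis are geometrically inseparable by a distance-transform
watershed, an intrinsic limit of shape-based splitting, and the dominant
error source. SACC on more heavily clustered scenes (25 %) with
generator-derived t = 95 and prominence = 8 regresses at slope ≈ 1.03.
Calibration recovery averages fits over 100 seeded sets; band coverage
averages over 200 sets. Problem sizes (51 patches of 500² px, 100–200
calibration sets) were chosen so each statistic is stable at the percent
level while the whole suite stays interactive.

## Coordinate and indexing conventions

Grid cells are 0-based, row-major, half-open pixel intervals from a
top-left origin; partial edge cells are discarded. The six-shade
pseudo-color bands partition [0, 255] by `band = floor(g·6/255)` (clipped
to 5), i.e. integer bands [0, 42], [43, 84], [85, 127], [128, 169],
[170, 212], [213, 255]; a legend maps band i to the density interval
[lower bound at g_lo, upper bound at g_hi] of the supplied model. The
default palette samples viridis at six points (any 6-color palette can be
passed); the shades are reproducible in spirit, not byte-identical to any
particular LUT file.

## Known limitations

* ACC undercounts dense clusters; SACC narrows but does not close the gap.
* Germ tubes inflate ACC counts; no tube detector is included.
* The min-gray "cell contains particles" selection is a proxy for a visual
  judgement; its threshold must be set relative to the blank noise level.
* Calibrations do not transfer across instruments or illumination setups;
  refit per setup.
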