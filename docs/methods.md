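# Methods

## The measurement problem

On a macroscopically dry surface that was colonized by bacteria while wet,
residual microdroplets of concentrated solution persist around cells and
aggregates (capillary pinning of the receding liquid front by particulates,
plus deliquescence of the solutes, which keeps the pinned droplets in
equilibrium with humid air). The quantities of interest are all 2D
projections measured per field of view: droplet areas, the live/dead
cell-covered area inside each droplet, and per-object survival rates.
Projected area serves as the proxy for cell number; the analysis assumes
cells within droplets are arranged in a single layer, so areas are
additive. `microwet` implements the measurement chain
(segment → assign → quantify → summarize) together with a generative model
of such scenes used to validate every stage against known ground truth.

## Generative scene model (`microwet.scene`)

A scene is a set of non-overlapping circular droplets with cells packed in
a single-layer disk at each droplet center. The model, and the defaults of
`SceneSpec`:

* **Droplet areas** — i.i.d. from the truncated power law `p(A) ∝ A^γ`,
  sampled by exact inverse-CDF transform (seedable, and the closed-form CDF
  doubles as a test oracle). Defaults `γ = −1.2` on `[10, 10⁴] µm²`, the
  regime observed for droplets around bacterial aggregates at moderate
  humidity.
* **Coupling of cell content to droplet size** — the cell-covered area
  inside a droplet is `c·A` under multiplicative log-normal noise, clipped
  to `≤ A`; defaults `c = 0.2`, `σ_log = 0.3`. Only the monotone increase
  of cell content with droplet size is empirically established; the linear
  form with noise is this package's modeling choice. The inverse
  (aggregate-first) mode, enabled by `aggregate_area_params =
  (mean_log10, sd_log10)`, draws aggregate areas from a log₁₀-normal
  distribution and derives droplet areas through the same coupling — used
  to emulate solitary-cell versus aggregated populations.
* **Cells** — footprint 1.0 µm² each (projected rod), count =
  cell area / footprint, placed on a golden-angle spiral with ~one-diameter
  spacing so rendered footprints stay essentially disjoint (the union of
  rendered cells then matches the summed footprint ground truth; perfectly
  confluent packing would make the union unverifiable). Solitary cells are
  aggregates of one.
* **Survival** — each cell is independently live with probability
  `s(A) = s_min + (s_max−s_min)·logistic(k·(log₁₀A − m))` of its host
  droplet area. Defaults `s_min = 0.02`, `s_max = 0.8`, `m = 3.0` (10³ µm²),
  `k = 3.5`: survival below 10² µm² is under 5%, above 10⁴ µm² around
  75–80%, matching the qualitative regime the pipeline is meant to resolve.
* **Rendering** — 16-bit channels at 0.1625 µm/px (a typical 40×/sCMOS
  scale; configurable). The blue (droplet) channel draws each droplet with
  a center-bright radial profile (rim at 70% of peak) and a 1-px Gaussian
  blur, so droplets are recoverable by an intensity threshold *and* show a
  strong rim gradient; green/red draw live/dead cell disks at
  `signal_level` over `background_level`; additive Gaussian noise
  `noise_sd` everywhere (photon statistics are not modeled). Defaults
  background 500, signal 5000, noise 100.
* **Geometry** — default field 332.8 × 332.8 µm (2048² px), 25
  aggregates/field; droplets placed largest-first by rejection sampling
  with 2 µm clearance (placement failure raises rather than silently
  dropping objects).

All randomness in a scene flows from `SceneSpec.seed`; sampling and
rendering are bit-reproducible.

What the generator does **not** emulate — irregular droplet outlines,
uneven illumination, photon noise, out-of-focus light, touching droplets,
multi-layer aggregates — bounds what passing tests show: they validate the
algorithmic chain, not robustness to every optical artifact of real
micrographs.

## Segmentation (`microwet.segment`)

Droplets: Gaussian smoothing (default σ = 2 px) → union of an intensity
mask (default Otsu) and a Sobel-gradient-magnitude mask (default the
99.9th percentile) → 8-connected components → hole filling → removal of
components below `min_droplet_area_um2` (default 1 µm²). The gradient
threshold is deliberately extreme: rims occupy well under 1% of a field,
so a moderate quantile floods the mask with noise pixels and pads every
droplet with a gradient annulus that biases areas upward; at the default,
20 seeded benchmark scenes give droplet-detection F1 = 1.0 and ~5% mean
area error at signal/noise 50, and the acceptance benchmark enforces
F1 ≥ 0.9 and ≤ 15% mean area error.

Cells: per-channel histogram thresholds (default Otsu — the specific
histogram method is configurable since any of them is defensible), with a
pixel above both thresholds resolved to the channel with the larger
background-normalized intensity (background estimated as the sub-threshold
median). Components below `min_cell_area_um2` (default 0.25 µm²) are
dropped. A constant image under an automatic threshold yields an empty
mask with a warning, not an exception, so batch runs survive blank fields.

## Quantification (`microwet.quantify`)

Cellular objects are 8-connected components of the union live∪dead mask.
Each object is assigned to the droplet sharing the most pixels with it
(ties to the smaller droplet id; no overlap → "dry", retained so
population totals conserve). A droplet's live/dead areas count only pixels
of its assigned objects that lie inside the droplet mask, which keeps
`cell_area ≤ droplet_area` an invariant even for objects straddling the
rim. Areas are pixel counts × (pixel size)².

## Statistics (`microwet.stats`)

* Binning is logarithmic throughout; `BinSpec` carries explicit edges,
  bin centers are geometric means, empty bins are reported with `n = 0`
  and NaN rather than dropped. Default droplet bins: 10⁰–10⁵ µm², two per
  decade.
* `size_distribution` reports counts/mm² per bin, mean ± SEM across
  'repeat' fields of view (the replicate unit for surface sections).
* `fit_power_law` provides `logbin_ls` (slope of log density vs log bin
  center — the estimator implied by the plotted, binned form, and the
  default for comparison with published exponents) and `truncated_mle`
  (bounded 1D likelihood maximization; SE from observed information via a
  central second difference, step 10⁻⁴; `xmax=None` reduces to the
  closed-form Hill estimator). MLE on unbounded support is improper for
  γ ≥ −1, which is why the truncated form is the principled option here.
* `survival_vs_droplet_size` defaults to the per-droplet mean (each
  droplet one observation, SEM over droplets); the area-pooled ratio per
  bin is available with `pooled=True`. Droplets without cells are
  excluded.
* `fit_contribution` regresses per-object survival on standardized log₁₀
  droplet area and log₁₀ aggregate area by a binomial GLM with the
  object's total cell area as frequency weight (area-weighted "events";
  with only two outcome classes a binary logistic model is the full
  model). Perfect separation is flagged and refit with a small L2 penalty
  (no standard errors in that case).
* `population_above_size` uses 100 log-spaced thresholds from 10^1.5 µm²
  to the largest droplet by default.

## Concentration (`microwet.concentration`)

Calibration curves are monotone piecewise-linear interpolants through
(concentration, intensity) knots, typically placed by the dilution series
1.11–20× of a concentrated stock; non-monotone intensities are rejected at
construction. Droplet mean intensity excludes a ~1 µm rim and bead pixels;
the rim is removed by thresholding the Euclidean distance transform at
`width/px + 0.5` pixels — the half pixel bridges pixel centers and the
mask edge, so a droplet whose every pixel is within the rim width of the
boundary is correctly reported as too small to measure (discrete
structuring-element erosion would leave its center pixel). Intensities
outside the knot range are linearly extrapolated from the terminal segment
and flagged `extrapolated` (dye self-quenching at high concentration is
not modeled — estimates far above the densest standard should be treated
as lower-quality). An `osmolarity` helper scales a *user-supplied* base
osmolarity by the estimated factor; no default base is shipped because it
depends on the medium recipe.

## Pipeline and formats (`microwet.io`, `microwet.cli`)

One 16-bit grayscale TIFF per channel (`<field>_{bf,green,red,blue}.tif`),
CSV tables whose columns mirror the published source-data schemas
(`droplet_area_um2`, `live_area_um2`, `dead_area_um2`, `repeat` as the
field-of-view id — so published raw tables load directly via
`read_source_droplets`, which also accepts the descriptive column names),
YAML configs, and a JSON run log with config hash and seed. Reruns with
the same config are byte-identical. Logging goes to stderr; stdout is
reserved for results.

## Problem sizes in tests

The bundled test-suite and acceptance benchmarks use 2048²-pixel fields
(20 fields for the image-pipeline benchmark), 10,000-sample exponent
recovery with 20 replicates, and 5,000-object regression recovery — sizes
chosen so each distributional check has comfortable statistical power
while a full run stays in the minutes range on one core.

## Known limitations

* 2D projection only; no volumetric correction, no z-stacks, no
  deconvolution, no time-lapse tracking.
* Circular droplets in the generator; area ground truth is exact but
  irregular-outline robustness is untested.
* The droplet-size ↔ cell-content coupling form (linear with log-normal
  noise) is a modeling choice; only its monotonicity is
  empirically grounded.
* `fit_contribution` treats objects as independent; within-field
  correlation is not modeled.
* Calibration assumes linear dye response between knots.
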