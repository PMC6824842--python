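# microwet

Quantitative image analysis of **microscopic surface wetness** on drying
surfaces colonized by bacteria.

When a solute-containing medium dries under moderate relative humidity,
complete evaporation is prevented by the deliquescent solutes, and stable
micrometer-scale droplets remain pinned around bacterial cells and
aggregates. Cell survival in this landscape depends strongly on the size of
the droplet a cell ends up in. `microwet` implements the full measurement
pipeline for this phenomenon, for microscopists and microbial ecologists
working with multi-channel micrographs of such surfaces:

1. **Segmentation** — droplets from a dedicated fluorescence channel
   (droplet centers are brighter than the periphery; the intensity gradient
   peaks at the rim), by combining an intensity mask and a
   gradient-magnitude mask after Gaussian smoothing; live and dead cells
   from the green (constitutive YFP) and red (propidium iodide) channels by
   histogram-based thresholds.
2. **Quantification** — per-droplet and per-cellular-object records:
   projected areas in µm², live/dead cell-covered areas, and assignment of
   each object to its *host droplet* by maximal pixel overlap.
3. **Statistics** — droplet-size distributions and power-law exponent fits,
   binned survival curves, 2D survival grids over (aggregate size, droplet
   size), an area-weighted logistic regression separating the two effects,
   and population-fraction-above-size curves.
4. **Concentration estimation** — droplet solute concentration from a
   reporter dye via monotone piecewise-linear calibration curves, with the
   droplet rim and bead pixels excluded from the intensity average.
5. **Synthetic scenes** — a generator that renders four-channel 16-bit
   fields with known ground truth, so every stage is testable without
   original micrographs.

## The statistical model

Droplet areas `A` follow a truncated power law, `p(A) ∝ A^γ` with `γ < 0`
on `[A_min, A_max]`; the exponent is estimated either by least squares on
log-binned densities (`logbin_ls`) or by maximum likelihood for the
truncated continuous power law (`truncated_mle`; with no upper bound this
is the Hill estimator `γ̂ = −(1 + n / Σ ln(Aᵢ/A_min))`).

Cell survival is summarized as live area / (live + dead) area — projected
area is the standard proxy for cell number in this single-layer setting —
and modeled in the generator as a logistic function of log₁₀ droplet area,

```
s(A) = s_min + (s_max − s_min) · σ( k · (log₁₀ A − m) )
```

rising from `s_min` in the smallest droplets to `s_max` in the largest.

## Worked example

Run the full synthetic pipeline (5 fields of 332.8 × 332.8 µm at
0.1625 µm/px, seeded):

```bash
microwet run-all --seed 1 --out demo_out
```

On this configuration the run produces `droplets.csv` with 125 droplets
pooled over the 5 fields, and:

* `power_law_logbin_ls.csv`: `gamma = -1.25 ± 0.04` — the log-binned
  least-squares exponent of the droplet-area distribution, consistent with
  the generator's `γ = −1.2`;
* `power_law_truncated_mle.csv`: `gamma = -1.23 ± 0.05` — the truncated
  maximum-likelihood estimate of the same exponent;
* `survival_vs_droplet_size.csv`: mean survival per half-decade of droplet
  area rising from ≈ 0.03–0.08 below 10² µm² to 0.58 at ~1.8×10³ µm² and
  0.73 at ~5.6×10³ µm² — survival increases with droplet size;
* `overall_survival.json`: `0.60` — the pooled live fraction, dominated by
  the many cells that reside in large, protective droplets.

Every stage is also available as a library function
(`microwet.sample_scene`, `microwet.segment_droplets`,
`microwet.fit_power_law`, …) and as individual CLI subcommands
(`simulate`, `segment`, `quantify`, `stats`, `calibrate`).

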