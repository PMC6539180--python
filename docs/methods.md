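# Methods

`peafield` re-implements, as a tested library, the image-analysis chain used
to phenotype pea breeding trials from drone (UAS) imagery: radiometric
correction of a five-band mosaic, vegetation-index grids, crop-surface-model
canopy metrics, georeferencing quality metrics, a multi-temporal lodging
score, a leaf-type classifier, and linear (Lasso-selected) biomass models.
Because the original field imagery and trait measurements are not available,
the package ships a synthetic trial generator with known ground truth, and
all quantitative claims in the test suite are about recovery of that truth.

## The analysis model

**Radiometric correction.** A white reference panel of nominal reflectance
0.99 across the visible/red-edge/NIR range is imaged in every scene. Each
band is rescaled by a single global gain `0.99 / mean(panel pixels)`. No
vignetting or spatially varying model is attempted — the workflow this
follows used one panel per flight, which identifies only a global gain.

**Vegetation indices.** Per pixel,

```
GRVI = (G − R)/(G + R)    NDVI = (NIR − R)/(NIR + R)    NDRE = (NIR − RE)/(NIR + RE)
NIRv = NIR · NDVI − 0.08
```

Pixels with a zero normalized-difference denominator become nodata rather
than ±inf, so plot sums stay finite. `NIRv` is also available in the
alternative form `(NDVI − 0.08) · NIR` (`variant="badgley"`, the form in the
index's original publication); the default follows the workflow being
reproduced, whose text describes subtracting 0.08 from the NIR × NDVI
product. Which form fed the original tables cannot be resolved from the
text, so both are first-class.

**Canopy surfaces.** The digital terrain model (DTM) is interpolated from
bare-soil elevations — piecewise-linear over a Delaunay triangulation of
the soil samples, nearest-value extrapolation outside their hull; at soil
sample pixels the DTM equals the DSM exactly. The crop surface model is the
per-pixel difference `CSM = DSM − DTM` (height above ground). Canopy is
segmented at a strict threshold `CSM > 0.15 m`; the threshold is an
empirical constant of the workflow, kept as a configuration default rather
than a fitted quantity, and the comparison is strict so the boundary case
is deterministic. Per plot:

```
CH = mean CSM over in-plot canopy pixels (0 if none)
CC = n_canopy_pixels × pixel_area
PV = CH × CC
```

The plot height statistic is not specified by the source workflow (mean vs
max vs percentile); the mean is used because `PV = CH × CC` then
approximates the integral of height over covered area. Upper percentiles
are available via `height_statistic="p95"` etc.

**Zonal statistics.** A pixel belongs to a plot polygon iff its center lies
strictly inside the polygon (half-open pixel cells). With alleys between
plots this is deterministic and never double-assigns a pixel. VI statistics
are computed over canopy (soil-masked) pixels by default; the unmasked mode
reproduces the soil contamination of early-season plot means and is exposed
because it cannot be established which mode produced the original report's
tables.

**Georeferencing QC.** Horizontal position error is the RMS horizontal
offset of observed GCP coordinates from surveyed truth,
`HPE = sqrt(Σ(EE² + NE²)/n)`. Vertical position error compares transect
roughness between a rectified and non-rectified surface: `ΔZ` of a series
is the sum of absolute adjacent differences and
`VPE = (ΔZ_R − ΔZ_NR)/n_segments` (default 4 segments). The signed form can
be negative; the absolute value is reported alongside because the
convention of the original tables is unstated.

**Lodging.** Between timepoints t1 < tk,
`score = (CH₁ − CH_k) × (CC₁ − CC_k)` (or the CH difference alone). A
lodged plot loses height and spreads its canopy, giving the product the
opposite sign from an erect plot. The sign convention is kept as defined
and correlations against the field lodging ratio (canopy height / plant
length, 1.0 = erect) are reported signed.

**Leaf type.** Semi-leafless (*af*) and normal (*Af*) pea types are
separated by a one-dimensional threshold on plot-mean green reflectance:
exhaustive search over midpoints of adjacent sorted training values,
minimizing training misclassification, ties broken toward the lower
threshold. This makes training accuracy invariant under any strictly
monotone transform of the green values.

**Biomass models.** `AGBM_est = (Σ coefᵢ xᵢ + intercept)/divisor` on
features standardized to zero mean and unit SD. Two frozen presets ship:
the winter model (GRVI-sum 1.56, NDVI-sum −0.83, NDRE-sum 0.75, CC −0.01,
intercept 8.85, divisor 1.5·10⁴; kg fresh weight) and the spring model
(GRVI-sum 7.80, NDVI-sum 2.46, NDVI-mean 4.98, NDRE-sum 4.98, PV 10.73,
intercept 87.83, divisor 1.0·10³; g dry weight). The divisors are carried
verbatim as unit constants. Because the original training means/SDs are
unpublished, preset predictions standardize by the *current* dataset, which
preserves the ranking structure but not absolute scale — documented, not
hidden. Fresh fits use the Lasso: a seeded 85% training split, penalty
chosen by 5-fold cross-validation over scikit-learn's logarithmic penalty
path with the **one-standard-error rule** (largest penalty within one SE of
the minimum CV error). The 1-SE rule is the conservative convention; the
plain CV minimum was observed to leave coefficients up to ~0.1 on
pure-noise responses, which defeats the selection purpose of the penalty.
Validation (Pearson r, MAE) is computed on the complete matched dataset,
matching the protocol being reproduced.

## The synthetic trial generator

The generator produces the conditions the analysis assumes, not
photorealistic imagery.

* **Layout.** Randomized complete block design: replicates are blocks
  stacked northward, entries randomized east-west within each block.
  Defaults: 20 entries × 3 replicates, 1.5 m × 5.0 m plots, 0.6 m alleys.
* **Growth.** Canopy height follows a beta-shaped kernel over accumulated
  degree days (0 °C base), normalized to peak at flowering (default
  1268 ADD, season end 2200 ADD, peak height 0.6 m for a vigor-1 entry).
  Cover follows the same kernel raised to 0.6 so it saturates earlier.
  Entry vigor is N(1, 0.15), with N(0, 0.05) plot-level noise — the only
  source of genetic + field variation. Winter imaging timepoints are
  365/784/1268/1725/1948 ADD; spring 1231/1424/1648 ADD.
* **Spectra.** Bare soil reflects {B 0.10, G 0.14, R 0.16, RE 0.22,
  NIR 0.25} (GRVI < 0); healthy canopy {0.04, 0.12, 0.06, 0.30, 0.50}
  (GRVI, NDVI, NDRE > 0). Canopy spectra relax toward soil as the growth
  curve falls (floor 0.4), so indices rise and fall with phenology.
  *Af* entries reflect +0.02 more green than *af* (jitter SD 0.005).
* **Biomass.** True AGBM is linear in standardized latent features
  (GRVI/NDVI/NDRE sums and covered area at the peak) with weights
  (0.5, 0.3, 0.15, 0.05), base 6 kg, scale 1.5 kg, Gaussian noise 0.1 kg.
* **Lodging.** A seeded, exactly-rounded fraction of plots lodges after the
  peak: lodging ratio U(0.50, 0.80) (erect plots U(0.90, 1.00)), height
  collapses to `max(ratio × erect, min(0.20 m, 0.95 × erect))`, cover
  spreads by factor `1 + 0.6(1 − ratio)`. The 0.20 m floor models the mat
  of piled vines a lodged canopy forms: however severe the lodging, the
  crop does not flatten to the ground, and in particular remains within
  the sensitivity of the 0.15 m canopy segmentation — the regime in which
  the multi-temporal score is informative at all. Severities below that
  regime make the score non-monotone (coverage vanishes instead of
  spreading), which is a genuine limitation of the method, not of the
  implementation.
* **Rendering.** Scenes default to 0.05 m GSD (the package's problem-size
  choice; at the source workflow's 0.005 m a scene is 100× larger with no
  additional structure to test). Within a plot each pixel is canopy with
  probability `cover_fraction` (per-pixel Bernoulli, seeded), making CC an
  unbiased cover estimator. Canopy pixels sit at `terrain + height` with a
  single height per plot and timepoint; terrain is a plane with a 1%
  east-west grade; the panel renders at 0.99 in all bands; additive
  Gaussian band noise defaults to 0.01 reflectance units. All randomness
  flows from one seed through named sub-streams, so runs are
  bit-reproducible and adding an operation never perturbs another's draws.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photogrammetric reconstruction error and mosaic
seams, BRDF/illumination variation, within-plot height texture, weeds,
row structure, spatially correlated soil, and measurement error in the
ground-truth traits beyond simple Gaussian noise. Recovery results here are
upper bounds on field performance.

## Numerical choices

* Nodata is a mask, never a sentinel in arithmetic; division-by-zero
  pixels are masked.
* Rasters are stored as ESRI ASCII grids at `%.17g`, which round-trips
  doubles exactly; tables as headered CSV at the same precision (parsed
  with the correctly-rounded `strtod`).
* Zero-variance guards for correlations use the value range (`ptp == 0`)
  rather than a computed SD, which can be a nonzero ~1e-16 for constant
  input.
* DTM soil samples are capped at 4000 by fixed-stride subsampling
  (deterministic); a denser cloud adds nothing to a low-order terrain
  surface.
* Nearest-neighbour degradation maps each coarse pixel center to the
  nearest source center; the output value set is a subset of the input's,
  and upsampling is refused.

## Known limitations

* Preset biomass models cannot reproduce the absolute estimates of the
  original workflow without its (unpublished) standardization parameters.
* The canopy-height statistic, VI masking mode, and NIRv form are
  configurable because the source description underdetermines them; results
  across those options differ most early in the season.
* `validate_heights` on noiseless synthetic scenes returns r ≈ 1 by
  construction; it is a wiring check there, not evidence about field DSMs.
* No CRS handling: coordinates are abstract projected meters, and
  shapefile input is not supported (GeoJSON only).
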