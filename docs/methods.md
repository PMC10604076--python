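# Methods

## The measurement model

Each well holds ~150 amphiphilic particles. A particle is modeled as three
concentric regions with radii `r_droplet < r_peg < r_outer` (defaults 90, 120,
150 µm): a fluorescent aqueous droplet of radiance `L`, a PEG hydrogel ring at
`peg_enrichment · L` (default 2, reflecting dye accumulation in the hydrogel),
and a non-fluorescent outer shell. Radiance is expressed in sensor digital
numbers per millisecond (DN/ms), so an exposure of `t` ms records
`clip(round(L·t + ε), 0, 2¹⁰−1)` with additive Gaussian read noise ε
(σ = 2 DN per frame by default; an optional Poisson term was deliberately
omitted — the Gaussian term is sufficient to exercise the HDR weighting).

Per-particle radiance is log-normal about a linear-with-plateau dose response
`mean(c) = min(intercept + slope·c, saturation)` with coefficient of variation
`particle_cv` (default 0.25). The log-normal choice reflects that intensities
are positive and right-skewed; the measured distribution family of real
particles is not established, so this is a modeling decision of the generator,
not a claim about the assay.

Default optics place 5.6 µm per pixel (~0.2× magnification onto a small-pitch
sensor), so a 300 µm particle spans ~54 px. The full sensor frame is
3280 × 2464; the package's standard desk-scale study condition,
`compact_well_config()`, keeps the identical particle scale, count (150) and
exposure bracket on a 1640 × 1232 half-field so that multi-well validation
runs complete in minutes on one CPU. Nothing else is changed between the two
configurations.

The generator emulates: exposure-dependent saturation (the brightest particles
clip at 2000 ms), modality contrast (dark particle rims on a bright field in
bright-field; bright PEG-ring scattering on a dark field in dark-field),
rigid inter-modality offsets, and a second-order radial aberration. It does
not model PSF blur, vignetting, speckle, droplet-to-droplet chemical
crosstalk, or particles resting on their side; conclusions from synthetic
tests therefore concern the computational chain, not the physics of a real
reader.

## HDR synthesis

Frames are registered to the first frame by phase correlation and fused as

    E(p) = Σᵢ w(zᵢ(p)) · zᵢ(p)/tᵢ  /  Σᵢ w(zᵢ(p))

with `w` a Gaussian centered at half the saturation value, σ a quarter of it,
and `w = 0` for clipped samples (`z ≥ 2^bit_depth − 1`), which carry no
radiance information. Pixels clipped in every frame fall back to the shortest
exposure's estimate and are flagged in `valid_mask`; quantification excludes
them. On a noiseless bracket the reconstruction is exact up to 10-bit
quantization of the shortest usable exposure — well under 1% for mid-range
signals.

## Registration and aberration

`phase_correlate` wraps upsampled phase cross-correlation (upsampling factor
20, ~0.05 px resolution); pure integer shifts on noiseless input are recovered
exactly. Chromatic aberration is modeled radially as
`r → r(1 + a₁r + a₂r²)` about the image center; correction samples the
distorted image at the forward-mapped radius (an inverse warp), and the
synthetic generator renders distortion with a numerically interpolated inverse
of the same map, so warp/correct round trips are exact to interpolation error
(< 0.1 px in practice).

Bright/dark-field to HDR registration correlates *Gaussian-smoothed gradient
magnitudes* (σ ≈ 0.6 · r_outer). The modalities place their sharp edges at
different concentric radii of the same particles (shell rim versus PEG ring),
so correlating raw images or raw gradients peaks on a circle of offsets with
radius equal to the ring-radius difference; smoothing to blob scale collapses
each particle to a single centered blob and restores a unique peak at the true
offset. Out-of-frame pixels after shifting are filled by edge replication and
excluded by the detection border margin.

## Detection

Per modality: min-max normalization, CLAHE (clip limit 0.01, tile ~1/8 image),
bilateral smoothing (σ_spatial 2 px, σ_range 0.1), Canny (σ 2 px, hysteresis
0.10/0.25 of the normalized range), dilation by a 3 px disc, hole filling,
then erosion by the same disc so region boundaries return to the pre-dilation
edge and ROI areas are not inflated. Candidate filters: area within
[0.25, 2.25]× the expected outer-disc area (wide enough for both the PEG-disc
footprint seen in fluorescence and the shell footprint seen in bright-field),
eccentricity ≤ 0.85, convexity (area / convex-hull area) ≥ 0.85, bounding box
clear of a 10 px border margin, and mutual exclusion of candidate pairs whose
equivalent discs overlap by more than 20% of the smaller disc (both members
removed — overlapping particles cannot be quantified reliably). The Canny
thresholds are empirical constants of the detection configuration, recorded
there.

Fusion is pixelwise OR of the three binary masks, relabeled, with the same
convexity constraint applied to the fused components: slightly offset
detections of one particle merge into a convex blob and survive; dumbbells
bridging two particles fail convexity and are removed. Each fused region
records which modalities' masks intersect it. Detection quality is scored
against ground truth by greedy one-to-one centroid matching within the
particle's outer radius.

## Quantification

The intensity statistic is the **mean** radiance over the ROI (not the sum),
so values are comparable across particle sizes. The droplet/PEG split uses a
concentric-disc model: the droplet ROI is the disc of radius
`droplet_fraction × equivalent_radius` (default 0.75, the nominal
droplet/PEG radius ratio) about the region centroid; the PEG ROI is the
remainder; combined is their union, and therefore always lies between the
droplet and PEG means (area-weighted average). A second segmentation of the
inner boundary was deliberately avoided — the concentric model is directly
testable against the generator's geometry.

## Swarm statistics

* Threshold: `μ₀ + k·σ₀` with sample SD (n−1); k = 3 by default.
* Exceedance is strict (`x > threshold`); ties have measure zero for
  continuous intensities.
* Classification: positive iff ≥ 1 particle above threshold by default; a
  fraction cutoff is available for sensitivity analyses.
* `sem_curve`: `s/√n` with the full-population sample SD, plus the relative
  form `s/(mean·√n)`. Going from 3 to 80 particles divides the SEM by
  `√(80/3) ≈ 5.16`.
* t tests are one-tailed Welch (unequal variance); two degenerate equal
  samples return p = 0.5 by the t = 0 convention.
* Monte Carlo subsampling draws without replacement ("subsets"), matched
  negative draws for the per-repeat t test, defaults 1–50 particles ×
  5000 repeats; with-replacement sampling is available behind a flag. One
  config seed spawns a per-subset-size substream, so results are reproducible
  and independent of the order of subset sizes. At subset sizes below 2 the
  t-test metric is undefined and reported as NaN. For small populations the
  false-negative rate of the default rule equals the hypergeometric
  probability that a subset contains zero above-threshold particles; the test
  suite verifies this against brute-force enumeration of all subsets at
  N = 12.
* `compare_methods` fits the threshold per repeat from that repeat's own
  negative control, computes fraction-above and mean intensity per repeat, and
  Welch-tests each statistic across repeats. A background shift shared within
  a repeat cancels in the fraction statistic (both the threshold and the
  intensities shift together) but inflates the across-repeat variance of the
  raw mean — which is why the fraction method discriminates better under
  drift.
* LOD is operational: the lowest tested non-zero dose whose mean intensity
  exceeds the negative-control threshold; a flat response reports
  not-detected (None).

## Numerical and interface choices

* Coordinates are 0-based (row, col); all CSVs state this in a header comment.
* Raw Bayer decoding extracts the red-site subimage (half resolution per
  axis) at native 10-bit depth; default pattern RGGB, overridable, since the
  sensor orientation is configuration, not a constant.
* The pipeline is deterministic: all randomness flows from the config seed,
  and re-running an identical config reproduces byte-identical CSVs.
* Placement uses rejection sampling with a bounded attempt budget
  (2000 × n); an over-packed configuration raises rather than silently
  returning fewer particles, and the truth object carries a shortfall field
  for deliberately degraded configurations.
* Degenerate inputs are defined, not accidental: constant images are
  unregisterable (error) and yield zero detections; empty ROIs after
  valid-mask exclusion raise; a zero-spread population gets a sharp-Gaussian
  density rather than a singular KDE.

## Validation problem sizes

The acceptance script and end-to-end tests use the half-field well
(1640 × 1232, 150 particles) for detection studies — five wells per run —
and the 520 × 640 twelve-particle well for pipeline round-trip checks; the
statistical layer is validated on drawn populations of 80 (per-sample
particle count) up to 10⁵ (tail calibration). These are the package's
standard study conditions and are fixed in the test fixtures and script.

## Known limitations

* The aberration model is radial-only and shared per modality; tangential or
  field-dependent distortion is out of scope.
* Merged particles are excluded, not split (no watershed); heavily packed
  wells will lose recall rather than gain false positives.
* The droplet/PEG split assumes concentric circular geometry; real particles
  imaged side-on violate it and are expected to be removed by the
  eccentricity/convexity filters instead.
* Absolute radiometric calibration (DN/ms to enzyme counts) is out of scope;
  all intensities are relative.
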