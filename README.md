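# dropswarm

Readout software for droplet-particle "swarm sensing" immunoassays read on a
low-cost multimodal imager.

In these assays a sample is partitioned across ~150 amphiphilic microparticles
(~300 µm diameter), each stabilizing a nanoliter aqueous droplet inside a PEG
hydrogel ring.  A fluorogenic enzyme reaction reports the analyte (e.g. the
heart-failure biomarker NT-proBNP), and every particle-droplet is an
independent measurement of the same sample.  A portable reader images each
well three ways: an exposure-bracketed fluorescence stack (100/500/1000/2000 ms,
10-bit raw red channel), a bright-field image and a dark-field image.

`dropswarm` implements the complete computation from raw frames to a
positive/negative call:

1. **HDR synthesis** — the bracketed low-dynamic-range frames are registered by
   phase correlation and fused into a relative radiance map
   `E = Σᵢ w(zᵢ)·zᵢ/tᵢ / Σᵢ w(zᵢ)` with a mid-weighted Gaussian `w` that
   zeroes clipped samples.
2. **Cross-modality registration** — bright/dark-field images are corrected for
   second-order radial chromatic aberration `r → r(1 + a₁r + a₂r²)` and
   rigidly registered to the HDR frame.
3. **Detection and fusion** — per modality: CLAHE + bilateral smoothing, Canny
   edges, dilation and hole filling, then area / eccentricity / convexity /
   border / overlap filtering; the three binary masks are fused by pixelwise OR
   under a convexity constraint (area / convex-hull area ≥ 0.85).
4. **Quantification** — the fused mask is superimposed on the HDR image and
   each particle's mean radiance is measured over the droplet, PEG, or combined
   ROI.
5. **Swarm statistics** — decision threshold `μ₀ + 3σ₀` from the
   negative-control population, fraction of particles above threshold,
   SEM-vs-n curves (`s/√n`), one-tailed Welch t tests, Monte Carlo subsampling
   of particle counts (1–50 particles, 5000 repeats, without replacement) with
   exact hypergeometric behavior, and dose-response / LOD summaries.

Because a single well yields tens of measurements, the *fraction above
threshold* statistic is robust to background drift that defeats raw mean
intensities — the package includes the comparison machinery to demonstrate
exactly that.

A first-class synthetic well generator (`dropswarm.synthetic_scene`) renders
ground-truthed multimodal wells — concentric droplet/PEG/shell geometry,
log-normal particle-to-particle dispersion, exposure-dependent saturation,
modality-specific contrast, inter-modality shifts and aberration — so the
entire chain is testable without any external data.

## Worked example

```python
import dropswarm as dw
from dropswarm.cli_io import RunConfig, run_pipeline
from dropswarm import swarm_stats as ss

neg = run_pipeline(RunConfig(out_dir="neg",
    scene=dw.compact_well_config(seed=0, concentration=0.0)))
pos = run_pipeline(RunConfig(out_dir="pos",
    scene=dw.compact_well_config(seed=1, concentration=0.1)))

neg_x = neg.intensities.query("roi_mode == 'combined'").mean_intensity.to_numpy()
pos_x = pos.intensities.query("roi_mode == 'combined'").mean_intensity.to_numpy()

model = ss.compute_threshold(neg_x, k=3)
print(f"negative well: {len(neg_x)} particles, mu0={model.mu0:.4f}, "
      f"sigma0={model.sigma0:.4f}, threshold={model.threshold:.4f}")
summary = ss.summarize(pos_x, model, condition=0.1)
print(f"0.1 ng/mL well: {summary.n_particles} particles, "
      f"mean={summary.mean_intensity:.4f}, "
      f"fraction above={summary.fraction_above:.3f} -> {summary.classification}")
```

prints

```
negative well: 150 particles, mu0=0.0518, sigma0=0.0113, threshold=0.0857
0.1 ng/mL well: 150 particles, mean=0.1021, fraction above=0.680 -> positive
```

All 150 seeded particles were detected and quantified in both wells
(fused recall and precision 1.0 against the generator's ground truth).  The
negative control sets the decision boundary at its mean plus three standard
deviations (radiance in DN/ms); at the 0.1 ng/mL clinical cutoff, 68% of
particles exceed it and the sample is called positive under the default
"≥ 1 particle above threshold" rule.

## Command line

```sh
dropswarm simulate --out well --seed 1            # ground-truthed fixture
dropswarm process --input-dir well --out run      # full image pipeline
dropswarm stats run/intensities.csv --negative-csv neg/intensities.csv
dropswarm montecarlo run/intensities.csv --negative-csv neg/intensities.csv
```

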