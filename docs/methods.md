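# Methods

This document records the simulation model, the analysis pipeline, the
numerical choices that required judgment, and the problem sizes the package
is designed for.

## 1. Synthetic movie model (`simgen`)

The generator produces the simplest movies that still exercise every
pipeline stage with known ground truth. It is phenomenological: it renders
what the microscope sees, not the underlying monomer diffusion or Arp2/3
kinetics.

**Geometry.** The cell occupies rows `y >= h(x, t)` of the image, where the
leading-edge height is a sum of traveling sinusoids:

```
h(x, t) = h0 + Σk Ak · sin(2π(x/λk − t/Tk) + φk)
```

Two waves (amplitudes 3 and 2 px, periods 23 and 41 s, wavelengths 48 and
29 px) give an edge that protrudes and retracts without ever being
stationary or periodic over a 100-frame movie.

**Intensity.** Inside the cell, both channels carry a diffuse monomer
background plus a lamellipodial network band that decays exponentially with
depth `d` from the edge (sub-pixel depth, so the edge is smooth at the
pixel level):

```
reference(d) = 100 + 200 · exp(−d / δ)          δ = 1 µm
probe(d)     = 100 + ρ · 200 · exp(−d / δ)
```

`ρ ∈ [0, 1]` is the ground-truth incorporation fraction — the single number
the whole pipeline exists to recover. Outside the cell the image is dark.
Each channel is multiplied by `exp(−k·t)` (default k = 0.002 /s) to model
photobleaching, then Poisson shot noise (1 count per intensity unit) and
Gaussian read noise (σ = 2) are applied.

**Defaults** (chosen to mimic the imaging regime of lamellipodia work:
0.1 µm pixels, 1 s frame interval, ~100 s movies):

| parameter | default | rationale |
|-----------|---------|-----------|
| image | 96 × 224 px | one cell edge plus ≥10 µm of cytoplasm below it |
| pixel size | 0.1 µm | typical 100× TIRF sampling |
| frame interval | 1 s | resolves 0.1 µm/s flow at 1 px/frame |
| frames | 100 | enough rows×frames pairs (~6000) for stable regression |
| network amplitude / background | 200 / 100 | 3:1 edge contrast, realistic for lamellipodia |
| decay depth δ | 1 µm | lamellipodium width scale |
| bleach rate | 0.002 /s | ~18 % loss over 100 s, strong enough to need correction |
| shot + read noise | Poisson + σ=2 | SNR ≈ 15 at the edge |

**Limits.** The generator does not model: filopodia, non-exponential
network profiles, spatially varying ρ, camera fixed-pattern noise, focus
drift, or flow within the cell-edge movie itself (flow appears only in the
dedicated speckle kymograph generator). Accuracy claims in the tests are
therefore claims about the pipeline's numerics, not about robustness to
every imaging pathology.

**Other generators.** `simulate_flow_kymograph` renders Gaussian speckle
streaks (σ = 1 px) drifting at `flow_speed` with speckles seeded upstream
of the field so density is stationary; `simulate_frap_series` draws
`F(t) = F0 + (F∞ − F0)(1 − exp(−t/τ))` with a set mobile fraction;
`simulate_shapes` rasterizes disks, squares, and stars for morphometrics.

## 2. Preprocessing (`stackio`)

Fixed order, as a chain on calibrated stacks:

1. **Background subtraction** — median of the out-of-cell region, floored
   at 0.
2. **Bleach correction** — per-channel log-linear fit of the in-cell frame
   sums over time; division by `exp(−k̂·t)`. Restores frame-sum
   stationarity to < 0.1 % on synthetic truth.
3. **Per-frame total-fluorescence normalization** — equalizes in-cell sums
   across frames (residual fluctuation the bleach fit missed).
4. **Channel mean matching** — scales the probe channel so both channels
   share the same in-cell mean.

The chain is idempotent to ~0.05 intensity units (re-estimating a
background median on an already-floored image is the only non-exact step).

A consequence of mean matching worth stating explicitly: the per-cell
regression slope is **not** ρ. A flat probe channel (ρ = 0) mean-matched to
a structured reference still regresses with slope `b ≈ 1/(1 + CV²)` where
CV is the reference's coefficient of variation inside the band — empirically
b ≈ 0.5–0.75 depending on geometry, never ≈ 0. This is exactly why the
normalization `r = (s − b)/(a − b)` against measured baseline (eGFP) and
standard (actin self-correlation) cohorts exists, and it cancels the effect:
cohort-level r recovers ρ within ±0.024 across ρ ∈ {0, 0.25, 0.5, 0.75, 1}
at default noise.

## 3. Edge tracking and adaptive kymographs (`edgetrack`)

**Segmentation.** Gaussian blur (σ = 1 px), Otsu threshold, largest
connected component, fill holes.

**Sub-pixel edge.** Marching-squares iso-contour on the blurred image. Two
non-obvious choices:

- *Half-maximum level refinement.* The Otsu level sits well below the
  midpoint of the edge intensity step, which biases the iso-contour
  outward by ~1.2 px. The level is refined once to the median midpoint of
  the blurred intensity sampled ±3 px along the local normals; under
  symmetric blurring the midpoint crossing coincides with the true step.
  Edge RMS error vs ground truth: 0.25 px (noise-free), 0.28 px (default
  noise).
- *Proximity-based contour pick at the refined level.* The refined level
  also crosses the exponential in-cell decay a second time deeper in the
  cell, and that spurious iso-contour can be longer than the edge. When
  re-tracing, the contour **closest to the provisional Otsu contour** is
  selected, not the longest one.

The contour is clipped to the ROI, resampled to equal arc length, and
oriented consistently across frames by nearest-neighbour endpoint matching.

**Adaptive kymograph.** For every frame, intensity is averaged along the
inward normal at each of S edge points over a band of depth 1 µm, giving an
S × T matrix that follows the moving edge. Sampling starts 1.5 px inside
the contour (`band_inset_px`): bilinear samples taken exactly on the
contour straddle the cell/background step, which breaks the affine
channel-identity property. With the inset, a noise-free ρ = 1 movie gives
probe and reference kymographs identical to ~1e−15 relative error, and the
kymograph mean matches a direct distance-transform band mean within 1 %.
Both channels use the identical sampling geometry, so geometric errors
cancel in the regression.

## 4. Correlation analysis (`corranalysis`)

Per kymograph row, the probe trace is aligned to the reference trace by
maximizing normalized cross-correlation over lags within ±10 frames
(positive lag = probe trails reference; ties resolved toward the smallest
|lag|, negative before positive). Aligned pairs from all rows are pooled
and fit by least squares **through the origin**, `slope = Σxy / Σx²`; the
reported R² is the squared Pearson correlation (the uncentered through-
origin R² is also stored). Group-level analysis averages per-cell slopes
into `s`, `b`, `a`, computes `r = (s − b)/(a − b)` clamped to [0, 1], the
integer-percent report, and `f_surf = (r_total − r_soln)/r_total` when a
solution-pathway cohort is supplied.

## 5. FRAP (`frap`)

Bounded nonlinear least squares of `F(t) = F0 + (F∞ − F0)(1 − exp(−t/τ))`
on the post-bleach samples; mobile fraction
`M = (F∞ − F0)/(F_pre − F0)` clamped to [0, 1]. Initialization: F0 from the
first post-bleach point, F∞ from the last 10 % of samples, τ from the
half-recovery time. Mean bias < 0.001 at 1 % noise; the acceptance bound is
|bias| ≤ 0.02 over M ∈ {0.1…0.9}, 100 curves each.

## 6. Retrograde flow (`profiles_flow`)

`flow_rate_auto` scans candidate velocities (201-point grid from 0 to
0.5 µm/s) with a Radon-style directional projection: every kymograph pixel
is assigned, with linear splitting, to the line of slope v through it
(indexed by time-zero intercept `c = s − v·t`); lines observed for at least
half the movie enter a count-weighted variance of line means. The variance
peaks when v matches the streak slope; the peak is refined parabolically.
Design note: a naive shear-and-average implementation either inflates the
variance at large v through under-sampled rows or, if rows are filtered,
discards speckles that enter the field mid-movie — the intercept binning
uses all pixels at every v. Confidence is the peak-to-median variance
ratio; measured separation on 20 + 20 kymographs is 1.8–2.8 for pure noise
vs 4.6–54 for default-noise streaks, and the low-confidence threshold 3.5
sits in that gap. Recovery at 0.10 µm/s: within 0.0006 µm/s across seeds.

Linescans sample the inward normal from 0.5 µm outside to a set depth
inside the edge at pixel steps (bilinear), normalized to the in-cell mean;
averages carry 1.96·SEM bands.

## 7. Morphometrics (`morphoshape`)

`circularity = 4π·area/perimeter²` and `solidity = area / convex-hull
area`. The perimeter is measured on the marching-squares contour resampled
to ~4 px chords: raw marching-squares contours staircase at ≤ 2√2 px
wavelength and inflate smooth perimeters by ~5 % (a rasterized disk would
score circularity 0.90); 4 px chords span the staircase while shortening an
80 px square's perimeter by only ~1 %. Measured: disks (r = 30–90) within
0.6 % of circularity 1, square within 1.2 % of π/4. The convex hull uses
the raw contour vertices (scipy `ConvexHull`), so a rasterized disk's
solidity is ≥ 0.99.

PCA standardizes the metric table, eigen-decomposes the covariance, and
flips signs so PC1 loads negatively on circularity (spikier cells score
higher). Verified against scikit-learn's PCA to 1e−10.

## 8. Problem sizes and runtimes

Designed for desk-scale synthetic work: movies of ~100 frames at
~100 × 200 px, cohorts of tens of movies. Measured on one CPU: simulate +
correlate one default movie ≈ 1.4 s; the 80-movie ρ-sweep acceptance test
≈ 3 min; `scripts/acceptance.py` ≈ 40 s; the full test suite ≈ 4 min.
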