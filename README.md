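# kymocorr

Quantify how actin fusion probes incorporate into the lamellipodial actin
network of migrating cells — leading-edge tracking, adaptive kymographs,
space-time correlation of a probe channel against an actin reference,
normalized incorporation rates, and the surface-delivered fraction — plus
the supporting FRAP, linescan, retrograde-flow, and morphometric analyses.
Everything is exercised end-to-end on synthetic movies with known ground
truth, so the whole pipeline is testable without any microscope data.

## The science in one paragraph

Monomeric actin can reach the growing tips of lamellipodial filaments two
ways: directly from solution, or handed over by membrane-associated
polymerases (nucleation-promoting factors) that bind profilin–actin through
proline-rich regions. An actin–profilin fusion probe that can use both
routes incorporates efficiently; a probe carrying a polymerase-binding-
deficient profilin mutant reports the solution-only route. Imaging each
probe (green) together with a reference actin marker (red), building
kymographs that follow the moving cell edge, and regressing probe intensity
against reference intensity row-by-row gives a per-cell slope `s`. The
slope is normalized between a free-eGFP baseline `b` (no incorporation) and
an actin self-correlation standard `a` (perfect incorporation):

```
r = (s − b) / (a − b)            # normalized incorporation rate, in [0, 1]
f_surf = (r_total − r_soln) / r_total   # fraction delivered at the membrane
```

With the measured rates `r_total = 0.70` (wildtype probe) and
`r_soln = 0.17` (mutant probe), `f_surf ≈ 0.757`: about three quarters of
the actin in the lamellipodium is delivered by membrane-associated
polymerases.

## Worked example

Simulate a two-channel movie whose probe channel carries a ground-truth
incorporation fraction ρ = 0.70, then run the per-cell correlation:

```python
from kymocorr import SimConfig, simulate_cell_movie, correlate_movie

movie, truth = simulate_cell_movie(SimConfig(rho=0.70, rng_seed=42))
res = correlate_movie(movie)
print(res.slope, res.n_pairs)   # 0.8620, 6131 aligned intensity pairs
```

The raw slope (0.862) is not ρ — preprocessing matches the channel means,
which compresses slopes toward 1. Normalizing against baseline and standard
cohorts recovers ρ; with the printed group slopes:

```python
from kymocorr import normalized_incorporation, surface_fraction

r, pct = normalized_incorporation(0.69, 0.10, 0.94)   # -> 0.702, "70%"
surface_fraction(0.70, 0.17)                          # -> 0.7571
```

Cohort-level recovery (10 synthetic movies per group) is what the
acceptance suite checks: at ρ = 0.70 the pipeline reports r ≈ 0.72.

### Command line

```bash
kymocorr simulate --seed 4 --out movie.tif        # movie + .truth.json
kymocorr kymo movie.tif --out kymo                # per-channel CSVs
kymocorr correlate movie.tif                      # slope / R² JSON
kymocorr normalize -s 0.69 -b 0.10 -a 0.94        # r=0.7024 (70%)
kymocorr fsurf --r-total 0.70 --r-soln 0.17       # 0.7571
kymocorr flow kymo_reference.csv --pixel-size 0.1 --interval 1.0
kymocorr frap curve.csv --post-index 5
kymocorr linescan movie.tif --out scan.csv
kymocorr morph mask1.tif mask2.tif --out morph.csv
kymocorr run --config pipeline.yaml               # full cohort pipeline
```

`run` takes a YAML config naming movie TIFFs for the `probe`, `baseline`
and `standard` groups (optionally `soln`), and writes `per_cell.csv` and
`summary.json` into `out_dir`.

## Package layout

| module | contents |
|--------|----------|
| `simgen` | synthetic movie / FRAP / flow-kymograph / shape generators with ground truth |
| `stackio` | TIFF movie I/O and the preprocessing chain (background, bleach, normalization, mean matching) |
| `edgetrack` | segmentation, sub-pixel leading-edge extraction, adaptive kymographs |
| `corranalysis` | row-lag alignment, through-origin regression, `r` and `f_surf` |
| `frap` | recovery-curve fitting, mobile fraction |
| `profiles_flow` | edge-anchored linescans, retrograde-flow estimators |
| `morphoshape` | circularity / solidity / PCA morphometrics |
| `cli` | click CLI and the end-to-end pipeline |

See `docs/methods.md` for the simulation model, numerical choices, and
their rationale.
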