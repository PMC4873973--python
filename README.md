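# macscount

Single-molecule counting of low-abundance proteins in mechanically
flattened bacteria — simulation and analysis tools.

Many regulatory proteins in *E. coli* are present in fewer than ten
copies per cell. When such cells are compressed between a coverslip and
an elastomer membrane, cytoplasmic diffusion slows from D ≈ 14 μm² s⁻¹
to below 1 μm² s⁻¹, so individual fluorescent-protein fusions stop
smearing and appear as diffraction-limited spots (~250 nm FWHM) that can
simply be counted per cell. Flattening also grows the footprint (~72%
at typical pressures) and halves the cell height, which dilutes
autofluorescence and spreads spots apart. The residual systematic error
is *spot overlap*: two molecules closer than the optical resolution
merge into one spot, which both deflates counts and — because
molecule-rich cells lose more spots — narrows the observed distribution
below Poisson (Fano factor σ_p²/⟨p⟩ < 1).

`macscount` implements the computational side of this measurement so it
can be exercised, validated and corrected without a microscope:

- **geometry** — 2-D spherocylinder cell footprints (pressed/unpressed),
  uniform molecule placement, Poisson(λ) population sampling with truth
  tables;
- **simulate** — synthetic EMCCD frames: integrated-Gaussian PSF,
  height-scaled autofluorescence, Poisson–Gamma electron multiplication
  (excess-noise factor 2), read noise, 16-bit quantization;
- **detect** — difference-of-Gaussians band-pass, thresholded strict
  local maxima, 7×7 intensity-weighted sub-pixel centroids, cell
  assignment through a segmentation mask, per-cell count tables;
- **overlap** — two independent undercounting simulations (single-linkage
  clustering at 250 nm vs full image rendering + spot finding), a
  forward model for the detected-count distribution given a true Poisson
  mean, and a maximum-likelihood inversion `infer_true_lambda`;
- **stats** — mean/variance/Fano/CV/zero-fraction summaries, Poisson
  overlay and χ² goodness of fit, cell-size conditioning, count/area
  concentration, and the first-order maturation correction
  f = k_m/(k_m + μ) with k_m = 1/τ_maturation, μ = ln2/τ_doubling;
- **frap** — polar-bleach FRAP in a 1-D rod with reflecting ends
  (cosine-series solution) and a nonlinear least-squares estimator of D.

## Worked example

`examples/overlap_correction.py` quantifies undercounting for a typical
pressed cell (3 × 0.9 μm spherocylinder, area ×1.72) and inverts it:

```
true molecules -> mean detected spots (250 nm resolution):
   2 ->  1.96
   4 ->  3.76
   6 ->  5.41
   8 ->  6.91
  10 ->  8.27
  12 ->  9.54

forward model at true mean 7.0: observed mean 6.08, detected Fano 0.75 (overlap narrows the distribution below 1)
inferred true mean: 7.03 (95% CI 6.95-7.11)
```

Reading: up to ~6–8 molecules per pressed cell the overlap loss is
modest (8 true molecules still show ~6.9 spots), the detected
distribution is visibly sub-Poisson (Fano 0.75), and the likelihood
inversion recovers the true mean of 7 to within half a percent from
5,000 cells. The other examples cover simulation + detection
(`simulate_and_count.py`), population statistics with size conditioning
(`count_statistics.py`) and FRAP fitting (`frap_diffusion.py`); each
prints a few annotated numbers and runs in seconds.

A thin CLI mirrors the library (`macscount simulate | detect |
overlap-curve | correct | analyze | frap-sim | frap-fit | run | demo`);
`macscount demo --out dir/` runs the whole pipeline on a small seeded
population.

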