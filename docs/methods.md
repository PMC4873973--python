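# Methods

This note documents the models behind `macscount`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that matter for reproducing results.

## Cell geometry and pressing

A cell footprint is a 2-D spherocylinder: a rectangle of size
(L − W) × W with two half-discs of diameter W, giving the analytic area
A = W(L − W) + π(W/2)². Pressing is modelled as a lateral affine
stretch of the footprint by `area_factor` (default 1.72, the average
footprint growth at typical valve pressures) with the pole-to-pole
length held fixed; an affine stretch multiplies the area exactly, so the
area invariant A_pressed = 1.72 · A_unpressed holds to machine
precision. The cell height drops by `height_factor` (default 0.5),
which enters only through the autofluorescence density. Molecules are
placed uniformly over the 2-D footprint by rejection sampling;
projecting to 2-D is justified because flattened cells are thinner than
the depth of focus, and we apply the same projection to unpressed cells
(defocus is out of scope). Population cell lengths follow a truncated
normal (defaults 3.0 ± 0.6 μm on [2.0, 4.5], width 0.9 μm), which keeps
footprints in the 2–6 μm² range of exponentially growing *E. coli* and
realizes "extreme sizes excluded" by construction. True copy numbers
are Poisson with mean 7.5 by default — the balanced-growth regime where
the tagged adapter protein averages 7–8 copies per cell.

## Image formation

Each molecule contributes an isotropic Gaussian of total
`photons_per_molecule` with σ = FWHM/2.3548 (FWHM default 250 nm). The
PSF is integrated per pixel with error-function differences rather than
point-sampled; at the 64 nm pixel size a point sample at the pixel
centre would overestimate the peak pixel by several percent.
Backgrounds: `autofluorescence_density` (photons μm⁻² per unit height
factor) inside each footprint — so flattening halves the per-pixel
background — plus a uniform `extracellular_background`. The EMCCD
chain is Poisson photoelectrons → Gamma(shape = n_pe, scale = em_gain)
for the multiplication register (the standard approximation; it
reproduces mean g·μ and variance 2g²μ, i.e. the excess-noise factor
of 2) → additive Gaussian read noise → ADU conversion, offset,
rounding, and clamping to 16 bits. Defaults (250 photons/molecule,
EM gain 300, 400 photons μm⁻² autofluorescence) put the peak-pixel SNR
of a spot over the in-cell background at roughly 5–10; "high-SNR"
checks use 400 photons/molecule. Spots are rendered static: the
use case is the fully immobilized regime, and motion blur of partially
mobile molecules is not modelled. Also not modelled: defocus,
photobleaching during acquisition, illumination gradients, and
channel-to-channel registration error.

## Spot detection

The detection chain follows classic particle-tracking practice. The
band-pass is a difference of Gaussians with σ_low = 1 px (pixel noise)
and σ_high = 3.3 px ≈ 2× the PSF σ (autofluorescence and other broad
features), negatives clamped so the output is a zero-background image.
Maxima must be strictly greater than all 8 neighbours and above
`peak_threshold` (default 30 filtered-ADU; at the default photon budget
a single molecule's filtered peak is above this in >99% of draws while
blank frames yield ≪ 1 false spot per cell). Peaks closer than
`min_separation` = 4 px merge, keeping the brighter — this prevents
double-counting one spot's shoulder and sets the image-side resolution
at about 4 px ≈ 256 nm, deliberately close to the 250 nm geometric
resolution. Sub-pixel positions are intensity-weighted centroids over a
7 × 7 box on the *filtered* image; the truncated-Gaussian centroid bias
is below 0.15 px. Peaks whose box would leave the frame are flagged
border-clipped and excluded from counts rather than fitted with a
shrunken box. Segmentation of the cytoplasmic-marker channel is plain
Otsu + hole filling + connected components + a 0.5 μm² minimum-area
filter; because segmentation quality is not what these tools are about,
every counting entry point also accepts ground-truth masks from the
simulator.

## Overlap model and inference

Optical resolvability is operationalized as single-linkage clustering:
molecules whose centre-to-centre distance is below the resolution
(default 250 nm) merge, transitively, into one detected spot. This is
the simplest defensible reading of "resolved at distance r"; cluster-
diameter merging would count slightly more spots at high density, and
the threshold is configurable. Undercounting curves are Monte Carlo
over uniform placements (component counting is vectorized as a batched
boolean transitive closure). The same quantity computed through the
full image chain (render → camera noise → spot finder) agrees with the
geometric model within ~5% up to 10 molecules per cell at high SNR,
which is the package's internal cross-validation of the two routes.

The forward model for observed counts is the Poisson(λ) mixture of the
MC-estimated conditional distributions P(detected = k | true = n), a
lower-triangular row-stochastic table estimated once (default 4,000–
5,000 reps per n up to the 1 − 10⁻⁷ Poisson quantile of the λ search
bound). Because the mixture weights are smooth in λ while the table is
fixed, the log likelihood is smooth and is maximized by bounded scalar
search (tolerance 10⁻⁴), with a profile-likelihood 95% interval via
root bracketing. The search bound 2.5·⟨k⟩ + 4 exploits that overlap
only deflates counts. All-zero data return λ̂ = 0 with a one-sided
interval. Self-consistency: counts drawn from the forward model at
λ ∈ {2, 5, 8} are recovered within ~1% from 5,000 cells.

The Fano factor of the forward model at λ = 7 in a ~2 μm² cell is ≈0.6:
overlap narrows distributions. By contrast, binomial thinning
(independent per-molecule loss) preserves Fano = 1 exactly — which is
why a sub-Poisson Fano is diagnostic of overlap rather than of uniform
detection inefficiency; a unit test pins both facts.

## Count statistics

Summaries use the unbiased (n − 1) variance. Size conditioning trims
the 1st/99th percentiles of the size covariate (default length), then
splits into quantile bins (default 5); conditioning removes the
extrinsic variance contributed by size–count scaling, so size-driven
overdispersion (pooled Fano > 1) collapses to per-bin Fano ≈ 1 when
production is Poisson. The χ² goodness of fit pools count bins left to
right until each expected frequency is ≥ 5 and uses bins − 2 degrees of
freedom (mean estimated); its type-I error is verified at α = 0.05 by
simulation. The χ² test itself is an addition for convenience — the
overlay plot is the traditional presentation. The maturation
correction assumes irreversible first-order maturation (rate
k_m = 1/τ_m) competing with dilution (μ = ln2/τ_d) and no degradation;
the mature fraction f = k_m/(k_m + μ) is ≈ 0.78 at τ_m = 10 min,
τ_d = 25 min, so observed means divide by f for only a ~28% correction.

## FRAP

Cells are treated as thin 1-D rods (the experimental counterpart uses
cephalexin-elongated cells, making the axial model apt); radial
diffusion is neglected. The bleach is a Gaussian notch in the axial
coordinate (centre 0.3 μm from the pole, σ 0.5 μm, depth 0.8 by
default), and the concentration evolves by the reflecting-boundary
cosine series c(x,t) = a₀ + Σ aₙ cos(nπx/L) e^(−D(nπ/L)²t), truncated
at 200 modes or amplitude < 10⁻¹²; notch coefficients are computed by
trapezoid quadrature on a 1024-point grid and ROI averages of the
cosine basis in closed form. Mass is conserved to machine precision.
The estimator fits the ROI mean with depth and D free (trust-region
least squares; D initialized from the observed half-recovery time via
the first-mode rate D(π/L)²). Traces with < 2% recovery are flagged
non-recovering and return D at the lower bound; fits whose record is
shorter than 3 first-mode time constants are flagged `short_trace`.
Parameter recovery at 1% multiplicative noise is unbiased within 5%
across D ∈ {0.5, 2, 14} μm² s⁻¹.

## Problem sizes and reproducibility

Default problem sizes were chosen so every Monte-Carlo assertion has
comfortable statistical margin while the whole suite and the
reproduction script each run in minutes on one core: 10⁴–10⁵ reps for
geometric curves and oracles, 150–200 reps per point for image-based
curves, 5,000 cells for inference checks, 20–25 replicates for FRAP
bias. All randomness flows from explicit `numpy` generators; pipelines
spawn per-stage substreams from one root seed, and rerunning with the
same seed reproduces TIFFs and CSVs byte for byte.

## Known limitations

The simulator's cells are rigid convex footprints on a sparse grid —
no cell–cell contact, no curved or dividing cells, no spatial
correlation in autofluorescence — so segmentation on real images will
be harder than on these frames; that is why counting accepts truth
masks and the segmentation stage is deliberately replaceable. The
overlap inversion assumes the population is represented by one geometry
(the pipeline uses the median-length cell); a size-stratified mixture
would be the natural extension. Intensity-based de-mixing of merged
spots is intentionally absent: the method counts resolvable spots, not
photons.
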