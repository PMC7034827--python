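# Methods

This note documents the models, estimators and numerical choices behind
`radnoise`, what the synthetic data does and does not emulate, and the
known limitations. Nothing here states a number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Acquisition model and phantom

The detector signal is modelled as

    counts = g · Poisson( f · Q · blur(s) ) + N(0, σ_e²)

with `s` the strictly positive linear-domain transmission image, `Q` the
baseline expected quanta per pixel at unit signal (default 5000), `f` the
dose fraction relative to baseline, `g` the detector gain (default 1
count/photon), `σ_e` electronic read noise in counts (default 2), and
`blur` a Gaussian of σ = 2 px standing in for scatter and detector blur
(the physical mechanism is scatter of photons in the object plus signal
spread in the detector; a Gaussian kernel is the simplest model with the
right qualitative effect). In the dose-normalized image the quantum
variance is `s / (f·Q·g⁻¹·…) ∝ 1/f`: halving the dose doubles the noise
variance, which the acceptance script verifies to well under 5%.

The phantom is deliberately stylized: two tilted ellipses for lung
fields (transmission 0.85), a central ellipse for heart/mediastinum
(0.25), sinusoidal bands for ribs, seeded random branching walks for
vessel trees, parabolic-cap blobs for nodules, filled polygons for
consolidations, and band-pass random texture for interstitial marking.
Every structure's presence, position and contrast is configurable and
recorded as a mask. The phantom emulates *the geometry a reader scores*
— edges, blobs, texture, graded attenuation — not radiographic realism:
no 3D projection, no anatomical variability, no detector MTF beyond the
scatter blur. Tests built on it therefore demonstrate structure- and
contrast-preservation behaviour of the engines under controlled noise,
and nothing about observer performance on real patients.

Pre-processing into the display domain is a log transform with recorded
min–max windowing, `p = (log(counts + c) − lo)/w` with `c = 0` for
strictly positive counts (else 1); the parameters are kept so the map is
invertible to ~1e-16. The log transform approximately variance-stabilizes
the signal-dependence of quantum noise, which is why the noise map is
estimated as a purely spatial field downstream.

## Noise map

`σ(x)` is estimated from the display image as 1.4826 × the local median
absolute deviation (window 7×7 by default) of the high-pass residual
`img − median₃ₓ₃(img)`, divided by a calibration gain. The gain is
obtained once per window size by Monte-Carlo (unit white Gaussian fields,
fixed internal seed) over the *entire* estimator chain, so it absorbs
both the median-residual operator's noise gain and the finite-window MAD
bias; this full-chain calibration is what makes the estimator unbiased
to within a few percent across σ ∈ [0.005, 0.1]. Median operations make
the estimate scale-equivariant and robust to anatomy: a noiseless step
edge leaks < 10% of its height, and only within ~2 px of the edge.

## Multi-scale decomposition and noise covariance

A Laplacian pyramid (default 4 levels, 5-tap binomial kernel [1,4,6,4,1]/16,
reflective boundaries) was chosen over wavelets because retaining the
intermediate low-pass images makes reconstruction exact by construction
— the inverse simply re-adds each band to the upsampled next level, so
`reconstruct(decompose(x)) = x` to machine precision for any kernel. The
upsampler reflect-pads the coarse grid *before* zero-insertion so that
boundary taps fall on real samples; without this, constants fail to
reproduce at the image edge.

Per-level noise is carried as variance maps, not full covariance
matrices: the denoiser consumes only a local per-pixel σ, and the
inter-pixel covariance of a decimated band is both enormous and unused.
Per-level scalar gains are calibrated by pushing unit-variance white
noise through the decomposition (default 50 Monte-Carlo passes, fixed
seed, cached per pyramid spec); the band-0 gain agrees with the
closed-form equivalent-filter energy (averaged over the four decimation
parities — the operator is cyclostationary with period 2) to well under
3%. The level-l variance map is the σ² field pushed through the same
smooth-and-decimate chain as the image, times the level gain; the
construction is exactly homogeneous of degree 2 in σ.

## Denoising engines

**Conventional (baseline).** Soft threshold per detail band at
`t_l = m_l · √gain_l · σ_global`, with `σ_global` the median of the noise
map and multipliers (3, 2, 1, 0.5) by default. This is the simplest
member of the global/local-shrinkage family the adaptive engine is
contrasted against; it has no spatial adaptivity by design.

**New (adaptive).** Per detail band, non-local means with the
noise-compensated patch distance `max(0, d² − 2σ²(p))` and bandwidth
`h(p) = k · σ_l(p)` where `σ_l(p)` comes from the band's variance map.
Defaults: patch radius 3 (7×7), search radius 10 (21×21), `k = 0.8`, and
a per-level schedule (1, 0.75, 0.5, 0.25) that tapers the strength at
coarse levels, where noise is weak and anatomy dominates. The self-weight
equals the maximum neighbour weight (the standard fix for
self-comparison bias), `σ = 0` pixels pass through unchanged (identity
limit), and the residual level is never filtered — after repeated
low-passing its noise is negligible and filtering it only erodes
large-scale anatomy. The vectorized implementation (one patch-distance
plane per search offset, shared reflective padding) is bit-compatible
with a literal four-nested-loop transcription of the formula to ≤ 1e-10;
that brute-force oracle is frozen in the test suite.

Two behavioural consequences of the `2σ²` compensation are worth
naming. First, on flat fields the weight distribution is scale-invariant
in σ, so the engine removes the same *fraction* of noise in quiet and
noisy regions — the package's operational definition of spatial
adaptivity, measured as the between-region imbalance of the reduction
factor (< 10% on average over a 10-seed suite, against > 129% for the
global baseline on every seed; per-seed values scatter several points
because the realized weight-1 neighbourhood fluctuates per noise
realization). Second, neighbours with `d² < 2σ²` keep weight 1 even as
`k → 0`, so the engine has a noise-reduction *floor*; comparisons "at
matched noise suppression" against the baseline therefore pick the
working point inside the overlap of the two engines' reachable ranges
(the baseline saturates once all detail bands are zeroed) and bisect
each engine's strength to it.

## Noise whitening

The smoothing stage removes a spatially correlated residual; re-injecting
part of it *whitened* restores a fine, visually uniform grain instead of
leaving the blotchy low-frequency texture that aggressive patch averaging
produces. The residual `r = original − denoised` is processed in
half-overlapping 64-px Hann tiles: per tile a periodogram is computed,
smoothed in frequency (Gaussian, σ = 8 bins, wrap-around — noise spectra
are smooth, so this trades no bias for large variance reduction), and
shape-averaged over a spatial Gaussian neighbourhood of tiles (σ = 2
tile steps) after normalizing each tile's PSD by its mean power — the
correlation *shape* varies slowly across a radiograph while the
*amplitude* varies quickly, and amplitude is handled separately. The
zero-phase filter `H ∝ PSD^{−1/2}` (floored at 1e-3 of mean power) is
applied per tile in the DFT domain with an analytic variance
normalization (`E[var out] = var in` under the estimated PSD; an
empirical per-tile rescale would re-add the estimator noise the smoothing
removed). The DC response, for which the mean-removed periodogram has no
estimate, is extrapolated from the four lowest non-DC bins. Finally the
whitened field is normalized by its local standard deviation (Gaussian
window, tile/2) and scaled to `β · σ_target(x)` from the noise map,
β = 0.5 by default; `β = 0` returns the denoised image exactly, and the
re-injected per-tile variance can never exceed `β²σ_target²` beyond
estimation error. Whether a vendor system whitens retained noise
in-place or re-injects a transformed residual is unknowable from the
outside; re-injection was chosen because it decouples the denoiser's
operating point from the grain amplitude, and is flagged in the config.

## Quality metrics

- **Radial NPS**: half-overlap Hann tiles, mean-detrended, periodograms
  averaged and collapsed to radial bins (DC excluded); normalization
  satisfies Parseval against the region variance within ~5%.
- **CNR**: `|mean_s − mean_b| / pooled σ` over disjoint ROIs.
- **Edge-preservation index**: Pearson correlation of Sobel gradient
  magnitudes restricted to the dilated top-5% true-gradient mask. Chosen
  over FSIM/GMSD for auditability (one correlation, one mask); invariant
  to affine intensity rescaling.
- **SSIM / PSNR**: scikit-image reference implementations.

## Reader-study statistics

Scores are Likert 1–5 over seven anatomical landmarks (AL1–AL7, summed
to a 35-point total) and three abnormal findings (nodule, consolidation,
interstitial marking), two readers × two sessions, aggregated as the
mean of available observations (granularity 0.25 with all four present).

- **ICC**: two-way random effects, absolute agreement, single rater
  (Shrout–Fleiss ICC2 / McGraw–Wong ICC(A,1), via pingouin) on per-image
  totals; banded < 0.40 poor, 0.40–0.59 fair, 0.60–0.74 good, 0.75–1.00
  excellent — so 0.747 is "good" and 0.750 "excellent". Absolute
  agreement (not consistency) because a constant reader offset *is* a
  disagreement in this design.
- **Non-inferiority**: differences `d = baseline − low` (positive =
  quality loss at low dose). Shapiro–Wilk at α = 0.05 gates the branch:
  normal → mean with two-sided 95% t CI; non-normal → Hodges–Lehmann
  pseudo-median with a signed-rank CI (Walsh averages bracketed at the
  exact null signed-rank critical value for n ≤ 25, normal approximation
  with continuity correction above; verified against R's `wilcox.test`).
  Non-inferiority holds iff the CI upper bound is below the margin —
  operationally a one-sided α = 0.025 test. Margins: 0.5 per item,
  3.5 = 0.5 × 7 for the total. Zero-variance differences short-circuit to
  a point CI. Signed-rank zeros are dropped and ties mid-ranked.
- **Group homogeneity**: one-way ANOVA F-test plus Tukey HSD adjusted
  pairwise p-values (statsmodels).
- **Dose accounting**: reduction rate = 100 · low/baseline ESE, one
  decimal; AEC cutoff bookkeeping carries 4.2 μGy baseline and
  2.5 / 2.11 / 1.78 μGy for the nominal 60/50/40% arms.

The score generator draws `item mean − shift·(arm = low) + subject RE +
reader bias + session noise`, rounds half-up and clips to 1–5. Defaults
(69 subjects, shift 0.15, σ_subject 0.4, σ_session 0.3, no reader bias)
give realistic granularity and an ICC in the high "excellent" range;
discretization attenuates nothing measurable at these noise levels (the
recovered shift is within 0.01 of truth on average). The generator
emulates the *design* (pairing, crossed readers/sessions, discreteness),
not reader psychology: no item correlation structure, no
session-learning or fatigue effects.

Monte-Carlo operating characteristics (computed by the acceptance
script): paired-t CI coverage 95% ± 2% at n = 23; non-inferiority type-I
error ≤ 3% at a true shift equal to the margin (σ_d = 0.49 — the
procedure's true rate is 2.5%, and the type-I run uses 3000 replicates so
binomial noise does not dominate the bound); ANOVA type-I 5% ± 2%.

## Problem sizes and numerical defaults

Test and acceptance runs use 128–256 px images, 3–4 pyramid levels, and
NLM with patch radius 2 / search radius 5 — sizes at which the brute-force
oracle and 10-seed Monte-Carlo suites are comfortable on a single core;
the engine itself is size-agnostic and the shipped defaults (512 px,
patch 3, search 10) are what one would use interactively. Tolerances:
pyramid reconstruction 1e-6 of dynamic range (achieved: ~1e-15), NLM
oracle equality 1e-10 (achieved: ~1e-13), preprocessing round trip 1e-9
relative.

## Known limitations

- No published parameters exist for any vendor engine; patch/search
  sizes, strength schedules and the choice of which levels to filter are
  this package's own defaults, all config-exposed.
- The noise map is purely spatial; residual signal-dependence of noise in
  the display domain beyond what the log transform flattens is ignored.
- The clinical reader-study tables of a real trial cannot be reproduced
  from synthetic data; the statistics layer is validated by operating
  characteristics and worked dose arithmetic instead.
- Whitening assumes locally stationary residual correlation within a
  64-px tile neighbourhood; pathological spatially varying correlation
  shapes would be under-fit.
- The sample-size calculation for a paired non-inferiority design is out
  of scope (no standard formula reproduces a fixed published planning
  number without knowing the authors' assumptions).
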