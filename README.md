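# radnoise

Spatially adaptive, multi-scale denoising for low-dose digital chest
radiography — and the paired non-inferiority reader-study statistics used
to decide whether the dose can actually be lowered.

## The problem

Chest radiography dose follows the ALARA principle: every fraction of
entrance skin exposure (ESE) that image processing can claw back is a
fraction patients stop receiving. Halving the dose roughly doubles the
quantum noise variance, and that noise is *spatially inhomogeneous* — the
mediastinum and retrocardiac regions sit behind far more attenuating
tissue than the lung fields. Classical multi-scale processing applies one
global shrinkage per frequency band and therefore over-smooths quiet
regions while under-cleaning noisy ones, blurring exactly the organ and
vessel boundaries a radiologist scores.

`radnoise` implements and evaluates two processing chains:

- **conventional engine** — Laplacian pyramid, per-band soft threshold
  `t_l = m_l · σ_global` from a single scalar noise estimate;
- **new engine** — per-pixel noise map `σ(x)` from the pre-processed
  image, propagated through the pyramid into per-level noise variance
  maps ("multi-scale noise covariance"), then per-band non-local means
  with a locally varying bandwidth, followed by a noise-whitening stage
  that de-correlates the residual and re-injects a controlled fraction of
  fine, spectrally flat grain.

The NLM weight for pixels `p, q` in a band with local noise `σ(p)` is

    w(p,q) = exp( − max(0, d²(p,q) − 2σ²(p)) / h²(p) ),   h(p) = k·σ(p)

with `d²` the mean squared patch difference — the `2σ²` term removes the
noise floor from the distance, and `h ∝ σ` makes the smoothing strength
follow the local noise level, which is what "spatially adaptive" means
here concretely.

On the evaluation side, the package carries the complete statistics of a
paired two-arm reader study: Likert score aggregation, two-way random
absolute-agreement ICC with the poor/fair/good/excellent banding,
Shapiro–Wilk-gated paired testing (paired *t* / Wilcoxon signed rank with
a Hodges–Lehmann estimate and signed-rank CI), non-inferiority against a
margin of 0.5 per item (3.5 for the 7-landmark total), one-way ANOVA with
Tukey HSD for group homogeneity, and ESE dose accounting. A seeded
synthetic chest-phantom simulator (stylized lungs, ribs, vessels,
nodules, consolidations; mixed Poisson–Gaussian dose-dependent noise) and
a reader-score generator make every stage testable end to end without any
clinical data.

## Worked example

```bash
python examples/denoise_and_compare_engines.py
```

```
input:        flat noise 0.0262, SSIM 0.8045
new engine    flat noise 0.0069 (74% removed), SSIM 0.9820, PSNR 41.5 dB, edge preservation 0.9822
conventional  flat noise 0.0062 (76% removed), SSIM 0.9731, PSNR 36.1 dB, edge preservation 0.9592
```

A half-dose acquisition of a 128×128 phantom: both engines remove ~75% of
the flat-region noise, but the adaptive engine keeps the edge-preservation
index (gradient correlation on true boundaries) at 0.982 vs 0.959 and
gains 5 dB of PSNR — noise suppression without boundary loss. The other
scripts in `examples/` walk through acquisition simulation, noise-map
estimation and covariance propagation, residual whitening, and the full
reader-study analysis (which prints an ICC with its band and a per-item
non-inferiority table).

A thin CLI wraps the same library calls:

```bash
radnoise simulate --size 256 --dose-fraction 0.5 --out raw.tif --truth-out truth.tif
radnoise denoise raw.tif --engine new --out out.tif --provenance-out prov.json
radnoise evaluate truth.tif out.tif
radnoise reader-stats scores.csv
```

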