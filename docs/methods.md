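# Methods

## Noise model

Magnitude MR data are modeled as Rician: `M = sqrt((A + n1)² + n2²)`
with `n1, n2` i.i.d. zero-mean Gaussians of standard deviation σ, so
`E[M²] = A² + 2σ²`. The density is
`p(M) = (M/σ²) exp(−(M²+A²)/2σ²) I0(AM/σ²)` for `M ≥ 0`, evaluated with
the exponentially scaled Bessel function so that large `AM/σ²` does not
overflow. At `A = 0` the model reduces to Rayleigh, which is what the
background σ estimator exploits: `σ̂ = sqrt(mean(M²_background)/2)`.
The estimator is written with the square root — the moment identity
`E[M²] = 2σ²` fixes the dimensions — and requires at least 100
background pixels.

Two auxiliary generators cover non-Rician stress tests. Salt & Pepper
noise corrupts each pixel independently with probability `d` and writes
0 or 1 with equal probability; the total density is the only parameter
commonly fixed, and the 50/50 split is this package's declared choice.
Speckle is multiplicative, `J = I + n·I`, with `n` drawn zero-mean
uniform with variance `v` (the uniform family is a declared choice; the
variance law `Var[J] = I²v` on constant images is what the tests pin).
All generators operate on the normalized [0,1] intensity scale, are pure
functions of (image, intensity, seed), and Rician/speckle outputs are
not clipped — downstream metrics accept values above 1, and the image
writers clip (with a logged warning) only at serialization time.

## The filter family

All three filters share one weighting machinery over a search window of
radius `rads` (window `(2·rads+1)²`, clipped at image borders with
renormalization) and patches of radius `radp` extracted with symmetric
(mirror) padding. The patch distance is kernel-weighted with the kernel
normalized to sum 1, so the uniform kernel (`a = ∞`, the default) gives
the mean squared patch difference; a Gaussian kernel of std `a` is
available. The patch similarity is `φ = exp(−d²/h²)`. Two patch
dialects exist: the default contiguous `(2·radp+1)²` neighborhood, and a
`stride2` dialect sampling the same number of pixels at even offsets (a
dilated grid); the dialect only changes where patch pixels are read.

* **NLM** — `x̂(i) = Σ w(i,j) y(j)` with the self-weight set to the
  maximum non-central φ in the window.
* **RNLM** — the same weights applied to squared magnitudes with bias
  subtraction, `x̂ = sqrt(max(Σ w y² − 2σ², 0))`. The square root is
  part of the estimator definition here (the output must be in intensity
  units); `no_sqrt=True` exposes the raw squared-magnitude form for
  comparison.
* **RNLM\*** — non-central weights `φ* = φ·ρ` with
  `ρ = 1/(1 + (|y(i)−y(j)|/Degc)^ω)`; the self-weight is the maximal
  non-central `φ*` times `ϑ = 1 + (2·radp+1)²/(1 + (Degc/|y(i)−y(k)|)^ω)`
  where `k` is the argmax (ties broken by first occurrence in raster
  order, making outputs deterministic). At `|y(i)−y(k)| = 0` the
  analytic limit ϑ = 1 is used. As `Degc → ∞` both ρ and ϑ tend to 1
  and RNLM\* collapses to RNLM — a limit the tests assert.

The fast implementation vectorizes over window offsets: for each offset
the patch-distance map over all centers is one kernel correlation of the
squared difference between the mirrored-padded image and its shifted
copy. A per-pixel loop reference (in the test tree, deliberately
sharing no array code) pins the fast path to 1e-8; in practice agreement
is at machine precision. If every weight underflows to zero at a pixel
(possible only for extreme `d²/h²`), the filter falls back to the
identity at that pixel.

### Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `h` | smoothing decay on the [0,1] scale; larger smooths more | 0.8 |
| `radp` | patch radius | 3 |
| `rads` | search-window radius (≥ radp) | 10 |
| `degc` | pixel-similarity transition position | 6.65 |
| `omega` | transition slope | 4 |
| `a` | patch-kernel std (∞ = uniform) | ∞ |

Defaults follow the averaged random-search optima reported for
musculoskeletal MR series. Note that `degc = 6.65` exceeds the whole
[0,1] range, so at the default the pixel-similarity terms are
essentially inert and RNLM\* behaves like RNLM — the reported optimum
evidently lives on a wider intensity scale. The particle-preserving
mechanism engages when `degc` sits *below* the particle-to-background
contrast of interest.

### Regime dependence under impulse noise

The Degc transition cuts both ways. With `degc` below the impulse
contrast, Salt & Pepper outliers are treated as particles: their
self-weights are boosted and the impulses survive, making RNLM\* *worse*
than RNLM on SSIM. With `degc` above the image's contrast scale
(≈ 0.6–1.0 on [0,1] for the phantoms here), ρ suppresses impulse pixels
as averaging candidates while self-weight boosts stay moderate, and
RNLM\* beats RNLM — the sign reported for impulse noise. The
qualitative tests therefore use `degc = 0.15` when probing particle
preservation under Rician noise and `degc = 0.7` when probing the
impulse-noise advantage; each is the regime in which the respective
claim is meaningful.

## Metrics

MSE, `SNR = 10·log10(Σs²/Σ(s−ŝ)²)` with the filtered image in the
signal role (role asymmetry is asserted by a test), `PSNR =
10·log10(peak²/MSE)`, the universal quality index (product of
correlation, luminance-similarity `2x̄ȳ/(x̄²+ȳ²)` and
contrast-similarity `2σxσy/(σx²+σy²)` factors — the symmetric
denominator is the only form bounded in [−1,1]), and SSIM
`l^α·c^β·s^γ` with `C1 = (0.01)², C2 = (0.03)², C3 = C2/2` on the unit
scale, α = β = γ = 1, population moments, global statistics by default
(an 8×8 sliding-window mode exists). Degenerate inputs return sentinels
(+∞ for zero-error SNR/PSNR, NaN for zero-variance Q/correlation)
rather than raising, so batch sweeps never abort. Intensity-difference
statistics use `ID = |native − filtered|·100` percent with the mode
taken as the center of the most populated of 256 bins over [0,100].

## Optimization

Pure random search: `n` combinations drawn uniformly (continuous `h`,
`degc`; discrete `radp`, `ω`), each scored by the grand-mean MSE over an
image set corrupted with Rician noise at σ ∈ {0.05, 0.1, 0.15, 0.2,
0.3} by default. Corruption seeds depend only on (seed, image, σ), so
every candidate faces identical noise and scores are comparable — the
alternative (re-corrupting per trial) would confound sampling noise with
parameter quality. Combinations are drawn one at a time in fixed field
order, giving the nested-seed prefix property: `best_mse(n)` is
non-increasing in `n` at a fixed seed. Variance reports across repeated
optimizations use the sample (n−1) convention.

## Robustness and segmentation analyses

Robustness curves corrupt each image at nine levels (0.1 … 0.9 by
default), filter, and average the metric panel over images per level.
Rician-aware filters can tie their bias correction to the swept level
(`sigma="level"`); for impulse noise the correction is disabled
(`sigma=0`) since the Rician second-moment model does not apply.
Intensity-difference studies pool per-pixel ID values across all levels
per filter setting. Filter comparisons report
`100·(mean_A − mean_B)/mean_B` of level-and-image-averaged SSIM and
correlation (relative differences, with the comparator in the
denominator).

Segmentation is histogram-domain fuzzy c-means on the distinct intensity
values weighted by pixel counts: centroids initialized at the
`(j+0.5)/C` quantiles (with fallbacks when skewed histograms collapse
quantiles), fuzzifier m = 2, convergence when the largest centroid shift
drops below 1e-6, each pixel assigned its maximal-membership class.
This is deterministic and permutation-invariant by construction. The
"fuzzy soft thresholding" label in the musculoskeletal literature defers
to an uncited algorithmic core; this histogram-FCM formulation is a
declared stand-in with the same interface and qualitative behavior.
Segmentations are compared as centroid renderings (labels replaced by
centroid intensities) so SSIM/SNR act on intensity-commensurate inputs.

## What the phantoms emulate — and what they do not

Phantoms are horizontal smooth tissue bands with distinct seeded mean
levels and small hard discs of known contrast at seeded, well-separated
positions, optionally blurred. They reproduce the features the filter
claims hinge on: piecewise-smooth anatomy, blurred edges, and tiny
high-contrast particles with exact ground-truth masks. They do not
model coil sensitivity or bias fields, spatially correlated noise,
non-central-χ multi-coil statistics, partial-volume texture, or 3-D
structure. Passing tests therefore demonstrate the algorithmic
properties (bias correction, particle preservation, monotone
degradation, segmentation benefit) under controlled conditions, not
clinical performance on real MR series; the reported clinical tables are
data-dependent and outside what desk-scale synthetic runs can reproduce.

## Problem sizes and numerical choices

Tests and the acceptance script run on 16–64 px phantoms with search
radii 3–5 and 10–50 optimizer trials — sizes chosen so the whole
evaluation reruns in seconds while every property remains sharply
resolved (the oracle comparisons sit at machine precision, and the
qualitative effects above have margins far from their thresholds).
Everything is float64; weight underflow falls back to identity; argmax
ties break by raster order; borders mirror-pad patches and clip search
windows; seeds derive from a single integer through SeedSequence-style
spawning and stay below 2³¹.
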