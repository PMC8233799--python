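# rnlmstar

Particle-preserving Rician non-local-means denoising and evaluation for
MR-like images.

Magnitude MR images carry Rician noise: the observed magnitude is
`M = sqrt((A + n1)^2 + n2^2)` with `n1, n2 ~ N(0, σ²)`, so low-signal
regions are biased upward (`E[M²] = A² + 2σ²`). Non-local-means (NLM)
filters handle this well, but they tend to average tiny high-contrast
spots — the 1–3-pixel particles that can represent small bone or
cartilage lesions — into the background. This package implements and
evaluates an optimized Rician NLM (RNLM\*) that keeps those particles.

## The filter

Classic NLM estimates each pixel as a weighted average over a search
window `Win(i)`:

    x̂(i) = Σ_{j ∈ Win(i)} w(i,j) · y(j),
    w(i,j) ∝ φ(i,j) = exp(−‖N(i) − N(j)‖²_{2,a} / h²),

with the self-weight `φ(i,i)` set to the maximum non-central weight.
The Rician-corrected variant (RNLM) operates on squared magnitudes:

    x̂(i) = sqrt( max( Σ_j w(i,j) · y(j)² − 2σ², 0 ) ).

RNLM\* multiplies the patch similarity by a pixel-intensity similarity

    ρ(i,j) = 1 / (1 + (|y(i) − y(j)| / Degc)^ω),

and rescales the self-weight by

    ϑ(i,k) = 1 + (2·radp + 1)² / (1 + (Degc / |y(i) − y(k)|)^ω),

where `k` is the best non-central match. When a center pixel differs
strongly from everything in its window — the tiny-particle case — ϑ
approaches `1 + (2·radp+1)²` and the pixel largely keeps its own value
instead of being averaged away.

Around the filter the package provides: seeded MR-like phantoms (layered
tissue bands plus high-contrast discs with known masks), Rician / Salt &
Pepper / speckle noise generators, quality metrics (MSE, SNR, PSNR,
Q-index, SSIM, correlation, intensity-difference statistics), a
random-search parameter optimizer, dynamic-noise robustness sweeps,
average/median baselines, and fuzzy soft-thresholding segmentation with
performance analysis.

## Worked example

```python
import numpy as np
import rnlmstar as rs

spec = rs.PhantomSpec(size=(48, 48), n_bands=1, n_particles=3,
                      particle_radius_px=1, particle_contrast=0.5,
                      edge_blur_sigma=0.0, seed=3, band_levels=(0.3,))
img = rs.make_phantom(spec)            # particles at 0.8 on a 0.3 field
mask = rs.particle_mask(spec)

noisy = rs.add_rician(img, sigma=0.1, seed=0)
params = rs.FilterParams(h=0.6, radp=2, rads=4, degc=0.15, omega=4)
star  = rs.rnlm_star_filter(noisy, params, sigma=0.1)
plain = rs.rnlm_filter(noisy, params, sigma=0.1)

print("particle attenuation, RNLM*:", round((img[mask] - star[mask]).mean(), 3))
print("particle attenuation, RNLM :", round((img[mask] - plain[mask]).mean(), 3))
print("SSIM RNLM*:", round(rs.ssim(img, star), 3))
```

Output:

```
particle attenuation, RNLM*: 0.139
particle attenuation, RNLM : 0.46
SSIM RNLM*: 0.608
```

The particles lose 0.14 of their 0.5 contrast under RNLM\* but 0.46 —
nearly everything — under plain RNLM at identical parameters.

The same pipeline is available from the shell:

```bash
rnlmstar phantom --size 64 64 --particles 3 --seed 3 --out phantom.png
rnlmstar add-noise --family rician --intensity 0.1 --seed 0 phantom.png noisy.png
rnlmstar denoise --method rnlm-star --h 0.6 --radp 2 --rads 4 --degc 0.15 \
    --sigma 0.1 noisy.png denoised.png
rnlmstar metrics phantom.png denoised.png
```

Every command writes a `<output>.manifest.json`; `rnlmstar run-config
MANIFEST` replays it bit-identically.

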