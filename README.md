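# srfdenoise

Noise reduction for fluorescence-microscopy images with a
**stochastically-connected random field (SRF)**, together with a
procedural phantom simulator and standard image-quality metrics
(SNR / ISNR / PSNR and ROI-based SNR / CNR).

Fluorescence images are photon-limited: the recorded signal is well
modelled as

```
V = g0 · Poisson(U) + N(m, σ_ε²)
```

where `U` is the noise-free photon image, `g0` the detector gain and
`(m, σ_ε)` the Gaussian dark current. At low photon counts the Poisson
term dominates and ordinary Gaussian denoisers are mis-specified. This
package is aimed at microscopists and image-analysis researchers who need
an edge-preserving denoiser for such data, plus a fully seeded synthetic
benchmark to evaluate it against ground truth.

## Method

1. **Variance stabilization.** The observation is mapped through the
   generalized Anscombe transform

   ```
   T(v) = (2/g0) · sqrt( g0·v + (3/8)·g0² + σ_ε² − g0·m )
   ```

   (argument clamped at 0), which renders the Poisson-Gaussian noise
   approximately Gaussian with unit variance, so a quadratic data term
   is valid in the transformed domain.

2. **SRF prior.** A random field is placed over the pixels with binary
   cliques inside an 11×11 neighbourhood. Edge existence is *stochastic*:
   the edge (i, j) is sampled with probability `exp(−d_ij / Q)`, where
   `d_ij` is a patch ("regional") L2 distance computed from the previous
   solution and `Q` is the flexibility constant. Sampled edges carry
   smoothness weights `w_ij = exp(−d_ij² / σ²)`, per-site normalized so
   the weights incident to any pixel sum to at most 1. This replaces the
   brittle hard connectivity threshold of standard random fields: smooth
   regions connect densely, while edges survive because dissimilar pixels
   connect only rarely.

3. **MAP energy and multi-layer optimization.**

   ```
   E(U) = Σ_i (t_i − t_obs,i)²  +  λ · Σ_(i,j)∈edges w_ij (t_i − t_j)²
   ```

   Each layer samples fresh cliques from the previous solution, then takes
   a single synchronous gradient step on `E`, the previous solution acting
   as that layer's observation (iterative scale-space). After the last
   layer the inverse transform maps the estimate back to detector counts.

Defaults: neighbourhood 11×11, region 3×3, `Q = σ = 1`, 20 layers,
`λ = 0.1`, step 0.5. `λ` and the layer count are the tunable smoothing
budget and are exposed to the built-in grid-search `tune`.

## Worked example

```python
import numpy as np
from srfdenoise import (PhantomSpec, SRFConfig, make_dataset, denoise,
                        psnr_db, isnr_db)

# 128x128 phantom at photon-conversion factor beta = 0.5
spec = PhantomSpec(size=(128, 128), beta=0.5, seed=7)
(truth, noisy), = make_dataset(spec, [0.5], seed=7)

den = denoise(noisy, spec.noise_params(), SRFConfig(seed=0))

print(f"PSNR noisy   : {psnr_db(truth, noisy):.2f} dB")
print(f"PSNR denoised: {psnr_db(truth, den):.2f} dB")
print(f"ISNR         : {isnr_db(truth, noisy, den):+.2f} dB")
```

prints

```
PSNR noisy   : 24.53 dB
PSNR denoised: 26.34 dB
ISNR         : +1.81 dB
```

i.e. at β = 0.5 (roughly half the nominal photon budget) the denoiser
recovers ~1.8 dB of fidelity relative to the raw acquisition. Positive
ISNR means the estimate is closer to the ground truth than the noisy
input; PSNR is reported against the 8-bit truth scale (MAX = 255).

The same pipeline is available from the shell:

```
srfdenoise simulate --size 256x256 --betas 0.1:0.9:0.1 --seed 17 --out data/
srfdenoise denoise data/noisy_b0.5.tif --gt data/gt.tif --out out/
srfdenoise evaluate --gt data/gt.tif --noisy data/noisy_b0.5.tif \
    --denoised out/denoised_run0_c0.tif --out report.csv
srfdenoise tune --gt data/gt.tif --noisy data/noisy_b0.5.tif --out tuned/
```

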