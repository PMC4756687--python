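# Methods

## Acquisition model

A single-channel fluorescence acquisition is modelled per pixel as

    V = g0 · Poisson(U) + N(m, σ_ε²),

with photon image `U ≥ 0`, detector gain `g0 > 0` and Gaussian dark
current `(m, σ_ε)`. `degrade` samples this forward model (Poisson first,
then gain, then the additive Gaussian). `estimate_params_from_background`
estimates `(m, σ_ε)` as the sample mean/std of a user-chosen photon-free
background ROI (≥ 100 pixels); the gain is unidentifiable from such a
region and defaults to 1 unless supplied.

## Variance stabilization

The generalized Anscombe transform

    T(v) = (2/g0) · sqrt( g0·v + (3/8)·g0² + σ_ε² − g0·m )

maps the observation to approximately unit-variance Gaussian noise. The
square-root argument is clamped at 0 (low counts after dark-current
subtraction), keeping the transform total and monotone. The inverse is
the algebraic inverse clamped to non-negative output; values below `T(0)`
map to 0. Monte-Carlo checks in the test suite show the stabilized std
stays within a few percent of 1 for photon levels 5–200 and gains 0.5–4,
failing gracefully only at very low counts where every stabilizer is
biased.

## SRF prior

Sites are pixels; binary cliques live inside a square neighbourhood
(default 11×11 — large neighbourhoods suit the big homogeneous regions of
fluorescence images). For sites i, j the *regional distance* is

    d_ij = ‖R_i − R_j‖₂ / region_size²,

the L2 norm of the difference of the `region_size × region_size` patches
(default 3×3, matching a point-spread function wider than one pixel)
centred at the two sites, computed on the previous layer's solution with
mirror padding at borders. Dividing by the patch pixel count keeps `Q`
and `σ` comparable across region sizes.

Edge existence is stochastic: each unordered in-neighbourhood pair is
included independently with probability

    P_ij = exp(−d_ij / Q),

equivalently `d_ij ≤ τ` with `τ ~ Exponential(mean Q)`. Included edges
carry raw weights `exp(−d_ij² / σ²)`, normalized per site by
`z_ij = max(s_i, s_j, 1)` with `s_i` the raw incident sum. This
normalization is symmetric and guarantees both that every weight lies in
[0, 1] and that the incident weights at any site sum to at most 1, which
in turn bounds the prior's Hessian and stabilizes the gradient step.

With unit-variance VST noise, the regional distance between two
noise-only 3×3 patches concentrates near `sqrt(2·9)/9 ≈ 0.47`, while a
structural edge of Δ VST units contributes about Δ/3. The defaults
`Q = σ = 1` therefore connect smooth regions with probability ≈ 0.6 and
suppress edges a few VST units tall; this matches the convention of tying
the flexibility constant to the smoothness constant, and the smoothness
constant to the (VST-domain) background noise level, which is ≈ 1 by
construction after stabilization.

## Energy and optimization

In the VST domain,

    E(U) = Σ_i (t_i − t_obs,i)² + λ Σ_(i,j)∈edges w_ij (t_i − t_j)².

The gradient is `2(t_i − t_obs,i) + 2λ Σ_j w_ij (t_i − t_j)` (each
unordered edge counted once in the energy); the test suite verifies it
against central finite differences to 1e−6.

Each layer: sample edges from the previous solution, freeze weights, take
**one** synchronous (Jacobi-style) gradient step with step size β = 0.5,
with the previous solution serving as the layer's observation; the
output seeds the next layer (iterative scale-space). Because the state is
initialized at the layer's observation, the unary gradient vanishes at
the evaluation point and the step moves along the weighted smoothing
direction scaled by `β·λ`; the unary term still anchors each layer's
energy and its descent check. With normalized weights the energy is
non-increasing at β = 0.5 whenever `β(2 + 4λ) ≤ 2`, comfortably satisfied
at the default λ.

### Choice of layers and λ

The per-layer smoothing coefficient is `2βλ·Σw ≤ λ` per site. At λ = 1
each layer would replace every pixel by a full neighbourhood average —
20 layers of that visibly blur sub-cellular structure and *reduce*
fidelity. The layer count and λ are exactly the parameters the standard
protocol tunes by grid search on a β = 0.5 phantom before applying them
across β; running that protocol here selects λ ≈ 0.1 at 20 layers
(ISNR ≈ +1.9 dB on the 128² phantom), which we adopt as defaults. Both
remain exposed through `GridSpec`/`tune`.

Multi-channel images are denoised per channel independently; σ can be set
per channel from the VST-domain std of a background ROI.

## Phantom

`generate_base` draws sparse rotated elliptical cells (≈ 1 cell per
5000 px²) on a zero background: interior intensity U(60, 120), a brighter
membrane rim, 1–3 nucleoli foci of radius 1–3 px at intensity
U(150, 255); quantized to integers in [0, 255] and interpreted as certain
photon counts. It is a synthetic, procedural stand-in emulating the
structure of public yeast-microscopy images (sparse elliptical cells with
bright sub-cellular foci); a file-based mode accepts a real base image.
`add_background_profiles` adds 200 isotropic Gaussian autofluorescence
profiles with peak photon counts U(0, 20) and widths U(2, 12) px (widths
are our choice; only the amplitudes are standard).

Acquisition uses a photon-conversion factor β ∈ (0, 1]:

    V = (1/β) · Poisson(β·U) + N(12, 0.5²).

`β·U` is the Poisson mean; dividing the counts by β keeps every β on the
truth's 8-bit intensity scale (so PSNR across β is well defined), giving
`E[V] = U + 12` and noise variance `U/β`. Equivalently this is a gain of
`1/β` applied to the photon image `β·U`, so the matching VST parameters
are `g0 = 1/β` (`PhantomSpec.noise_params()`). Sweeps share one
bit-identical ground truth across β.

What the phantom does **not** emulate: PSF blur, 3-D structure,
photobleaching, fixed-pattern noise, spatially varying gain, and the
texture statistics of real cells. Passing tests therefore demonstrate
correctness of the noise model, the sampler and the optimizer, and
improvement under Poisson-Gaussian noise — not performance on any
specific instrument's data.

Note the additive dark mean is deliberately *not* removed by the
pipeline (the estimate stays on detector scale, and `layers = 0` is an
exact VST round trip), so phantom MSEs contain a constant 12² offset
shared by noisy and denoised images; ISNR compares the two fairly but is
compressed relative to a dark-subtracted evaluation.

## Metrics

Ground-truth metrics are power ratios via MSE and use `10·log10`:
SNR `= 10·log10(Σu²/Σ(u−û)²)`, ISNR `= 10·log10(MSE_noisy/MSE_denoised)`,
PSNR `= 10·log10(MAX²/MSE)` with MAX defaulting to 255. ROI metrics are
amplitude ratios and use `20·log10`: SNR `= 20·log10(mean_cell/std_bg)`,
CNR `= 20·log10(|mean_cell − mean_bg|/std_bg)`. ISNR equals
PSNR(denoised) − PSNR(noisy) identically. Degenerate ratios yield ±inf,
serialized as the strings `"inf"`/`"-inf"`. Multi-run aggregation reports
mean and sample std, excluding (and counting) non-finite sentinels.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; multi-run protocols
derive run seeds as `master_seed + run_index`, and `denoise` spawns one
child seed per layer from `config.seed`, so outputs are bit-reproducible.
The test suite and `scripts/acceptance.py` use 4×4 lattices for gradient
checks, a 16×16 texture for connectivity frequencies, 64×64 phantoms for
energy descent, and 128²–256² phantoms with 5–30 noise seeds for the
fidelity, trend and dispersion measurements; these sizes give Monte-Carlo
standard errors well below the effects being measured.

## Known limitations

- The stabilizer (and hence the quadratic unary term) degrades below a
  few photons per pixel; at β = 0.1 improvements are smaller and fine
  structure (small nucleoli) can be lost.
- Distances at layer 1 are computed from the noisy stabilized image;
  spurious low weights across flat regions are corrected only gradually
  over layers.
- Edges are local (≤ neighbourhood radius); no non-local or image-wide
  connectivity, no PSF deconvolution, no graph-cut/message-passing
  inference.
- Per-channel processing ignores inter-channel correlation.
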