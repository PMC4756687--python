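"""Synthetic fluorescence-microscopy phantom generator.

Produces ground-truth/noisy image pairs mimicking a widefield fluorescence
acquisition of sparsely distributed yeast-like cells: an 8-bit-quantized
photon image of elliptical cells (dim interior, brighter membrane rim,
a few bright nucleoli foci), plus a diffuse autofluorescence background of
isotropic Gaussian profiles.  Acquisition applies photon-statistics via a
photon-conversion factor beta -- ``beta * U`` is the Poisson mean, and the
recorded counts are rescaled by ``1/beta`` so every beta shares the 8-bit
intensity scale of the truth -- followed by additive Gaussian dark current
(mean 12, std 0.5 by default).  Smaller beta means fewer detected photons
and a noisier image.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .noise_model import NoiseParams

__all__ = [
    "PhantomSpec",
    "generate_base",
    "add_background_profiles",
    "simulate_acquisition",
    "make_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom construction and acquisition parameters.

    base                "procedural" or a path to a grayscale image to use
                        as the 8-bit ground-truth photon image
    size                (height, width) in pixels
    n_profiles          autofluorescence Gaussian profiles (default 200)
    profile_amp_max     peak photon count of a profile (uniform in [0, max])
    profile_sigma_range widths of the profiles in pixels (uniform draw)
    beta                photon-conversion factor in (0, 1]
    dark_mean, dark_std additive Gaussian dark current (detector counts)
    seed                master seed for phantom construction
    """

    base: str = "procedural"
    size: tuple[int, int] = (256, 256)
    n_profiles: int = 200
    profile_amp_max: float = 20.0
    profile_sigma_range: tuple[float, float] = (2.0, 12.0)
    beta: float = 0.5
    dark_mean: float = 12.0
    dark_std: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.beta <= 1):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.n_profiles < 0:
            raise ValueError("n_profiles must be >= 0")
        if self.dark_std < 0:
            raise ValueError("dark_std must be >= 0")
        if self.size[0] < 1 or self.size[1] < 1:
            raise ValueError(f"size must be positive, got {self.size}")
        lo, hi = self.profile_sigma_range
        if not (0 < lo <= hi):
            raise ValueError("profile_sigma_range must satisfy 0 < min <= max")

    def noise_params(self) -> NoiseParams:
        """VST-matched acquisition parameters for this phantom.

        ``(1/beta) Poisson(beta U)`` is a gain of ``1/beta`` applied to the
        photon image ``beta U``, so the stabilizing gain is ``g0 = 1/beta``.
        """
        return NoiseParams(
            g0=1.0 / self.beta, m=self.dark_mean, sigma_eps=self.dark_std
        )

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "size": list(self.size),
            "n_profiles": self.n_profiles,
            "profile_amp_max": self.profile_amp_max,
            "profile_sigma_range": list(self.profile_sigma_range),
            "beta": self.beta,
            "dark_mean": self.dark_mean,
            "dark_std": self.dark_std,
            "seed": self.seed,
        }


def generate_base(spec: PhantomSpec) -> np.ndarray:
    """8-bit-quantized ground-truth photon image.

    Procedural mode draws sparse rotated elliptical cells on a zero
    background: interior intensity ~U(60, 120), a brighter membrane rim,
    and 1-3 bright nucleoli foci (intensity 150-255) per cell.  File mode
    loads a grayscale image and quantizes it to 8 bits.  Values are
    integers in [0, 255]; deterministic given ``spec.seed``.
    """
    if spec.base != "procedural":
        from .image_io import read_image

        channels = read_image(spec.base)
        img = channels[0]
        lo, hi = float(img.min()), float(img.max())
        scaled = (img - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(img)
        return np.rint(scaled)

    height, width = spec.size
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed).spawn(2)[0]
    )
    img = np.zeros((height, width))
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    scale = min(height, width)
    n_cells = max(2, round(height * width / 5000))
    for _ in range(n_cells):
        cy = rng.uniform(0.1 * height, 0.9 * height)
        cx = rng.uniform(0.1 * width, 0.9 * width)
        a = rng.uniform(0.03, 0.075) * scale  # semi-axes in pixels
        b = rng.uniform(0.03, 0.075) * scale
        theta = rng.uniform(0, np.pi)
        interior = rng.uniform(60, 120)
        rim = min(255.0, interior + rng.uniform(40, 80))
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        e = (xr / a) ** 2 + (yr / b) ** 2
        cell = np.where(e <= 1.0, interior, 0.0)
        cell = np.where((e > 0.72) & (e <= 1.0), rim, cell)  # membrane rim
        for _ in range(rng.integers(1, 4)):
            # nucleoli foci well inside the cell body
            rho = np.sqrt(rng.uniform(0.0, 0.35))
            ang = rng.uniform(0, 2 * np.pi)
            fy = cy + rho * b * np.sin(ang) * ct + rho * a * np.cos(ang) * st
            fx = cx + rho * a * np.cos(ang) * ct - rho * b * np.sin(ang) * st
            fr = rng.uniform(1.0, 3.0)
            amp = rng.uniform(150, 255)
            focus = (yy - fy) ** 2 + (xx - fx) ** 2 <= fr**2
            cell = np.where(focus & (e <= 1.0), amp, cell)
        img = np.maximum(img, cell)
    return np.clip(np.rint(img), 0, 255)


def add_background_profiles(truth, spec: PhantomSpec, seed=None) -> np.ndarray:
    """Add the diffuse autofluorescence background to a photon image.

    ``spec.n_profiles`` isotropic Gaussian profiles with uniform random
    centres, peak amplitudes uniform in [0, profile_amp_max] photons and
    widths uniform in ``profile_sigma_range``.  Strictly additive: the
    output is >= the input everywhere.
    """
    u = np.asarray(truth, dtype=float)
    if np.any(u < 0):
        raise ValueError("truth image must be non-negative")
    if seed is None:
        seed = np.random.SeedSequence(spec.seed).spawn(2)[1]
    rng = np.random.default_rng(seed)
    height, width = u.shape
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    out = u.copy()
    for _ in range(spec.n_profiles):
        cy = rng.uniform(0, height)
        cx = rng.uniform(0, width)
        amp = rng.uniform(0, spec.profile_amp_max)
        sig = rng.uniform(*spec.profile_sigma_range)
        out += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    return out


def simulate_acquisition(
    truth, spec: PhantomSpec, params: NoiseParams | None = None, seed=None
) -> np.ndarray:
    """One noisy acquisition: ``V = (1/beta) Poisson(beta U) + N(m, s^2)``.

    ``beta U`` is the Poisson mean; the recorded counts are rescaled by
    ``1/beta`` so all betas share the truth's intensity scale, hence
    ``E[V] = U + m`` while the noise variance scales as ``U / beta``
    (smaller beta = fewer photons = noisier).  Dark-current parameters
    ``(m, sigma_eps)`` come from ``params`` when given, else from the
    spec's ``dark_mean`` / ``dark_std``; the matching VST parameters for
    the result are ``spec.noise_params()`` (gain ``1/beta``).
    """
    u = np.asarray(truth, dtype=float)
    if np.any(u < 0):
        raise ValueError("truth image must be non-negative")
    m, s = (params.m, params.sigma_eps) if params is not None else (
        spec.dark_mean, spec.dark_std)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(spec.beta * u).astype(float)
    v = counts / spec.beta
    return v + rng.normal(m, s, size=u.shape)


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def make_dataset(
    spec: PhantomSpec,
    betas: list[float],
    seed=None,
    out_dir: str | Path | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Ground-truth/noisy pairs across a photon-conversion sweep.

    One ground truth (base + background profiles) is built once and shared
    bit-identically across all betas; each beta gets an independent noisy
    realization.  When ``out_dir`` is given, float32 TIFF pairs
    (``gt.tif``, ``noisy_b{beta}.tif``) and a JSON manifest (spec, seeds,
    checksums) are written there.
    """
    if not betas:
        raise ValueError("betas must be non-empty")
    for b in betas:
        if not (0 < b <= 1):
            raise ValueError(f"each beta must be in (0, 1], got {b}")
    if seed is None:
        seed = spec.seed
    master = np.random.SeedSequence(seed)
    base_ss, bg_ss, *noise_ss = master.spawn(2 + len(betas))
    if spec.base == "procedural":
        base = _seeded_base(spec, base_ss)
    else:
        base = generate_base(spec)
    truth = add_background_profiles(base, spec, seed=bg_ss)
    pairs = []
    for b, child in zip(betas, noise_ss):
        sp = _with(spec, beta=b)
        noisy = simulate_acquisition(truth, sp, seed=child)
        pairs.append((truth, noisy))
    if out_dir is not None:
        _write_dataset(Path(out_dir), spec, betas, seed, truth, pairs)
    return pairs


def _with(spec: PhantomSpec, **overrides) -> PhantomSpec:
    d = spec.to_dict()
    d.update(overrides)
    d["size"] = tuple(d["size"])
    d["profile_sigma_range"] = tuple(d["profile_sigma_range"])
    return PhantomSpec(**d)


def _seeded_base(spec: PhantomSpec, ss: np.random.SeedSequence) -> np.ndarray:
    return generate_base(_with(spec, seed=int(ss.generate_state(1)[0] % (2**31))))


def _write_dataset(out_dir, spec, betas, seed, truth, pairs) -> None:
    import tifffile

    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "gt.tif", truth.astype(np.float32))
    manifest = {
        "spec": spec.to_dict(),
        "master_seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
        "betas": [float(b) for b in betas],
        "files": {"gt.tif": _sha256(truth.astype(np.float32))},
    }
    for b, (_, noisy) in zip(betas, pairs):
        name = f"noisy_b{b:g}.tif"
        tifffile.imwrite(out_dir / name, noisy.astype(np.float32))
        manifest["files"][name] = _sha256(noisy.astype(np.float32))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
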