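"""Poisson-Gaussian acquisition model and variance-stabilizing transform.

A fluorescence-microscopy detector records

    V = g0 * Poisson(U) + Normal(m, sigma_eps^2)   (i.i.d. per pixel)

where ``U`` is the noise-free photon image, ``g0`` the detector gain and
``(m, sigma_eps)`` the dark-current (read-noise) Gaussian.  The generalized
Anscombe transform

    T(v) = (2/g0) * sqrt(g0*v + (3/8)*g0^2 + sigma_eps^2 - g0*m)

maps such an observation to approximately unit-variance Gaussian noise,
which is what makes a quadratic data-fidelity term valid downstream.  The
argument of the square root is clamped at 0 so the transform is total and
monotone even for low-count pixels after dark-current subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ROI

__all__ = [
    "NoiseParams",
    "degrade",
    "vst_forward",
    "vst_inverse",
    "estimate_params_from_background",
]


@dataclass(frozen=True)
class NoiseParams:
    """Poisson-Gaussian acquisition parameters.

    g0        detector gain on the photon signal (dimensionless, > 0)
    m         mean of the additive Gaussian dark current (intensity units)
    sigma_eps std of the additive Gaussian dark current (>= 0)
    """

    g0: float = 1.0
    m: float = 0.0
    sigma_eps: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.g0, self.m, self.sigma_eps)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"noise parameters must be finite, got {vals}")
        if self.g0 <= 0:
            raise ValueError(f"g0 must be > 0, got {self.g0}")
        if self.sigma_eps < 0:
            raise ValueError(f"sigma_eps must be >= 0, got {self.sigma_eps}")

    def to_dict(self) -> dict:
        return {"g0": self.g0, "m": self.m, "sigma_eps": self.sigma_eps}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseParams":
        return cls(
            g0=float(d.get("g0", 1.0)),
            m=float(d.get("m", 0.0)),
            sigma_eps=float(d.get("sigma_eps", 0.0)),
        )


def degrade(truth, params: NoiseParams, seed) -> np.ndarray:
    """Sample one Poisson-Gaussian acquisition of a photon image.

    Sampling order: Poisson on the photon counts, then gain, then additive
    Gaussian.  Deterministic for a fixed ``seed``.
    """
    u = np.asarray(truth, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("truth image must be finite")
    if np.any(u < 0):
        raise ValueError("truth image must be non-negative (photon counts)")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(u).astype(float)
    v = params.g0 * counts
    v = v + rng.normal(params.m, params.sigma_eps, size=u.shape)
    return v


def _gat_argument(v: np.ndarray, params: NoiseParams) -> np.ndarray:
    return (
        params.g0 * v
        + 0.375 * params.g0**2
        + params.sigma_eps**2
        - params.g0 * params.m
    )


def vst_forward(observed, params: NoiseParams) -> np.ndarray:
    """Generalized Anscombe transform; negative sqrt arguments clamp to 0."""
    v = np.asarray(observed, dtype=float)
    arg = np.maximum(_gat_argument(v, params), 0.0)
    return (2.0 / params.g0) * np.sqrt(arg)


def vst_inverse(transformed, params: NoiseParams) -> np.ndarray:
    """Algebraic inverse of :func:`vst_forward`, clamped to >= 0 output.

    Exact round trip (to floating precision) for values in the forward
    transform's valid domain; values below ``T(0)`` map to 0.
    """
    t = np.asarray(transformed, dtype=float)
    v = (
        (params.g0 * t / 2.0) ** 2
        - 0.375 * params.g0**2
        - params.sigma_eps**2
        + params.g0 * params.m
    ) / params.g0
    return np.maximum(v, 0.0)


def estimate_params_from_background(
    image, background: ROI, g0: float | None = None
) -> NoiseParams:
    """Estimate dark-current parameters from a photon-free background ROI.

    The background is assumed to contain no photon signal, so its sample
    mean and sample std estimate (m, sigma_eps) directly; the gain is then
    unidentifiable from the ROI and defaults to 1 unless supplied.
    """
    img = np.asarray(image, dtype=float)
    if background.area < 100:
        raise ValueError(
            f"background ROI has {background.area} pixels; need >= 100"
        )
    patch = background.extract(img)
    m = float(np.mean(patch))
    sigma_eps = float(np.std(patch, ddof=1))
    return NoiseParams(g0=1.0 if g0 is None else float(g0), m=m, sigma_eps=sigma_eps)
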