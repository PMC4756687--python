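"""Image-quality metrics for denoiser evaluation.

Ground-truth-based metrics (SNR, ISNR, PSNR) are power ratios computed from
mean squared errors and therefore use ``10*log10``.  ROI-based empirical
metrics (SNR, CNR) are amplitude ratios of region statistics and use
``20*log10``.  Degenerate ratios produce IEEE infinities; report
serialization renders them as the strings ``"inf"`` / ``"-inf"``, never as
numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROI",
    "MetricReport",
    "snr_db",
    "isnr_db",
    "psnr_db",
    "roi_snr_db",
    "roi_cnr_db",
    "aggregate_runs",
]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular region: 0-based top-left origin, half-open.

    Covers pixels ``image[y:y+h, x:x+w]``.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1 or self.x < 0 or self.y < 0:
            raise ValueError(f"invalid ROI {self!r}: need x,y >= 0 and w,h >= 1")

    @property
    def area(self) -> int:
        return self.w * self.h

    def validate_within(self, shape: tuple[int, int]) -> None:
        height, width = shape
        if self.y + self.h > height or self.x + self.w > width:
            raise ValueError(
                f"ROI {self!r} exceeds image bounds {height}x{width}"
            )

    def extract(self, image: np.ndarray) -> np.ndarray:
        self.validate_within(image.shape)
        return image[self.y : self.y + self.h, self.x : self.x + self.w]


def _as_pair(truth, estimate) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(truth, dtype=float)
    b = np.asarray(estimate, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def snr_db(truth, estimate) -> float:
    """Signal-to-noise ratio: ``10*log10(sum(u^2) / sum((u - u_hat)^2))``."""
    u, uhat = _as_pair(truth, estimate)
    signal = float(np.sum(u**2))
    if signal == 0.0:
        raise ValueError("snr_db undefined for identically-zero truth")
    err = float(np.sum((u - uhat) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(signal / err)


def isnr_db(truth, noisy, denoised) -> float:
    """Improvement in SNR: ``10*log10(MSE(noisy,truth) / MSE(denoised,truth))``.

    Positive values mean the denoiser moved the image closer to truth.
    """
    u, v = _as_pair(truth, noisy)
    _, uhat = _as_pair(truth, denoised)
    mse_noisy = _mse(v, u)
    mse_den = _mse(uhat, u)
    if mse_den == 0.0:
        return math.inf
    if mse_noisy == 0.0:
        return -math.inf
    return 10.0 * math.log10(mse_noisy / mse_den)


def psnr_db(truth, estimate, max_value: float = 255.0) -> float:
    """Peak SNR: ``10*log10(MAX^2 / MSE(truth, estimate))``."""
    if not max_value > 0:
        raise ValueError("max_value must be > 0")
    u, uhat = _as_pair(truth, estimate)
    mse = _mse(u, uhat)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / mse)


def roi_snr_db(image, cell: ROI, background: ROI) -> float:
    """Empirical SNR: ``20*log10(mean(cell) / std(background))`` in dB."""
    img = np.asarray(image, dtype=float)
    mu_cell = float(np.mean(cell.extract(img)))
    sd_bg = float(np.std(background.extract(img)))
    if mu_cell <= 0:
        raise ValueError("roi_snr_db undefined for non-positive cell mean")
    if sd_bg == 0.0:
        return math.inf
    return 20.0 * math.log10(mu_cell / sd_bg)


def roi_cnr_db(image, cell: ROI, background: ROI) -> float:
    """Contrast-to-noise ratio:
    ``20*log10(|mean(cell) - mean(bg)| / std(bg))`` in dB."""
    img = np.asarray(image, dtype=float)
    mu_cell = float(np.mean(cell.extract(img)))
    mu_bg = float(np.mean(background.extract(img)))
    sd_bg = float(np.std(background.extract(img)))
    contrast = abs(mu_cell - mu_bg)
    if sd_bg == 0.0:
        return math.inf
    if contrast == 0.0:
        return -math.inf
    return 20.0 * math.log10(contrast / sd_bg)


@dataclass
class MetricReport:
    """Metric values for one run, or an aggregate across runs.

    ``values`` maps metric names (``snr_db``, ``isnr_db``, ``psnr_db``,
    ``roi_snr_db``, ``roi_cnr_db``, ...) to dB values; for aggregates these
    are per-metric means.  ``std`` is present only for aggregates over >= 2
    runs; ``n_excluded`` counts non-finite values dropped per metric.
    """

    values: dict[str, float] = field(default_factory=dict)
    n_runs: int = 1
    std: dict[str, float] | None = None
    n_excluded: dict[str, int] | None = None

    def serializable(self) -> dict:
        def fmt(x):
            if x == math.inf:
                return "inf"
            if x == -math.inf:
                return "-inf"
            return x

        out = {
            "values": {k: fmt(v) for k, v in self.values.items()},
            "n_runs": self.n_runs,
        }
        if self.std is not None:
            out["std"] = {k: fmt(v) for k, v in self.std.items()}
        if self.n_excluded:
            out["n_excluded"] = dict(self.n_excluded)
        return out


def compute_report(
    truth,
    noisy,
    denoised,
    max_value: float = 255.0,
    cell: ROI | None = None,
    background: ROI | None = None,
) -> MetricReport:
    """Single-run report: ground-truth metrics plus optional ROI metrics."""
    values = {
        "snr_db": snr_db(truth, denoised),
        "isnr_db": isnr_db(truth, noisy, denoised),
        "psnr_db": psnr_db(truth, denoised, max_value),
        "psnr_noisy_db": psnr_db(truth, noisy, max_value),
    }
    if cell is not None and background is not None:
        values["roi_snr_db"] = roi_snr_db(denoised, cell, background)
        values["roi_cnr_db"] = roi_cnr_db(denoised, cell, background)
    return MetricReport(values=values, n_runs=1)


def aggregate_runs(reports: list[MetricReport]) -> MetricReport:
    """Mean and sample std per metric across runs.

    Non-finite sentinel values are excluded from the moments and counted in
    ``n_excluded``.  Std is reported only when >= 2 finite values remain.
    """
    if not reports:
        raise ValueError("aggregate_runs needs at least one report")
    keys: list[str] = []
    for r in reports:
        for k in r.values:
            if k not in keys:
                keys.append(k)
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    excluded: dict[str, int] = {}
    for k in keys:
        vals = [r.values[k] for r in reports if k in r.values]
        finite = [v for v in vals if math.isfinite(v)]
        n_skip = len(vals) - len(finite)
        if n_skip:
            excluded[k] = n_skip
        if finite:
            means[k] = float(np.mean(finite))
            if len(finite) >= 2:
                stds[k] = float(np.std(finite, ddof=1))
    return MetricReport(
        values=means,
        n_runs=len(reports),
        std=stds if len(reports) >= 2 else None,
        n_excluded=excluded or None,
    )
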