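"""Reading and writing microscopy images (TIFF, PNG).

Integer data are converted to float without rescaling: the VST operates on
count-scale values, so preserving the recorded scale is semantically
required.  Multi-page TIFFs (or channels-last colour images) come back as
one 2-D float array per channel, in file order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("srfdenoise")

__all__ = ["read_image", "write_image"]

_SUPPORTED_DTYPES = (
    np.uint8,
    np.uint16,
    np.int16,
    np.int32,
    np.float32,
    np.float64,
)


def _check_dtype(arr: np.ndarray, path) -> None:
    if not any(arr.dtype == np.dtype(d) for d in _SUPPORTED_DTYPES):
        raise ValueError(
            f"unsupported bit depth in {path}: dtype {arr.dtype} "
            f"(supported: {[np.dtype(d).name for d in _SUPPORTED_DTYPES]})"
        )


def _split_channels(arr: np.ndarray, path) -> list[np.ndarray]:
    if arr.ndim == 2:
        return [arr.astype(np.float64)]
    if arr.ndim == 3:
        # pages/channels first, or conventional channels-last colour
        if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            arr = np.moveaxis(arr, -1, 0)
        return [c.astype(np.float64) for c in arr]
    raise ValueError(
        f"unsupported image layout in {path}: {arr.ndim} dimensions"
    )


def read_image(path) -> list[np.ndarray]:
    """Read a TIFF or PNG as a list of 2-D float64 channels, file order.

    Integer values are preserved exactly (no [0, 1] rescaling).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(p)
    else:
        raise ValueError(f"unsupported file format: {suffix!r} ({p})")
    arr = np.asarray(arr)
    _check_dtype(arr, p)
    return _split_channels(arr, p)


def write_image(image, path, dtype_policy: str = "float32") -> None:
    """Write one channel (or a channel stack) to TIFF or PNG.

    ``dtype_policy``: ``float32`` (default, lossless round trip for float32
    data), ``uint8`` or ``uint16`` (values clipped to the type's range —
    logged when clipping occurs — and rounded half-to-even).
    """
    arr = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image must be finite")
    p = Path(path)
    if dtype_policy == "float32":
        out = arr.astype(np.float32)
    elif dtype_policy in ("uint8", "uint16"):
        hi = 255 if dtype_policy == "uint8" else 65535
        n_clip = int(np.sum((arr < 0) | (arr > hi)))
        if n_clip:
            logger.warning(
                "write_image(%s): clipped %d pixel(s) to [0, %d] for %s export",
                p, n_clip, hi, dtype_policy,
            )
        out = np.rint(np.clip(arr, 0, hi)).astype(dtype_policy)
    else:
        raise ValueError(f"unknown dtype_policy {dtype_policy!r}")
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(p, out)
    elif suffix == ".png":
        import imageio.v3 as iio

        if out.dtype == np.float32:
            raise ValueError("PNG export requires dtype_policy uint8 or uint16")
        iio.imwrite(p, out)
    else:
        raise ValueError(f"unsupported file format: {suffix!r} ({p})")
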