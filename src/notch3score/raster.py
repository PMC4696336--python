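"""Raster input/output and grayscale conversion.

All images are numpy arrays with the conventions shared by every module in
the package: row-major layout, origin at the top-left corner, 0-based
indices, half-open crops.  The working representation for scoring is an
8-bit grayscale image (``uint8``, shape ``(H, W)``); color micrographs are
``uint8`` arrays of shape ``(H, W, 3)``.  Binary masks are boolean arrays
of shape ``(H, W)``.

Inputs with more than 8 bits per channel are rejected rather than
rescaled: the scoring thresholds (150 for mouse sections, 100 for human
sections) are defined on the 0-255 scale and silent rescaling would change
their meaning.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ParameterError

#: Unweighted channel mean, the default RGB -> 8-bit conversion.
GRAY_WEIGHTS_EQUAL = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

#: Classic luma weights, offered as an alternative conversion.
GRAY_WEIGHTS_LUMA = (0.30, 0.59, 0.11)


def round_half_up8(x: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half-up to uint8.

    Half-up (76.5 -> 77) is the conventional rounding of interactive
    image tools; numpy's default rint rounds half to even.
    """
    return np.floor(np.clip(x, 0, 255) + 0.5).astype(np.uint8)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a TIFF/PNG micrograph as uint8 RGB or grayscale.

    Grayscale files load directly as 2-D ``uint8`` arrays; color files as
    ``(H, W, 3)`` (an alpha channel, if present, is dropped).  Files with
    more than 8 bits per channel raise :class:`FormatError` naming the
    offending depth.
    """
    arr = np.asarray(iio.imread(path))
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: unsupported bit depth {arr.dtype} "
            f"(only 8 bits per channel are supported)"
        )
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return np.ascontiguousarray(arr[:, :, :3])
    raise FormatError(f"{path}: unsupported raster layout with shape {arr.shape}")


def save_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write an 8-bit grayscale or RGB image to PNG/TIFF (lossless)."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        raise FormatError(f"can only write uint8 rasters, got {arr.dtype}")
    iio.imwrite(path, arr)


def to_gray8(
    img: np.ndarray,
    weights: tuple[float, float, float] = GRAY_WEIGHTS_EQUAL,
) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale by a weighted channel sum.

    Each output pixel is ``round(w_R*R + w_G*G + w_B*B)`` clipped to
    [0, 255].  Weights must be non-negative and sum to 1 (within 1e-9).
    A 2-D input is assumed to be grayscale already and is returned as a
    uint8 copy, so the conversion is idempotent.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,):
        raise ParameterError(f"expected 3 channel weights, got {weights!r}")
    if np.any(w < 0):
        raise ParameterError(f"channel weights must be non-negative, got {weights!r}")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ParameterError(f"channel weights must sum to 1, got sum {w.sum()!r}")

    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=True)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(f"expected an RGB image, got shape {arr.shape}")
    gray = arr[:, :, :3].astype(np.float64) @ w
    return round_half_up8(gray)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary region mask: nonzero pixels are members.

    Color mask files are accepted; a pixel is a member if any channel is
    nonzero.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        return arr.any(axis=2)
    return arr != 0


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit raster (members = 255)."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool).astype(np.uint8) * 255))
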