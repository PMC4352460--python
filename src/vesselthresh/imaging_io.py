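"""Image, mask and ground-truth I/O plus field-of-view derivation.

All readers normalize to the package-wide conventions: grayscale images
are ``float64`` in ``[0, 1]``; binary maps are ``bool``.  Fundus images
are stored in ordinary raster formats (PNG/TIFF/PPM/GIF); masks and
ground truth are single-channel images where any nonzero pixel means
inside / vessel.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Map an integer image to float64 in [0, 1]; pass floats through."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    out = arr.astype(np.float64)
    if out.size and out.max() > 1.0 + 1e-9:
        # float file on an 8-bit scale
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def read_fundus_image(path: str | Path) -> np.ndarray:
    """Read a fundus photograph as float64 in [0, 1].

    Returns a ``(H, W)`` array for single-channel files and ``(H, W, 3)``
    for color files; an alpha channel, if present, is dropped.

    Raises
    ------
    IOError
        If the file is missing or not a decodable raster image.
    ValueError
        If the channel count is neither 1 nor 3 (after dropping alpha).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise IOError(f"cannot read image file: {path} (not found)")
    except Exception as exc:  # undecodable / truncated
        raise IOError(f"cannot read image file: {path} ({exc})")
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 2:
        return _to_unit_float(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return _to_unit_float(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return _to_unit_float(arr[:, :, 0])
    raise ValueError(
        f"unsupported channel count in {path}: shape {arr.shape}; "
        "expected 1 or 3 channels"
    )


def extract_green_channel(img: np.ndarray) -> np.ndarray:
    """Return the green plane of an RGB image, values untouched.

    Vessels have their best contrast against the retinal background in
    the green channel, so every pipeline starts here.  A single-channel
    input is returned unchanged (with a logged notice) so grayscale
    files flow through the same pipelines.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        logger.info("extract_green_channel: input already single-channel")
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        return img[:, :, 1]
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {img.shape}")


def derive_fov_mask(img: np.ndarray, threshold_fraction: float = 0.15) -> np.ndarray:
    """Estimate the circular field-of-view mask from image brightness.

    The camera aperture is much brighter than the surrounding black
    frame, so the mask is taken as the largest connected component of
    ``{pixels > threshold_fraction * max}``, hole-filled.  When the
    input is color the red channel is used (strongest disc/background
    contrast).

    Parameters
    ----------
    img : ndarray
        Gray ``(H, W)`` or color ``(H, W, 3)`` image in [0, 1].
    threshold_fraction : float
        Fraction of the maximum intensity used as the cut, in (0, 1).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    img = np.asarray(img, dtype=np.float64)
    plane = img[:, :, 0] if img.ndim == 3 else img
    rough = plane > threshold_fraction * plane.max()
    if not rough.any():
        raise ValueError("degenerate input: no pixels above the FOV threshold")
    labels, n = ndimage.label(rough, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(rough, labels, index=np.arange(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def read_binary_map(path: str | Path) -> np.ndarray:
    """Read a mask / ground-truth image: nonzero pixels become True."""
    arr = read_fundus_image(path)
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return arr > 0


def write_binary_map(path: str | Path, bmap: np.ndarray) -> None:
    """Write a binary map as an 8-bit PNG (0 background, 255 vessel)."""
    bmap = np.asarray(bmap, dtype=bool)
    iio.imwrite(Path(path), (bmap.astype(np.uint8) * 255))


def write_gray_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] gray image as 8-bit PNG."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))
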