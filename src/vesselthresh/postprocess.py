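"""Morphological cleanup of thresholded vessel maps.

Three chains of increasing elaborateness:

* ``MO``   — morphological opening;
* ``MOMF`` — majority (median) filter, then opening;
* ``ATC``  — "all techniques combined": MOMF, then openings with line
  structuring elements in five directions (0, 30, 60, 120, 150
  degrees) OR-ed together, then morphological reconstruction of the
  directional response inside the MOMF map.

Openings and reconstruction are anti-extensive, so each chain can only
remove pixels relative to its opening input; the median step may fill
small gaps first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

__all__ = [
    "PostprocessSpec",
    "line_strel",
    "median_clean",
    "open_binary",
    "directional_filter",
    "reconstruct",
    "run_chain",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity everywhere


@dataclass
class PostprocessSpec:
    """Configuration of one cleanup chain.

    chain
        ``"MO"``, ``"MOMF"`` or ``"ATC"`` (case-insensitive).
    median_window
        Majority-filter window (default 2x2, anchored top-left).
    opening_se
        Structuring element of the plain opening; default 2x2 square.
    line_length
        Length in pixels of the directional line structuring elements.
        A length of 1 degenerates every line opening to the identity
        and is selectable but not the default.
    line_angles
        Directions of the line elements, degrees in [0, 180).
    """

    chain: str = "MO"
    median_window: tuple[int, int] = (2, 2)
    opening_se: np.ndarray | None = None
    line_length: int = 9
    line_angles: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0, 150.0)

    def __post_init__(self) -> None:
        self.chain = self.chain.upper()
        if self.chain not in ("MO", "MOMF", "ATC"):
            raise ValueError("chain must be one of MO, MOMF, ATC")
        if self.opening_se is None:
            self.opening_se = np.ones((2, 2), dtype=bool)
        if self.line_length < 1:
            raise ValueError("line_length must be >= 1")
        if any(not 0.0 <= a < 180.0 for a in self.line_angles):
            raise ValueError("line_angles must lie in [0, 180)")


def line_strel(length: int, angle_deg: float) -> np.ndarray:
    """Digital line structuring element of a given length and angle.

    The line passes through the center of an odd-sized footprint;
    angles follow the math convention (0 = horizontal, counter-
    clockwise positive with +y up, hence -row).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length == 1:
        return np.ones((1, 1), dtype=bool)
    theta = np.deg2rad(angle_deg)
    half = (length - 1) / 2.0
    dr = int(round(-half * np.sin(theta)))
    dc = int(round(half * np.cos(theta)))
    size_r, size_c = 2 * abs(dr) + 1, 2 * abs(dc) + 1
    se = np.zeros((size_r, size_c), dtype=bool)
    rr, cc = draw_line(abs(dr) - dr, abs(dc) - dc, abs(dr) + dr, abs(dc) + dc)
    se[rr, cc] = True
    return se


def median_clean(bmap: np.ndarray, window: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Majority vote over a sliding window on a binary map.

    Restores connectivity across 1-pixel gaps and deletes isolated
    speckle.  Even windows are anchored at the top-left pixel with
    symmetric padding; ties resolve toward background (noise-removal
    bias).
    """
    bmap = np.asarray(bmap, dtype=bool)
    h, w = window
    if h < 1 or w < 1:
        raise ValueError("window must be >= 1x1")
    oy = -(h // 2) if h % 2 == 0 else 0
    ox = -(w // 2) if w % 2 == 0 else 0
    counts = ndimage.correlate(
        bmap.astype(np.int64), np.ones((h, w), dtype=np.int64),
        mode="reflect", origin=(oy, ox),
    )
    return counts * 2 > h * w  # strict majority; ties -> background


def open_binary(bmap: np.ndarray, se: np.ndarray | None = None) -> np.ndarray:
    """Morphological opening (erosion then dilation); anti-extensive."""
    bmap = np.asarray(bmap, dtype=bool)
    if se is None:
        se = np.ones((2, 2), dtype=bool)
    se = np.asarray(se, dtype=bool)
    return ndimage.binary_opening(bmap, structure=se)


def directional_filter(
    bmap: np.ndarray,
    length: int = 9,
    angles: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0, 150.0),
) -> np.ndarray:
    """OR of line openings along several directions.

    Keeps any pixel supported by a line-like run of at least ``length``
    pixels in one of the directions; isolated blobs smaller than the
    lines vanish in every direction and so vanish from the union.
    """
    bmap = np.asarray(bmap, dtype=bool)
    out = np.zeros_like(bmap)
    for angle in angles:
        out |= open_binary(bmap, line_strel(length, angle))
    return out


def reconstruct(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Binary morphological reconstruction of ``marker`` inside ``mask``.

    Equivalent to geodesic dilation to stability: the union of the
    8-connected components of ``mask`` that intersect ``marker``.
    ``marker`` must be a subset of ``mask``.
    """
    marker = np.asarray(marker, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if marker.shape != mask.shape:
        raise ValueError("marker and mask must share a shape")
    if (marker & ~mask).any():
        raise ValueError("marker must be a subset of mask")
    if not marker.any():
        return np.zeros_like(mask)
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    keep = np.unique(labels[marker])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def run_chain(bmap: np.ndarray, spec: PostprocessSpec | None = None) -> np.ndarray:
    """Apply one of the MO / MOMF / ATC cleanup chains."""
    spec = spec or PostprocessSpec()
    bmap = np.asarray(bmap, dtype=bool)
    if spec.chain == "MO":
        return open_binary(bmap, spec.opening_se)
    momf = open_binary(median_clean(bmap, spec.median_window), spec.opening_se)
    if spec.chain == "MOMF":
        return momf
    directional = directional_filter(momf, spec.line_length, spec.line_angles)
    return reconstruct(directional, momf)
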