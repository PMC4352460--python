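"""Contrast enhancement and smoothing of the green channel.

CLAHE (contrast-limited adaptive histogram equalization) partitions the
image into contextual tiles, equalizes each tile's histogram after
clipping it at a limit ``beta`` (the clipped excess is redistributed
evenly over all bins, so histogram mass is conserved), maps each
intensity to its fractional rank ``r in [0, 1]`` within the tile, and
emits ``i_out = i1 + r * (i2 - i1)``.  Tile mappings are blended
bilinearly between tile centers so no seams appear.

Four smoothing variants are provided: an adaptive (local Wiener) noise
filter, a box average, a Gaussian, and average-then-Gaussian in
composition.  Borders are handled by symmetric reflection; even-sized
windows are anchored at the top-left pixel of the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CLAHEParams",
    "FilterSpec",
    "clip_histogram",
    "clahe_equalize",
    "smooth",
]


@dataclass
class CLAHEParams:
    """CLAHE tuning constants.

    clip_limit
        Fraction ``beta`` of the tile pixel count at which each
        histogram bin is clipped (``beta * m * m`` counts per bin);
        ``beta = 1`` disables clipping.
    tile_size
        Contextual-region size in pixels, ``(m, m)`` when an int.
        With ``tile_units="grid"`` the same numbers are read as the
        number of tiles along each axis instead.
    output_range
        ``(i1, i2)`` interval of the mapped intensities.
    n_bins
        Histogram resolution ``N``.
    """

    clip_limit: float = 0.04
    tile_size: tuple[int, int] | int = (75, 75)
    output_range: tuple[float, float] = (0.0, 1.0)
    n_bins: int = 256
    tile_units: str = "pixels"  # or "grid"

    def __post_init__(self) -> None:
        if isinstance(self.tile_size, int):
            self.tile_size = (self.tile_size, self.tile_size)
        if not 0.0 < self.clip_limit <= 1.0:
            raise ValueError("clip_limit must lie in (0, 1]")
        if min(self.tile_size) < 2:
            raise ValueError("tile_size must be >= 2")
        i1, i2 = self.output_range
        if not i1 < i2:
            raise ValueError("output_range must satisfy i1 < i2")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.tile_units not in ("pixels", "grid"):
            raise ValueError("tile_units must be 'pixels' or 'grid'")


def clip_histogram(hist: np.ndarray, clip: float) -> np.ndarray:
    """Clip bins at ``clip`` and spread the excess evenly over all bins.

    Total mass is conserved exactly (the renormalization that keeps
    ranks comparable between tiles with different clip losses).
    """
    hist = np.asarray(hist, dtype=np.float64)
    excess = np.maximum(hist - clip, 0.0).sum()
    return np.minimum(hist, clip) + excess / hist.size


def _tile_grid(shape: tuple[int, int], params: CLAHEParams) -> tuple[int, int, int, int]:
    """Resolve (tile_h, tile_w, n_ty, n_tx) for an image shape."""
    H, W = shape
    if params.tile_units == "grid":
        n_ty, n_tx = params.tile_size
        n_ty, n_tx = min(n_ty, H), min(n_tx, W)
        tile_h = int(np.ceil(H / n_ty))
        tile_w = int(np.ceil(W / n_tx))
    else:
        tile_h, tile_w = params.tile_size
        if tile_h > H or tile_w > W:
            raise ValueError(
                f"image {shape} smaller than one {tile_h}x{tile_w} tile"
            )
        n_ty = int(np.ceil(H / tile_h))
        n_tx = int(np.ceil(W / tile_w))
    return tile_h, tile_w, n_ty, n_tx


def clahe_equalize(img: np.ndarray, params: CLAHEParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    Each tile's clipped-histogram CDF gives a monotone rank map; a
    pixel's output is the bilinear blend of the four surrounding tile
    maps evaluated at its intensity, scaled into ``output_range``.
    """
    params = params or CLAHEParams()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("clahe_equalize expects a 2-D gray image")
    H, W = img.shape
    tile_h, tile_w, n_ty, n_tx = _tile_grid(img.shape, params)
    N = params.n_bins

    # pad (reflect) so the tile grid covers the image exactly
    pad_y, pad_x = n_ty * tile_h - H, n_tx * tile_w - W
    padded = np.pad(img, ((0, pad_y), (0, pad_x)), mode="symmetric")

    bins = np.clip((padded * N).astype(np.int64), 0, N - 1)
    area = tile_h * tile_w
    clip = params.clip_limit * area

    # per-tile clipped-CDF lookup tables: rank in [0, 1]
    luts = np.empty((n_ty, n_tx, N), dtype=np.float64)
    for ty in range(n_ty):
        for tx in range(n_tx):
            tile = bins[ty * tile_h:(ty + 1) * tile_h, tx * tile_w:(tx + 1) * tile_w]
            hist = np.bincount(tile.ravel(), minlength=N).astype(np.float64)
            hist = clip_histogram(hist, clip)
            luts[ty, tx] = np.cumsum(hist) / area

    # bilinear blend between tile-center mappings
    rows = np.arange(H, dtype=np.float64)
    cols = np.arange(W, dtype=np.float64)
    gy = np.clip((rows - (tile_h - 1) / 2.0) / tile_h, 0.0, n_ty - 1.0)
    gx = np.clip((cols - (tile_w - 1) / 2.0) / tile_w, 0.0, n_tx - 1.0)
    y0 = np.minimum(gy.astype(np.int64), n_ty - 1)
    x0 = np.minimum(gx.astype(np.int64), n_tx - 1)
    y1 = np.minimum(y0 + 1, n_ty - 1)
    x1 = np.minimum(x0 + 1, n_tx - 1)
    wy = (gy - y0)[:, None]
    wx = (gx - x0)[None, :]

    b = bins[:H, :W]
    Y0 = y0[:, None]
    Y1 = y1[:, None]
    X0 = x0[None, :]
    X1 = x1[None, :]
    r = (
        (1 - wy) * (1 - wx) * luts[Y0, X0, b]
        + (1 - wy) * wx * luts[Y0, X1, b]
        + wy * (1 - wx) * luts[Y1, X0, b]
        + wy * wx * luts[Y1, X1, b]
    )
    i1, i2 = params.output_range
    return i1 + r * (i2 - i1)


@dataclass
class FilterSpec:
    """One of the four smoothing variants.

    kind
        ``adaptive`` (local Wiener noise filter), ``average`` (box),
        ``gaussian``, or ``average_then_gaussian``.
    window
        Filter window, ``(h, w)`` when a pair.  Defaults per kind:
        4x4 adaptive, 3x3 otherwise.
    sigma
        Gaussian standard deviation in pixels (gaussian kinds only).
    """

    kind: str = "average"
    window: tuple[int, int] | int | None = None
    sigma: float = 0.5

    _DEFAULT_WINDOWS = {
        "adaptive": (4, 4),
        "average": (3, 3),
        "gaussian": (3, 3),
        "average_then_gaussian": (3, 3),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._DEFAULT_WINDOWS:
            raise ValueError(
                f"unknown filter kind {self.kind!r}; expected one of "
                f"{sorted(self._DEFAULT_WINDOWS)}"
            )
        if self.window is None:
            self.window = self._DEFAULT_WINDOWS[self.kind]
        if isinstance(self.window, int):
            self.window = (self.window, self.window)
        if min(self.window) < 1:
            raise ValueError("window must be >= 1x1")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _box_filter(img: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Box mean with reflect borders; even windows anchored top-left.

    A top-left anchor means output pixel (i, j) averages the window
    ``img[i:i+h, j:j+w]``.
    """
    h, w = window
    # scipy centers a size-s kernel at offsets [-(s//2), s-1-s//2];
    # origin -(s//2) shifts an even window to start at the pixel itself
    oy = -(h // 2) if h % 2 == 0 else 0
    ox = -(w // 2) if w % 2 == 0 else 0
    kernel = np.full((h, w), 1.0 / (h * w))
    return ndimage.correlate(img, kernel, mode="reflect", origin=(oy, ox))


def _wiener(img: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Local Wiener noise filter (adaptive): shrink toward the local
    mean in proportion to how much local variance exceeds the global
    noise-variance estimate (the mean of the local variances)."""
    m = _box_filter(img, window)
    m2 = _box_filter(img * img, window)
    var = np.maximum(m2 - m * m, 0.0)
    noise = var.mean()
    gain = np.zeros_like(var)
    np.divide(var - noise, var, out=gain, where=var > noise)
    return m + gain * (img - m)


def _gaussian(img: np.ndarray, window: tuple[int, int], sigma: float) -> np.ndarray:
    # truncate so the discrete kernel support matches the window
    radius = max((max(window) - 1) // 2, 1)
    return ndimage.gaussian_filter(
        img, sigma=sigma, mode="reflect", truncate=radius / sigma
    )


def smooth(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply one of the smoothing variants; see :class:`FilterSpec`."""
    img = np.asarray(img, dtype=np.float64)
    if spec.kind == "average":
        return _box_filter(img, spec.window)
    if spec.kind == "gaussian":
        return _gaussian(img, spec.window, spec.sigma)
    if spec.kind == "average_then_gaussian":
        return _gaussian(_box_filter(img, spec.window), spec.window, spec.sigma)
    if spec.kind == "adaptive":
        return _wiener(img, spec.window)
    raise ValueError(f"unknown filter kind {spec.kind!r}")
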