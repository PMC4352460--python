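"""Global threshold selection: Otsu, ISODATA, and the GLCM/IDM rule.

Otsu picks the histogram cut maximizing the between-class variance
``sigma_b^2(t) = w1 w2 (mu1 - mu2)^2``; ISODATA iterates
``t <- (m1 + m2) / 2`` on the two partition means to a fixed point.

The inverse-difference-moment (IDM) rule derives a threshold from image
texture rather than the histogram: gray-level co-occurrence matrices
(GLCMs) are computed for four distances ``d`` and four orientations
``Phi`` (0, 45, 90, 135 degrees), the IDM feature of each is arranged
in a 4x4 matrix ``F``, the per-orientation range (max - min over
distances) gives a row vector ``R_Phi``, and the threshold is
``Th = max(R_Phi) + mean(R_Phi)``, applied to the [0, 1]-rescaled,
average-filtered phase-congruency map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram",
    "IDMThresholdResult",
    "otsu_threshold",
    "variance_decomposition",
    "isodata_threshold",
    "quantize",
    "compute_glcm",
    "idm_feature",
    "idm_threshold",
    "binarize",
    "ORIENTATIONS_DEG",
]

#: the four standard co-occurrence orientations, degrees
ORIENTATIONS_DEG = (0, 45, 90, 135)


@dataclass
class Histogram:
    """Intensity histogram with explicit bin centers."""

    counts: np.ndarray
    bin_centers: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        if self.counts.ndim != 1 or self.counts.shape != self.bin_centers.shape:
            raise ValueError("counts and bin_centers must be matching 1-D arrays")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be nonnegative")
        if self.counts.sum() <= 0:
            raise ValueError("histogram is empty")

    @classmethod
    def from_image(
        cls,
        img: np.ndarray,
        n_bins: int = 256,
        value_range: tuple[float, float] = (0.0, 1.0),
        mask: np.ndarray | None = None,
    ) -> "Histogram":
        img = np.asarray(img, dtype=np.float64)
        values = img[np.asarray(mask, dtype=bool)] if mask is not None else img.ravel()
        counts, edges = np.histogram(values, bins=n_bins, range=value_range)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return cls(counts.astype(np.float64), centers)

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def mean(self) -> float:
        return float(np.dot(self.probabilities, self.bin_centers))


def variance_decomposition(hist: Histogram) -> tuple[float, np.ndarray, np.ndarray]:
    """Total, within-class and between-class variance at every cut.

    The cut at index ``t`` puts bins ``0..t`` in class 1 and the rest
    in class 2 (``t`` runs over ``0..n_bins-2``).  The decomposition
    ``sigma^2 = sigma_w^2(t) + sigma_b^2(t)`` holds identically.
    """
    p = hist.probabilities
    x = hist.bin_centers
    w1 = np.cumsum(p)[:-1]
    m1 = np.cumsum(p * x)[:-1]
    mu_total = float(np.dot(p, x))
    var_total = float(np.dot(p, (x - mu_total) ** 2))

    w2 = 1.0 - w1
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = m1 / w1
        mu2 = (mu_total - m1) / w2
        sigma_b = w1 * w2 * (mu1 - mu2) ** 2
        # within-class: weighted second moments about the class means
        ex2 = np.cumsum(p * x * x)[:-1]
        var1 = ex2 / w1 - mu1**2
        var2 = (np.dot(p, x * x) - ex2) / w2 - mu2**2
        sigma_w = w1 * var1 + w2 * var2
    sigma_b = np.where((w1 > 0) & (w2 > 0), sigma_b, 0.0)
    sigma_w = np.where((w1 > 0) & (w2 > 0), sigma_w, var_total)
    return var_total, sigma_w, sigma_b


def otsu_threshold(hist: Histogram) -> float:
    """Otsu's threshold: the bin-center value at the cut maximizing the
    between-class variance; the smallest maximizing cut wins ties.

    The returned value ``x(t*)`` is the center of the last bin of the
    lower class (binarize with ``value > t*``).
    """
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonempty bins")
    _, _, sigma_b = variance_decomposition(hist)
    # smallest t attaining the maximum; the tolerance keeps the
    # tie-break stable across the flat plateaus left by empty bins
    peak = sigma_b.max()
    t_star = int(np.argmax(sigma_b >= peak - 1e-12 * max(1.0, peak)))
    return float(hist.bin_centers[t_star])


def isodata_threshold(
    hist: Histogram,
    t0: float | None = None,
    tol: float | None = None,
    max_iter: int = 500,
) -> float:
    """ISODATA (iterative intermeans) threshold on a histogram.

    Starting from ``t0`` (default: the global mean intensity), iterate
    ``t <- (m1 + m2) / 2`` where ``m1``/``m2`` are the mean bin-center
    values of the histogram mass at values ``<= t`` / ``> t``, until
    the change falls below ``tol`` (default: half a bin width).  An
    empty partition reuses the previous partition's mean.
    """
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonempty bins")
    x = hist.bin_centers
    p = hist.probabilities
    if tol is None:
        widths = np.diff(x)
        tol = 0.5 * float(widths.min()) if widths.size else 0.5
    t = hist.mean if t0 is None else float(t0)

    m1_prev = m2_prev = t
    for _ in range(max_iter):
        low = x <= t
        w_low = p[low].sum()
        w_high = p[~low].sum()
        m1 = float(np.dot(p[low], x[low]) / w_low) if w_low > 0 else m1_prev
        m2 = float(np.dot(p[~low], x[~low]) / w_high) if w_high > 0 else m2_prev
        m1_prev, m2_prev = m1, m2
        t_new = 0.5 * (m1 + m2)
        if abs(t_new - t) < tol:
            # t is a fixed point to within tol (its own update moved
            # less than tol); returning it keeps that property exact
            return t
        t = t_new
    raise RuntimeError(f"ISODATA did not converge within {max_iter} iterations")


def quantize(img: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantize a [0, 1] image to integer levels ``0..n_levels-1``."""
    img = np.asarray(img, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
        raise ValueError("quantize expects intensities in [0, 1]")
    return np.minimum((np.clip(img, 0.0, 1.0) * n_levels).astype(np.intp), n_levels - 1)


def _offset(d: int, phi_deg: int) -> tuple[int, int]:
    """(row, col) displacement for distance d at orientation phi."""
    try:
        dr, dc = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[phi_deg]
    except KeyError:
        raise ValueError(f"phi must be one of {ORIENTATIONS_DEG}, got {phi_deg}")
    return dr * d, dc * d


def compute_glcm(
    quantized: np.ndarray, d: int, phi_deg: int, n_levels: int
) -> tuple[np.ndarray, int]:
    """Symmetric gray-level co-occurrence matrix.

    Counts ordered pixel pairs separated by the displacement of length
    ``d`` along orientation ``phi`` (0 = horizontal, 45 = diagonal,
    90 = vertical, 135 = antidiagonal); both the + and - displacement
    are counted, so the matrix is symmetric.

    Returns ``(C, R)``: integer counts ``C[i, j]`` and the total pair
    count ``R`` (normalize as ``p = C / R``).
    """
    quantized = np.asarray(quantized)
    if not np.issubdtype(quantized.dtype, np.integer):
        raise ValueError("compute_glcm expects an integer-quantized image")
    if d < 1:
        raise ValueError("distance d must be >= 1")
    dr, dc = _offset(d, phi_deg)
    H, W = quantized.shape
    if abs(dr) >= H or abs(dc) >= W:
        raise ValueError(f"offset d={d}, phi={phi_deg} exceeds image extent {H}x{W}")
    if quantized.min() < 0 or quantized.max() >= n_levels:
        raise ValueError("quantized levels out of range for n_levels")
    # diagonal displacements are d steps along the lattice direction
    # ((d, d) at 45 degrees), keeping the four distances distinct at
    # every orientation
    a = quantized[max(0, -dr):H - max(0, dr), max(0, -dc):W - max(0, dc)]
    b = quantized[max(0, dr):H + min(0, dr), max(0, dc):W + min(0, dc)]
    pairs = np.bincount(
        (a.ravel() * n_levels + b.ravel()).astype(np.int64),
        minlength=n_levels * n_levels,
    ).reshape(n_levels, n_levels)
    C = pairs + pairs.T  # count both +d and -d displacements
    return C, int(C.sum())


def idm_feature(p: np.ndarray, denominator: str = "plus") -> float:
    """Inverse difference moment of a normalized co-occurrence matrix.

    ``sum_ij p(i, j) / (1 + (i + j)^2)`` with the default ``plus``
    denominator; ``denominator="minus"`` selects the classical
    ``1 + (i - j)^2`` form.
    """
    p = np.asarray(p, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("idm_feature expects a normalized matrix (sum == 1)")
    i, j = np.indices(p.shape)
    if denominator == "plus":
        w = 1.0 / (1.0 + (i + j) ** 2)
    elif denominator == "minus":
        w = 1.0 / (1.0 + (i - j) ** 2)
    else:
        raise ValueError("denominator must be 'plus' or 'minus'")
    return float((p * w).sum())


@dataclass
class IDMThresholdResult:
    """The 4x4 IDM feature matrix and the derived threshold.

    ``F[i, j] = IDM(d_i, Phi_j)`` (rows: distances, columns:
    orientations 0/45/90/135 degrees); ``r_phi`` holds the range of
    each column of ``F``; ``threshold = max(r_phi) + mean(r_phi)``.
    """

    F: np.ndarray
    r_phi: np.ndarray
    threshold: float
    distances: tuple[int, ...] = (1, 2, 3, 4)
    orientations_deg: tuple[int, ...] = ORIENTATIONS_DEG


def idm_threshold(
    img: np.ndarray,
    distances: tuple[int, int, int, int] = (1, 2, 3, 4),
    n_levels: int = 16,
    denominator: str = "plus",
    range_axis: str = "column",
) -> IDMThresholdResult:
    """Texture-derived global threshold from multiscale IDM features.

    ``img`` should be the average-filtered phase-congruency map,
    rescaled to [0, 1]; the returned threshold applies to it directly.
    ``range_axis="column"`` (default) takes the range of each column of
    ``F`` (over distances, per orientation); ``"row"`` the transposed
    reading.  A constant image produces a zero threshold, flagged with
    a degenerate-threshold warning.
    """
    q = quantize(img, n_levels)
    F = np.empty((len(distances), len(ORIENTATIONS_DEG)))
    for a, d in enumerate(distances):
        for b, phi in enumerate(ORIENTATIONS_DEG):
            C, R = compute_glcm(q, d, phi, n_levels)
            F[a, b] = idm_feature(C / R, denominator=denominator)
    if range_axis == "column":
        r_phi = F.max(axis=0) - F.min(axis=0)
    elif range_axis == "row":
        r_phi = F.max(axis=1) - F.min(axis=1)
    else:
        raise ValueError("range_axis must be 'column' or 'row'")
    th = float(r_phi.max() + r_phi.mean())
    if th <= 0.0:
        warnings.warn(
            "degenerate IDM threshold (constant texture): Th = 0", stacklevel=2
        )
        th = 0.0
    th = min(th, 1.0)
    return IDMThresholdResult(
        F=F, r_phi=r_phi, threshold=th,
        distances=tuple(distances),
    )


def binarize(img: np.ndarray, t: float, polarity: str = "bright") -> np.ndarray:
    """Threshold an image into a boolean vessel map.

    ``polarity="bright"`` marks pixels ``> t`` (vessels bright, as in a
    phase-congruency map); ``"dark"`` marks pixels ``< t`` (vessels
    dark, as in the CLAHE-enhanced green channel).
    """
    img = np.asarray(img, dtype=np.float64)
    if polarity == "bright":
        return img > t
    if polarity == "dark":
        return img < t
    raise ValueError("polarity must be 'bright' or 'dark'")
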