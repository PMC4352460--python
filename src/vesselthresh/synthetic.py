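"""Fundus-like phantoms with known vessel ground truth.

A phantom emulates the green channel of a retinal photograph: a bright
background with a smooth low-order illumination field, a circular
camera field of view (FOV) on a dark surround, darker tubular vessels
with Gaussian cross-sectional intensity profiles (the standard model of
vessel cross sections), optional bright disk "lesions", and additive
Gaussian noise.  Vessels are laid down as recursive branching trees of
straight centerline segments whose widths taper at each branching.

Ground truth is defined geometrically — a pixel is vessel iff it lies
within half a width of some centerline — so rendering noise can never
leak into the labels.  The same seed always yields the same phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomSpec", "Phantom", "Segment", "render", "generate_phantom"]


#: one straight centerline piece: endpoints (row, col) and width in pixels
Segment = tuple[tuple[float, float], tuple[float, float], float]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; defaults depict a plausible healthy fundus.

    size, fov_radius
        Image extent and camera-aperture radius, pixels.
    n_vessel_trees, branch_depth
        Number of vessel trees rooted near the FOV rim and how many
        binary branchings each undergoes.
    width_range
        (min, max) vessel widths in pixels; roots start near the max
        and widths shrink by 0.8 per branching, floored at the min.
    vessel_contrast
        Intensity drop at a vessel centerline relative to background.
    profile_sigma
        Gaussian cross-section std as a fraction of the vessel width;
        the default 0.25 puts the half-width boundary at 2 sigma, so
        the labeled width matches the visually apparent vessel width.
    illumination_gradient
        Peak amplitude of the smooth (quadratic) illumination field.
    noise_sigma
        Std of the additive Gaussian noise.
    lesion_count
        Number of bright disk lesions (0 = healthy retina).
    """

    size: tuple[int, int] = (256, 256)
    fov_radius: float = 120.0
    n_vessel_trees: int = 3
    branch_depth: int = 3
    width_range: tuple[float, float] = (2.0, 6.0)
    vessel_contrast: float = 0.35
    profile_sigma: float = 0.25
    illumination_gradient: float = 0.12
    noise_sigma: float = 0.05
    lesion_count: int = 0
    background_level: float = 0.78
    outside_level: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_range[0] < 1.0:
            raise ValueError("vessel widths must be >= 1 pixel")
        if self.fov_radius <= 0:
            raise ValueError("fov_radius must be positive")
        if self.vessel_contrast <= 0:
            raise ValueError("vessel_contrast must be positive")


@dataclass(frozen=True)
class Phantom:
    """A rendered phantom: image in [0, 1], truth and FOV masks."""

    image: np.ndarray
    truth: np.ndarray
    fov: np.ndarray
    spec: PhantomSpec
    segments: tuple[Segment, ...] = ()


def _fov_disk(spec: PhantomSpec) -> np.ndarray:
    H, W = spec.size
    rr, cc = np.mgrid[0:H, 0:W]
    return (rr - (H - 1) / 2.0) ** 2 + (cc - (W - 1) / 2.0) ** 2 <= spec.fov_radius**2


def _tree_segments(spec: PhantomSpec, rng: np.random.Generator) -> list[Segment]:
    """Recursive branching centerline trees rooted near the FOV rim."""
    H, W = spec.size
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    wmin, wmax = spec.width_range
    segments: list[Segment] = []

    def grow(p: np.ndarray, direction: float, length: float, width: float, depth: int) -> None:
        # a branch is a few gently turning straight chunks
        n_chunks = 3
        q = p
        for _ in range(n_chunks):
            direction += rng.uniform(-0.15, 0.15)
            step = length / n_chunks
            nxt = q + step * np.array([-np.sin(direction), np.cos(direction)])
            segments.append(((q[0], q[1]), (nxt[0], nxt[1]), width))
            q = nxt
        if depth > 0:
            for sign in (1.0, -1.0):
                angle = direction + sign * rng.uniform(np.deg2rad(10), np.deg2rad(40))
                grow(q, angle, length * 0.85, max(width * 0.8, wmin), depth - 1)

    for _ in range(spec.n_vessel_trees):
        alpha = rng.uniform(0.0, 2.0 * np.pi)
        start = center + 0.92 * spec.fov_radius * np.array(
            [np.sin(alpha), np.cos(alpha)]
        )
        # head inward with some spread
        inward = np.arctan2(-(center[0] - start[0]), center[1] - start[1])
        direction = inward + rng.uniform(-0.5, 0.5)
        root_width = rng.uniform(0.75, 1.0) * wmax
        root_length = rng.uniform(0.55, 0.75) * spec.fov_radius
        grow(start, direction, root_length, root_width, spec.branch_depth)
    return segments


def _stamp_vessels(
    shape: tuple[int, int],
    segments: list[Segment],
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth field (max of Gaussian profiles) and geometric truth mask."""
    H, W = shape
    depth = np.zeros(shape)
    truth = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1), width in segments:
        sigma = spec.profile_sigma * width
        pad = width / 2.0 + 3.0 * sigma + 1.0
        rlo = max(int(np.floor(min(r0, r1) - pad)), 0)
        rhi = min(int(np.ceil(max(r0, r1) + pad)) + 1, H)
        clo = max(int(np.floor(min(c0, c1) - pad)), 0)
        chi = min(int(np.ceil(max(c0, c1) + pad)) + 1, W)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        vr, vc = r1 - r0, c1 - c0
        denom = vr * vr + vc * vc
        if denom == 0:
            t = np.zeros_like(rr, dtype=float)
        else:
            t = np.clip(((rr - r0) * vr + (cc - c0) * vc) / denom, 0.0, 1.0)
        dist = np.hypot(rr - (r0 + t * vr), cc - (c0 + t * vc))
        profile = spec.vessel_contrast * np.exp(-(dist**2) / (2.0 * sigma**2))
        np.maximum(depth[rlo:rhi, clo:chi], profile, out=depth[rlo:rhi, clo:chi])
        truth[rlo:rhi, clo:chi] |= dist <= width / 2.0
    return depth, truth


def _illumination(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth uneven illumination: a random quadratic field with the
    requested peak amplitude."""
    if amplitude == 0.0:
        return np.zeros(shape)
    H, W = shape
    Y = np.linspace(-1.0, 1.0, H)[:, None]
    X = np.linspace(-1.0, 1.0, W)[None, :]
    c = rng.uniform(-1.0, 1.0, size=5)
    fld = c[0] * X + c[1] * Y + c[2] * X * Y + c[3] * X**2 + c[4] * Y**2
    peak = np.abs(fld).max()
    return fld / peak * amplitude if peak > 0 else fld


def render(
    spec: PhantomSpec,
    segments: list[Segment],
    rng: np.random.Generator | None = None,
) -> Phantom:
    """Render explicit centerline segments into a phantom.

    Exposed separately from :func:`generate_phantom` so exactly placed
    vessels (e.g. one horizontal segment) can be rendered for analysis.
    """
    rng = rng or np.random.default_rng(spec.seed)
    fov = _fov_disk(spec)
    depth, truth = _stamp_vessels(spec.size, segments, spec)
    truth &= fov
    if not truth.any():
        raise ValueError("degenerate phantom: no vessel pixels inside the FOV")

    img = spec.background_level + _illumination(
        spec.size, spec.illumination_gradient, rng
    )
    img = img - depth

    for _ in range(spec.lesion_count):
        H, W = spec.size
        center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.1, 0.7) * spec.fov_radius
        lr, lc = center + rad * np.array([np.sin(ang), np.cos(ang)])
        lesion_r = rng.uniform(4.0, 10.0)
        rr, cc = np.mgrid[0:H, 0:W]
        d2 = (rr - lr) ** 2 + (cc - lc) ** 2
        img += rng.uniform(0.08, 0.15) * np.exp(-d2 / (2.0 * (lesion_r / 2.0) ** 2))

    img = np.where(fov, img, spec.outside_level)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.size)
    img = np.clip(img, 0.0, 1.0)
    return Phantom(image=img, truth=truth, fov=fov, spec=spec,
                   segments=tuple(segments))


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Generate a random branching-tree phantom from a spec.

    Deterministic in ``spec.seed``: the same spec yields bit-identical
    phantoms.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    segments = _tree_segments(spec, rng)
    return render(spec, segments, rng)
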