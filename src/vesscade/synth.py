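"""Synthetic vascular trees with Gaussian cross-section profiles.

The generator emulates tubular vascular trees for training and testing the
segmentation pipeline without external data: recursive bifurcating polyline
trees with per-generation radius decay, rasterized with the 2D-Gaussian
cross-section line model

    L(x') = exp(−(x'² + y'²) / (2 σ_r²)),   σ_r = k · r,

so the labeled boundary (distance r from the axis) sits at r/σ_r = 1/k
standard deviations of the intensity profile — a visible but soft edge at
the default k = 0.5. Additive Gaussian noise at configurable variance
reproduces the blurred-boundary regime, and optional vessel-like distractors
(isotropic blobs, bright plates, touching parallel tubes) exercise the
vessel-vs-vessel-like discrimination without entering the ground truth.

All randomness flows through a single integer seed; phantom generation is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axis import Centerline
from .volume import Volume

__all__ = [
    "TreeSpec",
    "Phantom",
    "generate_tree",
    "rasterize_tree",
    "add_gaussian_noise",
    "add_distractors",
    "make_phantom",
]


@dataclass(frozen=True)
class TreeSpec:
    """Geometry and appearance of one synthetic vascular tree.

    Radii span ``root_radius`` down to ``root_radius · decay^depth``;
    ``profile_k`` is the σ_r/r ratio of the intensity profile. Distractor
    counts default to zero (a plain tree + noise, the noise-robustness
    setting); they are opt-in.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    root_radius: float = 4.0
    depth: int = 3
    radius_decay: float = 0.72
    bifurcation_angle_deg: tuple[float, float] = (25.0, 50.0)
    segment_length: tuple[float, float] = (22.0, 34.0)
    profile_k: float = 0.5
    peak_intensity: float = 100.0
    background: float = 0.0
    axis_point_spacing: float = 0.75  # mm, spacing of centerline points
    n_blobs: int = 0
    n_plates: int = 0
    n_touching_tubes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_radius <= 0 or self.profile_k <= 0:
            raise ValueError("radii and profile_k must be positive")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 < self.radius_decay <= 1:
            raise ValueError("radius_decay must be in (0, 1]")


@dataclass
class Phantom:
    """A synthetic volume with its ground truth."""

    image: Volume
    gt_mask: Volume
    centerline: Centerline
    radii: np.ndarray  # per centerline point, mm


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return (v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c))


def _orthogonal(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    ref = rng.normal(size=3)
    w = np.cross(v, ref)
    n = np.linalg.norm(w)
    while n < 1e-8:
        ref = rng.normal(size=3)
        w = np.cross(v, ref)
        n = np.linalg.norm(w)
    return w / n


def generate_tree(spec: TreeSpec, rng: np.random.Generator | None = None,
                  ) -> tuple[list[np.ndarray], list[np.ndarray], list[int]]:
    """Recursive bifurcating polyline tree clipped to the volume.

    Returns ``(branch_points, branch_radii, branch_parents)``: per-branch
    arrays of points (mm) and per-point radii, plus each branch's parent
    branch index (−1 for the root). Segments follow a gently jittered
    direction random walk; child radii shrink by ``radius_decay`` per
    generation.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    margin = spec.root_radius + 2.0
    if np.any(extent < 2 * margin + 4.0):
        raise ValueError(f"volume extent {extent} cannot fit a root segment")
    # Root starts near the lower-x face, heading inward with a jitter.
    start = np.array([
        margin,
        rng.uniform(0.3, 0.7) * extent[1],
        rng.uniform(0.3, 0.7) * extent[2]])
    direction = np.array([1.0, 0.0, 0.0])
    direction = _rotate_about(direction, _orthogonal(direction, rng),
                              np.deg2rad(rng.uniform(0.0, 15.0)))

    branches: list[np.ndarray] = []
    radii: list[np.ndarray] = []
    parents: list[int] = []

    def grow(p0: np.ndarray, d0: np.ndarray, gen: int, parent: int) -> None:
        radius = spec.root_radius * spec.radius_decay ** gen
        length = rng.uniform(*spec.segment_length)
        step = spec.axis_point_spacing
        pts = [p0.copy()]
        d = d0.copy()
        n_steps = max(2, int(round(length / step)))
        clipped = False
        for _ in range(n_steps):
            # gentle random bend, ~2.5 deg per step
            d = _rotate_about(d, _orthogonal(d, rng),
                              np.deg2rad(rng.normal(0.0, 2.5)))
            d /= np.linalg.norm(d)
            nxt = pts[-1] + d * step
            if np.any(nxt < radius + 1.0) or np.any(nxt > extent - radius - 1.0):
                clipped = True
                break
            pts.append(nxt)
        if len(pts) < 2:
            return
        arr = np.asarray(pts)
        branches.append(arr)
        radii.append(np.full(len(arr), radius))
        parents.append(parent)
        me = len(branches) - 1
        if gen < spec.depth and not clipped:
            angle = np.deg2rad(rng.uniform(*spec.bifurcation_angle_deg))
            plane = _orthogonal(d, rng)
            frac = rng.uniform(0.35, 0.65)
            for sign in (1.0, -1.0):
                child_dir = _rotate_about(d, plane, sign * angle * (frac if sign > 0 else 1 - frac) * 2)
                grow(arr[-1], child_dir / np.linalg.norm(child_dir), gen + 1, me)

    grow(start, direction, 0, -1)
    if not branches:
        raise ValueError("tree generation produced no branch")
    return branches, radii, parents


def rasterize_tree(branches: list[np.ndarray], radii: list[np.ndarray],
                   parents: list[int], spec: TreeSpec) -> Phantom:
    """Render a tree into an intensity image and a binary ground-truth mask.

    Intensity at a voxel is ``background + peak · max_segments L`` with
    ``L = exp(−d²/(2σ_r²))``, d the distance to the densely resampled
    centerline and σ_r = k · local radius; the ground truth contains voxels
    with d ≤ local radius.
    """
    spacing = np.asarray(spec.spacing)
    shape = spec.shape
    profile = np.zeros(shape, dtype=np.float32)
    inside_margin = np.full(shape, -np.inf, dtype=np.float32)

    dense_step = 0.2  # mm; resampling step along branches
    for pts, rad in zip(branches, radii):
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if seg_len.sum() == 0:
            continue
        s = np.concatenate([[0.0], np.cumsum(seg_len)])
        s_new = np.arange(0.0, s[-1] + dense_step / 2, dense_step)
        dense = np.stack([np.interp(s_new, s, pts[:, k]) for k in range(3)], axis=1)
        r_new = np.interp(s_new, s, rad)
        for p, r in zip(dense, r_new):
            sigma = spec.profile_k * r
            half = max(3.0 * sigma, r + 1.0)
            lo = np.maximum(np.floor((p - half) / spacing).astype(int), 0)
            hi = np.minimum(np.ceil((p + half) / spacing).astype(int) + 1,
                            np.asarray(shape))
            if np.any(lo >= hi):
                continue
            gx = (np.arange(lo[0], hi[0]) * spacing[0] - p[0]) ** 2
            gy = (np.arange(lo[1], hi[1]) * spacing[1] - p[1]) ** 2
            gz = (np.arange(lo[2], hi[2]) * spacing[2] - p[2]) ** 2
            d2 = gx[:, None, None] + gy[None, :, None] + gz[None, None, :]
            sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
            np.maximum(profile[sl],
                       np.exp(-d2 / (2.0 * sigma * sigma)).astype(np.float32),
                       out=profile[sl])
            np.maximum(inside_margin[sl], (r - np.sqrt(d2)).astype(np.float32),
                       out=inside_margin[sl])

    image = Volume(spec.background + spec.peak_intensity * profile,
                   spec.spacing)
    gt = Volume((inside_margin >= 0).astype(np.uint8), spec.spacing)
    world = [b.copy() for b in branches]
    # branch parent point: last point of the parent branch
    attach = []
    offsets = np.cumsum([0] + [len(b) for b in branches[:-1]])
    for b, par in enumerate(parents):
        attach.append(-1 if par < 0 else int(offsets[par] + len(branches[par]) - 1))
    centerline = Centerline.from_branches(world, attach)
    all_radii = np.concatenate(radii)
    return Phantom(image, gt, centerline, all_radii)


def add_gaussian_noise(volume: Volume, variance: float,
                       seed: int | np.random.Generator = 0) -> Volume:
    """Additive i.i.d. zero-mean Gaussian noise of the given variance."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return volume.copy()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    noise = rng.normal(0.0, np.sqrt(variance), size=volume.shape)
    return volume.like(np.asarray(volume.data, dtype=np.float32)
                       + noise.astype(np.float32))


def add_distractors(phantom: Phantom, spec: TreeSpec,
                    seed: int | np.random.Generator = 0) -> Phantom:
    """Add vessel-like structures to the image; the ground truth is untouched.

    Blobs are isotropic Gaussians, plates are thin bright slabs of limited
    extent, and touching tubes are parallel non-vessel tubes laid against a
    randomly chosen vessel segment (the kissing-vessel scenario). Structures
    blend into the image by maximum, like the vessels themselves.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    img = np.asarray(phantom.image.data, dtype=np.float32).copy()
    spacing = np.asarray(phantom.image.spacing)
    shape = np.asarray(phantom.image.shape)
    extent = shape * spacing
    peak = spec.peak_intensity

    def splat(center: np.ndarray, half: float, factor_fn) -> None:
        lo = np.maximum(np.floor((center - half) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((center + half) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            return
        gx = np.arange(lo[0], hi[0]) * spacing[0] - center[0]
        gy = np.arange(lo[1], hi[1]) * spacing[1] - center[1]
        gz = np.arange(lo[2], hi[2]) * spacing[2] - center[2]
        X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        np.maximum(img[sl], (peak * factor_fn(X, Y, Z)).astype(np.float32),
                   out=img[sl])

    for _ in range(spec.n_blobs):
        c = rng.uniform(0.15, 0.85, size=3) * extent
        s = rng.uniform(1.0, 3.0)
        splat(c, 3.5 * s,
              lambda X, Y, Z, s=s: np.exp(-(X**2 + Y**2 + Z**2) / (2 * s * s)))

    for _ in range(spec.n_plates):
        c = rng.uniform(0.2, 0.8, size=3) * extent
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        t = rng.uniform(0.6, 1.2)  # thickness sigma, mm
        ext = rng.uniform(8.0, 14.0)  # lateral extent, mm
        def plate(X, Y, Z, n=n, t=t, ext=ext):
            dn = X * n[0] + Y * n[1] + Z * n[2]
            lat2 = np.maximum(X**2 + Y**2 + Z**2 - dn**2, 0.0)
            # thin across the normal, smoothly extended in-plane
            return np.exp(-dn**2 / (2 * t * t)) * np.exp(-lat2 / (2 * ext * ext))
        splat(c, 2.5 * ext + 3 * t, plate)

    if spec.n_touching_tubes:
        pts = phantom.centerline.points
        tans = phantom.centerline.tangents
        for _ in range(spec.n_touching_tubes):
            i = int(rng.integers(len(pts)))
            r_v = float(phantom.radii[i])
            r_t = rng.uniform(1.0, 2.0)
            off_dir = _orthogonal(tans[i], rng)
            axis0 = pts[i] + off_dir * (r_v + r_t)
            length = rng.uniform(10.0, 18.0)
            d = tans[i]
            sigma = spec.profile_k * r_t
            for s in np.arange(-length / 2, length / 2, 0.25):
                splat(axis0 + d * s, max(3 * sigma, r_t + 1.0),
                      lambda X, Y, Z, sg=sigma: np.exp(
                          -(X**2 + Y**2 + Z**2) / (2 * sg * sg)))

    new_image = phantom.image.like(img)
    return Phantom(new_image, phantom.gt_mask, phantom.centerline, phantom.radii)


def make_phantom(spec: TreeSpec) -> Phantom:
    """Generate and rasterize a tree, then add any configured distractors."""
    rng = np.random.default_rng(spec.seed)
    branches, radii, parents = generate_tree(spec, rng)
    phantom = rasterize_tree(branches, radii, parents, spec)
    if spec.n_blobs or spec.n_plates or spec.n_touching_tubes:
        phantom = add_distractors(phantom, spec, rng)
    return phantom
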