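"""The four gross-tumor-volume delineation methods under comparison.

* :func:`segment_gradient` — edge detection by the maximum negative
  radial SUV derivative along dense rays from a seed point, with an
  initial 6-axis ellipsoid bound and an edge-continuity regularisation.
  The result depends only on *relative* intensity changes, so it is
  invariant under multiplication of the image by any positive constant.
* :func:`segment_fixed_threshold` — voxels above a fixed SUV (default
  1.4) inside a user sphere.
* :func:`segment_percent_max` — voxels above a fraction (default 30 %)
  of the maximum SUV found inside the sphere.
* :func:`emulate_ct_delineation` — the CT reader's rule applied to the
  phantom's thickened-wall image: a per-slice region counts as tumor when
  its wall thickness is at least 5 mm or its diameter at least 10 mm.

All methods return a single connected component containing (or nearest
to) the seed/sphere centre.  Thresholds are inclusive (>=); sphere
membership is by voxel centre.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import ImageVolume, Structure

__all__ = [
    "SphereROI",
    "GradientSegParams",
    "segment_gradient",
    "segment_fixed_threshold",
    "segment_percent_max",
    "emulate_ct_delineation",
    "icosphere_directions",
]


@dataclass(frozen=True)
class SphereROI:
    """User-defined sphere placed over the tumor (centre and radius in mm)."""

    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class GradientSegParams:
    """Tunable parameters of the gradient edge detector.

    ``ray_count`` is rounded to the nearest subdivided-icosahedron face
    count (20·4^k); 320 rays give ~11 degree angular resolution.
    ``min_edge_strength`` is the fraction of the strongest radial
    derivative (over all rays) a ray's own edge must reach to be accepted;
    weaker rays inherit the continuity-regularised radius of their
    neighbours.  ``radial_step_mm`` defaults to half the smallest voxel
    spacing; ``smooth_sigma_samples`` is the Gaussian smoothing applied to
    each radial profile before differentiation, in sample units.
    """

    ray_count: int = 320
    radial_step_mm: float | None = None
    smooth_sigma_samples: float = 1.0
    max_radius_mm: float = 60.0
    #: the 6-axis ellipsoid is inscribed in the lesion, so for elongated
    #: (tube-like) lesions it under-bounds directions near the long axis;
    #: 2.0 keeps the true edge inside the search window up to ~7:1 aspect.
    bounding_scale: float = 2.0
    continuity_k: int = 9
    min_edge_strength: float = 0.3

    def __post_init__(self) -> None:
        if self.ray_count < 6:
            raise ValueError("need at least 6 rays")
        if self.radial_step_mm is not None and self.radial_step_mm <= 0:
            raise ValueError("radial step must be positive")
        if self.bounding_scale < 1:
            raise ValueError("bounding scale must be >= 1")
        if not (0 < self.min_edge_strength <= 1):
            raise ValueError("min edge strength must be in (0, 1]")
        if self.continuity_k < 1:
            raise ValueError("continuity window must be >= 1")


# ---------------------------------------------------------------------------
# ray geometry

def _icosahedron_faces() -> np.ndarray:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    return v[f]  # (20, 3, 3) triangles on the unit sphere


def icosphere_directions(ray_count: int = 320) -> np.ndarray:
    """Near-uniform unit directions: subdivided-icosahedron face centroids.

    The subdivision level is chosen so the face count (20·4^k) is nearest
    to ``ray_count``; the returned array has that exact face count.
    """
    k = max(0, round(math.log(max(ray_count, 20) / 20.0, 4)))
    tris = _icosahedron_faces()
    for _ in range(k):
        a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        for m in (ab, bc, ca):
            m /= np.linalg.norm(m, axis=1, keepdims=True)
        tris = np.concatenate([
            np.stack([a, ab, ca], 1), np.stack([ab, b, bc], 1),
            np.stack([ca, bc, c], 1), np.stack([ab, bc, ca], 1),
        ])
    centroids = tris.mean(axis=1)
    return centroids / np.linalg.norm(centroids, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# radial edge detection

def _boundary_distance(p0, direction, vol: ImageVolume) -> float:
    """Distance from p0 to the grid boundary along a unit direction."""
    t = math.inf
    for a in range(3):
        d = direction[a]
        if abs(d) < 1e-12:
            continue
        lo = vol.origin[a]
        hi = vol.origin[a] + (vol.shape[a] - 1) * vol.spacing[a]
        bound = hi if d > 0 else lo
        t = min(t, (bound - p0[a]) / d)
    return max(t, 0.0)


def _edge_along_rays(vol: ImageVolume, p0, directions, r_max, step, sigma_samples):
    """Locate the strongest negative radial derivative along each ray.

    Returns ``(radii, strengths)``; a NaN radius marks a ray with no
    negative derivative (no falling edge) within its search range.
    """
    p0 = np.asarray(p0, dtype=float)
    n = len(directions)
    radii = np.full(n, np.nan)
    strengths = np.zeros(n)
    r_max = np.broadcast_to(np.asarray(r_max, dtype=float), (n,))
    data = np.asarray(vol.data, dtype=float)
    for i, u in enumerate(directions):
        ri = min(r_max[i], _boundary_distance(p0, u, vol))
        if ri <= 2 * step:
            continue
        ts = np.arange(0.0, ri + step / 2.0, step)
        pts = p0[None, :] + ts[:, None] * np.asarray(u)[None, :]
        idx = vol.physical_to_index(pts)
        prof = ndimage.map_coordinates(data, idx.T, order=1, mode="nearest")
        if sigma_samples > 0:
            prof = ndimage.gaussian_filter1d(prof, sigma_samples, mode="nearest")
        deriv = np.gradient(prof, step)
        if len(ts) < 4:
            continue
        j = 1 + int(np.argmin(deriv[1:-1]))
        if deriv[j] < 0:
            radii[i] = ts[j]
            strengths[i] = -deriv[j]
    return radii, strengths


def _ellipsoid_radius(directions, axis_radii) -> np.ndarray:
    """Directional radius of the 6-half-axis ellipsoid (sign-matched axes)."""
    pos = axis_radii[0::2]  # +x, +y, +z half-axes
    neg = axis_radii[1::2]  # -x, -y, -z half-axes
    d = np.asarray(directions, dtype=float)
    semi = np.where(d >= 0, pos[None, :], neg[None, :])
    q = np.sum((d / semi) ** 2, axis=1)
    return 1.0 / np.sqrt(q)


def segment_gradient(pet: ImageVolume, seed_mm, params: GradientSegParams | None = None,
                     label: str = "GTV_GRAD") -> Structure:
    """Gradient-based delineation from a seed near the lesion centre.

    Stage 1: along the six anatomical half-axes the radius of the
    strongest negative SUV derivative is found; the six half-axes define
    an initial bounding ellipsoid.  Stage 2: dense rays are cast from the
    seed; along each, within ``bounding_scale`` times the ellipsoid radius
    for that direction, the maximum negative smoothed radial derivative
    marks the candidate edge.  Rays whose edge strength falls below
    ``min_edge_strength`` of the strongest ray are rejected; the radius
    field is regularised by the median over the ``continuity_k`` nearest
    ray directions (rejected rays inherit the regularised value), and the
    resulting star-convex region is rasterised.  The returned mask is the
    connected component containing the seed.
    """
    params = params or GradientSegParams()
    p0 = np.asarray(seed_mm, dtype=float)
    if not pet.contains_point(p0):
        raise ValueError("seed outside grid")
    if np.any(np.asarray(pet.data) < 0):
        raise ValueError("PET values must be non-negative")
    step = params.radial_step_mm or 0.5 * min(pet.spacing)

    axes = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    ax_radii, ax_strength = _edge_along_rays(
        pet, p0, axes, params.max_radius_mm, step, params.smooth_sigma_samples)
    if np.all(np.isnan(ax_radii)) or np.nanmax(ax_strength) <= 0:
        raise ValueError("no detectable lesion boundary")
    # order half-axes as (+x, -x, +y, -y, +z, -z); fill failed axes with
    # the median of the detected ones so the ellipsoid stays defined
    fill = np.nanmedian(ax_radii)
    ax_radii = np.where(np.isnan(ax_radii), fill, ax_radii)

    dirs = icosphere_directions(params.ray_count)
    bound = np.minimum(params.bounding_scale * _ellipsoid_radius(dirs, ax_radii),
                       params.max_radius_mm)
    radii, strengths = _edge_along_rays(pet, p0, dirs, bound, step,
                                        params.smooth_sigma_samples)
    if not np.any(strengths > 0):
        raise ValueError("no detectable lesion boundary")
    accepted = (strengths >= params.min_edge_strength * strengths.max()) \
        & np.isfinite(radii)

    # continuity of the tumor edge: median radius over neighbouring rays
    tree = cKDTree(dirs)
    k = min(params.continuity_k, len(dirs))
    _, nbrs = tree.query(dirs, k=k)
    nbrs = np.atleast_2d(nbrs)
    final = np.empty(len(dirs))
    global_med = np.median(radii[accepted])
    for i in range(len(dirs)):
        nb = nbrs[i]
        ok = nb[accepted[nb]]
        final[i] = np.median(radii[ok]) if len(ok) else global_med

    mask = _rasterize_star(pet, p0, dirs, final, tree)
    mask = _component_at(mask, pet, p0)
    return Structure.on_grid(label, mask, pet)


def _rasterize_star(vol: ImageVolume, p0, dirs, radii, tree: cKDTree) -> np.ndarray:
    """Voxelise the star-convex region {p0 + t·u : t <= r(u)}."""
    rmax = float(np.max(radii))
    lo = np.maximum(np.floor(vol.physical_to_index(p0 - rmax)).astype(int), 0)
    hi = np.minimum(np.ceil(vol.physical_to_index(p0 + rmax)).astype(int) + 1,
                    np.asarray(vol.shape))
    mask = np.zeros(vol.shape, dtype=bool)
    coords = [vol.origin[a] + np.arange(lo[a], hi[a]) * vol.spacing[a] for a in range(3)]
    dx = coords[0][:, None, None] - p0[0]
    dy = coords[1][None, :, None] - p0[1]
    dz = coords[2][None, None, :] - p0[2]
    rho = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    sub = np.zeros(rho.shape, dtype=bool)
    flat_rho = rho.ravel()
    inner = flat_rho <= rmax
    offs = np.stack(np.broadcast_arrays(dx, dy, dz), axis=-1).reshape(-1, 3)[inner]
    rr = flat_rho[inner]
    central = rr < 1e-9
    units = np.where(central[:, None], [[0, 0, 1.0]], offs / np.maximum(rr, 1e-9)[:, None])
    _, nearest = tree.query(units)
    keep = (rr <= radii[nearest]) | central
    flat = sub.ravel()
    idx = np.flatnonzero(inner)
    flat[idx[keep]] = True
    sub = flat.reshape(rho.shape)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def _component_at(mask: np.ndarray, vol: ImageVolume, point_mm) -> np.ndarray:
    """Connected component (26-connectivity) containing / nearest a point."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return mask
    seed_idx = np.clip(np.round(vol.physical_to_index(np.asarray(point_mm))).astype(int),
                       0, np.asarray(vol.shape) - 1)
    lab = labels[tuple(seed_idx)]
    if lab == 0:
        lab = _nearest_component(labels, n, vol, point_mm)
    return labels == lab


def _nearest_component(labels, n, vol: ImageVolume, point_mm) -> int:
    """Label of the component nearest a physical point; ties -> larger."""
    p = np.asarray(point_mm, dtype=float)
    best = None
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        pts = np.asarray(vol.origin) + idx * np.asarray(vol.spacing)
        d = float(np.min(np.linalg.norm(pts - p, axis=1)))
        size = len(idx)
        key = (round(d, 6), -size)
        if best is None or key < best[0]:
            best = (key, lab)
    return best[1]


# ---------------------------------------------------------------------------
# threshold methods

def _sphere_mask(vol: ImageVolume, roi: SphereROI) -> np.ndarray:
    c = np.asarray(roi.center_mm, dtype=float)
    ax = [vol.axis_coords(a) for a in range(3)]
    d2 = ((ax[0][:, None, None] - c[0]) ** 2 + (ax[1][None, :, None] - c[1]) ** 2
          + (ax[2][None, None, :] - c[2]) ** 2)
    return d2 <= roi.radius_mm ** 2


def _threshold_in_sphere(pet: ImageVolume, roi: SphereROI, threshold: float,
                         label: str) -> Structure:
    inside = _sphere_mask(pet, roi)
    if not inside.any():
        raise ValueError("sphere ROI does not intersect the grid")
    mask = inside & (np.asarray(pet.data, dtype=float) >= threshold)
    if not mask.any():
        warnings.warn(f"{label}: no voxel reaches threshold {threshold:g}; "
                      "returning empty mask", stacklevel=3)
        return Structure.on_grid(label, mask, pet)
    mask = _component_at(mask, pet, roi.center_mm)
    return Structure.on_grid(label, mask, pet)


def segment_fixed_threshold(pet: ImageVolume, roi: SphereROI,
                            threshold_suv: float = 1.4,
                            label: str = "GTV_1.4") -> Structure:
    """Fixed-SUV threshold (default 1.4) inside a user sphere.

    Keeps the connected component nearest the sphere centre; emits a
    warning and returns an empty mask if nothing reaches the threshold.
    """
    return _threshold_in_sphere(pet, roi, threshold_suv, label)


def segment_percent_max(pet: ImageVolume, roi: SphereROI, percent: float = 0.30,
                        label: str = "GTV_30%max") -> Structure:
    """Threshold at ``percent`` of the maximum SUV inside the sphere."""
    if not (0 < percent < 1):
        raise ValueError("percent must be in (0, 1)")
    inside = _sphere_mask(pet, roi)
    if not inside.any():
        raise ValueError("sphere ROI does not intersect the grid")
    suv_max = float(np.max(np.asarray(pet.data)[inside]))
    return _threshold_in_sphere(pet, roi, percent * suv_max, label)


# ---------------------------------------------------------------------------
# CT-criteria emulation

def _region_wall_and_diameter(region: np.ndarray, spacing_xy) -> tuple[float, float]:
    """Wall thickness and diameter (mm) of one in-plane region.

    Wall thickness is twice the deepest point of the region (maximum
    Euclidean distance to background), which equals the annulus width for
    a thickened-wall cross-section and the full diameter for a solid one.
    Diameter is the maximum pixel-centre distance plus one pixel (pixels
    count at full size, as slices do along z).
    """
    dist = ndimage.distance_transform_edt(region, sampling=spacing_xy)
    wall = 2.0 * float(dist.max())
    pts = np.argwhere(region).astype(float) * np.asarray(spacing_xy)
    if len(pts) > 1500:
        try:
            from scipy.spatial import ConvexHull
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    if len(pts) == 1:
        diam = 0.0
    else:
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        diam = float(np.sqrt(d2.max()))
    return wall, diam + max(spacing_xy)


def emulate_ct_delineation(ct_like: ImageVolume, min_wall_mm: float = 5.0,
                           min_diameter_mm: float = 10.0,
                           label: str = "GTV_CT") -> Structure:
    """Apply the CT reader's size criteria to the thickened-wall image.

    The CT-analog must be two-level (0/1).  Per axial slice each connected
    region is kept when its wall thickness is at least ``min_wall_mm`` or
    its diameter at least ``min_diameter_mm``; the output is the union of
    kept regions over slices.
    """
    data = np.asarray(ct_like.data, dtype=float)
    vals = np.unique(data)
    if not np.all(np.isclose(vals, 0.0) | np.isclose(vals, 1.0)):
        raise ValueError("CT-analog input must be two-level (0/1)")
    support = data > 0.5
    spacing_xy = ct_like.spacing[:2]
    out = np.zeros_like(support)
    for k in range(support.shape[2]):
        sl = support[:, :, k]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl)
        for lab in range(1, n + 1):
            region = labels == lab
            wall, diam = _region_wall_and_diameter(region, spacing_xy)
            if wall >= min_wall_mm or diam >= min_diameter_mm:
                out[:, :, k] |= region
    return Structure.on_grid(label, out, ct_like)
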