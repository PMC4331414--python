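"""Synthetic PET/CT phantom generator with known ground truth.

Each phantom case emulates one esophageal-cancer patient: a tubular tumor
of known longitudinal length (the stand-in for the pathologically measured
gross tumor length) embedded in low-uptake background.  The PET-like
volume is the two-level tumor indicator convolved with an isotropic
Gaussian point-spread function (partial-volume blur) plus optional
additive Gaussian noise; the CT-like volume shows the tumor support
dilated by a wall-thickening margin, emulating the over-segmented
esophageal-wall appearance that CT readers contour.

Simplifications relative to real data (see docs/methods.md): the esophagus
is a straight z-aligned tube, noise is additive Gaussian rather than a
reconstructed Poisson process, and uptake is homogeneous inside the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, Structure

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortCase",
    "make_tumor_phantom",
    "make_sphere_phantom",
    "make_cohort",
    "make_oar_set",
]

#: grid defaults: in-plane 2 mm for desk-scale speed, 4.25 mm slices
#: matching the PET acquisition sampling the study emulates.
DEFAULT_SHAPE = (64, 64, 48)
DEFAULT_SPACING = (2.0, 2.0, 4.25)


@dataclass
class PhantomSpec:
    """Parameters of one tubular-tumor phantom case.

    ``tumor_suv``/``background_suv`` default to 6.0/1.0 so that both the
    fixed 1.4-SUV threshold and the 30 %-of-SUVmax threshold are
    meaningful on defaults; ``psf_sigma_mm`` defaults to 4 mm, a typical
    clinical PET resolution.
    """

    length_mm: float = 60.0
    radius_mm: float = 10.0
    tumor_suv: float = 6.0
    background_suv: float = 1.0
    wall_margin_mm: float = 5.0
    psf_sigma_mm: float = 4.0
    noise_sigma: float = 0.0
    seed: int = 0
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.radius_mm <= 0:
            raise ValueError("tumor length and radius must be positive")
        if not (self.tumor_suv > self.background_suv >= 0):
            raise ValueError("need tumor SUV > background SUV >= 0")
        if self.psf_sigma_mm < 0 or self.noise_sigma < 0:
            raise ValueError("PSF sigma and noise sigma must be >= 0")
        if self.wall_margin_mm < 0:
            raise ValueError("wall-thickening margin must be >= 0")


@dataclass
class GroundTruth:
    """Known truth for one phantom: pre-blur support, length, volume."""

    mask: Structure
    length_cm: float
    volume_cm3: float


@dataclass
class CohortCase:
    case_id: str
    spec: PhantomSpec
    pet: ImageVolume
    ct_like: ImageVolume
    truth: GroundTruth


def _grid_axes(shape, spacing):
    x = np.arange(shape[0]) * spacing[0]
    y = np.arange(shape[1]) * spacing[1]
    z = np.arange(shape[2]) * spacing[2]
    return x, y, z


def make_tumor_phantom(spec: PhantomSpec):
    """Build (pet, ct_like, truth) for one tubular-tumor case.

    The tumor is a solid cylinder along z centred in the grid.  PET is
    ``bg + (tumor - bg) * indicator`` blurred by the PSF with seeded noise
    added and clipped at zero; the CT-analog is the indicator dilated by
    the wall-thickening margin (Euclidean, in physical mm), encoded 0/1.
    """
    shape, spacing = spec.shape, spec.spacing
    x, y, z = _grid_axes(shape, spacing)
    cx, cy, cz = ((n - 1) / 2.0 * s for n, s in zip(shape, spacing))

    pad = 3.0 * spec.psf_sigma_mm
    half_x = (shape[0] - 1) / 2.0 * spacing[0]
    half_y = (shape[1] - 1) / 2.0 * spacing[1]
    half_z = (shape[2] - 1) / 2.0 * spacing[2]
    if (spec.radius_mm + spec.wall_margin_mm + pad > min(half_x, half_y)
            or spec.length_mm / 2.0 + pad > half_z):
        raise ValueError("tumor does not fit in grid with 3-sigma PSF padding")

    rho2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    in_plane = rho2 <= spec.radius_mm ** 2
    in_z = np.abs(z - cz) <= spec.length_mm / 2.0
    support = in_plane[:, :, None] & in_z[None, None, :]

    img = np.full(shape, float(spec.background_suv))
    img[support] = spec.tumor_suv
    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / s for s in spacing]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
        img = np.clip(img, 0.0, None)  # SUV is non-negative
    pet = ImageVolume(img, spacing)

    if spec.wall_margin_mm > 0:
        dist = ndimage.distance_transform_edt(~support, sampling=spacing)
        wall = dist <= spec.wall_margin_mm
    else:
        wall = support
    ct_like = ImageVolume(wall.astype(float), spacing)

    truth_mask = Structure("truth", support, spacing)
    truth = GroundTruth(truth_mask, spec.length_mm / 10.0, truth_mask.volume_cm3)
    return pet, ct_like, truth


def make_sphere_phantom(radius_mm: float = 15.0, tumor_suv: float = 6.0,
                        background_suv: float = 1.0, psf_sigma_mm: float = 4.0,
                        noise_sigma: float = 0.0, seed: int = 0,
                        shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0)):
    """Calibration phantom: a blurred sphere at the grid centre.

    Returns ``(pet, center_mm, true_mask)``.  Used to validate the
    gradient edge detector against the one-dimensional blurred radial
    profile, for which the maximum-|derivative| radius can be computed
    independently.
    """
    x, y, z = _grid_axes(shape, spacing)
    cx, cy, cz = ((n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    r2 = ((x[:, None, None] - cx) ** 2 + (y[None, :, None] - cy) ** 2
          + (z[None, None, :] - cz) ** 2)
    support = r2 <= radius_mm ** 2
    img = np.full(shape, float(background_suv))
    img[support] = tumor_suv
    if psf_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=[psf_sigma_mm / s for s in spacing],
                                      mode="nearest")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise_sigma, size=shape), 0.0, None)
    pet = ImageVolume(img, spacing)
    return pet, (cx, cy, cz), Structure("truth", support, spacing)


def make_cohort(n: int, length_range_cm=(3.44, 11.00), template: PhantomSpec | None = None,
                seed: int = 0, radius_range_mm=(8.0, 12.0)) -> list[CohortCase]:
    """Generate a reproducible cohort of phantom cases.

    Tumor lengths are sampled uniformly over ``length_range_cm``
    (default 3.44–11.00 cm) and radii uniformly over ``radius_range_mm``;
    each case gets its own noise seed derived from ``seed``.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 (statistics undefined otherwise)")
    lo, hi = length_range_cm
    if not (0 < lo <= hi):
        raise ValueError("invalid length range")
    template = template or PhantomSpec()
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(lo * 10.0, hi * 10.0, size=n)
    radii = rng.uniform(radius_range_mm[0], radius_range_mm[1], size=n)
    case_seeds = rng.integers(0, 2**31 - 1, size=n)
    cases = []
    for i in range(n):
        spec = replace(template, length_mm=float(lengths[i]),
                       radius_mm=float(radii[i]), seed=int(case_seeds[i]))
        pet, ct_like, truth = make_tumor_phantom(spec)
        cases.append(CohortCase(f"case{i:02d}", spec, pet, ct_like, truth))
    return cases


def make_oar_set(grid: ImageVolume) -> dict[str, Structure]:
    """Simple organ-at-risk geometry on an arbitrary grid.

    Two lateral lung ellipsoids, one anterior heart ellipsoid and one
    posterior spinal-cord cylinder spanning the full craniocaudal extent,
    mutually disjoint and clear of the central tumor-axis region.
    Offsets are fixed in millimetres, so the grid must cover at least
    ~115 mm in-plane.
    """
    x, y, z = _grid_axes(grid.shape, grid.spacing)
    cx, cy, cz = grid.center()
    half_x = (grid.shape[0] - 1) / 2.0 * grid.spacing[0]
    half_y = (grid.shape[1] - 1) / 2.0 * grid.spacing[1]
    half_z = (grid.shape[2] - 1) / 2.0 * grid.spacing[2]
    if half_x < 57.0 or half_y < 52.0:
        raise ValueError("grid too small to place organs")

    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    def ellipsoid(c, semi):
        return (((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2
                + ((Z - c[2]) / semi[2]) ** 2) <= 1.0

    lung_semi = (17.0, 26.0, 0.9 * half_z)
    lungs = (ellipsoid((cx - 40.0, cy, cz), lung_semi)
             | ellipsoid((cx + 40.0, cy, cz), lung_semi))
    heart = ellipsoid((cx, cy - 38.0, cz), (20.0, 14.0, 30.0))
    cord = (((X - cx) ** 2 + (Y - (cy + 46.0)) ** 2) <= 5.0 ** 2) & np.ones_like(Z, bool)

    organs = {
        "total_lung": Structure.on_grid("total_lung", lungs, grid),
        "heart": Structure.on_grid("heart", heart, grid),
        "spinal_cord": Structure.on_grid("spinal_cord", np.broadcast_to(
            cord, grid.shape).copy(), grid),
    }
    return organs
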