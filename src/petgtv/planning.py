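"""Margin expansion, parametric synthetic dose, DVH and plan-quality metrics.

The treatment-protocol geometry: the clinical target volume (CTV) is the
GTV expanded 3 cm craniocaudally and 1 cm laterally/antero-posteriorly;
the planning target volume (PTV) adds an isotropic 0.5 cm.  The
prescription is 60 Gy in 30 fractions; plans must cover >= 95 % of the
PTV with the prescription isodose and keep the global hotspot below 10 %.

Real five-beam conformal optimisation is replaced by a parametric dose
bath: the PTV indicator, slightly expanded, convolved with a Gaussian
penumbra and rescaled (1-D bisection on a global factor) to meet the
coverage goal.  Dose falls off monotonically with distance outside the
PTV, which is what drives the organ-at-risk comparisons between plans.

Plan-quality metrics follow the clinical definitions: V_x is the percent
of a structure receiving at least x Gy; D_q the minimum dose to the
hottest q %; HI = (D2 - D98)/prescription × 100 %;
CI = (Vt,ref/Vt)·(Vt,ref/Vref) with the prescription dose as the
reference isodose level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, Structure, assert_congruent

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "PlanMetrics",
    "expand_margin_anisotropic",
    "expand_margin_isotropic",
    "resample_structure",
    "synthetic_dose",
    "compute_dvh",
    "dvh_value_at",
    "dvh_dose_at",
    "volume_fraction_at",
    "dose_to_hottest",
    "mean_dose",
    "max_dose",
    "homogeneity_index",
    "conformity_index",
    "evaluate_plan",
]


@dataclass
class DoseGrid:
    """A dose distribution (Gy) with its prescription level."""

    volume: ImageVolume
    prescription_gy: float

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if np.any(np.asarray(self.volume.data) < 0):
            raise ValueError("doses must be non-negative")


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve: % volume receiving >= each bin edge."""

    edges_gy: np.ndarray
    cum_pct: np.ndarray

    def __post_init__(self) -> None:
        self.edges_gy = np.asarray(self.edges_gy, dtype=float)
        self.cum_pct = np.asarray(self.cum_pct, dtype=float)
        if self.edges_gy.shape != self.cum_pct.shape:
            raise ValueError("edges and values must align")


@dataclass
class PlanMetrics:
    """Per-plan evaluation factors (the quantities of a plan report)."""

    lung_v5: float
    lung_v10: float
    lung_v20: float
    lung_v30: float
    lung_v40: float
    mld: float
    heart_v30: float
    heart_v40: float
    mhd: float
    cord_dmax: float
    ptv_d2: float
    ptv_d98: float
    hi: float
    ci: float
    vt_cm3: float
    vt_ref_cm3: float
    vref_cm3: float
    ptv_coverage_pct: float
    dmax_gy: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------
# margins

def _ellipsoid_dilate(mask: np.ndarray, spacing, margins) -> np.ndarray:
    """Dilate by the ellipsoid with semi-axes ``margins`` (mm), via a
    scaled Euclidean distance transform; a zero margin freezes that axis."""
    sampling = [sp / m if m > 0 else 1e9 for sp, m in zip(spacing, margins)]
    dist = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return dist <= 1.0 + 1e-9


def expand_margin_anisotropic(gtv: Structure, margins_mm, label: str = "CTV") -> Structure:
    """Minkowski dilation by the ellipsoid with semi-axes (lat, AP, cc) mm."""
    margins = tuple(float(m) for m in margins_mm)
    if any(m < 0 for m in margins):
        raise ValueError("margins must be >= 0")
    if gtv.is_empty():
        raise ValueError("cannot expand an empty structure")
    if all(m == 0 for m in margins):
        return Structure(label, gtv.mask.copy(), gtv.spacing, gtv.origin)
    new = _ellipsoid_dilate(gtv.mask, gtv.spacing, margins)
    return Structure(label, new, gtv.spacing, gtv.origin)


def expand_margin_isotropic(ctv: Structure, margin_mm: float = 5.0,
                            label: str = "PTV") -> Structure:
    """Isotropic margin expansion (default 0.5 cm, CTV -> PTV)."""
    return expand_margin_anisotropic(ctv, (margin_mm,) * 3, label=label)


def resample_structure(s: Structure, grid: ImageVolume, label: str | None = None) -> Structure:
    """Nearest-neighbour resampling of a mask onto another grid.

    Planning runs on its own dose grid (2.5 mm isotropic by default in the
    study pipeline), so segmentation masks defined on the PET grid are
    carried over by sampling the mask at each target voxel centre.
    """
    ax = [grid.axis_coords(a) for a in range(3)]
    idx = [np.round((ax[a] - s.origin[a]) / s.spacing[a]).astype(int) for a in range(3)]
    valid = [np.clip(idx[a], 0, s.mask.shape[a] - 1) for a in range(3)]
    inside = [(idx[a] >= 0) & (idx[a] <= s.mask.shape[a] - 1) for a in range(3)]
    sub = s.mask[np.ix_(valid[0], valid[1], valid[2])]
    inside3 = (inside[0][:, None, None] & inside[1][None, :, None]
               & inside[2][None, None, :])
    return Structure.on_grid(label or s.label, sub & inside3, grid)


# ---------------------------------------------------------------------------
# synthetic dose

def synthetic_dose(ptv: Structure, prescription_gy: float = 60.0,
                   penumbra_sigma_mm: float = 5.0,
                   interior_margin_mm: float | None = None,
                   target_coverage: float = 0.95,
                   hotspot_factor: float = 1.10) -> DoseGrid:
    """Conformal dose bath around the PTV.

    ``dose = prescription × s × g`` where ``g`` is the PTV indicator
    expanded by ``interior_margin_mm`` (default two penumbra sigmas) and
    convolved with the Gaussian penumbra; the global scale ``s`` is found
    by bisection as the smallest factor giving >= ``target_coverage`` of
    the PTV at the prescription level.  Raises if that scale would push
    the maximum dose to ``hotspot_factor`` × prescription or above.
    """
    if ptv.is_empty():
        raise ValueError("PTV is empty")
    if interior_margin_mm is None:
        interior_margin_mm = 2.0 * penumbra_sigma_mm
    core = _ellipsoid_dilate(ptv.mask, ptv.spacing, (interior_margin_mm,) * 3) \
        if interior_margin_mm > 0 else ptv.mask
    sigma_vox = [penumbra_sigma_mm / sp for sp in ptv.spacing]
    g = ndimage.gaussian_filter(core.astype(float), sigma=sigma_vox, mode="constant")
    g_ptv = g[ptv.mask]
    g_max = float(g.max())

    def coverage(scale: float) -> float:
        return float(np.mean(scale * g_ptv >= 1.0))

    lo, hi = 0.5, 1.0 / max(np.min(g_ptv), 1e-9) + 1e-6
    if coverage(hi) < target_coverage:  # pragma: no cover - hi covers all by construction
        raise ValueError("coverage goal unreachable")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if coverage(mid) >= target_coverage:
            hi = mid
        else:
            lo = mid
    # nudge above the bisection infimum so the coverage test still holds
    # after the dose array is scaled to Gy (different rounding path)
    scale = hi * (1.0 + 1e-9)
    if scale * g_max >= hotspot_factor:
        achievable = coverage(hotspot_factor / g_max * (1 - 1e-12))
        raise ValueError(
            "dose constraints unsatisfiable for this penumbra: coverage at the "
            f"hotspot limit is {100 * achievable:.1f}% (< {100 * target_coverage:.0f}%)")
    dose = prescription_gy * (scale * g)
    return DoseGrid(ImageVolume(dose, ptv.spacing, ptv.origin), prescription_gy)


# ---------------------------------------------------------------------------
# DVH and derived metrics

def _structure_doses(dose: DoseGrid, s: Structure) -> np.ndarray:
    assert_congruent(dose.volume, s)
    if s.is_empty():
        raise ValueError("empty structure has no DVH")
    return np.asarray(dose.volume.data, dtype=float)[s.mask]


def compute_dvh(dose: DoseGrid, s: Structure, bin_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH: value at edge d = % of structure voxels with dose >= d."""
    if bin_gy <= 0:
        raise ValueError("bin width must be positive")
    d = np.sort(_structure_doses(dose, s))
    top = d[-1] + 2 * bin_gy
    edges = np.arange(0.0, top + bin_gy, bin_gy)
    # voxels with dose >= edge, via searchsorted on the ascending doses
    cum = (len(d) - np.searchsorted(d, edges, side="left")) / len(d) * 100.0
    return DVHCurve(edges, cum)


def dvh_value_at(dvh: DVHCurve, dose_gy: float) -> float:
    """V_x read from the curve: % volume receiving >= dose_gy."""
    if dose_gy <= dvh.edges_gy[0]:
        return float(dvh.cum_pct[0])
    if dose_gy > dvh.edges_gy[-1]:
        return 0.0
    i = int(np.searchsorted(dvh.edges_gy, dose_gy, side="left"))
    return float(dvh.cum_pct[i])


def dvh_dose_at(dvh: DVHCurve, q_pct: float) -> float:
    """D_q read from the curve: highest edge with >= q % of the volume."""
    if not (0 < q_pct <= 100):
        raise ValueError("q must be in (0, 100]")
    ok = np.flatnonzero(dvh.cum_pct >= q_pct)
    return float(dvh.edges_gy[ok[-1]]) if ok.size else float(dvh.edges_gy[0])


def volume_fraction_at(dose: DoseGrid, s: Structure, x_gy: float) -> float:
    """Exact V_x (%) from voxel doses (inclusive >=)."""
    d = _structure_doses(dose, s)
    return float(np.mean(d >= x_gy) * 100.0)


def dose_to_hottest(dose: DoseGrid, s: Structure, q_pct: float) -> float:
    """Exact D_q (Gy): minimum dose received by the hottest q % of voxels."""
    if not (0 < q_pct <= 100):
        raise ValueError("q must be in (0, 100]")
    d = np.sort(_structure_doses(dose, s))[::-1]
    k = max(1, math.ceil(q_pct / 100.0 * len(d)))
    return float(d[k - 1])


def mean_dose(dose: DoseGrid, s: Structure) -> float:
    return float(np.mean(_structure_doses(dose, s)))


def max_dose(dose: DoseGrid, s: Structure) -> float:
    return float(np.max(_structure_doses(dose, s)))


def homogeneity_index(d2_gy: float, d98_gy: float, prescription_gy: float) -> float:
    """HI = (D2 - D98)/prescription × 100 % (lower is more homogeneous)."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    if d2_gy < d98_gy:
        raise ValueError("D2 must be >= D98")
    return (d2_gy - d98_gy) / prescription_gy * 100.0


def conformity_index(dose: DoseGrid, target: Structure,
                     reference_gy: float | None = None) -> float:
    """CI = (Vt,ref/Vt)·(Vt,ref/Vref), in (0, 1]; 1 is perfect conformity.

    ``Vt,ref`` is the target volume covered by the reference isodose and
    ``Vref`` the total volume it covers.  The reference level defaults to
    the prescription dose.
    """
    assert_congruent(dose.volume, target)
    if target.is_empty():
        raise ValueError("empty target")
    ref = dose.prescription_gy if reference_gy is None else reference_gy
    covered = np.asarray(dose.volume.data) >= ref
    vref = np.count_nonzero(covered)
    if vref == 0:
        raise ValueError("reference isodose covers no voxels")
    vt = np.count_nonzero(target.mask)
    vt_ref = np.count_nonzero(covered & target.mask)
    return float((vt_ref / vt) * (vt_ref / vref))


def evaluate_plan(dose: DoseGrid, ptv: Structure, oars: dict[str, Structure]) -> PlanMetrics:
    """All evaluation factors of one plan (lung/heart V_x, MLD, MHD,
    cord Dmax, PTV D2/D98, HI, CI, conformity volumes, coverage)."""
    lung, heart, cord = oars["total_lung"], oars["heart"], oars["spinal_cord"]
    d2 = dose_to_hottest(dose, ptv, 2.0)
    d98 = dose_to_hottest(dose, ptv, 98.0)
    rx = dose.prescription_gy
    covered = np.asarray(dose.volume.data) >= rx
    voxvol = ptv.voxel_volume_mm3 / 1000.0
    vt = np.count_nonzero(ptv.mask) * voxvol
    vt_ref = np.count_nonzero(covered & ptv.mask) * voxvol
    vref = np.count_nonzero(covered) * voxvol
    return PlanMetrics(
        lung_v5=volume_fraction_at(dose, lung, 5.0),
        lung_v10=volume_fraction_at(dose, lung, 10.0),
        lung_v20=volume_fraction_at(dose, lung, 20.0),
        lung_v30=volume_fraction_at(dose, lung, 30.0),
        lung_v40=volume_fraction_at(dose, lung, 40.0),
        mld=mean_dose(dose, lung),
        heart_v30=volume_fraction_at(dose, heart, 30.0),
        heart_v40=volume_fraction_at(dose, heart, 40.0),
        mhd=mean_dose(dose, heart),
        cord_dmax=max_dose(dose, cord),
        ptv_d2=d2,
        ptv_d98=d98,
        hi=homogeneity_index(d2, d98, rx),
        ci=conformity_index(dose, ptv),
        vt_cm3=float(vt),
        vt_ref_cm3=float(vt_ref),
        vref_cm3=float(vref),
        ptv_coverage_pct=volume_fraction_at(dose, ptv, rx),
        dmax_gy=float(np.max(dose.volume.data)),
    )
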