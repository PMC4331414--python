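"""Geometric comparison measures: longitudinal length, volume, overlap index.

Length convention: the craniocaudal extent is the slab extent — the first
and last occupied slices count at full thickness, so N occupied slices
give N × dz.  Lengths are measured along the straight z axis (the phantom
esophagus is straight).
"""

from __future__ import annotations

import numpy as np

from .volumes import Structure, assert_congruent

__all__ = ["longitudinal_length", "mask_volume", "overlap_index"]


def longitudinal_length(s: Structure) -> float:
    """Maximum longitudinal (craniocaudal) extent of a mask, in cm."""
    occupied = np.flatnonzero(s.mask.any(axis=(0, 1)))
    if occupied.size == 0:
        raise ValueError("empty mask has no length")
    n_slices = occupied[-1] - occupied[0] + 1
    return float(n_slices * s.spacing[2] / 10.0)


def mask_volume(s: Structure) -> float:
    """Mask volume in cm³ (voxel count × voxel volume); empty mask -> 0."""
    return float(np.count_nonzero(s.mask)) * s.voxel_volume_mm3 / 1000.0


def overlap_index(gtv_pet: Structure, gtv_ct: Structure) -> float:
    """Overlap index OI = |GTV_PET ∩ GTV_CT| / |GTV_CT|.

    Reflects the inclusion of the PET-derived contour within the CT
    contour: 1 means the CT volume is fully covered, 0 means disjoint.
    """
    assert_congruent(gtv_pet, gtv_ct)
    n_ct = np.count_nonzero(gtv_ct.mask)
    if n_ct == 0:
        raise ValueError("GTV_CT is empty (overlap index undefined)")
    inter = np.count_nonzero(gtv_pet.mask & gtv_ct.mask)
    return float(inter / n_ct)
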