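import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from petgtv.planning import (DoseGrid, compute_dvh, conformity_index, dose_to_hottest,
                             dvh_dose_at, dvh_value_at, expand_margin_anisotropic,
                             expand_margin_isotropic, homogeneity_index, mean_dose,
                             resample_structure, synthetic_dose, volume_fraction_at)
from petgtv.volumes import ImageVolume, Structure

import oracles


def struct(mask, spacing=(2.5, 2.5, 2.5), label="s"):
    return Structure(label, np.asarray(mask, bool), spacing)


def box(shape, lo, hi, spacing=(2.5, 2.5, 2.5)):
    mask = np.zeros(shape, bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return struct(mask, spacing)


@pytest.fixture(scope="module")
def small_plan():
    """A compact PTV with its synthetic dose, for DVH-level tests."""
    ptv = box((40, 40, 40), (15, 15, 12), (25, 25, 28))
    dose = synthetic_dose(ptv, prescription_gy=60.0, penumbra_sigma_mm=5.0)
    return ptv, dose


class TestMargins:
    def test_zero_margins_are_identity(self):
        s = box((12, 12, 12), (4, 4, 4), (8, 8, 8))
        out = expand_margin_anisotropic(s, (0, 0, 0))
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_box_z_extent_grows_by_twice_cc_margin(self):
        s = box((20, 20, 50), (8, 8, 18), (12, 12, 28))
        out = expand_margin_anisotropic(s, (10.0, 10.0, 30.0))
        zs = np.flatnonzero(out.mask.any(axis=(0, 1)))
        zs0 = np.flatnonzero(s.mask.any(axis=(0, 1)))
        grown_mm = ((zs[-1] - zs[0]) - (zs0[-1] - zs0[0])) * 2.5
        assert grown_mm == pytest.approx(60.0)

    @given(mask=hnp.arrays(np.bool_, (6, 6, 6), elements=st.booleans()),
           margins=st.tuples(*[st.sampled_from([0.0, 2.0, 3.5, 5.0])] * 3))
    @settings(max_examples=25)
    def test_matches_bruteforce_scaled_distance(self, mask, margins):
        if not mask.any():
            return
        s = struct(mask, spacing=(2.0, 2.0, 2.0))
        out = expand_margin_anisotropic(s, margins)
        expected = oracles.ellipsoid_dilation_oracle(mask, (2.0, 2.0, 2.0), margins)
        np.testing.assert_array_equal(out.mask, expected)

    def test_isotropic_sphere_volume_grows_to_r_plus_margin(self):
        spacing = (2.0, 2.0, 2.0)
        x = (np.arange(40) * 2.0)[:, None, None] - 39.0
        y = (np.arange(40) * 2.0)[None, :, None] - 39.0
        z = (np.arange(40) * 2.0)[None, None, :] - 39.0
        r = 15.0
        s = struct(x**2 + y**2 + z**2 <= r**2, spacing)
        out = expand_margin_isotropic(s, 5.0)
        # equivalent radius within half a voxel diagonal of r + margin
        r_eq = (3.0 * out.volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
        assert abs(r_eq - (r + 5.0)) <= np.linalg.norm(spacing) / 2.0

    def test_dilation_is_superset(self):
        s = box((10, 10, 10), (4, 4, 4), (6, 6, 6))
        out = expand_margin_isotropic(s, 5.0)
        assert np.all(~s.mask | out.mask)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expand_margin_anisotropic(struct(np.zeros((4, 4, 4))), (1, 1, 1))


class TestResampling:
    def test_roundtrip_on_identical_grid_is_identity(self):
        s = box((10, 10, 10), (2, 2, 2), (8, 8, 8))
        grid = ImageVolume(np.zeros((10, 10, 10)), (2.5, 2.5, 2.5))
        np.testing.assert_array_equal(resample_structure(s, grid).mask, s.mask)

    def test_extent_preserved_within_one_voxel(self):
        s = box((20, 20, 24), (5, 5, 6), (15, 15, 18), spacing=(2.0, 2.0, 4.25))
        fine = ImageVolume(np.zeros((16, 16, 40)), (2.5, 2.5, 2.5),
                           origin=(0.0, 0.0, 0.0))
        out = resample_structure(s, fine)
        zs = np.flatnonzero(out.mask.any(axis=(0, 1)))
        extent = (zs[-1] - zs[0] + 1) * 2.5
        orig = 12 * 4.25
        assert abs(extent - orig) <= 4.25


class TestSyntheticDose:
    def test_coverage_and_hotspot_goals(self, small_plan):
        ptv, dose = small_plan
        assert volume_fraction_at(dose, ptv, 60.0) >= 95.0
        assert float(np.max(dose.volume.data)) < 66.0

    def test_distant_dose_is_negligible(self, small_plan):
        ptv, dose = small_plan
        # corner voxels are > 5 penumbra sigmas from the PTV
        assert dose.volume.data[0, 0, 0] < 0.01 * 60.0

    def test_falls_monotonically_outside_ptv(self, small_plan):
        ptv, dose = small_plan
        xs = np.flatnonzero(ptv.mask.any(axis=(1, 2)))
        profile = dose.volume.data[xs[-1]:, 20, 20]
        assert np.all(np.diff(profile) <= 1e-9)

    def test_unreachable_constraints_reported(self):
        # a thin elongated PTV with a broad penumbra: its endpoints see
        # roughly half the central dose, so covering 95 % of it would
        # push the hotspot far beyond 110 % of the prescription
        ptv = box((40, 40, 40), (19, 19, 5), (21, 21, 35))
        with pytest.raises(ValueError, match="coverage"):
            synthetic_dose(ptv, 60.0, penumbra_sigma_mm=10.0,
                           interior_margin_mm=0.0)


class TestDvh:
    def test_uniform_dose_is_step_function(self):
        s = box((6, 6, 6), (0, 0, 0), (6, 6, 6))
        dose = DoseGrid(ImageVolume(np.full((6, 6, 6), 60.0), (2.5, 2.5, 2.5)), 60.0)
        dvh = compute_dvh(dose, s)
        assert dvh.cum_pct[0] == 100.0
        assert dvh_value_at(dvh, 60.0) == 100.0
        assert dvh_value_at(dvh, 60.2) == 0.0
        assert dvh_dose_at(dvh, 2.0) == pytest.approx(60.0, abs=0.1)

    def test_monotone_with_correct_endpoints(self, small_plan):
        ptv, dose = small_plan
        dvh = compute_dvh(dose, ptv)
        assert dvh.cum_pct[0] == 100.0
        assert np.all(np.diff(dvh.cum_pct) <= 0)
        assert dvh.cum_pct[-1] == 0.0

    def test_two_level_dose_vx_and_mean(self):
        s = box((4, 4, 4), (0, 0, 0), (4, 4, 4))
        d = np.full((4, 4, 4), 10.0)
        d[:, :, 2:] = 30.0
        dose = DoseGrid(ImageVolume(d, (2.5, 2.5, 2.5)), 60.0)
        assert volume_fraction_at(dose, s, 20.0) == 50.0
        assert mean_dose(dose, s) == pytest.approx(20.0)

    def test_mean_from_curve_matches_voxel_mean(self, small_plan):
        ptv, dose = small_plan
        dvh = compute_dvh(dose, ptv, bin_gy=0.1)
        # integrate the cumulative curve: mean = sum of bin widths x fraction
        mean_from_curve = np.trapezoid(dvh.cum_pct / 100.0, dvh.edges_gy)
        assert mean_from_curve == pytest.approx(mean_dose(dose, ptv), abs=0.1)

    def test_vx_dq_match_sorting_oracle(self, small_plan):
        ptv, dose = small_plan
        doses = dose.volume.data[ptv.mask]
        for x in (5.0, 20.0, 59.0, 61.0):
            assert volume_fraction_at(dose, ptv, x) == pytest.approx(
                oracles.vx_oracle(doses, x))
        for q in (2.0, 50.0, 98.0):
            assert dose_to_hottest(dose, ptv, q) == pytest.approx(
                oracles.dq_oracle(doses, q))

    def test_dq_vx_consistency(self, small_plan):
        ptv, dose = small_plan
        for q in (2.0, 50.0, 98.0):
            dq = dose_to_hottest(dose, ptv, q)
            assert volume_fraction_at(dose, ptv, dq) >= q

    def test_invalid_quantile_rejected(self, small_plan):
        ptv, dose = small_plan
        with pytest.raises(ValueError):
            dose_to_hottest(dose, ptv, 0.0)
        with pytest.raises(ValueError):
            dvh_dose_at(compute_dvh(dose, ptv), 101.0)


class TestIndices:
    def test_uniform_dose_has_zero_hi(self):
        assert homogeneity_index(60.0, 60.0, 60.0) == 0.0

    def test_hi_formula(self):
        assert homogeneity_index(63.0, 57.0, 60.0) == pytest.approx(10.0)

    def test_hi_preconditions(self):
        with pytest.raises(ValueError):
            homogeneity_index(57.0, 63.0, 60.0)
        with pytest.raises(ValueError):
            homogeneity_index(63.0, 57.0, 0.0)

    def test_hi_from_dvh_matches_sorting_oracle_within_bin(self, small_plan):
        ptv, dose = small_plan
        dvh = compute_dvh(dose, ptv, bin_gy=0.1)
        doses = dose.volume.data[ptv.mask]
        assert dvh_dose_at(dvh, 2.0) == pytest.approx(oracles.dq_oracle(doses, 2.0),
                                                      abs=0.1)
        assert dvh_dose_at(dvh, 98.0) == pytest.approx(oracles.dq_oracle(doses, 98.0),
                                                       abs=0.1)

    def _dose_covering(self, covered_mask, spacing=(2.5, 2.5, 2.5)):
        d = np.where(covered_mask, 60.0, 0.0)
        return DoseGrid(ImageVolume(d, spacing), 60.0)

    def test_ci_one_when_reference_equals_target(self):
        t = box((8, 8, 8), (2, 2, 2), (6, 6, 6))
        assert conformity_index(self._dose_covering(t.mask), t) == 1.0

    def test_ci_half_when_reference_doubles_target(self):
        t = box((8, 8, 8), (2, 2, 2), (6, 6, 6))
        ref = t.mask.copy()
        ref[0:2, 2:6, 2:6] = True
        ref[6:8, 2:6, 2:6] = True  # 128 voxels vs target 64
        assert conformity_index(self._dose_covering(ref), t) == pytest.approx(0.5)

    def test_ci_quarter_when_half_target_covered(self):
        t = box((8, 8, 8), (2, 2, 2), (6, 6, 6))
        ref = t.mask.copy()
        ref[:, :, 4:] = False      # half of the 64-voxel target
        ref[0:2, 2:6, 2:6] = True  # 32 voxels outside keep Vref = Vt
        assert conformity_index(self._dose_covering(ref), t) == pytest.approx(0.25)

    def test_ci_errors(self):
        t = box((8, 8, 8), (2, 2, 2), (6, 6, 6))
        with pytest.raises(ValueError, match="covers no voxels"):
            conformity_index(self._dose_covering(np.zeros((8, 8, 8), bool)), t)
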