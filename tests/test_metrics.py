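"""Centroid/offset/diameter measurements and group statistics.

Worked-example values come from the per-phantom offsets of the bundled
prototype calibration study dataset; expected statistics are recomputed
in-test by brute-force oracles (plain Python sums, analytic t CDF).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from histoqa import (
    BinaryMask,
    OffsetMeasurement,
    centroid,
    group_stats,
    measure_diameters,
    measure_offset,
    refine_calibration,
    reference_offset_groups,
    round_report,
    target_to_treatment_distance,
)

SP = 0.5


def mask_from_indices(indices, shape=(20, 20, 20), spacing=SP, origin=(0.25, 0.25, 0.25)):
    vals = np.zeros(shape, dtype=bool)
    for idx in indices:
        vals[tuple(idx)] = True
    return BinaryMask(vals, spacing, np.asarray(origin))


def sphere_mask(center, diameter, shape=(100, 100, 100), spacing=SP):
    origin = np.full(3, spacing / 2)
    ax = [origin[a] + spacing * np.arange(shape[a]) for a in range(3)]
    d2 = (
        (ax[0] - center[0])[:, None, None] ** 2
        + (ax[1] - center[1])[None, :, None] ** 2
        + (ax[2] - center[2])[None, None, :] ** 2
    )
    return BinaryMask(d2 <= (diameter / 2) ** 2, spacing, origin)


class TestCentroid:
    def test_single_voxel(self):
        m = mask_from_indices([(3, 5, 7)])
        assert np.allclose(centroid(m), [0.25 + 3 * SP, 0.25 + 5 * SP, 0.25 + 7 * SP])

    def test_two_voxel_midpoint(self):
        m = mask_from_indices([(0, 0, 0), (4, 2, 6)])
        assert np.allclose(centroid(m), [0.25 + 2 * SP, 0.25 + 1 * SP, 0.25 + 3 * SP])

    def test_sphere_centroid_symmetric(self):
        m = sphere_mask((25.0, 25.0, 25.0), 28.0)
        assert np.all(np.abs(centroid(m) - 25.0) <= SP / 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            centroid(mask_from_indices([]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_first_moment(self, data):
        n = data.draw(st.integers(1, 30))
        idx = data.draw(
            st.lists(
                st.tuples(*[st.integers(0, 9)] * 3), min_size=n, max_size=n, unique=True
            )
        )
        m = mask_from_indices(idx, shape=(10, 10, 10))
        expected = np.mean([[0.25 + SP * i for i in v] for v in idx], axis=0)
        assert np.all(np.abs(centroid(m) - expected) < 1e-12)


class TestMeasureOffset:
    def test_zero_when_centroid_equals_plan(self):
        m = mask_from_indices([(3, 3, 3)])
        off = measure_offset(centroid(m), m)
        assert off.euclidean_mm == 0.0

    def test_euclidean_from_printed_offsets(self):
        # first post-refinement phantom: (0.16, -0.28, -0.51) -> 0.603 mm
        off = OffsetMeasurement(0.16, -0.28, -0.51)
        assert off.euclidean_mm == pytest.approx(
            math.sqrt(0.16**2 + 0.28**2 + 0.51**2)
        )
        assert round_report(off.euclidean_mm, 3) == pytest.approx(0.603)

    def test_translation_shifts_offset_exactly(self):
        m = sphere_mask((20.0, 20.0, 20.0), 10.0, shape=(80, 80, 80))
        shift = (2, -3, 4)  # voxels
        m2 = BinaryMask(np.roll(m.values, shift, axis=(0, 1, 2)), m.spacing_mm, m.origin_mm)
        a = measure_offset((20.0, 20.0, 20.0), m)
        b = measure_offset((20.0, 20.0, 20.0), m2)
        assert np.allclose(b.vector - a.vector, np.array(shift) * SP)


class TestMeasureDiameters:
    def test_sphere_diameters(self):
        m = sphere_mask((25.0, 25.0, 25.0), 28.0)
        d = measure_diameters(m)
        assert np.all(np.abs(d.vector - 28.0) <= SP)

    def test_ellipsoid_diameters(self):
        origin = np.full(3, SP / 2)
        ax = [origin[a] + SP * np.arange(40) for a in range(3)]
        q = (
            ((ax[0] - 10.0) / 1.5)[:, None, None] ** 2
            + ((ax[1] - 10.0) / 1.5)[None, :, None] ** 2
            + ((ax[2] - 10.0) / 3.0)[None, None, :] ** 2
        )
        m = BinaryMask(q <= 1.0, SP, origin)
        d = measure_diameters(m)
        assert np.all(np.abs(d.vector - np.array([3.0, 3.0, 6.0])) <= SP)

    def test_disconnected_mask_rejected(self):
        m = mask_from_indices([(1, 1, 1), (10, 10, 10)])
        with pytest.raises(ValueError):
            measure_diameters(m)


class TestGroupStats:
    def test_reference_magnitudes_match_bruteforce(self):
        bcr, acr = reference_offset_groups()
        z_mags = [abs(o.dz_mm) for o in bcr]
        mean = sum(z_mags) / len(z_mags)
        sd = math.sqrt(sum((v - mean) ** 2 for v in z_mags) / (len(z_mags) - 1))
        gs = group_stats(bcr)
        assert gs.mean_abs_per_axis[2] == pytest.approx(mean, abs=1e-12)
        assert gs.sd_abs_per_axis[2] == pytest.approx(sd, abs=1e-12)

    def test_identical_groups_give_t0_p1(self):
        g = [OffsetMeasurement(0.1, 0.2, 0.3), OffsetMeasurement(0.4, 0.5, 0.6)]
        gs = group_stats(g, g)
        assert np.allclose(gs.t_statistic, 0.0)
        assert np.allclose(gs.p_value, 1.0)

    def test_pvalue_matches_analytic_t_distribution(self):
        bcr, acr = reference_offset_groups()
        gs = group_stats(bcr, acr)
        a = np.abs(np.array([o.vector for o in bcr]))
        b = np.abs(np.array([o.vector for o in acr]))
        na, nb = len(a), len(b)
        for axis in range(3):
            sa, sb = a[:, axis].std(ddof=1), b[:, axis].std(ddof=1)
            sp2 = ((na - 1) * sa**2 + (nb - 1) * sb**2) / (na + nb - 2)
            t = (a[:, axis].mean() - b[:, axis].mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * sps.t.sf(abs(t), na + nb - 2)
            assert gs.t_statistic[axis] == pytest.approx(t, abs=1e-10)
            assert gs.p_value[axis] == pytest.approx(p, abs=1e-10)

    def test_single_measurement_allowed_without_sd(self):
        gs = group_stats([OffsetMeasurement(0.1, 0.2, -2.4)])
        assert gs.n == 1
        assert np.all(np.isnan(gs.sd_per_axis))
        assert gs.mean_per_axis[2] == pytest.approx(-2.4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_stats([])

    def test_comparison_needs_two_per_group(self):
        g = [OffsetMeasurement(0.1, 0.2, 0.3), OffsetMeasurement(0.4, 0.5, 0.6)]
        with pytest.raises(ValueError):
            group_stats(g, [OffsetMeasurement(0.0, 0.0, 0.0)])


class TestRefineCalibration:
    def test_only_axes_above_threshold_corrected(self):
        bcr, _ = reference_offset_groups()
        corr = refine_calibration(group_stats(bcr))
        # X and Y means are < 1 mm; Z mean magnitude 2.38 mm exceeds it
        assert corr.correction_mm[0] == 0.0
        assert corr.correction_mm[1] == 0.0
        assert corr.correction_mm[2] == pytest.approx(-2.375, abs=1e-12)

    def test_all_small_offsets_give_zero_correction(self):
        g = [OffsetMeasurement(0.1, -0.2, 0.3), OffsetMeasurement(0.2, -0.1, 0.4)]
        assert refine_calibration(group_stats(g)).is_zero


class TestTargetToTreatmentDistance:
    def test_identical_masks_zero(self):
        m = sphere_mask((20.0, 20.0, 20.0), 10.0, shape=(80, 80, 80))
        d = target_to_treatment_distance(m, m)
        assert d.euclidean_mm == 0.0

    def test_known_translation(self):
        m = sphere_mask((20.0, 20.0, 20.0), 10.0, shape=(80, 80, 80))
        m2 = BinaryMask(np.roll(m.values, (0, 14, 0), axis=(0, 1, 2)), SP, m.origin_mm)
        d = target_to_treatment_distance(m, m2)
        assert d.dy_mm == pytest.approx(7.0)
        assert abs(d.dx_mm) < 1e-9 and abs(d.dz_mm) < 1e-9
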