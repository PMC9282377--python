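import itertools

import numpy as np
import pytest

from tibiapipe.morphometry import (
    CorticalVOISpec,
    TrabecularVOISpec,
    betti_numbers,
    bvtv,
    connectivity_density,
    cortical_analysis,
    degree_of_anisotropy,
    euler_characteristic,
    local_thickness,
    local_thickness_map,
    tb_n,
    trabecular_voi,
)
from tibiapipe.synthetic import make_morphometry_phantom


def euler_oracle(mask: np.ndarray) -> int:
    """Set-based cell counting: chi = V - E + F - C of the cubical complex."""
    verts, edges, faces, cubes = set(), set(), set(), set()
    for z, y, x in np.argwhere(mask):
        cubes.add((z, y, x))
        corners = list(itertools.product((z, z + 1), (y, y + 1), (x, x + 1)))
        verts.update(corners)
        for a, b in itertools.combinations(corners, 2):
            d = np.abs(np.subtract(a, b))
            if d.sum() == 1:
                edges.add(frozenset((a, b)))
        for axis in range(3):
            for off in (0, 1):
                face = tuple(sorted(c for c in corners if c[axis] == (z, y, x)[axis] + off))
                faces.add(face)
    return len(verts) - len(edges) + len(faces) - len(cubes)


class TestThickness:
    def test_plate_thickness_exact(self):
        img, exp = make_morphometry_phantom("plate", voxel_size=0.02, thickness_vox=8)
        th = local_thickness(exp["mask"], 0.02)
        assert th == pytest.approx(exp["thickness_mm"] * 1000, abs=0.5 * 0.02 * 1000)

    def test_rod_diameter_within_voxel(self):
        img, exp = make_morphometry_phantom("rod", voxel_size=0.02, diameter_vox=9)
        th = local_thickness(exp["mask"], 0.02)
        assert th == pytest.approx(exp["thickness_mm"] * 1000, abs=0.02 * 1000)

    def test_scale_equivariance(self):
        _, exp = make_morphometry_phantom("plate", thickness_vox=4, size=24)
        m = exp["mask"]
        m2 = m.repeat(2, 0).repeat(2, 1).repeat(2, 2)
        t1 = local_thickness_map(m)[m].mean()
        t2 = local_thickness_map(m2)[m2].mean()
        assert t2 == pytest.approx(2 * t1, rel=0.05)


class TestBVTVandTbN:
    def test_full_and_empty(self):
        roi = np.ones((4, 4, 4), bool)
        assert bvtv(np.ones((4, 4, 4), bool), roi) == 100.0
        assert bvtv(np.zeros((4, 4, 4), bool), roi) == 0.0

    def test_counting_oracle(self, rng):
        roi = np.ones((6, 6, 6), bool)
        bone = rng.random((6, 6, 6)) > 0.5
        assert bvtv(bone, roi) == pytest.approx(100 * bone.sum() / 216)

    def test_tb_n_ratio_convention(self):
        assert tb_n(20.0, 50.0) == pytest.approx(4.0)
        assert tb_n(0.0, 50.0) == 0.0
        with pytest.raises(ValueError):
            tb_n(10.0, 0.0)


class TestConnectivity:
    def test_euler_matches_set_oracle_on_random_masks(self, rng):
        for _ in range(20):
            m = rng.random((5, 5, 5)) > 0.6
            assert euler_characteristic(m) == euler_oracle(m)

    def test_single_cube(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert euler_characteristic(m) == 1

    def test_solid_ball_has_no_handles(self):
        _, exp = make_morphometry_phantom("ball", radius_vox=6)
        b0, b1, b2 = betti_numbers(exp["mask"], boundary_connectivity=False)
        assert (b0, b1, b2) == (1, 0, 0)

    def test_torus_has_one_handle(self):
        _, exp = make_morphometry_phantom("torus", major_vox=8, minor_vox=3)
        m = exp["mask"]
        assert euler_characteristic(m) == 0
        b0, b1, b2 = betti_numbers(m, boundary_connectivity=False)
        assert (b0, b1, b2) == (1, 1, 0)
        assert connectivity_density(m, 10.0) == pytest.approx(0.1)

    def test_disjoint_tori_additivity(self):
        _, exp = make_morphometry_phantom("torus", major_vox=8, minor_vox=3)
        m = exp["mask"]
        two = np.concatenate([m, np.zeros_like(m[:2]), m], axis=0)
        assert betti_numbers(two, boundary_connectivity=False)[1] == 2

    def test_enclosed_cavity_counted(self):
        m = np.ones((5, 5, 5), bool)
        m[2, 2, 2] = False
        b0, b1, b2 = betti_numbers(m, boundary_connectivity=False)
        assert (b0, b1, b2) == (1, 0, 1)


class TestAnisotropy:
    def test_ball_is_isotropic(self):
        _, exp = make_morphometry_phantom("ball", radius_vox=12)
        da = degree_of_anisotropy(exp["mask"], n_directions=128)
        assert da == pytest.approx(1.0, abs=0.05)

    def test_parallel_plates_strongly_anisotropic(self):
        m = np.zeros((40, 40, 40), bool)
        for z0 in range(2, 40, 10):
            m[z0:z0 + 2] = True
        da = degree_of_anisotropy(m, n_directions=128)
        assert da >= 3.0

    def test_quarter_turn_invariance(self):
        m = np.zeros((40, 40, 40), bool)
        for z0 in range(2, 40, 10):
            m[z0:z0 + 2] = True
        m[:, ::9, :] = True  # break full symmetry
        da1 = degree_of_anisotropy(m, n_directions=256, line_spacing=1.5)
        da2 = degree_of_anisotropy(np.rot90(m, axes=(1, 2)).copy(),
                                   n_directions=256, line_spacing=1.5)
        assert da2 == pytest.approx(da1, rel=0.02)


class TestCortical:
    def test_hollow_cylinder_geometry(self):
        img, exp = make_morphometry_phantom(
            "hollow_cylinder", voxel_size=0.02, outer_vox=20, inner_vox=14, height=40)
        m = exp["mask"]
        spec = CorticalVOISpec(center_slice=20, extent_mm=0.4, closing_radius_px=3)
        tt, ct, ratio, ct_th = cortical_analysis(m, spec, 0.02)
        assert ct_th == pytest.approx(6 * 0.02 * 1000, abs=0.02 * 1000)
        assert tt == pytest.approx(np.pi * (20 * 0.02) ** 2, rel=0.05)
        assert ratio < 1.0

    def test_solid_bar_ratio_one(self):
        m = np.zeros((20, 30, 30), bool)
        m[:, 5:25, 5:25] = True
        spec = CorticalVOISpec(center_slice=10, extent_mm=0.2, closing_radius_px=3)
        tt, ct, ratio, _ = cortical_analysis(m, spec, 0.02)
        assert ratio == pytest.approx(1.0)
        assert tt == pytest.approx(ct)

    def test_closing_removes_small_pore_preserving_outline(self):
        zz, yy, xx = np.indices((10, 41, 41))
        r2 = (yy - 20) ** 2 + (xx - 20) ** 2
        ring = (r2 <= 15**2) & (r2 > 8**2)
        m = np.zeros((10, 41, 41), bool)
        m[:] = ring
        m[:, 18:21, 8:11] = False  # 3-px pore inside the cortex
        spec = CorticalVOISpec(center_slice=5, extent_mm=0.1, closing_radius_px=5)
        tt, ct, ratio, _ = cortical_analysis(m, spec, 0.02)
        tt_ref, ct_ref, *_ = cortical_analysis(
            np.broadcast_to(ring, m.shape).copy(), spec, 0.02)
        assert ct == pytest.approx(ct_ref, rel=0.01)
        assert tt == pytest.approx(tt_ref, rel=0.01)


class TestTrabecularVOI:
    def test_slice_arithmetic_at_paper_resolution(self):
        # hollow ring cross-section so the endosteal ROI is non-empty
        mask = np.zeros((130, 24, 24), bool)
        mask[:, 3:21, 3:21] = True
        mask[:, 7:17, 7:17] = False
        spec = TrabecularVOISpec(reference_slice=5, offset_mm=0.2, extent_mm=1.0)
        roi = trabecular_voi(mask, spec, 0.0104)
        zs = np.flatnonzero(roi.any(axis=(1, 2)))
        assert zs[0] == 5 + 19   # 0.2 / 0.0104 = 19.23 -> 19
        assert zs.size == 96     # 1.0 / 0.0104 = 96.15 -> 96

    def test_constant_polygon_constant_roi(self):
        mask = np.zeros((60, 20, 20), bool)
        mask[:, 5:15, 5:15] = True
        poly = np.array([[4.0, 4.0], [16.0, 4.0], [16.0, 16.0], [4.0, 16.0]])
        spec = TrabecularVOISpec(reference_slice=0, offset_mm=0.1, extent_mm=0.3,
                                 contours={0: poly, 55: poly})
        roi = trabecular_voi(mask, spec, 0.02)
        zs = np.flatnonzero(roi.any(axis=(1, 2)))
        first = roi[zs[0]]
        assert all(np.array_equal(roi[z], first) for z in zs)

    def test_auto_roi_covers_phantom_trabecular_mask(self, coarse_phantom):
        spec, image, truth = coarse_phantom
        tspec = TrabecularVOISpec(reference_slice=truth.reference_slice)
        roi = trabecular_voi(truth.tibia_mask, tspec, spec.voxel_size)
        zs = np.flatnonzero(roi.any(axis=(1, 2)))
        trab = truth.trabecular_mask.copy()
        trab[:zs[0]] = trab[zs[-1] + 1:] = False
        covered = (roi & trab).sum() / max(trab.sum(), 1)
        assert covered >= 0.95

    def test_missing_contours_rejected(self):
        mask = np.ones((30, 10, 10), bool)
        spec = TrabecularVOISpec(reference_slice=0, contours={})
        with pytest.raises(ValueError):
            trabecular_voi(mask, spec, 0.02)
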