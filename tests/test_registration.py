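import numpy as np
import pytest

from tibiapipe.image import RigidTransform, VoxelImage, resample
from tibiapipe.registration import (
    FilterParams,
    detect_voi_start,
    exclude_fibula,
    gaussian_kernel_3d,
    gaussian_smooth,
    measure_length,
    nmi,
    rigid_register,
    select_voi,
)
from tibiapipe.synthetic import perturb_acquisition


class TestNMI:
    def test_identical_images_give_two(self, rng):
        a = rng.integers(0, 8, (20, 20, 20)).astype(float)
        assert nmi(a, a, bins=8) == pytest.approx(2.0, abs=1e-12)

    def test_independent_noise_approaches_one(self, rng):
        a = rng.random((48, 48, 48))
        b = rng.random((48, 48, 48))
        assert nmi(a, b, bins=16) == pytest.approx(1.0, abs=0.01)

    def test_grey_label_permutation_invariance(self, rng):
        a = rng.integers(0, 6, (16, 16, 16)).astype(float)
        b = rng.integers(0, 6, (16, 16, 16)).astype(float)
        perm = rng.permutation(6).astype(float)
        # relabel a's grey levels and rescale to keep bin boundaries aligned
        a2 = perm[a.astype(int)]
        assert nmi(a2, b, bins=6) == pytest.approx(nmi(a, b, bins=6), abs=1e-9)

    def test_self_beats_shifted_copy(self, rng):
        a = np.zeros((24, 24, 24))
        a[6:18, 6:18, 6:18] = rng.random((12, 12, 12)) + 1.0
        shifted = np.roll(a, 3, axis=2)
        assert nmi(a, a) > nmi(a, shifted)

    def test_constant_image_rejected(self):
        c = np.ones((8, 8, 8))
        with pytest.raises(ValueError):
            nmi(c, c)


class TestGaussianSmooth:
    def test_kernel_matches_hand_computed_values(self):
        k = gaussian_kernel_3d(FilterParams(3, 0.65))
        # direct evaluation of the normalized truncated Gaussian
        ax = np.array([-1.0, 0.0, 1.0])
        g = np.exp(-(ax**2) / (2 * 0.65**2))
        ref = g[:, None, None] * g[None, :, None] * g[None, None, :]
        ref /= ref.sum()
        assert np.allclose(k, ref, atol=1e-14)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert k[1, 1, 1] == pytest.approx(ref.max())

    def test_constant_image_unchanged(self):
        img = VoxelImage(np.full((8, 9, 10), 5.0), 0.1)
        out = gaussian_smooth(img)
        assert np.allclose(out.data, 5.0, atol=1e-10)

    def test_impulse_centre_weight(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0
        out = gaussian_smooth(VoxelImage(data, 0.1))
        k = gaussian_kernel_3d(FilterParams())
        assert out.data[4, 4, 4] == pytest.approx(k[1, 1, 1], abs=1e-7)

    def test_interior_sum_conserved(self, rng):
        data = np.zeros((16, 16, 16))
        data[4:12, 4:12, 4:12] = rng.random((8, 8, 8))
        out = gaussian_smooth(VoxelImage(data, 0.1))
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)


class TestLengthAndVOI:
    def test_length_from_slice_span(self):
        mask = np.zeros((120, 5, 5), bool)
        mask[10:110, 2, 2] = True
        assert measure_length(mask, 0.0104) == pytest.approx(1.04)

    def test_single_slice_object(self):
        mask = np.zeros((10, 4, 4), bool)
        mask[3, 1, 1] = True
        assert measure_length(mask, 0.0104) == pytest.approx(0.0104)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            measure_length(np.zeros((5, 5, 5), bool), 0.01)

    def test_voi_slice_arithmetic(self):
        mask = np.zeros((110, 6, 6), bool)
        mask[0:100, 2:4, 2:4] = True
        voi = select_voi(mask, 1.0, start_slice=5, fraction=0.8)
        assert (voi.start_slice, voi.end_slice) == (5, 84)
        assert voi.n_slices == 80

    def test_full_fraction_covers_whole_bone(self):
        mask = np.zeros((50, 4, 4), bool)
        mask[0:50, 1, 1] = True
        voi = select_voi(mask, 1.0, start_slice=0, fraction=1.0)
        assert (voi.start_slice, voi.end_slice) == (0, 49)

    def test_voi_beyond_image_raises(self):
        mask = np.ones((50, 4, 4), bool)
        with pytest.raises(ValueError):
            select_voi(mask, 1.0, start_slice=30, fraction=0.8)

    def test_voi_length_invariant(self, coarse_phantom):
        spec, image, truth = coarse_phantom
        voi = select_voi(truth.tibia_mask, spec.voxel_size,
                         truth.voi_start_slice, 0.8)
        v = spec.voxel_size
        assert 0.8 * voi.length_mm - v <= voi.n_slices * v <= 0.8 * voi.length_mm + v

    def test_phantom_length_matches_truth(self, coarse_phantom):
        spec, image, truth = coarse_phantom
        L = measure_length(truth.tibia_mask, spec.voxel_size)
        assert abs(L - truth.true_length_mm) <= 2 * spec.voxel_size


class TestExcludeFibula:
    def test_mask_without_fibula_unchanged(self):
        mask = np.zeros((20, 10, 10), bool)
        mask[:, 3:7, 3:7] = True
        out = exclude_fibula(mask, (5, 10))
        assert np.array_equal(out, mask)

    def test_touching_components_resolved_to_one(self):
        # big block and small rod touching only inside the junction range
        mask = np.zeros((30, 20, 20), bool)
        mask[:, 2:12, 2:12] = True          # tibia surrogate
        mask[0:20, 13:15, 6:8] = True       # fibula surrogate
        mask[14:16, 12, 6] = True           # bridge inside junction range
        out = exclude_fibula(mask, (12, 18))
        from scipy import ndimage
        _, n = ndimage.label(out, structure=np.ones((3, 3, 3), int))
        assert n == 1
        assert not out[5, 13:15, 6:8].any()  # fibula rod removed

    def test_phantom_fibula_fully_removed(self, coarse_phantom):
        spec, image, truth = coarse_phantom
        out = exclude_fibula(truth.bone_mask, truth.junction_zrange)
        assert not (out & truth.fibula_mask).any()
        # tibia voxels outside the junction range survive untouched
        assert (out & truth.tibia_mask).sum() == truth.tibia_mask.sum()

    def test_detect_voi_start_near_truth(self, coarse_phantom):
        spec, image, truth = coarse_phantom
        est = detect_voi_start(truth.bone_mask)
        assert abs(est - truth.voi_start_slice) <= 2


class TestRigidRegistration:
    def test_self_registration_returns_identity(self, coarse_phantom):
        spec, image, truth = coarse_phantom
        t = rigid_register(image, image)
        assert np.abs(t.angles_deg).max() < 0.1
        assert np.abs(t.translation_mm).max() < 0.1 * spec.voxel_size + 0.05

    def test_known_rotation_recovered(self, coarse_phantom):
        spec, image, truth = coarse_phantom
        true_t = RigidTransform([5.0, 0, 0], [0, 0, 0], image.center_mm())
        moved = resample(image, true_t, "lanczos",
                         background=float(np.median(image.data[0])))
        rec = rigid_register(moved, image)
        # recovered transform is the inverse of the applied one
        assert rec.angles_deg[0] == pytest.approx(-5.0, abs=0.5)

    def test_perturbation_recovery_within_tolerance(self, coarse_phantom):
        spec, image, truth = coarse_phantom
        scan, t2 = perturb_acquisition(image, truth, 2.0, 0.10, seed=21)
        rng = np.random.default_rng(5)
        init = RigidTransform(rng.uniform(-2, 2, 3), rng.uniform(-0.2, 0.2, 3),
                              scan.center_mm())
        res = rigid_register(scan, image, init=init, full_output=True)
        resid = res.transform.compose(t2.applied_transform)
        assert np.abs(resid.angles_deg).max() < 0.5
        assert np.abs(resid.translation_mm).max() < 0.05
        assert res.nmi_opt >= res.nmi_init
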