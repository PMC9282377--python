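import numpy as np
import pytest
from scipy import ndimage

from tibiapipe.microfe import (
    FailureCriterion,
    LoadCase,
    MaterialModel,
    apparent_stiffness,
    assemble_and_solve,
    assemble_stiffness,
    build_model,
    element_stiffness,
    failure_load,
    strain_field,
)

E_BONE = 14800.0


def solve_dense(model, load):
    """Independent dense direct-solve oracle (same BCs, LAPACK solve)."""
    K = assemble_stiffness(model).toarray()
    n_dof = model.n_nodes * 3
    prescribed = np.zeros(n_dof, bool)
    values = np.zeros(n_dof)
    for nid in model.distal_nodes:
        prescribed[3 * nid:3 * nid + 3] = True
    uz = 3 * model.proximal_nodes + 2
    prescribed[uz] = True
    values[uz] = load.applied_displacement_mm
    free = ~prescribed
    u = values.copy()
    u[free] = np.linalg.solve(K[np.ix_(free, free)],
                              -K[np.ix_(free, prescribed)] @ values[prescribed])
    return u.reshape(-1, 3)


def random_connected_mesh(rng, max_side=6):
    while True:
        shape = rng.integers(2, max_side + 1, 3)
        mask = rng.random(shape) > 0.4
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, ndimage.generate_binary_structure(3, 1))
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (np.argmax(sizes) + 1)
        zs = np.flatnonzero(mask.any(axis=(1, 2)))
        if zs.size >= 2 and mask.sum() >= 4:
            return mask


class TestElementStiffness:
    def test_rank_and_rigid_modes(self):
        K = element_stiffness(MaterialModel(), 0.0104)
        w = np.linalg.eigvalsh(K)
        assert (w > 1e-9 * w[-1]).sum() == 18
        assert w[0] >= -1e-9 * w[-1]
        for dof in range(3):
            v = np.tile(np.eye(3)[dof], 8)
            assert np.abs(K @ v).max() < 1e-12 * np.abs(K).max()

    def test_scales_linearly_with_h_and_E(self):
        K1 = element_stiffness(MaterialModel(1000.0, 0.3), 1.0)
        assert np.allclose(element_stiffness(MaterialModel(1000.0, 0.3), 2.0), 2 * K1)
        assert np.allclose(element_stiffness(MaterialModel(3000.0, 0.3), 1.0), 3 * K1)

    def test_symmetry(self):
        K = element_stiffness(MaterialModel(), 1.0)
        assert np.allclose(K, K.T)


class TestSolve:
    def test_single_element_uniform_strain(self):
        model = build_model(np.ones((1, 1, 1), bool), 1.0, MaterialModel(1000.0, 0.0))
        load = LoadCase(0.1)
        res = assemble_and_solve(model, load, solver="direct")
        e_el, e_nd = strain_field(res, model)
        assert np.allclose(e_el, -0.1, atol=1e-12)
        # nu = 0: no transverse displacement anywhere
        assert np.abs(res.displacements[:, :2]).max() < 1e-12

    def test_sparse_equals_dense_oracle(self, rng):
        for _ in range(8):
            mask = random_connected_mesh(rng)
            model = build_model(mask, 0.5)
            load = LoadCase(0.05)
            res = assemble_and_solve(model, load, solver="pcg", tol=1e-12)
            ref = solve_dense(model, load)
            scale = np.abs(ref).max()
            assert np.abs(res.displacements - ref).max() < 1e-8 * scale

    def test_translation_invariance(self, rng):
        mask = np.zeros((8, 6, 6), bool)
        mask[1:7, 1:4, 2:5] = True
        m1 = build_model(mask, 0.5)
        shifted = np.roll(mask, (0, 2, 1), axis=(0, 1, 2))
        m2 = build_model(shifted, 0.5)
        r1 = assemble_and_solve(m1, solver="direct")
        r2 = assemble_and_solve(m2, solver="direct")
        assert r1.stiffness_n_mm == pytest.approx(r2.stiffness_n_mm, rel=1e-10)

    def test_reaction_balance(self):
        mask = np.ones((10, 3, 3), bool)
        model = build_model(mask, 0.2)
        res = assemble_and_solve(model, solver="direct")
        prox = res.solver_info["proximal_reaction_n"]
        assert res.total_reaction_n == pytest.approx(-prox, rel=1e-6)

    def test_disconnected_mesh_rejected(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0:2, 0:2, 0:2] = True
        mask[3:5, 3:5, 3:5] = True
        with pytest.raises(ValueError, match="components"):
            build_model(mask, 0.5)


class TestStiffnessAndFailure:
    def test_bar_matches_analytic_formula(self):
        # E A / L for a slender bar with nu = 0
        mask = np.ones((40, 6, 6), bool)
        h = 0.0104
        model = build_model(mask, h, MaterialModel(E_BONE, 0.0))
        load = LoadCase(0.1)
        res = assemble_and_solve(model, load, solver="pcg")
        expected = E_BONE * (6 * h) ** 2 / (40 * h)
        assert apparent_stiffness(res, load) == pytest.approx(expected, rel=1e-6)

    def test_doubling_E_doubles_stiffness(self):
        mask = np.ones((10, 3, 3), bool)
        r1 = assemble_and_solve(build_model(mask, 0.3, MaterialModel(1000, 0.3)),
                                solver="direct")
        r2 = assemble_and_solve(build_model(mask, 0.3, MaterialModel(2000, 0.3)),
                                solver="direct")
        assert r2.stiffness_n_mm == pytest.approx(2 * r1.stiffness_n_mm, rel=1e-9)

    def test_two_bars_in_parallel(self):
        one = np.zeros((12, 3, 3), bool)
        one[:, :, 0] = True
        two = np.zeros((12, 3, 3), bool)
        two[:, :, 0] = two[:, :, 2] = True
        two[0, :, :] = two[-1, :, :] = True  # merge at the ends
        r1 = assemble_and_solve(build_model(one, 0.3), solver="direct")
        r2 = assemble_and_solve(build_model(two, 0.3), solver="direct")
        assert r2.stiffness_n_mm == pytest.approx(2 * r1.stiffness_n_mm, rel=0.15)

    def test_uniform_bar_failure_closed_form(self):
        mask = np.ones((40, 6, 6), bool)
        h = 0.0104
        model = build_model(mask, h, MaterialModel(E_BONE, 0.0))
        load = LoadCase(0.1)
        res = assemble_and_solve(model, load, solver="pcg")
        strain_field(res, model)
        f = failure_load(res, model)
        L = 40 * h
        expected = res.stiffness_n_mm * 0.01442 * L
        assert f == pytest.approx(expected, rel=1e-6)

    def test_failure_load_independent_of_displacement(self):
        mask = np.zeros((10, 4, 4), bool)
        mask[:, 1:3, 1:3] = True
        mask[4:6, 1:4, 1:3] = True  # asymmetry
        model = build_model(mask, 0.3)
        f = []
        for d in (0.1, 0.05):
            res = assemble_and_solve(model, LoadCase(d), solver="direct")
            strain_field(res, model)
            f.append(failure_load(res, model))
        assert f[0] == pytest.approx(f[1], rel=1e-9)

    def test_single_node_fraction_is_conservative(self):
        mask = np.zeros((10, 4, 4), bool)
        mask[:, 1:3, 1:3] = True
        mask[4:6, 1:4, 1:3] = True
        model = build_model(mask, 0.3)
        res = assemble_and_solve(model, solver="direct")
        strain_field(res, model)
        f_single = failure_load(res, model,
                                FailureCriterion(node_fraction=1.0 / model.n_nodes))
        f_decile = failure_load(res, model, FailureCriterion(node_fraction=0.10))
        assert f_single <= f_decile

    def test_rigid_body_field_has_zero_strain(self):
        mask = np.ones((4, 3, 3), bool)
        model = build_model(mask, 0.5)
        res = assemble_and_solve(model, solver="direct")
        res.displacements = np.tile([0.3, -0.2, 0.1], (model.n_nodes, 1))
        e_el, _ = strain_field(res, model)
        assert np.abs(e_el).max() < 1e-12

    def test_removing_voxels_never_stiffens(self):
        full = np.ones((10, 4, 4), bool)
        holed = full.copy()
        holed[5, 1:3, 1:3] = False
        r_full = assemble_and_solve(build_model(full, 0.3), solver="direct")
        r_holed = assemble_and_solve(build_model(holed, 0.3), solver="direct")
        assert r_holed.stiffness_n_mm < r_full.stiffness_n_mm

    def test_principal_strain_rotation_invariance(self):
        # quarter-turn of the mesh about z permutes the strain tensor axes
        mask = np.zeros((8, 5, 5), bool)
        mask[:, 1:4, 1:3] = True
        m1 = build_model(mask, 0.4)
        m2 = build_model(np.rot90(mask, axes=(1, 2)).copy(), 0.4)
        r1 = assemble_and_solve(m1, solver="direct")
        r2 = assemble_and_solve(m2, solver="direct")
        e1, _ = strain_field(r1, m1)
        e2, _ = strain_field(r2, m2)
        assert np.sort(e1) == pytest.approx(np.sort(e2), rel=1e-9, abs=1e-15)
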