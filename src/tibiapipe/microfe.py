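"""Voxel-based linear-elastic micro-finite-element analysis.

Every bone voxel becomes an 8-node hexahedral element with isotropic linear
elastic material (default E = 14800 MPa, nu = 0.3). Uniaxial compression is
simulated by fully constraining the distal end surface and prescribing an
axial displacement (default 0.1 mm) on every proximal-surface node;
transverse DOFs at the loaded end stay free. Apparent stiffness is the sum
of axial reaction forces at the constrained surface divided by the applied
displacement. Failure load scales the linear solution until 10% of the
nodes reach a third principal strain of -14420 µε.

Units are MPa - mm - N throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, cg, spsolve

GAUSS = 1.0 / np.sqrt(3.0)


@dataclass
class MaterialModel:
    youngs_modulus_mpa: float = 14800.0
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if not self.youngs_modulus_mpa > 0:
            raise ValueError("E must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("nu must be in [0, 0.5)")

    def hooke_matrix(self) -> np.ndarray:
        E, nu = self.youngs_modulus_mpa, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.diag_indices(3)] = lam + 2 * mu
        D[3, 3] = D[4, 4] = D[5, 5] = mu
        return D


@dataclass
class LoadCase:
    applied_displacement_mm: float = 0.1

    def __post_init__(self) -> None:
        if not self.applied_displacement_mm > 0:
            raise ValueError("displacement must be positive")


@dataclass
class FailureCriterion:
    node_fraction: float = 0.10
    critical_strain: float = -14420e-6

    def __post_init__(self) -> None:
        if not (0 < self.node_fraction <= 1):
            raise ValueError("node_fraction must be in (0, 1]")
        if not self.critical_strain < 0:
            raise ValueError("critical strain must be compressive (negative)")


@dataclass
class FEModel:
    """Voxel hexahedral mesh with end-surface node sets."""

    elem_nodes: np.ndarray        # (n_elem, 8) global node indices
    node_grid_idx: np.ndarray     # (n_nodes, 3) (z, y, x) node-grid indices
    voxel_size: float
    material: MaterialModel
    proximal_nodes: np.ndarray    # node indices on the loaded (low-z) surface
    distal_nodes: np.ndarray      # node indices on the constrained (high-z) surface

    @property
    def n_nodes(self) -> int:
        return self.node_grid_idx.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elem_nodes.shape[0]


@dataclass
class FEResult:
    displacements: np.ndarray     # (n_nodes, 3) mm, (ux, uy, uz)
    total_reaction_n: float       # axial force at the constrained surface
    stiffness_n_mm: float
    element_e3: np.ndarray | None = None
    nodal_e3: np.ndarray | None = None
    failure_load_n: float | None = None
    solver_info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Element stiffness
# ---------------------------------------------------------------------------

# corner order: n = dz*4 + dy*2 + dx, natural coords aligned with (x, y, z)
_CORNERS = np.array([(dz, dy, dx) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)])
_XI_NODES = np.column_stack([
    2 * _CORNERS[:, 2] - 1,   # xi   <-> x
    2 * _CORNERS[:, 1] - 1,   # eta  <-> y
    2 * _CORNERS[:, 0] - 1,   # zeta <-> z
]).astype(float)


def _shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """dN_i/d(x,y,z) at natural point xi for a cube of edge h; (8, 3)."""
    g = np.empty((8, 3))
    for i, (x0, y0, z0) in enumerate(_XI_NODES):
        g[i, 0] = x0 * (1 + y0 * xi[1]) * (1 + z0 * xi[2]) / 8.0
        g[i, 1] = (1 + x0 * xi[0]) * y0 * (1 + z0 * xi[2]) / 8.0
        g[i, 2] = (1 + x0 * xi[0]) * (1 + y0 * xi[1]) * z0 / 8.0
    return g * (2.0 / h)


def _b_matrix(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix, engineering order (xx,yy,zz,xy,yz,zx)."""
    B = np.zeros((6, 24))
    for i in range(8):
        gx, gy, gz = grad[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def element_stiffness(material: MaterialModel, h: float) -> np.ndarray:
    """24x24 stiffness of a cubic trilinear hexahedron (2x2x2 Gauss)."""
    if not h > 0:
        raise ValueError("element size must be positive")
    D = material.hooke_matrix()
    detj_w = (h / 2.0) ** 3
    K = np.zeros((24, 24))
    for gx in (-GAUSS, GAUSS):
        for gy in (-GAUSS, GAUSS):
            for gz in (-GAUSS, GAUSS):
                B = _b_matrix(_shape_gradients(np.array([gx, gy, gz]), h))
                K += B.T @ D @ B * detj_w
    return (K + K.T) / 2.0


def element_b_center(h: float) -> np.ndarray:
    """B matrix at the element centroid."""
    return _b_matrix(_shape_gradients(np.zeros(3), h))


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------

def build_model(
    mask: np.ndarray,
    voxel_size: float,
    material: MaterialModel | None = None,
    require_connected: bool = True,
) -> FEModel:
    """Convert a bone mask into a hexahedral mesh with end node sets."""
    material = material or MaterialModel()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no elements")
    if require_connected:
        _, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
        if n > 1:
            raise ValueError(
                f"mesh has {n} 6-connected components; apply the connectivity "
                "filter before meshing")
    elems = np.argwhere(mask)  # (n_elem, 3) z, y, x
    nz, ny, nx = mask.shape
    grid_shape = (nz + 1, ny + 1, nx + 1)
    corner_nodes = elems[:, None, :] + _CORNERS[None, :, :]  # (n_elem, 8, 3)
    flat = np.ravel_multi_index(
        (corner_nodes[..., 0], corner_nodes[..., 1], corner_nodes[..., 2]),
        grid_shape,
    )
    used, inverse = np.unique(flat, return_inverse=True)
    elem_nodes = inverse.reshape(-1, 8).astype(np.int64)
    node_grid_idx = np.column_stack(np.unravel_index(used, grid_shape)).astype(np.int64)
    zmin, zmax = node_grid_idx[:, 0].min(), node_grid_idx[:, 0].max()
    proximal = np.flatnonzero(node_grid_idx[:, 0] == zmin)
    distal = np.flatnonzero(node_grid_idx[:, 0] == zmax)
    return FEModel(elem_nodes, node_grid_idx, float(voxel_size), material,
                   proximal, distal)


def assemble_stiffness(model: FEModel) -> sparse.csr_matrix:
    """Assemble the global stiffness matrix (CSR, full, no BCs)."""
    Ke = element_stiffness(model.material, model.voxel_size)
    edof = (model.elem_nodes[:, :, None] * 3
            + np.arange(3)[None, None, :]).reshape(-1, 24)
    n_dof = model.n_nodes * 3
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    vals = np.tile(Ke.ravel(), model.n_elements)
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(n_dof, n_dof))
    return K.tocsr()


def _block_jacobi(K: sparse.csr_matrix) -> LinearOperator:
    """Nodal 3x3 block-Jacobi preconditioner for a node-aligned system."""
    n_dof = K.shape[0]
    n_nodes = n_dof // 3
    coo = K.tocoo()
    same_node = (coo.row // 3) == (coo.col // 3)
    r, c, v = coo.row[same_node], coo.col[same_node], coo.data[same_node]
    blocks = np.zeros((n_nodes, 3, 3))
    blocks[r // 3, r % 3, c % 3] = v
    inv = np.linalg.inv(blocks)

    def apply(x: np.ndarray) -> np.ndarray:
        return np.einsum("nij,nj->ni", inv, x.reshape(-1, 3)).ravel()

    return LinearOperator(K.shape, matvec=apply)


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

def assemble_and_solve(
    model: FEModel,
    load: LoadCase | None = None,
    tol: float = 1e-8,
    solver: str = "auto",
    max_iter: int = 20000,
) -> FEResult:
    """Solve the uniaxial-compression load case.

    Distal-surface nodes are fully fixed; proximal-surface nodes get the
    axial displacement prescribed with transverse DOFs free. `solver` is
    "auto" (direct below 60k DOF, else PCG), "direct", or "pcg"
    (Jacobi-preconditioned conjugate gradients, relative residual <= tol).
    """
    load = load or LoadCase()
    d = load.applied_displacement_mm
    K = assemble_stiffness(model)
    n_dof = model.n_nodes * 3

    prescribed = np.zeros(n_dof, dtype=bool)
    values = np.zeros(n_dof)
    for nid in model.distal_nodes:
        prescribed[3 * nid:3 * nid + 3] = True
    uz_dofs = 3 * model.proximal_nodes + 2
    prescribed[uz_dofs] = True
    values[uz_dofs] = d  # push the proximal end toward the distal end

    free = ~prescribed
    n_free = int(free.sum())
    method = solver
    if solver == "auto":
        method = "direct" if n_free <= 60000 else "pcg"

    info: dict = {"solver": method, "n_free_dof": n_free}
    if method == "direct":
        u = values.copy()
        Kff = K[free][:, free]
        b = -K[free][:, prescribed] @ values[prescribed]
        u[free] = spsolve(Kff.tocsc(), b)
    elif method == "pcg":
        # keep the full (node-aligned) system: zero prescribed rows/columns,
        # unit diagonal there, and move the known values to the right side
        up = np.where(prescribed, values, 0.0)
        rhs = -(K @ up)
        rhs[prescribed] = values[prescribed]
        dmask = sparse.diags(free.astype(float))
        Kmod = (dmask @ K @ dmask + sparse.diags(prescribed.astype(float))).tocsr()
        if np.any(Kmod.diagonal() <= 0):
            raise ValueError("singular system: unconstrained rigid mode")
        M = _block_jacobi(Kmod)
        # warm start: linear axial ramp between the two end planes
        zidx = model.node_grid_idx[:, 0].astype(float)
        zmin, zmax = zidx.min(), zidx.max()
        ramp = d * (zmax - zidx) / (zmax - zmin)
        x0 = np.zeros(n_dof)
        x0[2::3] = ramp
        x0[prescribed] = values[prescribed]
        sol, cg_info = cg(Kmod, rhs, x0=x0, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
        if cg_info != 0:
            raise RuntimeError(f"PCG did not converge (info={cg_info})")
        u = sol
        u[prescribed] = values[prescribed]
        res = np.linalg.norm(Kmod @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
        info["relative_residual"] = float(res)
    else:
        raise ValueError(f"unknown solver {solver!r}")

    f = K @ u
    distal_uz = 3 * model.distal_nodes + 2
    reaction = float(f[distal_uz].sum())
    info["proximal_reaction_n"] = float(f[uz_dofs].sum())
    stiffness = abs(reaction) / d
    return FEResult(
        displacements=u.reshape(-1, 3),
        total_reaction_n=reaction,
        stiffness_n_mm=stiffness,
        solver_info=info,
    )


def apparent_stiffness(result: FEResult, load: LoadCase | None = None) -> float:
    """|sum of axial reactions at the constrained surface| / displacement."""
    load = load or LoadCase()
    return abs(result.total_reaction_n) / load.applied_displacement_mm


# ---------------------------------------------------------------------------
# Strain recovery and failure load
# ---------------------------------------------------------------------------

def strain_field(result: FEResult, model: FEModel) -> tuple[np.ndarray, np.ndarray]:
    """Element-centroid third principal strains and nodal averages.

    The strain tensor is evaluated from the trilinear shape-function
    gradients at each element centroid; e3 is the smallest eigenvalue.
    Nodal e3 is the unweighted mean over incident elements.
    """
    B0 = element_b_center(model.voxel_size)
    u = result.displacements.reshape(-1)
    edof = (model.elem_nodes[:, :, None] * 3
            + np.arange(3)[None, None, :]).reshape(-1, 24)
    ue = u[edof]                       # (n_elem, 24)
    eps = ue @ B0.T                    # (n_elem, 6) xx,yy,zz,xy,yz,zx (eng.)
    T = np.empty((eps.shape[0], 3, 3))
    T[:, 0, 0] = eps[:, 0]
    T[:, 1, 1] = eps[:, 1]
    T[:, 2, 2] = eps[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = eps[:, 3] / 2.0
    T[:, 1, 2] = T[:, 2, 1] = eps[:, 4] / 2.0
    T[:, 0, 2] = T[:, 2, 0] = eps[:, 5] / 2.0
    ev = np.linalg.eigvalsh(T)
    element_e3 = ev[:, 0]
    nodal_sum = np.zeros(model.n_nodes)
    counts = np.zeros(model.n_nodes)
    np.add.at(nodal_sum, model.elem_nodes.ravel(),
              np.repeat(element_e3, 8))
    np.add.at(counts, model.elem_nodes.ravel(), 1.0)
    nodal_e3 = nodal_sum / counts
    result.element_e3 = element_e3
    result.nodal_e3 = nodal_e3
    return element_e3, nodal_e3


def failure_load(
    result: FEResult,
    model: FEModel | None = None,
    criterion: FailureCriterion | None = None,
) -> float:
    """Linear-scaling failure load in N.

    The solution is scaled by s = critical_strain / v where v is the k-th
    smallest nodal e3 and k = ceil(node_fraction * n_nodes); the failure
    load is s * |total reaction|.
    """
    criterion = criterion or FailureCriterion()
    if result.nodal_e3 is None:
        if model is None:
            raise ValueError("strain_field must be computed first (or pass model)")
        strain_field(result, model)
    e3 = result.nodal_e3
    k = int(np.ceil(criterion.node_fraction * e3.size))
    k = max(k, 1)
    v = np.partition(e3, k - 1)[k - 1]
    if v >= 0:
        raise ValueError(
            f"no compressive strain at the {criterion.node_fraction:.0%} "
            f"node percentile (e3 = {v:.3e})")
    s = criterion.critical_strain / v
    load_n = s * abs(result.total_reaction_n)
    result.failure_load_n = float(load_n)
    return float(load_n)


def save_result_hdf5(result: FEResult, path) -> None:
    """Optional HDF5 dump of nodal displacements and third principal strains."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("displacements_mm", data=result.displacements)
        if result.nodal_e3 is not None:
            f.create_dataset("nodal_e3", data=result.nodal_e3)
        f.attrs["stiffness_n_mm"] = result.stiffness_n_mm
        f.attrs["total_reaction_n"] = result.total_reaction_n
        if result.failure_load_n is not None:
            f.attrs["failure_load_n"] = result.failure_load_n


def strain_histogram(
    nodal_e3: np.ndarray,
    bin_edges: np.ndarray | None = None,
) -> "pd.DataFrame":
    """Frequency table of nodal third principal strains (for CSV export)."""
    import pandas as pd

    if bin_edges is None:
        bin_edges = np.linspace(nodal_e3.min(), nodal_e3.max(), 51)
    hist, edges = np.histogram(nodal_e3, bins=bin_edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": hist,
        "frequency": hist / max(nodal_e3.size, 1),
    })
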