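"""Synthetic tibia phantoms with known ground truth.

No public micro-CT data accompany the measurement protocol this package
implements, so every downstream stage is exercised on procedurally
generated phantoms: a curved tubular "tibia" (superellipse cross-section
swept along a bowed centerline, cortical shell thickening toward the
midshaft), a proximal trabecular rod lattice, a low-density growth-plate
band (giving the VOI start slice an objective ground truth), a fibula rod
merging at a tibio-fibular junction, spatially varying mineral density
under a known linear calibration, additive Gaussian image noise, and rigid
repositioning between repeat "scans".

Geometric test phantoms (bars, plates, rods, tori, balls, hollow
cylinders) with closed-form expectations are provided for the morphometry
and FE oracles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .densitometry import CalibrationLaw, partition_bmc, partition_labels, voxel_bmc
from .image import RigidTransform, VoxelImage, resample
from .registration import select_voi


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class TrabecularRegion:
    """Rod-lattice compartment below the growth plate (normalized z range)."""

    tau_range: tuple[float, float] = (0.085, 0.32)
    fill_fraction: float = 0.22
    rod_spacing_mm: float = 0.28
    rod_radius_override_mm: float | None = None

    @property
    def rod_radius_mm(self) -> float:
        if self.rod_radius_override_mm is not None:
            return self.rod_radius_override_mm
        # three orthogonal rod families; overlap neglected
        return self.rod_spacing_mm * float(np.sqrt(self.fill_fraction / (3 * np.pi)))


@dataclass
class FibulaSpec:
    enabled: bool = True
    tau_start: float = 0.12
    junction_tau: tuple[float, float] = (0.50, 0.58)
    radius_mm: float = 0.25
    max_gap_mm: float = 0.55
    junction_gap_vox: float = 4.0   # closest approach, in voxels


@dataclass
class PhantomSpec:
    """Tibia phantom parameters; defaults mirror the in vivo protocol scale
    (10.4 µm voxels, ~16 mm tibia). Use :meth:`coarse` for the desk-scale
    reduced-resolution phantom."""

    image_shape: tuple[int, int, int] = (1546, 442, 270)  # (nz, ny, nx)
    voxel_size: float = 0.0104
    tibia_length_mm: float = 16.0
    shaft_curvature_mm: float = 0.8          # lateral (-y) bow amplitude
    shaft_semi_axes_mm: tuple[float, float] = (0.55, 0.65)  # (a=x, b=y)
    flare_proximal: float = 2.2
    flare_decay_proximal: float = 0.12    # normalized-z decay of the flare
    flare_distal: float = 1.35
    superellipse_exponent: float = 2.5
    cortical_thickness_profile: tuple[tuple[float, float], ...] = (
        (0.0, 0.10), (0.5, 0.30), (1.0, 0.18))
    plate_tau_range: tuple[float, float] = (0.055, 0.085)
    trabecular: TrabecularRegion = field(default_factory=TrabecularRegion)
    fibula: FibulaSpec = field(default_factory=FibulaSpec)
    density_cortical: float = 1100.0         # mgHA/cc
    density_trabecular: float = 900.0
    density_cartilage: float = 60.0
    density_axial_ripple: float = 0.04       # relative cortical TMD modulation
    calibration: CalibrationLaw = field(
        default_factory=lambda: CalibrationLaw(slope=5.0, intercept=-200.0))
    noise_sd: float = 8.0                    # grey levels
    background_grey: float | None = None     # derived from calibration if None
    bone_peak_grey: float | None = None
    margin_slices: int = 4

    def __post_init__(self) -> None:
        nz, ny, nx = self.image_shape
        if self.tibia_length_mm > nz * self.voxel_size:
            raise ValueError("tibia longer than the image along z")
        if self.density_cortical <= 0 or self.density_trabecular <= 0:
            raise ValueError("densities must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(t for _, t in self.cortical_thickness_profile) <= 0:
            raise ValueError("degenerate geometry: zero-thickness cortex")
        p0, p1 = self.plate_tau_range
        if not (0 < p0 < p1 < 1):
            raise ValueError("growth plate band must lie inside the tibia")
        if self.background_grey is None:
            self.background_grey = float(self.calibration.grey_from_tmd(0.0))
        if self.bone_peak_grey is None:
            self.bone_peak_grey = float(
                self.calibration.grey_from_tmd(self.density_cortical))

    @property
    def z_top_mm(self) -> float:
        return self.margin_slices * self.voxel_size

    @property
    def growth_plate_slice(self) -> int:
        """Last slice index containing growth-plate tissue."""
        p1 = self.plate_tau_range[1]
        return int(np.floor((self.z_top_mm + p1 * self.tibia_length_mm)
                            / self.voxel_size))

    @classmethod
    def coarse(cls, voxel_size: float = 0.04) -> "PhantomSpec":
        """Reduced-resolution phantom for desk-scale end-to-end runs.

        A 5.2 mm tibia with the cross-section scaled less than the length so
        the cortical shell stays several voxels thick; trabecular rods are
        scaled up accordingly.
        """
        L = 5.2
        nz = int(round(L / voxel_size)) + 10
        ny = int(round(2.6 / voxel_size))
        nx = int(round(2.0 / voxel_size))
        return cls(
            image_shape=(nz, ny, nx),
            voxel_size=voxel_size,
            tibia_length_mm=L,
            shaft_curvature_mm=0.30,
            shaft_semi_axes_mm=(0.30, 0.34),
            flare_proximal=2.5,
            flare_decay_proximal=0.20,
            flare_distal=1.3,
            cortical_thickness_profile=((0.0, 0.08), (0.5, 0.17), (1.0, 0.12)),
            trabecular=TrabecularRegion(
                tau_range=(0.085, 0.32), fill_fraction=0.30, rod_spacing_mm=0.36,
                rod_radius_override_mm=0.075),
            fibula=FibulaSpec(radius_mm=0.09, max_gap_mm=0.28),
            noise_sd=8.0,
        )


@dataclass
class GroundTruth:
    """Generator record of truth in the canonical (aligned) frame."""

    bone_mask: np.ndarray         # all bone incl. fibula
    trabecular_mask: np.ndarray   # metaphyseal lattice (subset of bone)
    fibula_mask: np.ndarray
    voi_start_slice: int          # first slice with no growth-plate tissue
    true_length_mm: float
    true_partition_bmc: np.ndarray  # (10, 4) mg, noise-free
    true_total_bmc: float           # mg, noise-free, over the 80% VOI
    applied_transform: RigidTransform
    junction_zrange: tuple[int, int] = (0, 0)
    reference_slice: int = 0        # growth-plate merge surrogate
    density: np.ndarray | None = None  # noise-free mineral density (mgHA/cc)

    @property
    def tibia_mask(self) -> np.ndarray:
        return self.bone_mask & ~self.fibula_mask


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _interp_profile(profile: tuple[tuple[float, float], ...], tau: float) -> float:
    xs = np.array([p[0] for p in profile])
    ys = np.array([p[1] for p in profile])
    return float(np.interp(tau, xs, ys))


def _rasterize(spec: PhantomSpec) -> dict:
    """Noise-free masks and density field for a phantom spec."""
    nz, ny, nx = spec.image_shape
    v = spec.voxel_size
    L = spec.tibia_length_mm
    a0, b0 = spec.shaft_semi_axes_mm
    p = spec.superellipse_exponent
    cx0 = (nx - 1) / 2.0 * v
    # leave room on the -y (lateral) side for the bow and the fibula
    cy0 = (ny - 1) * v * 0.62

    X, Y = np.meshgrid(np.arange(nx) * v, np.arange(ny) * v)
    bone = np.zeros((nz, ny, nx), dtype=bool)
    trab = np.zeros_like(bone)
    fib = np.zeros_like(bone)
    cart = np.zeros_like(bone)
    density = np.zeros((nz, ny, nx), dtype=np.float64)

    p0, p1 = spec.plate_tau_range
    t0, t1 = spec.trabecular.tau_range
    rod_s = spec.trabecular.rod_spacing_mm
    rod_r = spec.trabecular.rod_radius_mm
    margin = 3.5 * v                      # lattice clearance from the endosteum
    tau_anchor = t0 + 0.015               # lattice-to-cortex anchor level

    # vertical rod lattice grid (fixed in the image frame); a rod is only
    # instantiated in a slice when its full cross-section fits inside the
    # core, so no sub-voxel sliver rods arise at the compartment boundary
    gx = np.arange(cx0 - 1.2 * a0 * spec.flare_proximal, cx0 + 1.2 * a0 * spec.flare_proximal, rod_s)
    gy = np.arange(cy0 - 1.4 * b0 * spec.flare_proximal, cy0 + 1.4 * b0 * spec.flare_proximal, rod_s)
    rod_discs = {
        (xi, yj): (X - xi) ** 2 + (Y - yj) ** 2 <= rod_r**2
        for xi in gx for yj in gy
    }
    z_levels = np.arange(spec.z_top_mm, spec.z_top_mm + L, rod_s)

    fj0, fj1 = spec.fibula.junction_tau
    rf = spec.fibula.radius_mm

    for iz in range(nz):
        z = iz * v
        tau = (z - spec.z_top_mm) / L
        if tau < 0 or tau > 1:
            continue
        flare = (1.0
                 + (spec.flare_proximal - 1.0)
                 * np.exp(-((tau / spec.flare_decay_proximal) ** 2))
                 + (spec.flare_distal - 1.0) * np.exp(-(((1 - tau) / 0.08) ** 2)))
        a, b = a0 * flare, b0 * flare
        t = _interp_profile(spec.cortical_thickness_profile, tau)
        cy = cy0 - spec.shaft_curvature_mm * np.sin(np.pi * tau)
        cx = cx0

        def sellipse(sa: float, sb: float) -> np.ndarray:
            sa, sb = max(sa, 0.02), max(sb, 0.02)
            return (np.abs((X - cx) / sa) ** p + np.abs((Y - cy) / sb) ** p) <= 1.0

        outer = sellipse(a, b)
        inner = sellipse(a - t, b - t)
        core = sellipse(a - t - margin, b - t - margin)
        cortex = outer & ~inner
        bone[iz] |= cortex
        density[iz][cortex] = spec.density_cortical * (
            1.0 + spec.density_axial_ripple * np.sin(4 * np.pi * tau))

        def rod_centers() -> list[tuple[float, float]]:
            """Grid points inside the core; their discs are stamped whole so
            no sub-voxel sliver rods arise (overshoot stays in the margin)."""
            sa = max(a - t - margin, 0.02)
            sb = max(b - t - margin, 0.02)
            return [(xi, yj) for (xi, yj) in rod_discs
                    if (abs((xi - cx) / sa) ** p + abs((yj - cy) / sb) ** p) <= 1.0]

        def full_rods(centers) -> np.ndarray:
            out = np.zeros((ny, nx), dtype=bool)
            for c in centers:
                out |= rod_discs[c]
            return out

        def connector_segments(centers, w: float) -> np.ndarray:
            """Full-thickness struts between adjacent rods (convex core keeps
            the straight segments inside the compartment)."""
            out = np.zeros((ny, nx), dtype=bool)
            ys_of = {}
            xs_of = {}
            for xi, yj in centers:
                ys_of.setdefault(xi, []).append(yj)
                xs_of.setdefault(yj, []).append(xi)
            for yj, xs_ in xs_of.items():
                xs_ = sorted(xs_)
                for x1, x2 in zip(xs_[:-1], xs_[1:]):
                    out |= (np.abs(Y - yj) <= w) & (X >= x1) & (X <= x2)
            for xi, ys_ in ys_of.items():
                ys_ = sorted(ys_)
                for y1, y2 in zip(ys_[:-1], ys_[1:]):
                    out |= (np.abs(X - xi) <= w) & (Y >= y1) & (Y <= y2)
            return out

        if tau < p0:  # epiphysis: shell with solid spongy interior
            lat = inner
            bone[iz] |= lat
            density[iz][lat & ~cortex] = spec.density_trabecular
        elif tau <= p1:  # growth plate: cartilage interior
            cart[iz] = inner
            density[iz][inner & ~cortex] = spec.density_cartilage
        elif tau <= t1:  # metaphyseal trabecular compartment
            centers = rod_centers()
            lat = full_rods(centers)
            # horizontal struts between adjacent rods at regular z levels
            for zk in z_levels:
                dz = abs(z - zk)
                if dz <= rod_r:
                    w = np.sqrt(rod_r**2 - dz**2)
                    lat |= connector_segments(centers, w)
            bone[iz] |= lat
            trab[iz] = lat & ~cortex
            density[iz][lat & ~cortex] = spec.density_trabecular
        if abs(tau - tau_anchor) * L <= rod_r:  # anchor rods reach the cortex
            w = np.sqrt(max(rod_r**2 - ((tau - tau_anchor) * L) ** 2, 0.0))
            anchor = ((np.abs(X - cx0) <= w) | (np.abs(Y - cy) <= w)) & inner
            bone[iz] |= anchor
            density[iz][anchor & ~cortex] = spec.density_trabecular

        if spec.fibula.enabled and spec.fibula.tau_start <= tau <= fj1:
            g_min = spec.fibula.junction_gap_vox * v
            if tau < fj0:
                frac = (fj0 - tau) / (fj0 - spec.fibula.tau_start)
                gap = g_min + (spec.fibula.max_gap_mm - g_min) * frac
            else:
                gap = g_min
            yf = cy - b - gap - rf
            fslice = (X - cx0) ** 2 + (Y - yf) ** 2 <= rf**2
            fslice &= ~bone[iz]
            fib[iz] |= fslice
            bone[iz] |= fslice
            density[iz][fslice] = 0.95 * spec.density_cortical

    return {
        "bone": bone, "trabecular": trab, "fibula": fib, "cartilage": cart,
        "density": density,
    }


def _junction_zrange(spec: PhantomSpec) -> tuple[int, int]:
    fj0, fj1 = spec.fibula.junction_tau
    v, L, zt = spec.voxel_size, spec.tibia_length_mm, spec.z_top_mm
    z0 = int(np.floor((zt + (fj0 - 0.04) * L) / v))
    z1 = int(np.ceil((zt + (fj1 + 0.02) * L) / v))
    return max(z0, 0), min(z1, spec.image_shape[0] - 1)


def generate_tibia(spec: PhantomSpec, seed: int) -> tuple[VoxelImage, GroundTruth]:
    """Generate a noisy grey-level tibia phantom and its ground truth.

    The same spec and seed give bit-identical output. Ground-truth BMC is
    computed from the noise-free density field over the 80%-length VOI of
    the fibula-excluded bone.
    """
    raster = _rasterize(spec)
    bone, fib = raster["bone"], raster["fibula"]
    density = raster["density"]
    if not bone.any():
        raise ValueError("degenerate geometry: phantom contains no bone")

    tissue = bone | raster["cartilage"]
    grey = np.full(spec.image_shape, spec.background_grey, dtype=np.float64)
    grey[tissue] = spec.calibration.grey_from_tmd(density[tissue])
    rng = np.random.default_rng(seed)
    if spec.noise_sd > 0:
        grey = grey + rng.normal(0.0, spec.noise_sd, size=grey.shape)
    image = VoxelImage(grey.astype(np.float32), spec.voxel_size)

    tibia = bone & ~fib
    cart_slices = np.flatnonzero(raster["cartilage"].any(axis=(1, 2)))
    voi_start = int(cart_slices[-1]) + 1 if cart_slices.size else spec.growth_plate_slice + 1

    from .registration import measure_length

    true_length = measure_length(tibia, spec.voxel_size)
    voi = select_voi(tibia, spec.voxel_size, voi_start, fraction=0.8)
    labels = partition_labels(voi)
    bmc_vol = voxel_bmc(density, spec.voxel_size)
    table = partition_bmc(bmc_vol, labels, voi)

    truth = GroundTruth(
        bone_mask=bone,
        trabecular_mask=raster["trabecular"],
        fibula_mask=fib,
        voi_start_slice=voi_start,
        true_length_mm=true_length,
        true_partition_bmc=table.bmc_mg,
        true_total_bmc=table.total_mg,
        applied_transform=RigidTransform(center_mm=image.center_mm()),
        junction_zrange=_junction_zrange(spec),
        reference_slice=voi_start,
        density=density,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Acquisition perturbation (repositioning between repeat scans)
# ---------------------------------------------------------------------------

def perturb_acquisition(
    image: VoxelImage,
    truth: GroundTruth,
    max_rot_deg: float,
    max_trans_mm: float,
    seed: int,
) -> tuple[VoxelImage, GroundTruth]:
    """Apply a random rigid repositioning to a phantom "scan".

    The transform is drawn uniformly within the bounds and applied with the
    same Lanczos interpolator the pipeline uses for alignment. Ground-truth
    masks stay in the canonical frame; the applied transform is recorded so
    registration recovery can be scored (the registration should recover
    its inverse).
    """
    if max_rot_deg < 0 or max_trans_mm < 0:
        raise ValueError("bounds must be non-negative")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-max_rot_deg, max_rot_deg, size=3)
    trans = rng.uniform(-max_trans_mm, max_trans_mm, size=3)
    t = RigidTransform(angles, trans, image.center_mm())
    if t.is_identity():
        return image.copy(), dataclasses.replace(truth, applied_transform=t)

    # the bone appears at T^-1(bone) in the output; check its bbox stays inside
    zs, ys, xs = np.nonzero(truth.bone_mask)
    v = image.voxel_size
    lo = np.array([xs.min(), ys.min(), zs.min()]) * v
    hi = np.array([xs.max(), ys.max(), zs.max()]) * v
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    moved = t.inverse().apply(corners)
    extent = image.physical_extent
    if np.any(moved < 0) or np.any(moved > extent[None, :]):
        raise ValueError("perturbation pushes bone outside the field of view")

    border = np.concatenate([
        image.data[0].ravel(), image.data[-1].ravel(),
        image.data[:, 0].ravel(), image.data[:, -1].ravel(),
    ])
    background = float(np.median(border))
    out = resample(image, t, interpolator="lanczos", background=background)
    return out, dataclasses.replace(truth, applied_transform=t)


# ---------------------------------------------------------------------------
# Anabolic (treatment) effect
# ---------------------------------------------------------------------------

def apply_anabolic_effect(spec: PhantomSpec, bmc_gain_fraction: float) -> PhantomSpec:
    """Return a spec whose noise-free VOI BMC is (1 + gain) x baseline.

    The gain is realized mainly as cortical apposition (thickness scales
    by (1 + gain)^0.8, mirroring anabolic bone formation) with a small
    tissue-density adjustment calibrated on the noise-free field so the
    programmed total BMC gain is met within float accuracy. Apposition
    rather than densification also carries the gain into the micro-FE
    stiffness, which sees geometry but not tissue density.
    """
    if bmc_gain_fraction <= -1:
        raise ValueError("gain must be > -1")
    if bmc_gain_fraction == 0.0:
        return spec
    ft = (1.0 + bmc_gain_fraction) ** 0.8
    thicker = tuple((tau, t * ft) for tau, t in spec.cortical_thickness_profile)
    candidate = dataclasses.replace(spec, cortical_thickness_profile=thicker)
    base_bmc = _noise_free_voi_bmc(spec)
    cand_bmc = _noise_free_voi_bmc(candidate)
    density_scale = (1.0 + bmc_gain_fraction) * base_bmc / cand_bmc
    return dataclasses.replace(
        candidate,
        density_cortical=spec.density_cortical * density_scale,
        density_trabecular=spec.density_trabecular * density_scale,
    )


def _noise_free_voi_bmc(spec: PhantomSpec) -> float:
    raster = _rasterize(spec)
    tibia = raster["bone"] & ~raster["fibula"]
    cart = np.flatnonzero(raster["cartilage"].any(axis=(1, 2)))
    start = int(cart[-1]) + 1 if cart.size else spec.growth_plate_slice + 1
    voi = select_voi(tibia, spec.voxel_size, start, fraction=0.8)
    bmc = voxel_bmc(raster["density"], spec.voxel_size)
    return float(bmc[voi.mask].sum())


# ---------------------------------------------------------------------------
# Geometric oracle phantoms
# ---------------------------------------------------------------------------

def make_bar_phantom(
    nx: int, ny: int, nz: int,
    grey: float = 1000.0,
    voxel_size: float = 0.0104,
    pad: int = 2,
    background: float = 0.0,
) -> VoxelImage:
    """Solid cuboid of nx x ny x nz foreground voxels in an empty margin."""
    if min(nx, ny, nz) < 1:
        raise ValueError("bar dimensions must be >= 1 voxel")
    data = np.full((nz + 2 * pad, ny + 2 * pad, nx + 2 * pad), background,
                   dtype=np.float32)
    data[pad:pad + nz, pad:pad + ny, pad:pad + nx] = grey
    return VoxelImage(data, voxel_size)


def make_morphometry_phantom(
    kind: str,
    voxel_size: float = 0.02,
    **params,
) -> tuple[VoxelImage, dict]:
    """Binary-valued test phantom with analytic morphometry expectations.

    kinds: "plate" (thickness_vox, size), "rod" (diameter_vox, length),
    "torus" (major_vox, minor_vox), "ball" (radius_vox),
    "hollow_cylinder" (outer_vox, inner_vox, height).
    """
    fg, bg = 100.0, 0.0
    if kind == "plate":
        t = int(params.get("thickness_vox", 8))
        n = int(params.get("size", 48))
        m = np.zeros((t + 8, n, n), dtype=bool)
        m[4:4 + t] = True
        expected = {"thickness_mm": t * voxel_size}
    elif kind == "rod":
        d = float(params.get("diameter_vox", 9))
        length = int(params.get("length", 60))
        n = int(d) + 9
        zz, yy, xx = np.indices((length, n, n))
        c = (n - 1) / 2.0
        m = (yy - c) ** 2 + (xx - c) ** 2 <= (d / 2.0) ** 2
        expected = {"thickness_mm": d * voxel_size}
    elif kind == "torus":
        R = float(params.get("major_vox", 12))
        r = float(params.get("minor_vox", 4))
        n = int(2 * (R + r)) + 9
        h = int(2 * r) + 9
        zz, yy, xx = np.indices((h, n, n))
        cz, c = (h - 1) / 2.0, (n - 1) / 2.0
        rho = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        m = (rho - R) ** 2 + (zz - cz) ** 2 <= r**2
        expected = {"euler": 0, "b1": 1}
    elif kind == "ball":
        r = float(params.get("radius_vox", 12))
        n = int(2 * r) + 9
        zz, yy, xx = np.indices((n, n, n))
        c = (n - 1) / 2.0
        m = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
        expected = {"euler": 1, "b1": 0, "da": 1.0}
    elif kind == "hollow_cylinder":
        ro = float(params.get("outer_vox", 20))
        ri = float(params.get("inner_vox", 14))
        height = int(params.get("height", 40))
        n = int(2 * ro) + 9
        zz, yy, xx = np.indices((height, n, n))
        c = (n - 1) / 2.0
        rho2 = (yy - c) ** 2 + (xx - c) ** 2
        m = (rho2 <= ro**2) & (rho2 > ri**2)
        expected = {
            "ct_th_mm": (ro - ri) * voxel_size,
            "tt_ar_mm2": np.pi * (ro * voxel_size) ** 2,
        }
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    img = VoxelImage(np.where(m, fg, bg).astype(np.float32), voxel_size)
    expected["mask"] = m
    return img, expected
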