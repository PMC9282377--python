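"""Standard trabecular and cortical morphometry.

Implements the classical model-independent parameters: bone volume fraction,
local (inscribed-sphere) thickness and separation, trabecular number,
connectivity density from the Euler characteristic of the cubical complex,
degree of anisotropy from the mean-intercept-length (MIL) fabric ellipsoid,
and midshaft cortical geometry.

Conventions that the commercial packages leave unstated are declared
explicitly here: Tb.N = (BV/TV) / Tb.Th; DA is the ratio of the longest to
the shortest semi-axis of the MIL ellipsoid (>= 1); "connectivity around
the boundary" is approximated by mirror-padding one voxel before counting
cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk


@dataclass
class TrabecularVOISpec:
    """Trabecular VOI below the growth-plate reference cross-section.

    The VOI starts `offset_mm` distal to the reference slice (the one where
    the medial and lateral growth-plate sides merge) and extends
    `extent_mm` further distally. In-plane ROIs either come from polygon
    contours (manual surrogate) or from the automated endosteal fallback.
    """

    reference_slice: int
    offset_mm: float = 0.2
    extent_mm: float = 1.0
    contours: dict[int, np.ndarray] | None = None  # slice -> (n, 2) (x, y)

    def __post_init__(self) -> None:
        if self.offset_mm <= 0 or self.extent_mm <= 0:
            raise ValueError("offset and extent must be positive (mm)")


@dataclass
class CorticalVOISpec:
    """1 mm stack centred at the tibial midshaft (50% of L)."""

    center_slice: int
    extent_mm: float = 1.0
    closing_radius_px: int = 10

    def __post_init__(self) -> None:
        if self.extent_mm <= 0:
            raise ValueError("extent must be positive")


@dataclass
class MorphometrySummary:
    tb_bvtv_pct: float
    tb_th_um: float
    tb_sp_um: float
    tb_n_per_mm: float
    conn_d_per_mm3: float
    da: float
    tt_ar_mm2: float
    ct_ar_mm2: float
    ct_ar_tt_ar: float
    ct_th_um: float

    def to_dict(self) -> dict:
        return {
            "Tb.BV/TV": self.tb_bvtv_pct,
            "Tb.Th": self.tb_th_um,
            "Tb.Sp": self.tb_sp_um,
            "Tb.N": self.tb_n_per_mm,
            "Conn.D": self.conn_d_per_mm3,
            "DA": self.da,
            "Tt.Ar": self.tt_ar_mm2,
            "Ct.Ar": self.ct_ar_mm2,
            "Ct.Ar/Tt.Ar": self.ct_ar_tt_ar,
            "Ct.Th": self.ct_th_um,
        }


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Trabecular VOI
# ---------------------------------------------------------------------------

def _polygon_mask(shape: tuple[int, int], poly: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon2mask

    # polygon2mask expects (row, col) = (y, x)
    return polygon2mask(shape, np.asarray(poly)[:, ::-1])


def endosteal_roi_slice(bone_slice: np.ndarray) -> np.ndarray:
    """Automated endosteal ROI: filled envelope minus the cortical shell.

    The shell is taken as the bone component(s) touching the envelope
    boundary; the ROI is the envelope eroded by 2 voxels with the dilated
    shell removed, leaving the medullary space and the trabeculae inside it.
    """
    if not bone_slice.any():
        return np.zeros_like(bone_slice, dtype=bool)
    env = ndimage.binary_fill_holes(bone_slice)
    boundary = env & ~ndimage.binary_erosion(env)
    lab, n = ndimage.label(bone_slice, structure=np.ones((3, 3), int))
    touching = np.unique(lab[boundary & bone_slice])
    shell = np.isin(lab, touching[touching > 0])
    roi = ndimage.binary_erosion(env, iterations=2) & ~ndimage.binary_dilation(shell)
    return roi


def trabecular_voi(
    bone_mask: np.ndarray,
    spec: TrabecularVOISpec,
    voxel_size: float,
) -> np.ndarray:
    """Return the in-plane ROI volume for trabecular analysis.

    With contours supplied, ROIs are linearly interpolated between key
    slices; otherwise the automated endosteal ROI is used per slice.
    """
    off = _round_half_up(spec.offset_mm / voxel_size)
    ext = _round_half_up(spec.extent_mm / voxel_size)
    z0 = spec.reference_slice + off
    z1 = z0 + ext - 1
    if z0 < 0 or z1 >= bone_mask.shape[0]:
        raise ValueError("trabecular VOI outside the image")
    roi = np.zeros_like(bone_mask, dtype=bool)
    if spec.contours is not None:
        keys = sorted(spec.contours)
        if not keys:
            raise ValueError("manual mode requires contours")
        shape = bone_mask.shape[1:]
        key_masks = {k: _polygon_mask(shape, spec.contours[k]) for k in keys}
        for z in range(z0, z1 + 1):
            lo = max([k for k in keys if k <= z], default=keys[0])
            hi = min([k for k in keys if k >= z], default=keys[-1])
            if lo == hi:
                roi[z] = key_masks[lo]
            else:
                w = (z - lo) / (hi - lo)
                blend = (1 - w) * key_masks[lo] + w * key_masks[hi]
                roi[z] = blend >= 0.5
    else:
        for z in range(z0, z1 + 1):
            roi[z] = endosteal_roi_slice(bone_mask[z])
    return roi


def bvtv(bone_mask: np.ndarray, roi: np.ndarray) -> float:
    """Bone volume fraction in percent within the ROI."""
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    return 100.0 * int((bone_mask & roi).sum()) / n_roi


# ---------------------------------------------------------------------------
# Local thickness (largest inscribed sphere)
# ---------------------------------------------------------------------------

def local_thickness_map(mask: np.ndarray) -> np.ndarray:
    """Model-independent local thickness in voxels.

    Thickness at a voxel is the diameter of the largest sphere that contains
    the voxel and fits inside the structure (distance transform followed by
    sphere painting in decreasing radius order).
    """
    if not mask.any():
        return np.zeros(mask.shape)
    dt = ndimage.distance_transform_edt(mask)
    coords = np.argwhere(mask)
    radii = dt[mask]
    order = np.argsort(radii)[::-1]
    th = _paint_spheres()(
        np.ascontiguousarray(coords[order]),
        np.ascontiguousarray(radii[order]),
        mask.shape,
    )
    return th * mask


def _paint_spheres():
    global _PAINT_IMPL
    try:
        return _PAINT_IMPL
    except NameError:
        pass
    import numba

    @numba.njit(cache=True)
    def impl(coords, radii, shape):  # pragma: no cover
        nz, ny, nx = shape
        th = np.zeros((nz, ny, nx))
        for i in range(coords.shape[0]):
            z, y, x = coords[i, 0], coords[i, 1], coords[i, 2]
            r = radii[i]
            d = 2.0 * r
            ri = int(np.floor(r))
            r2 = r * r
            for zz in range(max(z - ri, 0), min(z + ri + 1, nz)):
                dz2 = (zz - z) ** 2
                for yy in range(max(y - ri, 0), min(y + ri + 1, ny)):
                    dy2 = (yy - y) ** 2
                    if dz2 + dy2 > r2:
                        continue
                    for xx in range(max(x - ri, 0), min(x + ri + 1, nx)):
                        if dz2 + dy2 + (xx - x) ** 2 <= r2 and th[zz, yy, xx] < d:
                            th[zz, yy, xx] = d
        return th

    _PAINT_IMPL = impl
    return impl


def local_thickness(mask: np.ndarray, voxel_size: float) -> float:
    """Volume-weighted mean local thickness in µm."""
    if not mask.any():
        raise ValueError("empty mask")
    th = local_thickness_map(mask)
    return float(th[mask].mean()) * voxel_size * 1000.0


def separation(bone_mask: np.ndarray, roi: np.ndarray, voxel_size: float) -> float:
    """Tb.Sp: local thickness of the non-bone phase within the ROI, µm."""
    bg = roi & ~bone_mask
    if not bg.any():
        raise ValueError("no background inside ROI")
    th = local_thickness_map(bg)
    return float(th[bg].mean()) * voxel_size * 1000.0


def tb_n(bvtv_pct: float, tb_th_um: float) -> float:
    """Trabecular number (1/mm) under the ratio convention (BV/TV)/Tb.Th."""
    if tb_th_um <= 0:
        raise ValueError("Tb.Th must be positive")
    return (bvtv_pct / 100.0) / (tb_th_um / 1000.0)


# ---------------------------------------------------------------------------
# Connectivity density (Euler characteristic of the cubical complex)
# ---------------------------------------------------------------------------

def euler_characteristic(mask: np.ndarray) -> int:
    """Euler characteristic V - E + F - C of the voxel cubical complex."""
    m = np.pad(np.asarray(mask, dtype=bool), 1)

    def count(axes: tuple[int, ...]) -> int:
        acc = np.zeros(m.shape, dtype=bool)
        n_sh = 1 << len(axes)
        for bits in range(n_sh):
            sh = m
            for i, ax in enumerate(axes):
                if bits >> i & 1:
                    sh = np.roll(sh, 1, axis=ax)
            acc = acc | sh
        return int(acc.sum())

    C = int(m.sum())
    F = sum(count((a,)) for a in range(3))
    E = sum(count(tuple(a for a in range(3) if a != ax)) for ax in range(3))
    V = count((0, 1, 2))
    return V - E + F - C


def betti_numbers(mask: np.ndarray, boundary_connectivity: bool = True) -> tuple[int, int, int]:
    """(b0, b1, b2) of a binary volume.

    b0: foreground components (26-connectivity); b2: enclosed cavities
    (background components not touching the border, 6-connectivity);
    b1 = b0 + b2 - chi. With `boundary_connectivity` the volume is
    mirror-padded one voxel before the Euler count, the usual "connectivity
    around the boundary" assumption.
    """
    mask = np.asarray(mask, dtype=bool)
    if boundary_connectivity:
        work = np.pad(mask, 1, mode="edge")
    else:
        work = mask
    chi = euler_characteristic(work)
    lab, b0 = ndimage.label(work, structure=np.ones((3, 3, 3), int))
    bg = ~work
    labb, nb = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
    border_labels = np.unique(
        np.concatenate([
            labb[0].ravel(), labb[-1].ravel(),
            labb[:, 0].ravel(), labb[:, -1].ravel(),
            labb[:, :, 0].ravel(), labb[:, :, -1].ravel(),
        ])
    )
    touching = np.unique(border_labels[border_labels > 0])
    b2 = nb - touching.size
    b1 = b0 + b2 - chi
    return int(b0), int(b1), int(b2)


def connectivity_density(mask: np.ndarray, roi_volume_mm3: float) -> float:
    """Conn.D = b1 / ROI volume (1/mm^3)."""
    if roi_volume_mm3 <= 0:
        raise ValueError("ROI volume must be positive")
    _, b1, _ = betti_numbers(mask)
    return b1 / roi_volume_mm3


# ---------------------------------------------------------------------------
# Degree of anisotropy (MIL fabric)
# ---------------------------------------------------------------------------

def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform directions on the upper hemisphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = i / n  # upper hemisphere only
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def mean_intercept_length(
    mask: np.ndarray,
    direction: np.ndarray,
    line_spacing: float = 2.0,
    step: float = 0.7,
) -> float | None:
    """MIL along one direction: bone line length / intercept count.

    Parallel test lines cover the bounding box on a grid perpendicular to
    the direction; the mask is sampled with nearest-neighbour interpolation
    at `step`-voxel intervals. Returns None when no intercepts are found.
    """
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    # orthonormal basis (d, u, v)
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    shape = np.array(mask.shape, dtype=float)  # (z, y, x)
    center = (shape - 1) / 2.0
    radius = float(np.linalg.norm(shape) / 2.0)
    n_lines = max(int(2 * radius / line_spacing), 1)
    offs = (np.arange(n_lines) - (n_lines - 1) / 2.0) * line_spacing
    ts = np.arange(-radius, radius + step, step)
    # lines: origin = center + o1*u + o2*v, points = origin + t*d   (z,y,x order)
    o1, o2 = np.meshgrid(offs, offs, indexing="ij")
    origins = center + o1[..., None] * u + o2[..., None] * v
    pts = origins[..., None, :] + ts[None, None, :, None] * d  # (L, L, T, 3)
    idx = np.round(pts).astype(int)
    inside = np.all((idx >= 0) & (idx < shape.astype(int)), axis=-1)
    vals = np.zeros(idx.shape[:-1], dtype=bool)
    ii = idx[inside]
    vals[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    bone_len = vals.sum() * step
    # intercepts: entries into bone along each line
    entries = vals[..., 1:] & ~vals[..., :-1]
    n_int = int(entries.sum()) + int(vals[..., 0].sum())
    if n_int == 0:
        return None
    return float(bone_len / n_int)


def degree_of_anisotropy(
    mask: np.ndarray,
    n_directions: int = 128,
    line_spacing: float = 2.0,
) -> float:
    """DA from the MIL fabric ellipsoid (longest / shortest semi-axis).

    An ellipsoid 1/MIL(w)^2 = w' A w is least-squares fitted over
    quasi-uniform directions; DA = sqrt(lmax(A) / lmin(A)) >= 1.
    """
    if not mask.any():
        raise ValueError("empty mask")
    # crop to the foreground bounding box so test lines cover the structure
    zs, ys, xs = np.nonzero(mask)
    mask = mask[zs.min():zs.max() + 1, ys.min():ys.max() + 1,
                xs.min():xs.max() + 1]
    dirs = _fibonacci_hemisphere(n_directions)
    rows, rhs = [], []
    import warnings

    for d in dirs:
        mil = mean_intercept_length(mask, d[::-1], line_spacing)  # d is (x,y,z)->(z,y,x)
        if mil is None or mil <= 0:
            warnings.warn("direction without intercepts dropped from MIL fit")
            continue
        x, y, z = d
        rows.append([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z])
        rhs.append(1.0 / mil**2)
    if len(rows) < 6:
        raise ValueError("too few valid MIL directions for the ellipsoid fit")
    coef, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    A = np.array([
        [coef[0], coef[3], coef[4]],
        [coef[3], coef[1], coef[5]],
        [coef[4], coef[5], coef[2]],
    ])
    ev = np.linalg.eigvalsh(A)
    if ev[0] <= 0:
        raise ValueError("MIL ellipsoid fit is not positive definite")
    return float(np.sqrt(ev[-1] / ev[0]))


# ---------------------------------------------------------------------------
# Cortical analysis
# ---------------------------------------------------------------------------

def cortical_analysis(
    bone_mask: np.ndarray,
    spec: CorticalVOISpec,
    voxel_size: float,
) -> tuple[float, float, float, float]:
    """Midshaft cortical geometry: (Tt.Ar, Ct.Ar, Ct.Ar/Tt.Ar, Ct.Th).

    Per slice of the 1 mm stack the cortex is closed with a round kernel to
    remove intracortical pores; Tt.Ar is the filled periosteal envelope
    area, Ct.Ar the closed cortex area. Ct.Th is the inscribed-sphere
    thickness of the 3-D closed cortical stack, in µm.
    """
    half = _round_half_up(spec.extent_mm / voxel_size / 2.0)
    z0 = spec.center_slice - half
    z1 = spec.center_slice + half
    if z0 < 0 or z1 >= bone_mask.shape[0]:
        raise ValueError("cortical VOI outside the image")
    footprint = disk(spec.closing_radius_px)
    pad = spec.closing_radius_px + 1
    tt, ct = [], []
    closed_stack = np.zeros_like(bone_mask[z0:z1 + 1], dtype=bool)
    for i, z in enumerate(range(z0, z1 + 1)):
        sl = bone_mask[z]
        if not sl.any():
            raise ValueError(f"empty midshaft cross-section at slice {z}")
        p = np.pad(sl, pad)
        closed = ndimage.binary_closing(p, structure=footprint)[pad:-pad, pad:-pad]
        filled = ndimage.binary_fill_holes(closed)
        closed_stack[i] = closed
        tt.append(filled.sum())
        ct.append(closed.sum())
    area = voxel_size**2
    tt_ar = float(np.mean(tt)) * area
    ct_ar = float(np.mean(ct)) * area
    ct_th = local_thickness(closed_stack, voxel_size)
    return tt_ar, ct_ar, ct_ar / tt_ar, ct_th
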