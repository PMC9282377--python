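"""Image alignment and volume-of-interest selection.

These are the operator-dependent steps of the pipeline: each tibia image is
rigidly registered to a reference (follow-up scans to their baseline) with
normalized mutual information (NMI) as the optimization criterion, resampled
with a Lanczos windowed-sinc kernel, smoothed with a small Gaussian, and a
volume of interest (VOI) spanning 80% of the tibia length below the growth
plate is selected with the fibula excluded by 2-D + 3-D connectivity
filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .image import RigidTransform, VoxelImage, resample


class RegistrationError(RuntimeError):
    """Raised when the rigid registration fails to converge.

    Carries the last iterate so a caller can inspect or restart.
    """

    def __init__(self, message: str, last_transform: RigidTransform | None = None):
        super().__init__(message)
        self.last_transform = last_transform


@dataclass
class FilterParams:
    """3-D Gaussian noise filter: odd cubic kernel, sigma in voxels."""

    kernel: int = 3
    sigma: float = 0.65

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class VOISelection:
    """VOI spanning `fraction` of the tibia length below the growth plate."""

    start_slice: int
    end_slice: int
    length_mm: float
    fraction: float
    mask: np.ndarray  # bone mask (fibula excluded), zero outside the slice range

    @property
    def n_slices(self) -> int:
        return self.end_slice - self.start_slice + 1

    @property
    def slices(self) -> slice:
        return slice(self.start_slice, self.end_slice + 1)


# ---------------------------------------------------------------------------
# Normalized mutual information
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def nmi(a: VoxelImage | np.ndarray, b: VoxelImage | np.ndarray, bins: int = 64) -> float:
    """NMI(A, B) = (H(A) + H(B)) / H(A, B) on the joint grey histogram.

    Each image is min-max scaled individually before binning; the value lies
    in [1, 2], with 2 for identical images.
    """
    x = a.data if isinstance(a, VoxelImage) else np.asarray(a)
    y = b.data if isinstance(b, VoxelImage) else np.asarray(b)
    if x.shape != y.shape:
        raise ValueError("images must share the same grid")
    qx = _quantize(x.ravel(), bins)
    qy = _quantize(y.ravel(), bins)
    joint = np.bincount(qx * bins + qy, minlength=bins * bins).astype(float)
    joint /= joint.sum()
    hxy = _entropy(joint)
    if hxy == 0.0:
        raise ValueError("joint entropy is zero (constant image); NMI undefined")
    jm = joint.reshape(bins, bins)
    hx = _entropy(jm.sum(axis=1))
    hy = _entropy(jm.sum(axis=0))
    return (hx + hy) / hxy


def _quantize(v: np.ndarray, bins: int, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    lo = float(v.min()) if lo is None else lo
    hi = float(v.max()) if hi is None else hi
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.intp)
    q = ((v - lo) * (bins / (hi - lo))).astype(np.intp)
    return np.clip(q, 0, bins - 1)


# ---------------------------------------------------------------------------
# Rigid registration (multi-resolution Powell over 6 parameters)
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    transform: RigidTransform
    nmi_init: float
    nmi_opt: float
    n_evaluations: int


def _shrink(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def rigid_register(
    moving: VoxelImage,
    fixed: VoxelImage,
    init: RigidTransform | None = None,
    bins: int = 64,
    shrink_factors: tuple[int, ...] = (4, 2),
    max_evaluations: int = 2000,
    xtol: float = 0.01,
    full_output: bool = False,
) -> RigidTransform | RegistrationResult:
    """Find the rigid transform maximizing NMI(fixed, moving ∘ T).

    Optimizes the 6 rigid parameters (3 Euler angles in degrees, 3
    translations in mm, rotation centre at the fixed-image centre) with
    Powell's method at each resolution level, coarse to fine. Linear
    interpolation is used inside the objective; callers resample once with
    the Lanczos kernel afterwards.
    """
    if abs(moving.voxel_size - fixed.voxel_size) > 1e-9:
        raise ValueError("moving and fixed must share the voxel size")
    if init is None:
        init = RigidTransform(center_mm=fixed.center_mm())
    center = fixed.center_mm()
    x = np.concatenate([init.angles_deg, init.translation_mm])
    mov_lo, mov_hi = float(moving.data.min()), float(moving.data.max())
    background = mov_lo
    n_eval = 0
    last = init

    import SimpleITK as sitk  # local import keeps module import light

    # evaluate NMI only over the fixed image's foreground bounding box
    fg = fixed.data > (0.5 * (fixed.data.min() + fixed.data.max()))
    if fg.any():
        zs, ys, xs = np.nonzero(fg)
        pad = 6
        bbox = tuple(slice(max(int(c.min()) - pad, 0), int(c.max()) + pad + 1)
                     for c in (zs, ys, xs))
    else:
        bbox = (slice(None),) * 3

    for factor in shrink_factors:
        fix_data = _shrink(fixed.data, factor)
        crop = tuple(slice(b.start // factor if b.start else 0,
                           -(-b.stop // factor) if b.stop else None)
                     for b in bbox)
        fix_l = VoxelImage(fix_data[crop], fixed.voxel_size * factor)
        mov_l = VoxelImage(_shrink(moving.data, factor), moving.voxel_size * factor)
        fix_sitk = fix_l.to_sitk()
        origin = np.array([crop[2].start or 0, crop[1].start or 0,
                           crop[0].start or 0], dtype=float) * fixed.voxel_size * factor
        fix_sitk.SetOrigin(tuple(origin))
        mov_sitk = mov_l.to_sitk()
        qf = _quantize(fix_l.data.ravel(), bins)

        def objective(p: np.ndarray) -> float:
            nonlocal n_eval, last
            n_eval += 1
            t = RigidTransform(p[:3], p[3:], center)
            last = t
            out = sitk.Resample(
                mov_sitk, fix_sitk, t.to_sitk(), sitk.sitkLinear,
                background, sitk.sitkFloat32,
            )
            m = sitk.GetArrayFromImage(out).ravel()
            qm = _quantize(m, bins, mov_lo, mov_hi)
            joint = np.bincount(qf * bins + qm, minlength=bins * bins).astype(float)
            joint /= joint.sum()
            hxy = _entropy(joint)
            if hxy == 0.0:
                return 0.0
            jm = joint.reshape(bins, bins)
            return -(_entropy(jm.sum(axis=1)) + _entropy(jm.sum(axis=0))) / hxy

        direc = np.diag([1.0, 1.0, 1.0, 0.2, 0.2, 0.2]) * factor
        res = optimize.minimize(
            objective, x, method="Powell",
            options={
                "xtol": xtol * factor, "ftol": 1e-7,
                "maxfev": max_evaluations, "direc": direc,
            },
        )
        if not res.success and "Maximum number" in str(res.message):
            raise RegistrationError(
                f"registration did not converge within {max_evaluations} "
                f"evaluations at shrink factor {factor}", last)
        x = np.asarray(res.x, dtype=float)
        f_opt = -float(res.fun)

    # NMI at the initial transform, on the finest level used (the objective
    # closure from the last loop iteration); never return worse than init
    x_init = np.concatenate([init.angles_deg, init.translation_mm])
    f_init = -objective(x_init)
    if f_opt < f_init:
        x, f_opt = x_init, f_init
    transform = RigidTransform(x[:3], x[3:], center)
    if full_output:
        return RegistrationResult(transform, f_init, f_opt, n_eval)
    return transform


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def gaussian_kernel_3d(params: FilterParams) -> np.ndarray:
    """Truncated discrete Gaussian kernel, normalized to sum 1."""
    half = params.kernel // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * params.sigma**2))
    k = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    return k / k.sum()


def gaussian_smooth(image: VoxelImage, params: FilterParams | None = None) -> VoxelImage:
    """Apply the noise filter (default 3x3x3 kernel, sigma 0.65 voxels)."""
    params = params or FilterParams()
    k = gaussian_kernel_3d(params)
    out = ndimage.convolve(image.data.astype(np.float64), k, mode="reflect")
    return VoxelImage(out, image.voxel_size)


# ---------------------------------------------------------------------------
# Length, VOI, fibula
# ---------------------------------------------------------------------------

def measure_length(mask: np.ndarray, voxel_size: float) -> float:
    """Tibia length from the most proximal to the most distal bone slice."""
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    if zs.size == 0:
        raise ValueError("empty mask: cannot measure length")
    return float(zs[-1] - zs[0] + 1) * voxel_size


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_voi(
    mask: np.ndarray,
    voxel_size: float,
    start_slice: int,
    fraction: float = 0.8,
) -> VOISelection:
    """Select the VOI starting below the growth plate.

    The VOI covers ``fraction`` of the total tibia length L measured on the
    (fibula-excluded) bone mask, starting at ``start_slice`` (the first
    cross-section where growth-plate tissue is no longer visible).
    """
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    if zs.size == 0:
        raise ValueError("empty bone mask")
    if not (zs[0] <= start_slice <= zs[-1]):
        raise ValueError(
            f"start_slice {start_slice} outside bone extent [{zs[0]}, {zs[-1]}]")
    length = float(zs[-1] - zs[0] + 1) * voxel_size
    n = _round_half_up(fraction * length / voxel_size)
    end_slice = start_slice + n - 1
    if end_slice >= mask.shape[0]:
        raise ValueError(
            f"VOI end slice {end_slice} beyond image (nz={mask.shape[0]}); "
            "choose an earlier start slice or smaller fraction")
    end_slice = min(end_slice, int(zs[-1]))
    voi_mask = np.zeros_like(mask, dtype=bool)
    voi_mask[start_slice:end_slice + 1] = mask[start_slice:end_slice + 1]
    return VOISelection(int(start_slice), int(end_slice), length, fraction, voi_mask)


def exclude_fibula(
    mask: np.ndarray,
    junction_zrange: tuple[int, int],
    connectivity_3d: int = 26,
) -> np.ndarray:
    """Remove the fibula from a segmented tibia mask.

    Within ``junction_zrange`` (inclusive) each cross-section keeps only its
    largest 2-D (8-connected) component, severing the tibio-fibular bridge;
    the largest 3-D component of the whole volume is then kept, discarding
    the disconnected fibula.
    """
    z0, z1 = junction_zrange
    if z0 > z1 or z0 < 0 or z1 >= mask.shape[0]:
        raise ValueError(f"invalid junction z-range {junction_zrange}")
    out = mask.copy()
    s2 = np.ones((3, 3), dtype=int)
    for z in range(z0, z1 + 1):
        sl = out[z]
        if not sl.any():
            warnings.warn(f"empty cross-section at slice {z} inside junction range")
            continue
        lab, n = ndimage.label(sl, structure=s2)
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            out[z] = lab == (int(np.argmax(sizes)) + 1)
    s3 = np.ones((3, 3, 3), dtype=int) if connectivity_3d == 26 else None
    lab, n = ndimage.label(out, structure=s3)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        out = lab == (int(np.argmax(sizes)) + 1)
    return out.astype(bool)


def detect_voi_start(bone_mask: np.ndarray, search_fraction: float = 0.5) -> int:
    """Heuristic growth-plate end: first slice where plate tissue is gone.

    Looks for the proximal band where the endosteal interior holds no bone
    (the cartilaginous plate), and returns the first slice distal to it.
    Intended as an operator surrogate; phantom ground truth is authoritative.
    """
    nz = bone_mask.shape[0]
    zmax = max(int(nz * search_fraction), 2)
    interior_bone = np.zeros(zmax)
    for z in range(zmax):
        sl = bone_mask[z]
        if not sl.any():
            interior_bone[z] = np.nan
            continue
        env = ndimage.binary_fill_holes(sl)
        interior = ndimage.binary_erosion(env, iterations=3)
        interior_bone[z] = (sl & interior).sum()
    valid = ~np.isnan(interior_bone)
    if not valid.any():
        raise ValueError("no bone in the proximal half; cannot locate growth plate")
    thr = 0.05 * np.nanmax(interior_bone)
    empty = (interior_bone < thr) & valid
    # first run of >=2 "hollow" slices below the proximal bone end
    runs = np.flatnonzero(empty)
    if runs.size == 0:
        raise ValueError("no growth-plate band detected")
    # contiguous run containing the first hollow slice
    end = runs[0]
    for z in runs:
        if z <= end + 1:
            end = z
        else:
            break
    return int(end + 1)
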