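"""Densitometric analysis: TMD calibration, VOI summary, 40-partition BMC map.

Grey levels are converted to tissue mineral density (TMD, mgHA/cc) by a
linear calibration law; per-voxel bone mineral content (BMC, mg) is TMD
times the voxel volume. The VOI is divided into 10 longitudinal sections
(1 = proximal, 10 = distal), each split into anterior / medial / posterior /
lateral quadrants by two perpendicular lines through the cross-section
centroid, giving a 40-partition BMC map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import VoxelImage
from .registration import VOISelection

MM3_TO_CC = 1e-3

QUADRANTS = ("anterior", "medial", "posterior", "lateral")


@dataclass
class CalibrationLaw:
    """TMD = slope * grey + intercept (mgHA/cc)."""

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")

    def grey_from_tmd(self, tmd: np.ndarray | float) -> np.ndarray | float:
        return (tmd - self.intercept) / self.slope


@dataclass
class DensitometricSummary:
    """Whole-VOI densitometric parameters (Tot BMC etc.)."""

    bmc_mg: float
    bmd_mg_cc: float
    tmd_mg_cc: float
    bv_mm3: float
    tv_mm3: float
    bvtv_pct: float
    av_tot_area_mm2: float
    min_tot_area_mm2: float
    av_bone_area_mm2: float
    min_bone_area_mm2: float
    length_mm: float

    def to_dict(self) -> dict:
        return {
            "L": self.length_mm,
            "Tot BMC": self.bmc_mg,
            "Tot TMD": self.tmd_mg_cc,
            "Tot BV": self.bv_mm3,
            "Tot TV": self.tv_mm3,
            "Tot BMD": self.bmd_mg_cc,
            "Tot BV/TV": self.bvtv_pct,
            "AvTotArea": self.av_tot_area_mm2,
            "AvBoneArea": self.av_bone_area_mm2,
            "MinTotArea": self.min_tot_area_mm2,
            "MinBoneArea": self.min_bone_area_mm2,
        }


@dataclass
class PartitionScheme:
    """10 longitudinal sections x 4 anatomical quadrants.

    Quadrants are measured by the azimuth of (voxel - slice centroid) about
    +x: anterior is centred on +x, then counter-clockwise medial (+y),
    posterior, lateral. Boundary lines sit at 45 deg to the axes (half-open
    bins), configurable through `angle_offset_deg`.
    """

    n_sections: int = 10
    angle_offset_deg: float = 0.0
    centroid_from: str = "bone"  # or "envelope"


@dataclass
class PartitionTable:
    """BMC (mg) per longitudinal section x quadrant."""

    bmc_mg: np.ndarray  # (n_sections, 4)
    section_slices: list[tuple[int, int]]
    centroids_mm: np.ndarray | None = None  # (n_slices, 2) (x, y) per VOI slice

    @property
    def total_mg(self) -> float:
        return float(self.bmc_mg.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bmc_mg, columns=list(QUADRANTS))
        df.index = np.arange(1, self.bmc_mg.shape[0] + 1)
        df.index.name = "section"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


# ---------------------------------------------------------------------------
# Calibration and per-voxel BMC
# ---------------------------------------------------------------------------

def to_tmd(
    image: VoxelImage | np.ndarray,
    law: CalibrationLaw,
    clamp: bool = True,
) -> np.ndarray:
    """Convert grey levels to TMD (mgHA/cc), clamped at zero below.

    `clamp=False` keeps negative noise excursions; integrating the
    unclamped density over a region is unbiased under zero-mean noise,
    which is what the BMC integral uses.
    """
    data = image.data if isinstance(image, VoxelImage) else np.asarray(image)
    tmd = law.slope * data.astype(np.float64) + law.intercept
    return np.maximum(tmd, 0.0) if clamp else tmd


def voxel_bmc(tmd: np.ndarray, voxel_size: float) -> np.ndarray:
    """Per-voxel BMC in mg: TMD [mg/cc] * voxel volume [cc]."""
    return tmd * (voxel_size**3 * MM3_TO_CC)


# ---------------------------------------------------------------------------
# Whole-VOI summary
# ---------------------------------------------------------------------------

def slice_envelope(bone_slice: np.ndarray) -> np.ndarray:
    """Per-slice filled envelope (2-D hole-filled bone mask)."""
    return ndimage.binary_fill_holes(bone_slice)


def integration_region(
    voi: VOISelection,
    dilation_vox: int = 2,
    faint: np.ndarray | None = None,
) -> np.ndarray:
    """BMC integration region: the VOI bone mask dilated within VOI slices.

    The dilation captures the support of the resampling and noise filters
    so the densitometric integral over the region is conserved under
    smoothing; partial-volume mineral at the bone surface is counted.
    `faint` optionally adds voxels with weak mineral signal inside the
    per-slice periosteal envelope (partial-volume trabeculae below the
    segmentation threshold); voxels outside the envelope — such as an
    excluded fibula — are never added.
    """
    region = voi.mask.copy()
    if dilation_vox > 0:
        region = ndimage.binary_dilation(
            region, structure=np.ones((3, 3, 3), bool), iterations=dilation_vox)
    if faint is not None:
        add = np.zeros_like(region)
        for z in range(voi.start_slice, voi.end_slice + 1):
            if voi.mask[z].any():
                add[z] = faint[z] & slice_envelope(voi.mask[z])
        region |= add
    region[:voi.start_slice] = False
    region[voi.end_slice + 1:] = False
    return region


def summarize(
    tmd: np.ndarray,
    voi: VOISelection,
    voxel_size: float,
    region: np.ndarray | None = None,
) -> DensitometricSummary:
    """Whole-VOI densitometric summary.

    BMC integrates per-voxel mineral over `region` (default: the VOI bone
    mask itself; the pipeline passes the one-voxel-dilated region). TMD,
    BV and the areas are computed on the bone mask; TV is the volume of
    the per-slice filled envelope; BMD = BMC / TV. Slices without bone are
    excluded from the per-slice minima.
    """
    bone = voi.mask
    if region is None:
        region = bone
    vol_mm3 = voxel_size**3
    area_mm2 = voxel_size**2
    vox_cc = vol_mm3 * MM3_TO_CC

    nb = int(bone.sum())
    if nb == 0:
        raise ValueError("VOI contains no bone voxels")
    bmc = float(tmd[region].sum()) * vox_cc
    mean_tmd = float(tmd[bone].mean())

    tot_areas, bone_areas = [], []
    tv_vox = 0
    for z in range(voi.start_slice, voi.end_slice + 1):
        sl = bone[z]
        if not sl.any():
            continue
        env = slice_envelope(sl)
        tv_vox += int(env.sum())
        tot_areas.append(env.sum() * area_mm2)
        bone_areas.append(sl.sum() * area_mm2)
    tv_mm3 = tv_vox * vol_mm3
    bv_mm3 = nb * vol_mm3
    bmd = bmc / (tv_mm3 * MM3_TO_CC)
    return DensitometricSummary(
        bmc_mg=bmc,
        bmd_mg_cc=bmd,
        tmd_mg_cc=mean_tmd,
        bv_mm3=bv_mm3,
        tv_mm3=tv_mm3,
        bvtv_pct=100.0 * bv_mm3 / tv_mm3,
        av_tot_area_mm2=float(np.mean(tot_areas)),
        min_tot_area_mm2=float(np.min(tot_areas)),
        av_bone_area_mm2=float(np.mean(bone_areas)),
        min_bone_area_mm2=float(np.min(bone_areas)),
        length_mm=voi.length_mm,
    )


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

def section_ranges(n_slices: int, n_sections: int) -> list[tuple[int, int]]:
    """Split `n_slices` into contiguous sections; remainder slices go one
    each to the most proximal sections. Returns (start, end) offsets,
    inclusive, relative to the VOI start."""
    base, rem = divmod(n_slices, n_sections)
    if base == 0:
        raise ValueError(f"VOI of {n_slices} slices cannot hold {n_sections} sections")
    out = []
    z = 0
    for s in range(n_sections):
        n = base + (1 if s < rem else 0)
        out.append((z, z + n - 1))
        z += n
    return out


def partition_labels(
    voi: VOISelection,
    scheme: PartitionScheme | None = None,
    region: np.ndarray | None = None,
) -> np.ndarray:
    """Label each voxel of the BMC integration region with its partition.

    `region` defaults to the VOI bone mask; per-slice centroids always come
    from the bone mask (or its envelope). Returns an int array; 0 =
    outside, otherwise label = section * 4 + quadrant + 1 with section in
    0..n_sections-1 and quadrant indexing (anterior, medial, posterior,
    lateral).
    """
    scheme = scheme or PartitionScheme()
    bone = voi.mask
    if region is None:
        region = bone
    labels = np.zeros(bone.shape, dtype=np.int16)
    ranges = section_ranges(voi.n_slices, scheme.n_sections)
    offset = np.deg2rad(scheme.angle_offset_deg)
    for s, (a, b) in enumerate(ranges):
        for z in range(voi.start_slice + a, voi.start_slice + b + 1):
            sl = bone[z]
            target = region[z]
            if not target.any():
                continue
            cen_src = slice_envelope(sl) if scheme.centroid_from == "envelope" else sl
            if not cen_src.any():
                cen_src = target
            ys, xs = np.nonzero(cen_src)
            cy, cx = ys.mean(), xs.mean()
            ys, xs = np.nonzero(target)
            az = np.arctan2(ys - cy, xs - cx) - offset  # 0 = +x (anterior)
            # anterior [-45,45), medial [45,135), posterior [135,225), lateral [225,315)
            quad = np.floor((np.rad2deg(az) + 45.0) / 90.0).astype(int) % 4
            labels[z, ys, xs] = s * 4 + quad + 1
    return labels


def partition_bmc(
    bmc_volume: np.ndarray,
    labels: np.ndarray,
    voi: VOISelection,
    scheme: PartitionScheme | None = None,
) -> PartitionTable:
    """Sum per-voxel BMC into the section x quadrant table."""
    scheme = scheme or PartitionScheme()
    n = scheme.n_sections
    sums = ndimage.sum_labels(
        bmc_volume, labels, index=np.arange(1, n * 4 + 1))
    table = np.asarray(sums, dtype=float).reshape(n, 4)
    ranges = [
        (voi.start_slice + a, voi.start_slice + b)
        for a, b in section_ranges(voi.n_slices, n)
    ]
    return PartitionTable(table, ranges)
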