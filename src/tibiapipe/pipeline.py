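"""Single-image analysis orchestration.

Runs the stages in protocol order — (optional) rigid alignment, Lanczos
resampling, Gaussian smoothing, fibula exclusion, VOI selection,
histogram-peak thresholding, densitometry with the 40-partition BMC map,
standard morphometry, and the micro-FE compression model — and collects
every numeric output with its provenance into one JSON-serializable
record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import densitometry as dm
from . import microfe as fe
from . import morphometry as mm
from . import registration as reg
from . import segmentation as seg
from .image import RigidTransform, VoxelImage, resample


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    calibration: dm.CalibrationLaw = field(
        default_factory=lambda: dm.CalibrationLaw(slope=5.0, intercept=-200.0))
    filter_params: reg.FilterParams = field(default_factory=reg.FilterParams)
    voi_fraction: float = 0.8
    junction_zrange: tuple[int, int] | None = None
    partition_scheme: dm.PartitionScheme = field(default_factory=dm.PartitionScheme)
    threshold: float | None = None           # None: histogram-peak rule
    bmc_dilation_vox: int = 2                # BMC integration-region dilation
    faint_fraction: float = 0.5              # sub-threshold signal floor (of
                                             # the background-to-threshold gap)
    despeckle_min_size: int = 10
    material: fe.MaterialModel = field(default_factory=fe.MaterialModel)
    load: fe.LoadCase = field(default_factory=fe.LoadCase)
    criterion: fe.FailureCriterion = field(default_factory=fe.FailureCriterion)
    fe_solver: str = "auto"
    fe_tol: float = 1e-8
    run_morphometry: bool = True
    run_fe: bool = True
    trabecular_offset_mm: float = 0.2
    trabecular_extent_mm: float = 1.0
    cortical_extent_mm: float = 1.0
    closing_radius_px: int = 10
    da_directions: int = 64
    registration_shrink: tuple[int, ...] = (4, 2)


@dataclass
class AnalysisRecord:
    """All outputs of one pipeline run plus the parameters that made them."""

    provenance: dict
    densitometric: dict
    partition_bmc_mg: list          # 10 x 4 nested lists
    morphometric: dict | None
    fe_summary: dict | None
    aligned_image: "VoxelImage | None" = None   # optional, never serialized

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps({
            "provenance": self.provenance,
            "densitometric": self.densitometric,
            "partition_bmc_mg": self.partition_bmc_mg,
            "morphometric": self.morphometric,
            "fe_summary": self.fe_summary,
        }, indent=indent, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "AnalysisRecord":
        d = json.loads(text)
        return cls(d["provenance"], d["densitometric"], d["partition_bmc_mg"],
                   d["morphometric"], d["fe_summary"])


def analyze_image(
    image: VoxelImage,
    start_slice: int | None,
    config: AnalysisConfig | None = None,
    fixed: VoxelImage | None = None,
    init_transform: RigidTransform | None = None,
    reference_slice: int | None = None,
    keep_aligned: bool = False,
    extra_transform: RigidTransform | None = None,
) -> AnalysisRecord:
    """Run the full analysis on one image.

    With `fixed` given the image is first rigidly registered to it (NMI,
    Powell) and resampled once with the Lanczos kernel; `extra_transform`
    (an operator's accepted residual misalignment) is composed into that
    single resampling. `start_slice` is
    the operator-selected first VOI cross-section below the growth plate
    (in the aligned frame); None invokes the automated heuristic.
    `reference_slice` seeds the trabecular VOI (defaults to start_slice).
    """
    config = config or AnalysisConfig()
    v = image.voxel_size
    prov: dict = {"voxel_size_mm": v, "voi_fraction": config.voi_fraction}

    transform = RigidTransform(center_mm=image.center_mm())
    aligned = image
    if fixed is not None:
        try:
            transform = reg.rigid_register(
                image, fixed, init=init_transform,
                shrink_factors=config.registration_shrink)
            if extra_transform is not None:
                transform = transform.compose(extra_transform)
            background = float(np.median(np.concatenate([
                image.data[0].ravel(), image.data[-1].ravel()])))
            aligned = resample(image, transform, "lanczos",
                               background=background, reference=fixed)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("registration", e) from e
    prov["transform"] = transform.to_dict()

    try:
        smoothed = reg.gaussian_smooth(aligned, config.filter_params)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("smoothing", e) from e

    try:
        if config.threshold is not None:
            thr = config.threshold
            g_bg = float(smoothed.data.min())
        else:
            g_bg, g_bone = seg.histogram_peak_threshold(smoothed, return_peaks=True)
            thr = (g_bg + g_bone) / 2.0
        mask = seg.binarize(smoothed, thr)
        if config.junction_zrange is not None:
            mask = reg.exclude_fibula(mask, config.junction_zrange)
        else:
            mask = seg.largest_component(mask, connectivity=26)
        prov["threshold"] = thr
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("segmentation", e) from e

    try:
        if start_slice is None:
            start_slice = reg.detect_voi_start(mask)
        voi = reg.select_voi(mask, v, start_slice, config.voi_fraction)
        prov["start_slice"] = int(start_slice)
        prov["voi"] = {"start": voi.start_slice, "end": voi.end_slice,
                       "length_mm": voi.length_mm}
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("voi_selection", e) from e

    try:
        tmd = dm.to_tmd(smoothed, config.calibration, clamp=False)
        bmc_vol = dm.voxel_bmc(tmd, v)
        faint = smoothed.data >= (g_bg + config.faint_fraction * (thr - g_bg))
        region = dm.integration_region(voi, config.bmc_dilation_vox, faint)
        summary = dm.summarize(tmd, voi, v, region)
        labels = dm.partition_labels(voi, config.partition_scheme, region)
        table = dm.partition_bmc(bmc_vol, labels, voi, config.partition_scheme)
        if abs(table.total_mg - summary.bmc_mg) > 1e-9 * max(summary.bmc_mg, 1e-30):
            raise AssertionError("partition BMC does not sum to total BMC")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("densitometry", e) from e

    morpho = None
    if config.run_morphometry:
        try:
            morpho = _morphometry(mask, voi, config, v,
                                  reference_slice or start_slice)
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("morphometry", e) from e

    fe_summary = None
    if config.run_fe:
        try:
            fe_mask = seg.largest_component(voi.mask, connectivity=6)
            model = fe.build_model(fe_mask, v, config.material)
            result = fe.assemble_and_solve(
                model, config.load, tol=config.fe_tol, solver=config.fe_solver)
            fe.strain_field(result, model)
            failure = fe.failure_load(result, model, config.criterion)
            fe_summary = {
                "stiffness_n_mm": result.stiffness_n_mm,
                "failure_load_n": failure,
                "n_elements": model.n_elements,
                "n_nodes": model.n_nodes,
                "solver": result.solver_info.get("solver"),
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("microfe", e) from e

    return AnalysisRecord(
        provenance=prov,
        densitometric=summary.to_dict(),
        partition_bmc_mg=table.bmc_mg.tolist(),
        morphometric=morpho,
        fe_summary=fe_summary,
        aligned_image=aligned if keep_aligned else None,
    )


def _morphometry(
    mask: np.ndarray,
    voi: reg.VOISelection,
    config: AnalysisConfig,
    v: float,
    reference_slice: int,
) -> dict:
    clean = seg.despeckle(mask, config.despeckle_min_size)
    tspec = mm.TrabecularVOISpec(
        reference_slice=reference_slice,
        offset_mm=config.trabecular_offset_mm,
        extent_mm=config.trabecular_extent_mm)
    roi = mm.trabecular_voi(clean, tspec, v)
    trab = clean & roi
    tb_bvtv = mm.bvtv(clean, roi)
    tb_th = mm.local_thickness(trab, v) if trab.any() else float("nan")
    tb_sp = mm.separation(clean, roi, v)
    tb_n_val = mm.tb_n(tb_bvtv, tb_th) if np.isfinite(tb_th) else float("nan")
    roi_vol = float(roi.sum()) * v**3
    conn_d = mm.connectivity_density(trab, roi_vol)
    da = (mm.degree_of_anisotropy(trab, n_directions=config.da_directions)
          if trab.any() else float("nan"))

    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    mid = int(zs[0] + round(0.5 * (zs[-1] - zs[0])))
    cspec = mm.CorticalVOISpec(
        center_slice=mid, extent_mm=config.cortical_extent_mm,
        closing_radius_px=config.closing_radius_px)
    tt_ar, ct_ar, ratio, ct_th = mm.cortical_analysis(mask, cspec, v)
    return {
        "Tb.BV/TV": tb_bvtv, "Tb.Th": tb_th, "Tb.Sp": tb_sp, "Tb.N": tb_n_val,
        "Conn.D": conn_d, "DA": da,
        "Tt.Ar": tt_ar, "Ct.Ar": ct_ar, "Ct.Ar/Tt.Ar": ratio, "Ct.Th": ct_th,
    }
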