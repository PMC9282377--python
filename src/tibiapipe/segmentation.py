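"""Global thresholding and connectivity filtering.

Bone is segmented with a specimen-specific global threshold, the mean of
the grey levels of the background and bone peaks of the image histogram.
Unconnected voxels are removed with a 6-connectivity (face) rule before
meshing, and small speckles (< 10 voxels) are removed before morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .image import VoxelImage


@dataclass
class SegmentationParams:
    threshold: float
    connectivity: int = 6
    despeckle_min_size: int = 10

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.despeckle_min_size < 1:
            raise ValueError("despeckle_min_size must be >= 1")


def histogram_peak_threshold(
    image: VoxelImage | np.ndarray,
    voi_mask: np.ndarray | None = None,
    bins: int = 256,
    smooth_window: int = 5,
    min_separation_frac: float = 0.25,
    return_peaks: bool = False,
) -> float | tuple[float, float]:
    """Specimen-specific global threshold from the grey-level histogram.

    threshold = (grey(background peak) + grey(bone peak)) / 2. Peaks are
    local maxima of a moving-average-smoothed histogram; the background
    peak is the most prominent one and the bone peak the most prominent
    maximum at least `min_separation_frac` of the grey range away from it
    (partial-volume shoulders between the modes are thereby skipped).
    """
    data = image.data if isinstance(image, VoxelImage) else np.asarray(image)
    values = data[voi_mask] if voi_mask is not None else data.ravel()
    hist, edges = np.histogram(values, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    kernel = np.ones(smooth_window) / smooth_window
    sm = np.convolve(hist.astype(float), kernel, mode="same")
    # pad so maxima at the histogram ends are detectable
    padded = np.concatenate([[sm.min() - 1], sm, [sm.min() - 1]])
    peaks, props = find_peaks(padded, prominence=0.0)
    peaks -= 1
    if peaks.size < 2:
        raise ValueError(
            "fewer than two histogram peaks detected; "
            "supply a manual threshold")
    order = np.argsort(props["prominences"])[::-1]
    g1 = centers[peaks[order[0]]]
    min_sep = min_separation_frac * (centers[-1] - centers[0])
    g2 = None
    for i in order[1:]:
        height = padded[peaks[i] + 1]
        # secondary peak must stand out of the counting (Poisson) noise
        if props["prominences"][i] < 5.0 * np.sqrt(height + 1.0):
            continue
        if abs(centers[peaks[i]] - g1) >= min_sep:
            g2 = centers[peaks[i]]
            break
    if g2 is None:
        raise ValueError(
            "no second histogram peak separated from the background mode; "
            "supply a manual threshold")
    if return_peaks:
        lo, hi = sorted((float(g1), float(g2)))
        return lo, hi
    return float((g1 + g2) / 2.0)


def binarize(image: VoxelImage | np.ndarray, threshold: float) -> np.ndarray:
    """Foreground where grey >= threshold (ties are bone)."""
    data = image.data if isinstance(image, VoxelImage) else np.asarray(image)
    return data >= threshold


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def largest_component(mask: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Keep only the largest connected component (default face connectivity).

    Size ties are broken toward the component containing the smallest linear
    voxel index.
    """
    if not mask.any():
        raise ValueError("empty mask has no components")
    lab, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 1:
        return mask.astype(bool)
    sizes = np.bincount(lab.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size > 1:
        flat = lab.ravel()
        first_idx = {int(b): np.flatnonzero(flat == b)[0] for b in best}
        keep = min(first_idx, key=first_idx.get)
    else:
        keep = int(best[0])
    return lab == keep


def despeckle(mask: np.ndarray, min_size: int = 10, connectivity: int = 26) -> np.ndarray:
    """Remove 3-D foreground regions smaller than `min_size` voxels (strict <)."""
    if not mask.any():
        return mask.astype(bool)
    lab, _ = ndimage.label(mask, structure=_structure(connectivity))
    sizes = np.bincount(lab.ravel())
    small = np.flatnonzero(sizes < min_size)
    small = small[small > 0]
    if small.size == 0:
        return mask.astype(bool)
    return mask.astype(bool) & ~np.isin(lab, small)
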