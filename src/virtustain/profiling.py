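"""Segmentation and feature extraction for stained (or virtually stained) images.

The pipeline mirrors the standard cell-profiling recipe for adipocytes:

1. **nuclei** are identified first, with window-local (adaptive) Otsu
   thresholding and shape-based declumping (distance-transform watershed) —
   nuclear intensity varies across a field, and clumped nuclei split at
   their necks;
2. **cytoplasm** is segmented as secondary objects: seeded watershed
   propagation from the nuclei into an adaptively thresholded foreground
   with a larger window, so every cell region inherits its nucleus label
   and the cytoplasm count always equals the nucleus count;
3. **lipid droplets** are segmented independently in two global-threshold
   passes targeting the small and the large size population, declumped by
   intensity (droplets are uniformly round, but touching droplets meet at
   an intensity valley), then merged keeping large-pass objects and any
   small-pass object not substantially overlapping one.

Features per structure class: object count, mean area (px), integrated
intensity, mean of per-object mean intensities, and the population standard
deviation of those per-object means.  Intensities are measured on
[0, 1]-rescaled images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

FEATURES = ("count", "mean_area", "integrated_intensity",
            "mean_intensity", "std_intensity")


@dataclass
class SegmentationParams:
    diameter_range: tuple[float, float] = (8.0, 40.0)
    threshold_strategy: str = "global"  # "global" | "adaptive"
    adaptive_window: int = 50
    declump: str = "none"  # "shape" | "intensity" | "none"
    min_size: int | None = None  # default: quarter of the min-diameter disk
    fill_holes: bool = True
    smoothing_sigma: float | None = None  # default: min diameter / 4
    declump_h: float = 0.15  # seed prominence, fraction of foreground range
    threshold_correction: float = 1.0

    def __post_init__(self):
        lo, hi = self.diameter_range
        if not (0 < lo < hi):
            raise ValueError("diameter range must satisfy 0 < min < max")
        if self.threshold_strategy not in ("global", "adaptive"):
            raise ValueError(f"unknown strategy {self.threshold_strategy!r}")
        if self.declump not in ("shape", "intensity", "none"):
            raise ValueError(f"unknown declump mode {self.declump!r}")
        if (self.threshold_strategy == "adaptive"
                and self.adaptive_window <= hi):
            warnings.warn(
                "adaptive window should exceed the largest expected diameter",
                stacklevel=2)

    @property
    def _min_size(self) -> int:
        if self.min_size is not None:
            return self.min_size
        return max(1, int(np.pi * (self.diameter_range[0] / 2) ** 2 / 4))

    @property
    def _sigma(self) -> float:
        if self.smoothing_sigma is not None:
            return self.smoothing_sigma
        return max(0.5, self.diameter_range[0] / 4)


def _adaptive_threshold(image: np.ndarray, window: int,
                        correction: float) -> np.ndarray | None:
    """Window-local Otsu threshold surface (None for a constant image)."""
    flat = image.ravel()
    if flat.max() == flat.min():
        return None
    global_t = threshold_otsu(image)
    h, w = image.shape
    nby, nbx = max(1, int(np.ceil(h / window))), max(1, int(np.ceil(w / window)))
    tmap = np.empty((nby, nbx))
    for by in range(nby):
        for bx in range(nbx):
            block = image[by * window:(by + 1) * window,
                          bx * window:(bx + 1) * window]
            if block.max() == block.min():
                tmap[by, bx] = global_t
            else:
                tmap[by, bx] = threshold_otsu(block)
    # window-local thresholds are bounded relative to the global split so
    # that foreground-free windows cannot threshold their own noise floor
    tmap = np.clip(tmap, 0.7 * global_t, 1.5 * global_t)
    full = np.repeat(np.repeat(tmap, window, axis=0), window, axis=1)
    full = ndi.gaussian_filter(full, window / 2.0, mode="nearest")
    return correction * full[:h, :w]


def _threshold(image: np.ndarray, params: SegmentationParams) -> np.ndarray | None:
    if params.threshold_strategy == "global":
        if image.max() == image.min():
            return None
        return image > params.threshold_correction * threshold_otsu(image)
    tmap = _adaptive_threshold(image, params.adaptive_window,
                               params.threshold_correction)
    if tmap is None:
        return None
    return image > tmap


def _declump(mask: np.ndarray, image: np.ndarray,
             params: SegmentationParams) -> np.ndarray:
    if params.declump == "none":
        return cc_label(mask)
    if params.declump == "shape":
        edt = ndi.distance_transform_edt(mask)
        min_dist = max(1, int(params.diameter_range[0] / 2))
        coords = peak_local_max(edt, min_distance=min_dist,
                                labels=cc_label(mask), exclude_border=False)
        markers = np.zeros_like(mask, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        markers, _ = ndi.label(ndi.binary_dilation(markers > 0))
        return watershed(-edt, markers, mask=mask)
    # intensity declumping: seeds at prominent smoothed-intensity maxima
    sm = ndi.gaussian_filter(image.astype(np.float64), params._sigma)
    fg = sm[mask]
    span = fg.max() - fg.min()
    work = np.where(mask, sm, fg.min())
    if span <= 0:
        return cc_label(mask)
    seeds = h_maxima(work, params.declump_h * span)
    seeds &= mask
    markers, _ = ndi.label(seeds)
    return watershed(-sm, markers, mask=mask)


def _size_filter(labels: np.ndarray,
                 params: SegmentationParams) -> np.ndarray:
    """Drop objects below min size or outside the equivalent-diameter range."""
    if labels.max() == 0:
        return labels.astype(np.int32)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    eq_diam = 2.0 * np.sqrt(counts / np.pi)
    lo, hi = params.diameter_range
    keep = (counts >= params._min_size) & (eq_diam >= lo) & (eq_diam <= hi)
    remap = np.zeros(len(counts), dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return remap[labels]


def identify_primary(image: np.ndarray,
                     params: SegmentationParams) -> np.ndarray:
    """Threshold, fill holes, declump, and size-filter one channel.

    Returns an int32 label map (0 = background, labels contiguous 1..K).
    An all-background result is a valid empty map, not an error.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    mask = _threshold(image, params)
    if mask is None:
        if params.threshold_strategy == "adaptive":
            warnings.warn("constant image: adaptive threshold undefined, "
                          "returning empty label map", stacklevel=2)
        return np.zeros(image.shape, dtype=np.int32)
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    # drop specks before declumping so they cannot seed watershed regions
    pre = cc_label(mask)
    counts = np.bincount(pre.ravel())
    counts[0] = 0
    small = np.flatnonzero(counts < params._min_size)
    if small.size:
        mask &= ~np.isin(pre, small)
    labels = _declump(mask, image, params)
    return _size_filter(labels, params)


def identify_secondary(image: np.ndarray, seeds: np.ndarray,
                       params: SegmentationParams) -> np.ndarray:
    """Propagate seed labels outward to cell boundaries.

    Watershed on the inverted (smoothed) intensity, constrained to the
    thresholded foreground united with the seeds, so each secondary object
    is a superset of its seed and carries the seed's label.  The object
    count therefore always equals the seed count.
    """
    image, seeds = np.asarray(image), np.asarray(seeds)
    if image.shape != seeds.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs seeds {seeds.shape}")
    if seeds.max() == 0:
        return np.zeros(image.shape, dtype=np.int32)
    mask = _threshold(image, params)
    mask = np.zeros(image.shape, bool) if mask is None else mask
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    mask |= seeds > 0
    sm = ndi.gaussian_filter(image.astype(np.float64), params._sigma)
    labels = watershed(-sm, markers=seeds.astype(np.int32), mask=mask)
    # keep only the regions connected to a seed
    return labels.astype(np.int32)


def segment_droplets(image: np.ndarray, params_small: SegmentationParams,
                     params_large: SegmentationParams) -> np.ndarray:
    """Two-pass droplet segmentation targeting the two size populations.

    Large-pass objects are kept as-is; a small-pass object is added only if
    at most half of its area overlaps large-pass objects (otherwise it is a
    re-detection of the same droplet).  Labels are contiguous in the output.
    """
    for p in (params_small, params_large):
        if p.threshold_strategy != "global" or p.declump != "intensity":
            raise ValueError("droplet passes require global thresholding "
                             "and intensity declumping")
    small = identify_primary(image, params_small)
    large = identify_primary(image, params_large)
    merged = large.astype(np.int32).copy()
    next_label = int(merged.max()) + 1
    for lb in range(1, int(small.max()) + 1):
        obj = small == lb
        overlap = np.count_nonzero(large[obj]) / obj.sum()
        if overlap <= 0.5:
            keep = obj & (merged == 0)
            if keep.any():
                merged[keep] = next_label
                next_label += 1
    # relabel contiguously
    present = np.unique(merged)
    present = present[present > 0]
    remap = np.zeros(int(merged.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    return remap[merged]


def extract_features(labels: np.ndarray, intensity: np.ndarray) -> dict:
    """Per-structure-class summary features from a label map.

    ``mean_intensity`` is the mean over objects of per-object mean
    intensities; ``std_intensity`` is the population standard deviation of
    those per-object means.  An empty label map yields count 0 and NaN for
    the remaining features.
    """
    labels, intensity = np.asarray(labels), np.asarray(intensity)
    if labels.shape != intensity.shape:
        raise ValueError(
            f"shape mismatch: {labels.shape} vs {intensity.shape}")
    k = int(labels.max())
    if k == 0:
        return {"count": 0, "mean_area": np.nan,
                "integrated_intensity": np.nan, "mean_intensity": np.nan,
                "std_intensity": np.nan}
    idx = np.arange(1, k + 1)
    areas = ndi.sum_labels(np.ones_like(intensity, dtype=np.float64),
                           labels, idx)
    sums = ndi.sum_labels(intensity.astype(np.float64), labels, idx)
    means = sums / areas
    return {
        "count": k,
        "mean_area": float(areas.mean()),
        "integrated_intensity": float(sums.sum()),
        "mean_intensity": float(means.mean()),
        "std_intensity": float(means.std()),
    }


@dataclass
class ProfilingConfig:
    """Per-structure segmentation parameters for the 3-channel pipeline."""

    nuclei: SegmentationParams = field(default_factory=lambda: SegmentationParams(
        diameter_range=(10.0, 50.0), threshold_strategy="adaptive",
        adaptive_window=64, declump="shape"))
    # cytoplasm: relaxed threshold correction compensates the uneven dye
    # texture, whose dips otherwise erode the cell boundary
    cytoplasm: SegmentationParams = field(default_factory=lambda: SegmentationParams(
        diameter_range=(20.0, 180.0), threshold_strategy="adaptive",
        adaptive_window=200, declump="none", threshold_correction=0.7))
    droplets_small: SegmentationParams = field(default_factory=lambda: SegmentationParams(
        diameter_range=(3.0, 18.0), threshold_strategy="global",
        declump="intensity"))
    droplets_large: SegmentationParams = field(default_factory=lambda: SegmentationParams(
        diameter_range=(18.0, 80.0), threshold_strategy="global",
        declump="intensity", smoothing_sigma=4.0))


def profile_image(image: np.ndarray, config: ProfilingConfig | None = None,
                  image_id: str | int = 0) -> tuple[dict, pd.DataFrame]:
    """Run the full nuclei -> cytoplasm -> droplets pipeline on one image.

    ``image`` is a (3, H, W) array, channels droplets/cytoplasm/nuclei, on
    the [0, 1] scale.  Returns the label maps and a FeatureTable slice with
    one row per structure class.
    """
    config = config or ProfilingConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("expected a (3, H, W) image")
    nuclei = identify_primary(image[2], config.nuclei)
    cyto = identify_secondary(image[1], nuclei, config.cytoplasm)
    drops = segment_droplets(image[0], config.droplets_small,
                             config.droplets_large)
    labels = {"droplets": drops, "cytoplasm": cyto, "nuclei": nuclei}
    rows = []
    for cls, (lab, ch) in {"droplets": (drops, 0), "cytoplasm": (cyto, 1),
                           "nuclei": (nuclei, 2)}.items():
        feats = extract_features(lab, image[ch])
        rows.append({"image": image_id, "structure": cls, **feats})
    return labels, pd.DataFrame(rows)


__all__ = ["SegmentationParams", "ProfilingConfig", "FEATURES",
           "identify_primary", "identify_secondary", "segment_droplets",
           "extract_features", "profile_image"]
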