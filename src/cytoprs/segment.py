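"""Classical myeloblast nucleus segmentation and per-pixel evaluation.

Pipeline: blue-excess channel -> global Otsu -> morphological opening +
hole filling -> distance-transform watershed (to split touching nuclei)
-> area/solidity filtering -> myeloblast vs other-WBC classification by
area and circularity. Externally produced label masks can be ingested
instead, so a learned segmenter can be slotted in behind the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, regionprops
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

MYELOBLAST = "myeloblast"
OTHER_WBC = "other_wbc"


@dataclass(frozen=True)
class SegmentationConfig:
    min_area: float = 40.0
    max_area: float = 4000.0
    min_solidity: float = 0.70
    blast_min_area: float = 250.0
    blast_min_circularity: float = 0.60
    opening_radius: int = 1
    peak_min_distance: int = 9
    #: absolute floor on the blue-excess channel; keeps the data-adaptive
    #: Otsu threshold from hallucinating foreground on cell-free tiles
    min_blue_excess: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.blast_min_area <= self.max_area):
            raise ValueError("need 0 < min_area < blast_min_area <= max_area")
        if not (0 < self.min_solidity <= 1):
            raise ValueError("min_solidity must be in (0, 1]")
        if not (0 < self.blast_min_circularity <= 1):
            raise ValueError("blast_min_circularity must be in (0, 1]")


@dataclass
class CellInstance:
    """One segmented cell: mask patch at an offset within the tile."""

    label: int
    mask: np.ndarray
    offset: tuple[int, int]
    contour: np.ndarray
    area_px: int
    cell_class: str
    centroid: tuple[float, float]


@dataclass
class PixelMetrics:
    tpr: float
    tnr: float
    f1: float
    n_pixels: int


def blue_excess(rgb: np.ndarray) -> np.ndarray:
    """b = B - (R+G)/2; nuclei stain blue-dominant under Wright-Giemsa."""
    rgb = np.asarray(rgb, dtype=float)
    return rgb[..., 2] - (rgb[..., 0] + rgb[..., 1]) / 2.0


def _instance_from_region(region, label: int, cell_class: str) -> CellInstance:
    y0, x0, _, _ = region.bbox
    mask = region.image
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len)[:-1] - 1.0 + np.array([y0, x0], dtype=float)
    return CellInstance(
        label=label,
        mask=mask,
        offset=(y0, x0),
        contour=contour,
        area_px=int(region.area),
        cell_class=cell_class,
        centroid=tuple(region.centroid),
    )


def segment_tile(rgb: np.ndarray, config: SegmentationConfig | None = None) -> list[CellInstance]:
    """Segment nuclei on an 8-bit RGB tile into classified cell instances.

    Labels are assigned in raster order of the component centroids.
    A tile with no thresholdable foreground yields an empty list.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("segment_tile expects an HxWx3 RGB image")
    config = config or SegmentationConfig()

    b = blue_excess(rgb)
    if b.max() <= b.min():
        return []
    thr = max(threshold_otsu(b), config.min_blue_excess)
    fg = b > thr
    if config.opening_radius > 0:
        fg = opening(fg, disk(config.opening_radius))
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return []

    distance = ndi.distance_transform_edt(fg)
    comp_labels, _ = ndi.label(fg)
    peaks = peak_local_max(
        distance,
        min_distance=config.peak_min_distance,
        labels=comp_labels,
        exclude_border=False,
    )
    markers = np.zeros_like(comp_labels)
    for k, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = k
    if markers.max() == 0:
        labels = comp_labels
    else:
        labels = watershed(-distance, markers, mask=fg)

    kept = []
    for region in regionprops(labels):
        area = region.area
        if area < config.min_area or area > config.max_area:
            continue
        if region.solidity < config.min_solidity:
            continue
        perimeter = region.perimeter
        circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
        is_blast = area >= config.blast_min_area and circularity >= config.blast_min_circularity
        kept.append((region, MYELOBLAST if is_blast else OTHER_WBC))

    kept.sort(key=lambda rc: (rc[0].centroid[0], rc[0].centroid[1]))
    return [
        _instance_from_region(region, label, cls)
        for label, (region, cls) in enumerate(kept, start=1)
    ]


def instances_to_label_image(
    instances: list[CellInstance], shape: tuple[int, int], cell_class: str | None = None
) -> np.ndarray:
    """Rasterize instances to a 16-bit label image (0 = background)."""
    out = np.zeros(shape, dtype=np.uint16)
    for inst in instances:
        if cell_class is not None and inst.cell_class != cell_class:
            continue
        y0, x0 = inst.offset
        h, w = inst.mask.shape
        region = out[y0 : y0 + h, x0 : x0 + w]
        region[inst.mask] = inst.label
    return out


def instances_from_label_image(label_image: np.ndarray, cell_class: str) -> list[CellInstance]:
    """Mask-ingest path: wrap an external label image as cell instances."""
    return [
        _instance_from_region(region, int(region.label), cell_class)
        for region in regionprops(np.asarray(label_image).astype(np.int32))
    ]


def evaluate_segmentation(pred_mask: np.ndarray, truth_mask: np.ndarray) -> PixelMetrics:
    """Per-pixel TPR / TNR / F1 of a binary prediction against truth.

    Rates with an empty denominator (truth class absent) are defined as 1.
    """
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tpr = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    tnr = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 1.0
    return PixelMetrics(tpr=tpr, tnr=tnr, f1=f1, n_pixels=pred.size)


def pool_pixel_metrics(pairs: list[tuple[np.ndarray, np.ndarray]]) -> PixelMetrics:
    """Pool the per-pixel confusion over tiles (single held-out-set rates)."""
    tp = tn = fp = fn = 0
    for pred_mask, truth_mask in pairs:
        pred = np.asarray(pred_mask).astype(bool)
        truth = np.asarray(truth_mask).astype(bool)
        if pred.shape != truth.shape:
            raise ValueError("shape mismatch in pooled metrics")
        tp += int(np.sum(pred & truth))
        tn += int(np.sum(~pred & ~truth))
        fp += int(np.sum(pred & ~truth))
        fn += int(np.sum(~pred & truth))
    tpr = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    tnr = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 1.0
    n = sum(np.asarray(p).size for p, _ in pairs)
    return PixelMetrics(tpr=tpr, tnr=tnr, f1=f1, n_pixels=n)
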