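"""Tile/cohort-level feature extraction driving the per-cell descriptors.

Texture is computed on the Rec.601 luma of the RGB tile, restricted to
the nucleus mask of each myeloblast. Cells come either from the classical
segmenter or from ingested label masks (ground truth or an external
model's output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from cytoprs.features.aggregate import CellFeatures, aggregate_patient, aggregate_tile
from cytoprs.features.catalog import PATIENT_FEATURE_NAMES
from cytoprs.features.descriptors import compute_cell_features
from cytoprs.segment import MYELOBLAST, SegmentationConfig, segment_tile
from cytoprs.simulate import Cohort

logger = logging.getLogger(__name__)


def rgb_to_luma(rgb: np.ndarray) -> np.ndarray:
    """Rec.601 luma: 0.299 R + 0.587 G + 0.114 B."""
    rgb = np.asarray(rgb, dtype=float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


@dataclass
class TileFeatureSummary:
    stats: dict[str, dict[str, float]] | None  # None when the tile has no myeloblasts
    n_blasts: int
    n_cells: int


@dataclass
class FeatureExtractionResult:
    features: pd.DataFrame  # patient_id + the 214 named columns
    exclusions: list[dict]


def features_from_label_mask(
    gray: np.ndarray, label_mask: np.ndarray, n_levels: int = 16
) -> list[CellFeatures]:
    """Per-cell base descriptors for every labeled component in a mask."""
    label_mask = np.asarray(label_mask).astype(np.int32)
    out = []
    for lab, sl in enumerate(ndi.find_objects(label_mask), start=1):
        if sl is None:
            continue
        m = label_mask[sl] == lab
        out.append(CellFeatures(values=compute_cell_features(gray[sl], m, n_levels)))
    return out


def extract_tile_features(
    rgb: np.ndarray,
    blast_mask: np.ndarray | None = None,
    wbc_mask: np.ndarray | None = None,
    seg_config: SegmentationConfig | None = None,
    n_levels: int = 16,
) -> TileFeatureSummary:
    """Cross-cell statistics for one tile.

    With ``blast_mask`` given, the mask-ingest path is used (``wbc_mask``
    contributing only to the WBC count); otherwise the classical
    segmenter runs on the tile.
    """
    gray = rgb_to_luma(rgb)
    cells: list[CellFeatures] = []
    if blast_mask is not None:
        cells = features_from_label_mask(gray, blast_mask, n_levels)
        n_blasts = len(cells)
        n_other = int(len(np.unique(wbc_mask)) - 1) if wbc_mask is not None else 0
    else:
        instances = segment_tile(rgb, seg_config)
        n_other = 0
        for inst in instances:
            if inst.cell_class == MYELOBLAST:
                y0, x0 = inst.offset
                h, w = inst.mask.shape
                patch = gray[y0 : y0 + h, x0 : x0 + w]
                cells.append(CellFeatures(values=compute_cell_features(patch, inst.mask, n_levels)))
            else:
                n_other += 1
        n_blasts = len(cells)
    stats = aggregate_tile(cells) if cells else None
    return TileFeatureSummary(stats=stats, n_blasts=n_blasts, n_cells=n_blasts + n_other)


def _load_mask(cohort_or_dir, row, col):
    if isinstance(cohort_or_dir, Cohort):
        tile = cohort_or_dir.tiles[row["tile_path"]]
        return tile.blast_mask if col == "blast_mask_path" else tile.wbc_mask
    return iio.imread(Path(cohort_or_dir) / row[col])


def _load_rgb(cohort_or_dir, row):
    if isinstance(cohort_or_dir, Cohort):
        return cohort_or_dir.tiles[row["tile_path"]].rgb
    return iio.imread(Path(cohort_or_dir) / row["tile_path"])


def extract_cohort_features(
    source: Cohort | str | Path,
    manifest: pd.DataFrame | None = None,
    use_truth_masks: bool = True,
    seg_config: SegmentationConfig | None = None,
    n_levels: int = 16,
) -> FeatureExtractionResult:
    """Patient-level 214-feature table for a whole cohort.

    ``source`` is an in-memory :class:`~cytoprs.simulate.Cohort` or a
    directory holding tiles/masks referenced by ``manifest`` (which
    defaults to the cohort's own manifest).
    """
    if manifest is None:
        if not isinstance(source, Cohort):
            manifest = pd.read_csv(Path(source) / "manifest.csv")
        else:
            manifest = source.manifest

    rows = []
    exclusions: list[dict] = []
    for pid, group in manifest.groupby("patient_id", sort=True):
        tile_stats = []
        n_blasts_total = 0
        n_cells_total = 0
        for _, row in group.iterrows():
            rgb = _load_rgb(source, row)
            if use_truth_masks:
                blast_mask = _load_mask(source, row, "blast_mask_path")
                wbc_mask = _load_mask(source, row, "wbc_mask_path")
                summary = extract_tile_features(rgb, blast_mask, wbc_mask, n_levels=n_levels)
            else:
                summary = extract_tile_features(rgb, seg_config=seg_config, n_levels=n_levels)
            tile_stats.append(summary.stats)
            n_blasts_total += summary.n_blasts
            n_cells_total += summary.n_cells
        try:
            vec = aggregate_patient(tile_stats, n_blasts_total, n_cells_total)
        except ValueError as exc:
            logger.warning("excluding patient %s: %s", pid, exc)
            exclusions.append({"patient_id": pid, "reason": "no_myeloblasts", "detail": str(exc)})
            continue
        rows.append({"patient_id": pid, **vec.as_dict()})

    features = pd.DataFrame(rows, columns=["patient_id", *PATIENT_FEATURE_NAMES])
    return FeatureExtractionResult(features=features, exclusions=exclusions)
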