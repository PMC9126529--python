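"""Cross-cell tile statistics and tile-to-patient averaging.

For each of the 53 base descriptors, four statistics (mean, median,
sample standard deviation, Fisher-Pearson skewness g1) are taken across
the myeloblasts of a tile; patient-level values are the plain mean of
each tile statistic over the patient's non-missing tiles, followed by
two count features (total blast count, blast percentage of all WBCs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cytoprs.features.catalog import (
    BASE_DESCRIPTORS,
    N_PATIENT_FEATURES,
    PATIENT_FEATURE_NAMES,
    TILE_STATISTICS,
)


@dataclass
class CellFeatures:
    """The 53 named base descriptors of one segmented cell."""

    values: dict[str, float]
    cell_class: str = "myeloblast"

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != BASE_DESCRIPTORS:
            raise ValueError("CellFeatures must hold exactly the 53 catalog descriptors in order")


@dataclass
class PatientFeatureVector:
    """Ordered 214-element patient feature vector."""

    values: np.ndarray
    names: tuple[str, ...]
    n_blasts: int
    n_wbc: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != N_PATIENT_FEATURES or self.names != PATIENT_FEATURE_NAMES:
            raise ValueError("patient vector must match the frozen 214-name catalog")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _stat_matrix(mat: np.ndarray) -> np.ndarray:
    """Columns of ``mat`` -> rows (mean, median, sample std, skewness g1).

    std is 0 for n = 1; g1 is 0 for n < 3 or zero second moment.
    """
    n = mat.shape[0]
    means = mat.mean(axis=0)
    medians = np.median(mat, axis=0)
    stds = mat.std(axis=0, ddof=1) if n > 1 else np.zeros(mat.shape[1])
    if n >= 3:
        c = mat - means
        m2 = (c**2).mean(axis=0)
        m3 = (c**3).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            skews = np.where(m2 > 0, m3 / np.maximum(m2, 1e-300) ** 1.5, 0.0)
    else:
        skews = np.zeros(mat.shape[1])
    return np.vstack([means, medians, stds, skews])


def aggregate_tile(cells: list[CellFeatures]) -> dict[str, dict[str, float]]:
    """Per-descriptor cross-cell statistics over a tile's myeloblasts."""
    blasts = [c for c in cells if c.cell_class == "myeloblast"]
    if not blasts:
        raise ValueError("aggregate_tile requires at least one myeloblast")
    mat = np.array([[c.values[d] for d in BASE_DESCRIPTORS] for c in blasts], dtype=float)
    stats = _stat_matrix(mat)
    return {
        desc: dict(zip(TILE_STATISTICS, stats[:, k])) for k, desc in enumerate(BASE_DESCRIPTORS)
    }


def aggregate_patient(
    tile_stats: list[dict[str, dict[str, float]] | None],
    n_blasts: int,
    n_wbc: int,
) -> PatientFeatureVector:
    """Average tile statistics over non-missing tiles and append counts.

    ``None`` entries mark tiles with zero myeloblasts; they are excluded
    from the average. All tiles missing is an error (patient excluded
    upstream with a logged reason).
    """
    present = [t for t in tile_stats if t is not None]
    if not present:
        raise ValueError("all tiles missing: patient has no myeloblasts")
    values = []
    for desc in BASE_DESCRIPTORS:
        for stat in TILE_STATISTICS:
            values.append(float(np.mean([t[desc][stat] for t in present])))
    values.append(float(n_blasts))
    values.append(n_blasts / n_wbc if n_wbc > 0 else np.nan)
    return PatientFeatureVector(
        values=np.asarray(values), names=PATIENT_FEATURE_NAMES, n_blasts=n_blasts, n_wbc=n_wbc
    )
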