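"""Frozen catalog of per-cell base descriptors and the patient-level feature names.

The patient vector is 53 base descriptors x 4 cross-cell tile statistics
(averaged over tiles) plus two count features, for 214 entries total.
Order is fixed; downstream CSV columns and model serialization rely on it.
"""

from __future__ import annotations

HARALICK_NAMES: tuple[str, ...] = (
    "haralick_energy",
    "haralick_contrast",
    "haralick_correlation",
    "haralick_variance",
    "haralick_homogeneity",
    "haralick_sum_average",
    "haralick_sum_variance",
    "haralick_sum_entropy",
    "haralick_entropy",
    "haralick_difference_variance",
    "haralick_difference_entropy",
    "haralick_imc1",
    "haralick_imc2",
)

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "intensity_mean",
    "intensity_variance",
    "intensity_skewness",
    "intensity_kurtosis",
    "intensity_entropy",
    "intensity_energy",
    "intensity_range",
    "intensity_mad",
)

MORPHOMETRY_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "equivalent_diameter",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "solidity",
    "extent",
    "circularity",
)

HU_NAMES: tuple[str, ...] = tuple(f"hu_moment_{k}" for k in range(1, 8))

EFD_NAMES: tuple[str, ...] = tuple(f"efd_harmonic_{k}" for k in range(1, 11))

IRREGULARITY_NAMES: tuple[str, ...] = (
    "fractal_dimension",
    "radial_variance",
    "bending_energy",
    "concavity_density",
    "convex_perimeter_ratio",
)

BASE_DESCRIPTORS: tuple[str, ...] = (
    HARALICK_NAMES
    + FIRST_ORDER_NAMES
    + MORPHOMETRY_NAMES
    + HU_NAMES
    + EFD_NAMES
    + IRREGULARITY_NAMES
)

TILE_STATISTICS: tuple[str, ...] = ("mean", "median", "std", "skewness")

COUNT_FEATURE_NAMES: tuple[str, ...] = ("n_blasts_total", "blast_percentage")

PATIENT_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{desc}__{stat}" for desc in BASE_DESCRIPTORS for stat in TILE_STATISTICS
) + COUNT_FEATURE_NAMES

N_BASE_DESCRIPTORS = len(BASE_DESCRIPTORS)
N_PATIENT_FEATURES = len(PATIENT_FEATURE_NAMES)

assert N_BASE_DESCRIPTORS == 53
assert N_PATIENT_FEATURES == 214
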