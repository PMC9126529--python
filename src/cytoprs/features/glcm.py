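"""Masked gray-level co-occurrence matrices and Haralick descriptors.

The GLCM is accumulated only over pixel pairs that both fall inside the
cell mask, with intensities quantized over the mask's own dynamic range,
so the descriptors are invariant to additive intensity shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cytoprs.features.catalog import HARALICK_NAMES

#: distance-1 offsets at 0, 45, 90 and 135 degrees, as (dy, dx)
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))

_LOG_EPS = 1e-12


@dataclass
class GLCMatrix:
    """Normalized co-occurrence distribution within a cell mask."""

    p: np.ndarray
    n_levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.n_levels, self.n_levels):
            raise ValueError(
                f"GLCM shape {self.p.shape} does not match n_levels={self.n_levels}"
            )


def quantize(gray: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Linearly bin intensities to ``n_levels`` over the masked [min, max] range.

    A constant region maps entirely to level 0.
    """
    gray = np.asarray(gray, dtype=float)
    vals = gray[mask]
    lo = vals.min()
    hi = vals.max()
    if hi <= lo:
        return np.zeros(gray.shape, dtype=np.intp)
    q = ((gray - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def compute_glcm(
    gray: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCMatrix:
    """Compute the masked GLCM pooled over ``offsets`` and normalized to sum 1.

    A pair contributes only when both of its pixels lie inside ``mask``.
    With no valid pair (e.g. a single masked pixel) the result is an
    all-zero matrix flagged degenerate.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or np.asarray(gray).shape != mask.shape:
        raise ValueError("gray and mask must be 2-D arrays of identical shape")
    if not mask.any():
        raise ValueError("empty mask")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")

    q = quantize(gray, mask, n_levels)
    h, w = mask.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for dy, dx in offsets:
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        if y0 >= y1 or x0 >= x1:
            continue
        src = (slice(y0, y1), slice(x0, x1))
        dst = (slice(y0 + dy, y1 + dy), slice(x0 + dx, x1 + dx))
        valid = mask[src] & mask[dst]
        i = q[src][valid]
        j = q[dst][valid]
        counts += np.bincount(i * n_levels + j, minlength=n_levels * n_levels).reshape(
            n_levels, n_levels
        )
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return GLCMatrix(
            np.zeros((n_levels, n_levels)), n_levels, tuple(offsets), symmetric, degenerate=True
        )
    return GLCMatrix(counts / total, n_levels, tuple(offsets), symmetric)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > _LOG_EPS]
    return float(-(p * np.log2(p)).sum())


def haralick_features(glcm: GLCMatrix) -> dict[str, float]:
    """Haralick's 13 texture descriptors from a normalized GLCM.

    All logarithms are base 2 with the 0*log(0) := 0 convention.
    Correlation is defined as 0 when either marginal is degenerate.
    A degenerate GLCM yields an all-zero vector.
    """
    if glcm.degenerate:
        return {name: 0.0 for name in HARALICK_NAMES}
    p = glcm.p
    ng = glcm.n_levels
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("GLCM is not normalized")

    levels = np.arange(ng, dtype=float)
    i = levels[:, None]
    j = levels[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    var_x = float(((levels - mu_x) ** 2) @ px)
    var_y = float(((levels - mu_y) ** 2) @ py)

    energy = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    cov = float((i * j * p).sum()) - mu_x * mu_y
    sd = np.sqrt(var_x * var_y)
    correlation = float(cov / sd) if sd > 0 else 0.0
    variance = float(((i - mu_x) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())

    # p_{x+y}(k), k = 0..2(Ng-1); p_{x-y}(k), k = 0..Ng-1
    ksum = np.arange(2 * ng - 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    kdiff = np.arange(ng, dtype=float)
    p_diff = np.zeros(ng)
    idx_sum = (i + j).astype(int)
    idx_diff = np.abs(i - j).astype(int)
    np.add.at(p_sum, idx_sum.ravel(), p.ravel())
    np.add.at(p_diff, idx_diff.ravel(), p.ravel())

    sum_average = float(ksum @ p_sum)
    sum_variance = float(((ksum - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy_bits(p_sum)
    entropy = _entropy_bits(p.ravel())
    diff_mean = float(kdiff @ p_diff)
    difference_variance = float(((kdiff - diff_mean) ** 2) @ p_diff)
    difference_entropy = _entropy_bits(p_diff)

    # information measures of correlation
    pxy = px[:, None] * py[None, :]
    nz = (p > _LOG_EPS) | (pxy > _LOG_EPS)
    log_pxy = np.where(pxy > _LOG_EPS, np.log2(np.maximum(pxy, _LOG_EPS)), 0.0)
    hxy1 = float(-(p * log_pxy)[nz].sum())
    hxy2 = float(-(pxy * log_pxy)[nz].sum())
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    values = (
        energy,
        contrast,
        correlation,
        variance,
        homogeneity,
        sum_average,
        sum_variance,
        sum_entropy,
        entropy,
        difference_variance,
        difference_entropy,
        imc1,
        imc2,
    )
    return dict(zip(HARALICK_NAMES, values))
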