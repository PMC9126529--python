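"""First-order intensity statistics and nuclear shape descriptors.

Shape descriptors are computed on the binary nucleus mask: 10 classical
morphometrics, 7 Hu invariant moments (signed log-magnitude), 10 elliptic
Fourier harmonic magnitudes (scale-normalized by harmonic 1), and 5
boundary-irregularity measures.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from cytoprs.features.catalog import (
    BASE_DESCRIPTORS,
    EFD_NAMES,
    FIRST_ORDER_NAMES,
    HU_NAMES,
    IRREGULARITY_NAMES,
    MORPHOMETRY_NAMES,
)
from cytoprs.features.glcm import compute_glcm, haralick_features

_N_HISTOGRAM_BINS = 16
_N_RESAMPLED_CONTOUR = 128


def first_order_features(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Eight intensity-distribution statistics over the masked pixels.

    Variance/skewness/kurtosis are population moments; kurtosis is excess;
    entropy/energy use a 16-bin histogram over the masked intensity range
    (a constant region has entropy 0 and energy 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(gray, dtype=float)[mask]
    mean = float(vals.mean())
    centered = vals - mean
    m2 = float((centered**2).mean())
    if m2 > 0:
        m3 = float((centered**3).mean())
        m4 = float((centered**4).mean())
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2 - 3.0
    else:
        skewness = 0.0
        kurtosis = 0.0
    lo = float(vals.min())
    rng = float(vals.max()) - lo
    if rng > 0:
        idx = np.minimum(
            ((vals - lo) * (_N_HISTOGRAM_BINS / rng)).astype(np.intp), _N_HISTOGRAM_BINS - 1
        )
        hist = np.bincount(idx, minlength=_N_HISTOGRAM_BINS)
        p = hist / hist.sum()
        p_nz = p[p > 0]
        entropy = float(-(p_nz * np.log2(p_nz)).sum())
        energy = float((p**2).sum())
    else:
        entropy = 0.0
        energy = 1.0
    mad = float(np.median(np.abs(vals - np.median(vals))))
    values = (mean, m2, skewness, kurtosis, entropy, energy, rng, mad)
    return dict(zip(FIRST_ORDER_NAMES, values))


def _closed_contour(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of the padded mask, last point dropped."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("shape_features: no contour found (degenerate mask)")
    contour = max(contours, key=len)
    contour = contour[:-1] - 1.0  # drop duplicate endpoint, undo padding
    if len(contour) < 8:
        raise ValueError("shape_features: contour shorter than 8 points (degenerate mask)")
    return contour


def _resample_contour(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed contour to ``n`` points equally spaced in arc length."""
    closed = np.vstack([contour, contour[:1]])
    seg = np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1))
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise ValueError("shape_features: zero-length contour")
    ti = np.linspace(0.0, total, n, endpoint=False)
    y = np.interp(ti, t, closed[:, 0])
    x = np.interp(ti, t, closed[:, 1])
    return np.column_stack([y, x])


def _efd_magnitudes(contour: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Elliptic Fourier descriptor magnitudes (Kuhl-Giardina), harmonics 1..n."""
    closed = np.vstack([contour, contour[:1]])
    d = np.diff(closed, axis=0)
    dy, dx = d[:, 0], d[:, 1]
    dt = np.sqrt(dx**2 + dy**2)
    keep = dt > 0
    dx, dy, dt = dx[keep], dy[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    big_t = t[-1]
    phi = 2.0 * np.pi * t / big_t
    n = np.arange(1, n_harmonics + 1)[:, None]
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = big_t / (2.0 * n.ravel() ** 2 * np.pi**2)
    a = const * (cos_d @ (dx / dt))
    b = const * (sin_d @ (dx / dt))
    c = const * (cos_d @ (dy / dt))
    e = const * (sin_d @ (dy / dt))
    return np.sqrt(a**2 + b**2 + c**2 + e**2)


def _box_counting_dimension(points: np.ndarray, extent: int) -> float:
    """Box-counting fractal dimension of a boundary point set."""
    max_size = max(2, extent // 2)
    sizes = []
    s = 1
    while s <= max_size:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        sizes = [1, 2]
    counts = []
    shifted = points - points.min(axis=0)
    span = int(shifted.max()) + 2
    for size in sizes:
        boxes = np.floor(shifted / size).astype(np.int64)
        counts.append(len(np.unique(boxes[:, 0] * span + boxes[:, 1])))
    log_inv = -np.log(np.asarray(sizes, dtype=float))
    log_cnt = np.log(np.asarray(counts, dtype=float))
    # least-squares slope of log(count) vs log(1/size)
    x = log_inv - log_inv.mean()
    slope = float((x @ (log_cnt - log_cnt.mean())) / (x @ x))
    return slope


def _central_moments(mask: np.ndarray):
    """Central moments mu_pq (p+q <= 3) of a binary mask and its centroid."""
    ys, xs = np.nonzero(mask)
    n = float(len(ys))
    cy, cx = ys.mean(), xs.mean()
    dy = ys - cy
    dx = xs - cx
    dy2, dx2 = dy * dy, dx * dx
    mu = {
        (0, 0): n,
        (2, 0): float(dy2.sum()),
        (0, 2): float(dx2.sum()),
        (1, 1): float((dy * dx).sum()),
        (3, 0): float((dy2 * dy).sum()),
        (0, 3): float((dx2 * dx).sum()),
        (2, 1): float((dy2 * dx).sum()),
        (1, 2): float((dy * dx2).sum()),
    }
    return mu, (float(cy), float(cx))


def _hu_moments(mu: dict) -> np.ndarray:
    n00 = mu[(0, 0)]
    eta = {pq: m / n00 ** (1.0 + (pq[0] + pq[1]) / 2.0) for pq, m in mu.items() if pq != (0, 0)}
    e20, e02, e11 = eta[(2, 0)], eta[(0, 2)], eta[(1, 1)]
    e30, e03, e21, e12 = eta[(3, 0)], eta[(0, 3)], eta[(2, 1)], eta[(1, 2)]
    a = e30 + e12
    b = e21 + e03
    c = e30 - 3 * e12
    d = 3 * e21 - e03
    return np.array(
        [
            e20 + e02,
            (e20 - e02) ** 2 + 4 * e11**2,
            c**2 + d**2,
            a**2 + b**2,
            c * a * (a**2 - 3 * b**2) + d * b * (3 * a**2 - b**2),
            (e20 - e02) * (a**2 - b**2) + 4 * e11 * a * b,
            d * a * (a**2 - 3 * b**2) - c * b * (3 * a**2 - b**2),
        ]
    )


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """32 shape descriptors of a single-component binary mask."""
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area < 4:
        raise ValueError("shape_features: mask too small (area)")

    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    if perimeter <= 0:
        raise ValueError("shape_features: zero perimeter (degenerate mask)")
    mu, centroid = _central_moments(mask)
    # covariance eigenvalues of the pixel cloud -> ellipse axes
    a_c = mu[(2, 0)] / area
    c_c = mu[(0, 2)] / area
    b_c = mu[(1, 1)] / area
    disc = np.sqrt(max((a_c - c_c) ** 2 + 4 * b_c**2, 0.0))
    lam1 = (a_c + c_c + disc) / 2.0
    lam2 = (a_c + c_c - disc) / 2.0
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    if minor <= 0:
        raise ValueError("shape_features: zero minor axis (line-like mask)")
    eccentricity = np.sqrt(max(1.0 - lam2 / lam1, 0.0)) if lam1 > 0 else 0.0

    contour = _closed_contour(mask)
    hull = ConvexHull(contour[:, ::-1])
    hull_area = float(hull.volume)
    convex_perimeter = float(hull.area)  # 2-D hull "area" attribute is the perimeter

    morpho = dict(
        zip(
            MORPHOMETRY_NAMES,
            (
                area,
                perimeter,
                float(np.sqrt(4.0 * area / np.pi)),
                float(eccentricity),
                major,
                minor,
                major / minor,
                area / hull_area if hull_area > 0 else 0.0,
                area / mask.size,
                4.0 * np.pi * area / perimeter**2,
            ),
        )
    )

    hu_raw = _hu_moments(mu)
    hu = dict(zip(HU_NAMES, (float(np.sign(v) * np.log10(abs(v) + 1e-30)) for v in hu_raw)))

    mags = _efd_magnitudes(contour, n_harmonics=10)
    if mags[0] <= 0:
        raise ValueError("shape_features: degenerate first Fourier harmonic")
    efd = dict(zip(EFD_NAMES, (mags / mags[0]).astype(float)))

    # irregularity measures on the resampled boundary; a circular moving
    # average suppresses pixel-scale stair-step noise before curvature
    rs = _resample_contour(contour, _N_RESAMPLED_CONTOUR)
    kernel = np.ones(7) / 7.0
    rs = np.column_stack(
        [
            np.convolve(np.concatenate([rs[-3:, k], rs[:, k], rs[:3, k]]), kernel, mode="valid")
            for k in (0, 1)
        ]
    )
    radii = np.sqrt(((rs - np.asarray(centroid)) ** 2).sum(axis=1))
    mean_r = radii.mean()
    radial_variance = float(radii.var() / mean_r**2) if mean_r > 0 else 0.0

    d1 = (np.roll(rs, -1, axis=0) - np.roll(rs, 1, axis=0)) / 2.0
    d2 = np.roll(rs, -1, axis=0) - 2.0 * rs + np.roll(rs, 1, axis=0)
    speed_sq = (d1**2).sum(axis=1)
    cross = d1[:, 1] * d2[:, 0] - d1[:, 0] * d2[:, 1]
    ok = speed_sq > 1e-12
    curvature = np.zeros(len(rs))
    curvature[ok] = cross[ok] / speed_sq[ok] ** 1.5
    bending_energy = float((curvature**2).mean())

    orient = np.sign(np.sum(cross)) or 1.0
    concave = (np.sign(cross) == -orient) & (np.abs(cross) > 1e-9)
    # merge runs of consecutive concave vertices into single concavities
    n_concavities = int(np.sum(concave & ~np.roll(concave, 1)))
    concavity_density = n_concavities / perimeter

    fractal = _box_counting_dimension(contour, int(max(mask.shape)))

    irregular = dict(
        zip(
            IRREGULARITY_NAMES,
            (
                fractal,
                radial_variance,
                bending_energy,
                float(concavity_density),
                convex_perimeter / perimeter,
            ),
        )
    )
    return {**morpho, **hu, **efd, **irregular}


def compute_cell_features(
    gray: np.ndarray, mask: np.ndarray, n_levels: int = 16
) -> dict[str, float]:
    """All 53 base descriptors for one cell, in frozen catalog order."""
    glcm = compute_glcm(gray, mask, n_levels=n_levels)
    values = {}
    values.update(haralick_features(glcm))
    values.update(first_order_features(gray, mask))
    values.update(shape_features(mask))
    return {name: values[name] for name in BASE_DESCRIPTORS}
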