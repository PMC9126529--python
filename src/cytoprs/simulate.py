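"""Synthetic Wright-Giemsa-like aspirate tiles with ground truth and survival.

Each patient carries a latent chromatin-heterogeneity value ``h`` drawn
uniformly on a configurable range. ``h`` drives two things:

* rendering — myeloblast nuclei carry a chromatin texture built from a
  smoothed Gaussian coarse field (kernel width drawn per cell from a
  right-skewed gamma law whose skew shrinks as ``h`` grows, moving the
  across-cell skewness of GLCM correlation) plus a sparse "clump"
  impulse process whose per-cell power is drawn with between-cell
  variance proportional to ``h`` (so the across-cell variance of GLCM
  contrast grows with ``h``), plus fine grain, hard-saturated so the
  per-cell intensity range — and hence the GLCM quantization grid — is
  stable;
* outcome — relapse-free survival time is exponential with rate
  ``baseline_hazard * exp(beta_texture * h)``, censored uniformly on
  ``(0, censor_horizon)``.

Tiles carry exact per-cell label masks, so the segmentation stage can be
bypassed (truth-mask ingest) or evaluated per pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

BACKGROUND_RGB = (236, 210, 218)
RBC_RGB = (230, 156, 162)
WBC_NUCLEUS_RGB = (88, 48, 118)
BLAST_NUCLEUS_RGB = (128, 84, 160)

# texture model constants (see module docstring)
# Chromatin texture = smooth coarse field (peak-to-peak normalized, random
# smoothing width) + sparse high-magnitude "clump" impulses + small Gaussian
# grain, hard-saturated at +/- _SATURATION (stain saturation). Saturation
# pins the per-cell intensity range, so GLCM quantization bins are stable
# and contrast reads the impulse density almost linearly. The between-cell
# spread of the impulse density grows with h, which is what links h to the
# variance of contrast across cells.
_COARSE_PEAK_TO_PEAK = 48.0
_SATURATION = 34.0
_IMPULSE_MAGNITUDE_RANGE = (16.0, 26.0)
# (blur sigma, measured squared-difference attenuation) pairs
_IMPULSE_BLUR_CHOICES = ((0.0, 1.0), (0.35, 0.86), (0.42, 0.60))
_IMPULSE_POWER_BASE = 90.0  # density * magnitude^2 at the reference point
_IMPULSE_SIGMA_MIN = 0.04
_IMPULSE_SIGMA_SLOPE = 0.50
_IMPULSE_DENSITY_BOUNDS = (0.01, 0.45)
_GRAIN_AMPLITUDE = 7.0
_CLIP_SIGMAS = 2.0
_WIDTH_SHAPE_MIN = 2.0
_WIDTH_SHAPE_SLOPE = 10.0
_WIDTH_MEAN = 1.5
_WIDTH_FLOOR = 2.5


class PlacementError(RuntimeError):
    """Raised when requested cells cannot be placed without overlap."""


@dataclass(frozen=True)
class SimulationParams:
    n_patients: int
    tiles_per_patient: int = 6
    tile_px: int = 512
    blasts_per_tile_range: tuple[int, int] = (6, 12)
    other_wbc_per_tile_range: tuple[int, int] = (4, 8)
    rbc_per_tile_range: tuple[int, int] = (12, 20)
    blast_radius_range: tuple[float, float] = (11.0, 15.0)
    wbc_radius_range: tuple[float, float] = (4.0, 6.5)
    rbc_radius_range: tuple[float, float] = (6.0, 9.0)
    beta_texture: float = 1.0
    baseline_hazard: float = 1.0 / 400.0
    censor_horizon: float = 1500.0
    heterogeneity_range: tuple[float, float] = (-1.0, 1.0)
    train_frac: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.tiles_per_patient < 1:
            raise ValueError("tiles_per_patient must be >= 1")
        if self.tile_px < 64:
            raise ValueError("tile_px must be >= 64")
        if self.blasts_per_tile_range[0] < 2:
            raise ValueError("blasts_per_tile_range lower bound must be >= 2")
        if self.censor_horizon <= 0 or self.baseline_hazard <= 0:
            raise ValueError("censor_horizon and baseline_hazard must be positive")
        lo, hi = self.heterogeneity_range
        if hi < lo:
            raise ValueError("heterogeneity_range must be non-decreasing")
        if hi == lo:
            warnings.warn("degenerate heterogeneity_range (zero width)", stacklevel=2)


def small_cohort_params(
    n_patients: int, seed: int, beta_texture: float = 1.0, **overrides
) -> SimulationParams:
    """Desk-scale parameters for simulation-heavy model tests.

    Smaller tiles, two tiles per patient and lighter backgrounds keep
    20-seed recovery studies within a CPU-minute budget while preserving
    the texture-hazard link.
    """
    base = SimulationParams(
        n_patients=n_patients,
        tiles_per_patient=2,
        tile_px=160,
        blasts_per_tile_range=(6, 9),
        other_wbc_per_tile_range=(3, 5),
        rbc_per_tile_range=(2, 4),
        beta_texture=beta_texture,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


@dataclass
class PatientTruth:
    patient_id: str
    h: float
    rfs_days: float
    event: int
    relapse_1yr: int
    true_event_time: float
    n_blasts_total: int
    n_wbc_total: int
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticTile:
    rgb: np.ndarray
    blast_mask: np.ndarray
    wbc_mask: np.ndarray


@dataclass
class Cohort:
    """Simulated cohort: tile-level manifest, hidden truth and tile pixels."""

    manifest: pd.DataFrame
    truths: list[PatientTruth]
    tiles: dict[str, SyntheticTile]
    params: SimulationParams

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [t.patient_id for t in self.truths],
                "h": [t.h for t in self.truths],
                "true_event_time": [t.true_event_time for t in self.truths],
            }
        )


def _h_norm(h: float, rng_range: tuple[float, float]) -> float:
    lo, hi = rng_range
    if hi == lo:
        return 0.5
    return float(np.clip((h - lo) / (hi - lo), 0.0, 1.0))


def _place_cells(
    rng: np.random.Generator,
    occupied: list[tuple[float, float, float]],
    count: int,
    radius_range: tuple[float, float],
    tile_px: int,
    spacing: float = 3.0,
    max_attempts_per_cell: int = 400,
    required: bool = True,
) -> list[tuple[float, float, float]]:
    placed = []
    for _ in range(count):
        r = rng.uniform(*radius_range)
        margin = r + 2.0
        ok = False
        for _attempt in range(max_attempts_per_cell):
            cy = rng.uniform(margin, tile_px - margin)
            cx = rng.uniform(margin, tile_px - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + spacing) ** 2 for y, x, rr in occupied):
                ok = True
                break
        if not ok:
            if required:
                raise PlacementError(
                    f"could not place {count} cells of radius ~{r:.0f} in a {tile_px}px tile"
                )
            continue
        occupied.append((cy, cx, r))
        placed.append((cy, cx, r))
    return placed


def _disc_mask(cy: float, cx: float, r: float, shape: tuple[int, int]) -> tuple[slice, slice, np.ndarray]:
    y0 = max(0, int(np.floor(cy - r - 1)))
    y1 = min(shape[0], int(np.ceil(cy + r + 2)))
    x0 = max(0, int(np.floor(cx - r - 1)))
    x1 = min(shape[1], int(np.ceil(cx + r + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return slice(y0, y1), slice(x0, x1), m


def _paint(rgb: np.ndarray, sl: tuple[slice, slice], m: np.ndarray, color) -> None:
    region = rgb[sl[0], sl[1]]
    region[m] = color


def render_tile(params: SimulationParams, h: float, rng: np.random.Generator) -> SyntheticTile:
    """Render one tile plus exact blast/WBC label masks for heterogeneity ``h``."""
    lo, hi = params.heterogeneity_range
    if not (min(lo, hi) - 1e-9 <= h <= max(lo, hi) + 1e-9):
        raise ValueError(f"h={h} outside heterogeneity_range {params.heterogeneity_range}")
    n = params.tile_px
    hn = _h_norm(h, params.heterogeneity_range)
    shape = (n, n)

    rgb = np.empty((n, n, 3), dtype=float)
    rgb[:] = BACKGROUND_RGB
    rgb += rng.normal(0.0, 2.0, size=rgb.shape)

    blast_mask = np.zeros(shape, dtype=np.uint16)
    wbc_mask = np.zeros(shape, dtype=np.uint16)

    n_blasts = int(rng.integers(params.blasts_per_tile_range[0], params.blasts_per_tile_range[1] + 1))
    n_wbc = int(
        rng.integers(params.other_wbc_per_tile_range[0], params.other_wbc_per_tile_range[1] + 1)
    )
    n_rbc = int(rng.integers(params.rbc_per_tile_range[0], params.rbc_per_tile_range[1] + 1))

    occupied: list[tuple[float, float, float]] = []
    blast_pos = _place_cells(rng, occupied, n_blasts, params.blast_radius_range, n)
    wbc_pos = _place_cells(rng, occupied, n_wbc, params.wbc_radius_range, n, spacing=6.0)
    rbc_pos = _place_cells(rng, occupied, n_rbc, params.rbc_radius_range, n, required=False)

    # decorative RBC ellipses
    for cy, cx, r in rbc_pos:
        theta = rng.uniform(0, np.pi)
        b_ax = r * rng.uniform(0.65, 0.9)
        sl_y, sl_x, box = _disc_mask(cy, cx, r, shape)
        yy, xx = np.mgrid[sl_y, sl_x]
        u = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
        v = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        ell = (u / r) ** 2 + (v / b_ax) ** 2 <= 1.0
        _paint(rgb, (sl_y, sl_x), ell, RBC_RGB)

    # other WBCs: small lobed nuclei (union of overlapping discs)
    for k, (cy, cx, r) in enumerate(wbc_pos, start=1):
        n_lobes = int(rng.integers(2, 4))
        sl_y, sl_x, _ = _disc_mask(cy, cx, r * 1.8, shape)
        footprint = np.zeros((sl_y.stop - sl_y.start, sl_x.stop - sl_x.start), dtype=bool)
        for _lobe in range(n_lobes):
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0.2, 0.55) * r
            ly, lx = cy + off * np.sin(ang), cx + off * np.cos(ang)
            lr = r * rng.uniform(0.55, 0.8)
            ys, xs, m = _disc_mask(ly, lx, lr, shape)
            footprint[ys.start - sl_y.start : ys.stop - sl_y.start,
                      xs.start - sl_x.start : xs.stop - sl_x.start] |= m
        _paint(rgb, (sl_y, sl_x), footprint, WBC_NUCLEUS_RGB)
        noise = rng.normal(0.0, 4.0, size=footprint.shape)
        for c in range(3):
            rgb[sl_y, sl_x, c][footprint] += noise[footprint]
        wbc_mask[sl_y, sl_x][footprint] = k

    # myeloblasts: large round nuclei with h-linked chromatin texture
    sigma_imp = _IMPULSE_SIGMA_MIN + _IMPULSE_SIGMA_SLOPE * hn
    width_shape = _WIDTH_SHAPE_MIN + _WIDTH_SHAPE_SLOPE * hn
    for k, (cy, cx, r) in enumerate(blast_pos, start=1):
        sl_y, sl_x, m = _disc_mask(cy, cx, r, shape)
        _paint(rgb, (sl_y, sl_x), m, BLAST_NUCLEUS_RGB)
        # impulse power (density * mean squared magnitude): symmetric bounded
        # law with h-scaled between-cell spread. Magnitude level and the
        # big/small split are per-cell nuisance draws that reshape the
        # difference histogram without moving its power (contrast channel).
        z_amp = float(np.clip(rng.standard_normal(), -_CLIP_SIGMAS, _CLIP_SIGMAS))
        power = _IMPULSE_POWER_BASE * (1.0 + sigma_imp * z_amp)
        magnitude = float(rng.uniform(*_IMPULSE_MAGNITUDE_RANGE))
        nu = float(rng.uniform(0.2, 0.8))  # fraction of full-magnitude impulses
        mean_sq = magnitude**2 * (nu + (1.0 - nu) / 2.0)
        density = float(np.clip(power / mean_sq, *_IMPULSE_DENSITY_BOUNDS))
        width = _WIDTH_FLOOR + float(rng.gamma(width_shape, _WIDTH_MEAN / width_shape))
        coarse = gaussian_filter(rng.standard_normal(m.shape), width)
        pk = coarse[m].max() - coarse[m].min()
        if pk > 0:
            coarse = (coarse - coarse[m].min()) / pk - 0.5
        mag_field = np.where(rng.random(m.shape) < nu, magnitude, magnitude / np.sqrt(2.0))
        impulses = np.where(
            rng.random(m.shape) < density,
            mag_field * np.where(rng.random(m.shape) < 0.5, 1.0, -1.0),
            0.0,
        )
        # per-cell clump sharpness: optional sub-pixel blur of the impulses,
        # rescaled so the expected squared neighbor difference is unchanged;
        # reshapes the difference histogram without moving the contrast channel
        s_blur, alpha = _IMPULSE_BLUR_CHOICES[rng.integers(0, len(_IMPULSE_BLUR_CHOICES))]
        if s_blur > 0:
            impulses = gaussian_filter(impulses, s_blur) / np.sqrt(alpha)
        # grain: per-cell mixture of pixel-scale, 2x2- and 3x3-block noise.
        # Each blocked component is scaled so the expected squared neighbor
        # difference (the GLCM-contrast channel) is mix-invariant, while the
        # small-absolute-difference distribution is reshaped; this perturbs
        # absolute-difference statistics without touching contrast.
        w1, w2, w3 = rng.dirichlet((0.4, 0.4, 0.4))
        grain = np.zeros(m.shape)
        for w_c, block in ((w1, 1), (w2, 2), (w3, 3)):
            sub = (
                (m.shape[0] + block - 1) // block,
                (m.shape[1] + block - 1) // block,
            )
            g = np.clip(rng.standard_normal(sub), -_CLIP_SIGMAS, _CLIP_SIGMAS)
            g = np.repeat(np.repeat(g, block, axis=0), block, axis=1)
            grain += np.sqrt(w_c * block) * g[: m.shape[0], : m.shape[1]]
        grain *= _GRAIN_AMPLITUDE
        texture = np.clip(
            _COARSE_PEAK_TO_PEAK * coarse + impulses + grain, -_SATURATION, _SATURATION
        )
        for c in range(3):
            rgb[sl_y, sl_x, c][m] += texture[m]
        blast_mask[sl_y, sl_x][m] = k

    return SyntheticTile(
        rgb=np.clip(rgb, 0, 255).astype(np.uint8), blast_mask=blast_mask, wbc_mask=wbc_mask
    )


def _draw_covariates(rng: np.random.Generator) -> dict[str, float]:
    age = float(rng.normal(55.0, 10.0))
    while not (18.0 <= age <= 80.0):
        age = float(rng.normal(55.0, 10.0))
    return {
        "age": round(age, 1),
        "sex": int(rng.integers(0, 2)),
        "comorbidity_index": int(rng.poisson(2.0)),
    }


def simulate_cohort(params: SimulationParams, out_dir: str | Path | None = None) -> Cohort:
    """Simulate patients, render their tiles and build the manifest.

    With ``out_dir`` set, tiles/masks are written as PNG (8-bit RGB tiles,
    16-bit label masks) together with ``manifest.csv`` and the simulation-only
    ``truth.csv``; otherwise everything stays in memory.
    """
    rng = np.random.default_rng(params.seed)
    patient_rngs = rng.spawn(params.n_patients)
    split_rng = rng.spawn(1)[0]

    ids = [f"P{k:04d}" for k in range(1, params.n_patients + 1)]
    order = split_rng.permutation(params.n_patients)
    n_train = int(round(params.train_frac * params.n_patients))
    split = np.array(["val"] * params.n_patients, dtype=object)
    split[order[:n_train]] = "train"

    lo, hi = params.heterogeneity_range
    truths: list[PatientTruth] = []
    tiles: dict[str, SyntheticTile] = {}
    rows = []

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "tiles").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    for idx, (pid, prng) in enumerate(zip(ids, patient_rngs)):
        h = float(prng.uniform(lo, hi)) if hi > lo else float(lo)
        rate = params.baseline_hazard * np.exp(params.beta_texture * h)
        t_event = float(prng.exponential(1.0 / rate))
        t_cens = float(prng.uniform(0.0, params.censor_horizon))
        rfs = max(min(t_event, t_cens), 1e-3)
        event = int(t_event <= t_cens)
        relapse = int(event == 1 and t_event <= 365.0)
        cov = _draw_covariates(prng)

        n_blasts_total = 0
        n_wbc_total = 0
        patient_tiles = []
        for t in range(params.tiles_per_patient):
            tile = render_tile(params, h, prng)
            tile_id = f"{pid}_t{t}"
            nb = int(tile.blast_mask.max())
            nw = int(tile.wbc_mask.max())
            n_blasts_total += nb
            n_wbc_total += nb + nw
            patient_tiles.append((tile_id, tile))

        truths.append(
            PatientTruth(
                patient_id=pid,
                h=h,
                rfs_days=rfs,
                event=event,
                relapse_1yr=relapse,
                true_event_time=t_event,
                n_blasts_total=n_blasts_total,
                n_wbc_total=n_wbc_total,
                covariates=cov,
            )
        )

        for tile_id, tile in patient_tiles:
            if out_dir is not None:
                tile_path = str(Path("tiles") / f"{tile_id}.png")
                blast_path = str(Path("masks") / f"{tile_id}_blast.png")
                wbc_path = str(Path("masks") / f"{tile_id}_wbc.png")
                iio.imwrite(out_dir / tile_path, tile.rgb)
                iio.imwrite(out_dir / blast_path, tile.blast_mask)
                iio.imwrite(out_dir / wbc_path, tile.wbc_mask)
            else:
                tile_path = tile_id
                blast_path = f"{tile_id}_blast"
                wbc_path = f"{tile_id}_wbc"
                tiles[tile_id] = tile
            rows.append(
                {
                    "patient_id": pid,
                    "split": split[idx],
                    "tile_path": tile_path,
                    "blast_mask_path": blast_path,
                    "wbc_mask_path": wbc_path,
                    "rfs_days": rfs,
                    "event": event,
                    "relapse_1yr": relapse,
                    **cov,
                }
            )

    manifest = pd.DataFrame(rows)
    cohort = Cohort(manifest=manifest, truths=truths, tiles=tiles, params=params)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        cohort.truth_frame().to_csv(out_dir / "truth.csv", index=False)
    return cohort


def load_tile(cohort_or_dir: Cohort | str | Path, tile_path: str) -> np.ndarray:
    """Fetch a tile's RGB pixels from an in-memory cohort or an output directory."""
    if isinstance(cohort_or_dir, Cohort):
        return cohort_or_dir.tiles[tile_path].rgb
    return iio.imread(Path(cohort_or_dir) / tile_path)
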