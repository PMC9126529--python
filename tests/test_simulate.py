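"""Synthetic cohort generator: determinism, geometry, mask and survival laws."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, spearmanr

from cytoprs.features.extract import extract_tile_features
from cytoprs.simulate import (
    PlacementError,
    SimulationParams,
    render_tile,
    simulate_cohort,
    small_cohort_params,
)


class TestParams:
    def test_rejects_single_patient(self):
        with pytest.raises(ValueError, match="n_patients"):
            SimulationParams(n_patients=1)

    def test_rejects_tiny_tile(self):
        with pytest.raises(ValueError, match="tile_px"):
            SimulationParams(n_patients=4, tile_px=32)

    def test_rejects_single_blast_lower_bound(self):
        with pytest.raises(ValueError, match="blasts_per_tile_range"):
            SimulationParams(n_patients=4, blasts_per_tile_range=(1, 4))

    def test_degenerate_heterogeneity_range_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            SimulationParams(n_patients=4, heterogeneity_range=(0.3, 0.3))


class TestRenderTile:
    def test_blast_count_forced_by_params(self, tiny_params):
        from dataclasses import replace

        params = replace(tiny_params, blasts_per_tile_range=(2, 2))
        tile = render_tile(params, 0.0, np.random.default_rng(1))
        assert tile.blast_mask.max() == 2

    def test_determinism_bit_identical(self, tiny_params):
        a = render_tile(tiny_params, 0.2, np.random.default_rng(11))
        b = render_tile(tiny_params, 0.2, np.random.default_rng(11))
        np.testing.assert_array_equal(a.rgb, b.rgb)
        np.testing.assert_array_equal(a.blast_mask, b.blast_mask)
        np.testing.assert_array_equal(a.wbc_mask, b.wbc_mask)

    def test_masks_disjoint_and_in_bounds(self, rendered_tile):
        overlap = (rendered_tile.blast_mask > 0) & (rendered_tile.wbc_mask > 0)
        assert not overlap.any()
        assert rendered_tile.blast_mask.shape == rendered_tile.rgb.shape[:2]

    def test_each_label_single_connected_component(self, rendered_tile):
        from scipy import ndimage as ndi

        for mask in (rendered_tile.blast_mask, rendered_tile.wbc_mask):
            for lab in range(1, int(mask.max()) + 1):
                _, n = ndi.label(mask == lab, structure=np.ones((3, 3)))
                assert n == 1

    def test_h_outside_range_rejected(self, tiny_params):
        with pytest.raises(ValueError, match="heterogeneity_range"):
            render_tile(tiny_params, 5.0, np.random.default_rng(0))

    def test_placement_error_when_overcrowded(self):
        params = SimulationParams(
            n_patients=2,
            tile_px=64,
            blasts_per_tile_range=(30, 30),
            blast_radius_range=(10.0, 12.0),
        )
        with pytest.raises(PlacementError):
            render_tile(params, 0.0, np.random.default_rng(0))

    def test_contrast_variance_increases_with_h(self, tiny_params):
        """Across-cell variance of GLCM contrast rises monotonically in h."""
        rng = np.random.default_rng(42)
        hs = np.linspace(-1.0, 1.0, 5)
        all_h, all_v = [], []
        for h in hs:
            for _ in range(20):
                tile = render_tile(tiny_params, float(h), rng)
                s = extract_tile_features(tile.rgb, tile.blast_mask, tile.wbc_mask)
                all_h.append(h)
                all_v.append(s.stats["haralick_contrast"]["std"] ** 2)
        all_h, all_v = np.asarray(all_h), np.asarray(all_v)
        means = [all_v[all_h == h].mean() for h in hs]
        assert means[-1] > means[0]
        rho = spearmanr(hs, means).statistic
        assert rho > 0.8


class TestSimulateCohort:
    def test_manifest_tile_count(self):
        params = small_cohort_params(5, seed=2)
        cohort = simulate_cohort(params)
        assert len(cohort.manifest) == 5 * params.tiles_per_patient

    def test_determinism_manifest_and_pixels(self):
        params = small_cohort_params(4, seed=8)
        a = simulate_cohort(params)
        b = simulate_cohort(params)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for key in a.tiles:
            np.testing.assert_array_equal(a.tiles[key].rgb, b.tiles[key].rgb)

    def test_truth_invariants(self):
        cohort = simulate_cohort(small_cohort_params(30, seed=5))
        for t in cohort.truths:
            assert t.rfs_days > 0
            assert t.event in (0, 1)
            if t.relapse_1yr:
                assert t.event == 1 and t.rfs_days <= 365
            assert t.n_blasts_total <= t.n_wbc_total

    def test_round_trip_to_disk(self, tmp_path):
        params = small_cohort_params(3, seed=4)
        cohort = simulate_cohort(params, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "truth.csv").exists()
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert len(manifest) == len(cohort.manifest)
        import imageio.v3 as iio

        row = manifest.iloc[0]
        rgb = iio.imread(tmp_path / row["tile_path"])
        assert rgb.dtype == np.uint8 and rgb.ndim == 3
        mask = iio.imread(tmp_path / row["blast_mask_path"])
        assert mask.dtype == np.uint16

    def test_null_beta_no_association(self):
        """beta_texture = 0: Kendall tau between h and event is ~0."""
        params = small_cohort_params(500, seed=6, beta_texture=0.0, tiles_per_patient=1,
                                     blasts_per_tile_range=(2, 3), other_wbc_per_tile_range=(0, 1),
                                     rbc_per_tile_range=(0, 1))
        cohort = simulate_cohort(params)
        h = [t.h for t in cohort.truths]
        ev = [t.event for t in cohort.truths]
        tau = kendalltau(h, ev).statistic
        assert abs(tau) < 0.1

    def test_event_fraction_under_defaults(self):
        """Default hazard law yields a mixed censored/observed cohort."""
        rng = np.random.default_rng(123)
        params = SimulationParams(n_patients=2)  # defaults for the hazard law
        lo, hi = params.heterogeneity_range
        h = rng.uniform(lo, hi, 300)
        t_event = rng.exponential(1.0 / (params.baseline_hazard * np.exp(params.beta_texture * h)))
        censor = rng.uniform(0, params.censor_horizon, 300)
        frac = np.mean(t_event <= censor)
        assert 0.4 <= frac <= 0.9

    def test_proportional_hazards_direction(self):
        """Empirical events/person-time hazard ratio above/below median h > 1."""
        params = small_cohort_params(1000, seed=9, tiles_per_patient=1,
                                     blasts_per_tile_range=(2, 2), other_wbc_per_tile_range=(0, 1),
                                     rbc_per_tile_range=(0, 1), tile_px=96,
                                     blast_radius_range=(8.0, 10.0))
        cohort = simulate_cohort(params)
        h = np.array([t.h for t in cohort.truths])
        times = np.array([t.rfs_days for t in cohort.truths])
        events = np.array([t.event for t in cohort.truths])
        med = np.median(h)
        hi = h >= med
        rate_hi = events[hi].sum() / times[hi].sum()
        rate_lo = events[~hi].sum() / times[~hi].sum()
        assert rate_hi / rate_lo > 1.0

    def test_split_fractions(self):
        cohort = simulate_cohort(small_cohort_params(50, seed=10))
        pat = cohort.manifest.drop_duplicates("patient_id")
        assert (pat["split"] == "train").sum() == 30
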