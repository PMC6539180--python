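"""The trial simulator: layout geometry, growth/lodging truth, rendering."""

import itertools

import numpy as np
import pytest

from peafield.geo_io import BAND_NAMES
from peafield.surface_model import build_dtm, compute_csm, segment_canopy, \
    plot_canopy_metrics, soil_mask_from_plots
from peafield.synthetic_field import (AgbmLink, GrowthParams, LATENT_FEATURES,
                                      SceneSpec, SyntheticFieldError,
                                      default_panel_region,
                                      generate_trial_layout, generate_truth,
                                      render_scene)
from peafield.zonal import polygon_pixel_mask


class TestTrialLayout:
    def test_full_trial_dimensions(self):
        layout = generate_trial_layout(20, 3, plot_size=(1.5, 5.0), seed=1)
        assert len(layout.plots) == 60
        for p in layout.plots:
            assert p.polygon.area == pytest.approx(7.5)

    def test_degenerate_single_plot_at_origin(self):
        layout = generate_trial_layout(1, 1, origin=(10.0, 20.0))
        assert len(layout.plots) == 1
        minx, miny, _, _ = layout.plots[0].polygon.bounds
        assert (minx, miny) == (10.0, 20.0)

    def test_pairwise_interiors_disjoint_bruteforce(self):
        layout = generate_trial_layout(5, 3, alley=0.5, seed=2)
        for a, b in itertools.combinations(layout.plots, 2):
            assert not a.polygon.intersection(b.polygon).area > 0

    def test_rcbd_every_entry_replicate_pair_once(self):
        layout = generate_trial_layout(7, 4, seed=3)
        pairs = {(p.entry, p.replicate) for p in layout.plots}
        assert len(pairs) == 28

    def test_entry_order_randomized_between_blocks(self):
        layout = generate_trial_layout(12, 2, seed=4)
        block = {}
        for p in layout.plots:
            block.setdefault(p.replicate, []).append(p.entry)
        assert block[1] != block[2]  # seeded permutation differs

    @pytest.mark.parametrize("kwargs,field", [
        (dict(n_entries=0, n_reps=1), "n_entries"),
        (dict(n_entries=1, n_reps=0), "n_reps"),
        (dict(n_entries=1, n_reps=1, plot_size=(0.0, 5.0)), "width"),
        (dict(n_entries=1, n_reps=1, plot_size=(1.5, -1.0)), "length"),
    ])
    def test_invalid_dimensions_rejected_naming_field(self, kwargs, field):
        with pytest.raises(SyntheticFieldError, match=field):
            generate_trial_layout(**kwargs)


class TestGenerateTruth:
    def _layout(self, n_entries=10, n_reps=3):
        return generate_trial_layout(n_entries, n_reps, seed=5)

    def test_growth_peaks_at_configured_flowering_timepoint(self):
        truth = generate_truth(self._layout(), (365, 784, 1268, 1725, 1948), seed=6)
        mean_h = truth.table.groupby("ADD")["true_mean_height"].mean()
        assert mean_h[1268] > mean_h[365]
        assert mean_h[1268] > mean_h[1948]

    def test_noiseless_agbm_is_exactly_linear_in_latents(self):
        truth = generate_truth(self._layout(), (1268,),
                               agbm_link=AgbmLink(noise_sd=0.0), seed=7)
        lat = truth.plot_truth.loc[:, list(LATENT_FEATURES)].to_numpy()
        design = np.column_stack([lat, np.ones(len(lat))])
        agbm = truth.plot_truth["AGBM"].to_numpy()
        _, residual, _, _ = np.linalg.lstsq(design, agbm, rcond=None)
        residual = agbm - design @ np.linalg.lstsq(design, agbm, rcond=None)[0]
        np.testing.assert_allclose(residual, 0.0, atol=1e-10)

    def test_lodging_count_exact_over_seeded_draw(self):
        layout = generate_trial_layout(50, 2, seed=8)  # 100 plots
        truth = generate_truth(layout, (1268, 1948), lodging_fraction=0.3, seed=8)
        assert int(truth.plot_truth["lodged"].sum()) == 30

    def test_lodged_plots_lower_height_higher_cover_than_counterfactual(self):
        layout = self._layout()
        kwargs = dict(timepoints=(1268, 1948), seed=9)
        lodged = generate_truth(layout, lodging_fraction=1.0, **kwargs)
        erect = generate_truth(layout, lodging_fraction=0.0, **kwargs)
        late_l = lodged.for_timepoint(1948).set_index("plot_id")
        late_e = erect.for_timepoint(1948).set_index("plot_id")
        assert (late_l["true_mean_height"] < late_e["true_mean_height"]).all()
        assert (late_l["true_cover_fraction"] > late_e["true_cover_fraction"]).all()

    def test_bounds_invariants(self):
        truth = generate_truth(self._layout(), (365, 1268, 1948),
                               lodging_fraction=0.2, seed=10)
        t = truth.table
        assert t["true_cover_fraction"].between(0, 1).all()
        assert (t["true_mean_height"] >= 0).all()
        assert t["lodging_ratio"].between(0, 1, inclusive="right").all()
        assert set(t["leaf_type"]) == {"af", "Af"}

    def test_soil_grvi_negative_canopy_grvi_positive(self):
        truth = generate_truth(self._layout(), (1268,), seed=11)
        t = truth.for_timepoint(1268)
        soil_grvi = (t["soil_G"] - t["soil_R"]) / (t["soil_G"] + t["soil_R"])
        can_grvi = (t["canopy_G"] - t["canopy_R"]) / (t["canopy_G"] + t["canopy_R"])
        assert (soil_grvi < 0).all()
        assert (can_grvi > 0).all()

    def test_empty_timepoints_rejected(self):
        with pytest.raises(SyntheticFieldError, match="empty"):
            generate_truth(self._layout(), ())

    def test_decreasing_timepoints_rejected(self):
        with pytest.raises(SyntheticFieldError, match="increasing"):
            generate_truth(self._layout(), (1268, 784))


class TestRenderScene:
    def _tiny(self, seed=12, **spec_kwargs):
        layout = generate_trial_layout(2, 2, plot_size=(1.0, 2.0), alley=0.5,
                                       seed=seed)
        truth = generate_truth(layout, (1268.0,), seed=seed)
        spec = SceneSpec(gsd=0.05, seed=seed, **spec_kwargs)
        return layout, truth, spec

    def test_noiseless_full_cover_dsm_is_terrain_plus_height(self):
        layout, truth, spec = self._tiny(noise_sd=0.0, slope=(0.0, 0.0),
                                         base_elevation=100.0)
        truth.table["true_cover_fraction"] = 1.0
        truth.table["true_mean_height"] = 0.5
        stack, dsm = render_scene(truth, layout, spec, 1268.0)
        for p in layout.plots:
            inside = polygon_pixel_mask(p.polygon, dsm.transform, dsm.shape)
            np.testing.assert_allclose(dsm.values[inside], 100.5)

    def test_canopy_pixel_ndvi_from_configured_reflectance(self):
        layout, truth, spec = self._tiny(noise_sd=0.0)
        truth.table["true_cover_fraction"] = 1.0
        truth.table["canopy_NIR"] = 0.50
        truth.table["canopy_R"] = 0.10
        stack, _ = render_scene(truth, layout, spec, 1268.0)
        p = layout.plots[0]
        inside = polygon_pixel_mask(p.polygon, stack.transform, stack.shape)
        ndvi = (stack.bands["NIR"][inside] - stack.bands["R"][inside]) \
            / (stack.bands["NIR"][inside] + stack.bands["R"][inside])
        np.testing.assert_allclose(ndvi, (0.5 - 0.1) / (0.5 + 0.1), atol=1e-12)

    def test_panel_pixels_at_nominal_reflectance_every_band(self):
        layout, truth, spec = self._tiny(noise_sd=0.0)
        stack, _ = render_scene(truth, layout, spec, 1268.0)
        panel = default_panel_region(layout, spec)
        inside = polygon_pixel_mask(panel, stack.transform, stack.shape)
        assert inside.any()
        for b in BAND_NAMES:
            np.testing.assert_array_equal(stack.bands[b][inside], 0.99)

    def test_rendering_bit_reproducible_for_fixed_seed(self):
        layout, truth, spec = self._tiny()
        a, da = render_scene(truth, layout, spec, 1268.0)
        b, db = render_scene(truth, layout, spec, 1268.0)
        np.testing.assert_array_equal(da.values, db.values)
        for band in BAND_NAMES:
            np.testing.assert_array_equal(a.bands[band], b.bands[band])

    def test_coarse_gsd_rejected_with_plot_id(self):
        layout, truth, _ = self._tiny()
        spec = SceneSpec(gsd=3.0, seed=1)
        with pytest.raises(SyntheticFieldError, match="P00"):
            render_scene(truth, layout, spec, 1268.0)

    def test_unknown_timepoint_rejected(self):
        layout, truth, spec = self._tiny()
        with pytest.raises(SyntheticFieldError, match="timepoint"):
            render_scene(truth, layout, spec, 999.0)

    def test_canopy_fraction_converges_to_cover_binomial(self):
        layout = generate_trial_layout(1, 1, plot_size=(2.0, 2.0), seed=20)
        truth = generate_truth(layout, (1268.0,), seed=20)
        cover = 0.6
        truth.table["true_cover_fraction"] = cover
        truth.table["true_mean_height"] = 0.5
        plot = layout.plots[0]
        total_canopy, total_px = 0, 0
        for seed in range(15):
            spec = SceneSpec(gsd=0.05, noise_sd=0.0, slope=(0.0, 0.0), seed=seed)
            stack, dsm = render_scene(truth, layout, spec, 1268.0)
            inside = polygon_pixel_mask(plot.polygon, dsm.transform, dsm.shape)
            canopy = dsm.values[inside] > dsm.values[inside].min() + 0.25
            total_canopy += int(canopy.sum())
            total_px += int(inside.sum())
        phat = total_canopy / total_px
        se = np.sqrt(cover * (1 - cover) / total_px)
        assert abs(phat - cover) < 3 * se


class TestRenderExtractRecovery:
    def test_noiseless_full_cover_recovers_height_exactly(self):
        layout = generate_trial_layout(3, 2, seed=21)
        truth = generate_truth(layout, (1268.0,), seed=21)
        truth.table["true_cover_fraction"] = 1.0
        spec = SceneSpec(gsd=0.05, noise_sd=0.0, seed=21)
        stack, dsm = render_scene(truth, layout, spec, 1268.0)
        dtm = build_dtm(dsm, soil_mask_from_plots(dsm, layout.plots))
        csm = compute_csm(dsm, dtm)
        mask = segment_canopy(csm)
        sub = truth.for_timepoint(1268.0).set_index("plot_id")
        for p in layout.plots:
            m = plot_canopy_metrics(csm, mask, p)
            expected = sub.loc[p.plot_id, "true_mean_height"]
            assert m.ch_uas == pytest.approx(expected, abs=1e-6)
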