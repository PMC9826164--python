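"""Synthetic landscape generator: dynamics, measurement model, documents, invariants."""

import numpy as np
import pytest

from conftest import make_stack
from ifmaudit.carbon_accounting import CONSTANTS
from ifmaudit.geodata_io import zonal_fraction, zonal_series
from ifmaudit.synthetic_landscape import (
    GrowthBoost,
    LandscapeConfig,
    StopHarvest,
    apply_measurement_model,
    generate_scene,
)
from ifmaudit.trend_stats import trend


def quick_config(**kw):
    kw.setdefault("grid_shape", (72, 72))
    kw.setdefault("n_projects", 2)
    kw.setdefault("project_area_range", (20.0, 35.0))
    kw.setdefault("rng_seed", 11)
    return LandscapeConfig(**kw)


class TestConfigValidation:
    @pytest.mark.parametrize("kw, field", [
        (dict(harvest_retention=1.2), "harvest_retention"),
        (dict(years=(2000, 2005)), "years"),
        (dict(public_fraction=-0.1), "public_fraction"),
        (dict(background_fractions=(0.5, 0.2, 0.2, 0.2)), "background_fractions"),
        (dict(low_value_species="oak"), "low_value_species"),
        (dict(project_placement_bias="cheapest"), "project_placement_bias"),
        (dict(project_area_range=(400.0, 500.0)), "project_area_range"),
    ])
    def test_invariant_violations_name_the_field(self, kw, field):
        with pytest.raises(ValueError, match=field):
            generate_scene(quick_config(**kw))


class TestDeterminismAndLimits:
    def test_same_seed_gives_bit_identical_scene(self):
        a = generate_scene(quick_config())
        b = generate_scene(quick_config())
        np.testing.assert_array_equal(a.true_carbon.values, b.true_carbon.values)
        np.testing.assert_array_equal(a.harvest.values, b.harvest.values)
        np.testing.assert_array_equal(a.species_fractions["tanoak"],
                                      b.species_fractions["tanoak"])
        assert [p.area_ha for p in a.projects] == [p.area_ha for p in b.projects]

    def test_different_seed_differs(self):
        a = generate_scene(quick_config())
        b = generate_scene(quick_config(rng_seed=12))
        assert not np.array_equal(a.true_carbon.values, b.true_carbon.values)

    def test_no_harvest_limit_gives_all_zero_stack(self):
        scene = generate_scene(quick_config(harvest_prob_by_region=0.0))
        assert scene.harvest.values.sum() == 0

    def test_no_dynamics_conserves_carbon(self):
        scene = generate_scene(quick_config(
            growth_rate_by_region=0.0, harvest_prob_by_region=0.0,
            growth_noise_cv=0.0, transient_noise_cv=0.0))
        first = scene.true_carbon.values[0]
        for layer in scene.true_carbon.values[1:]:
            np.testing.assert_allclose(layer, first, rtol=1e-10)

    def test_harvest_stack_is_strictly_binary(self, small_scene):
        assert set(np.unique(small_scene.harvest.values)) <= {0, 1}

    def test_species_fractions_sum_to_one_on_vegetated_pixels(self, small_scene):
        total = sum(np.nan_to_num(v) for v in small_scene.species_fractions.values())
        veg = ~np.isnan(next(iter(small_scene.species_fractions.values())))
        np.testing.assert_allclose(total[veg], 1.0, atol=1e-6)


class TestRealizedRates:
    def test_coastal_percent_growth_near_configured_rate(self, default_scene):
        m = default_scene.region_mask("coastal") & ~default_scene.all_project_mask()
        r = trend(zonal_series(default_scene.true_carbon, m))
        target = default_scene.truth.growth_rates()["coastal"] * 100
        assert abs(r.percent_rate - target) < 0.3

    def test_interior_percent_growth_is_negligible(self, default_scene):
        m = default_scene.region_mask("interior") & ~default_scene.all_project_mask()
        r = trend(zonal_series(default_scene.true_carbon, m))
        assert abs(r.percent_rate) <= 0.3

    def test_realized_harvest_fraction_within_30pct_of_configured(self, default_scene):
        for region in default_scene.region_names:
            cfgp = default_scene.truth.harvest_probs()[region]
            frac = zonal_fraction(default_scene.harvest, default_scene.region_mask(region))
            realized = float(np.nanmean(frac.values))
            assert abs(realized - cfgp) / cfgp < 0.30


class TestMeasurementModel:
    def test_identity_below_onset(self):
        out = apply_measurement_model(make_stack(np.full((1, 2, 2), 100.0)), 210.0, 0.5)
        np.testing.assert_allclose(out.values, 100.0)

    def test_piecewise_compression_above_onset(self):
        out = apply_measurement_model(make_stack(np.full((1, 1, 1), 310.0)), 210.0, 0.5)
        assert out.values[0, 0, 0] == pytest.approx(260.0)

    def test_monotone_nondecreasing(self):
        true = np.linspace(0, 500, 101)[None, :, None]
        obs = apply_measurement_model(make_stack(true), 210.0, 0.5).values
        assert (np.diff(obs[0, :, 0]) >= 0).all()

    def test_negative_carbon_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            apply_measurement_model(make_stack(np.full((1, 1, 1), -5.0)), 210.0, 0.5)

    def test_nonpositive_onset_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            apply_measurement_model(make_stack(np.zeros((1, 1, 1))), 0.0, 0.5)

    def test_scene_observed_never_exceeds_true_above_onset(self, small_scene):
        onset = small_scene.truth.saturation_onset
        hi = small_scene.true_carbon.values > onset
        assert (small_scene.observed_carbon.values[hi]
                <= small_scene.true_carbon.values[hi] + 1e-9).all()


class TestEffectsAndPlacement:
    def test_stop_harvest_clears_project_pixels_after_start(self):
        scene = generate_scene(quick_config(
            project_start_year=2009, effect_injection=(StopHarvest(2009),)))
        proj = scene.all_project_mask()
        post = scene.harvest.years > 2009
        assert scene.harvest.values[post][:, proj].sum() == 0
        # harvest elsewhere continues
        assert scene.harvest.values[post][:, ~proj].sum() > 0

    def test_growth_boost_raises_project_slope(self):
        # stop harvest in both arms so removals do not erode the injected gain
        base = generate_scene(quick_config(
            project_start_year=2005, effect_injection=(StopHarvest(2005),)))
        boosted = generate_scene(quick_config(
            project_start_year=2005,
            effect_injection=(StopHarvest(2005), GrowthBoost(1.0, 2005))))
        proj = base.all_project_mask()
        post = base.true_carbon.years > 2005
        gain = (boosted.true_carbon.values[post][:, proj]
                - base.true_carbon.values[post][:, proj])
        years_since = np.arange(1, post.sum() + 1)
        per_year = gain.mean(axis=1) / years_since
        assert per_year.mean() == pytest.approx(1.0, rel=0.15)

    def test_recently_harvested_bias_raises_pre_placement_harvest(self):
        scene = generate_scene(quick_config(
            rng_seed=3, project_placement_bias="recently_harvested"))
        start = scene.truth.project_start_year
        pre = scene.harvest.window(scene.harvest.years[0], start - 1).values.mean(axis=0)
        proj = scene.all_project_mask()
        assert pre[proj].mean() > pre.mean()

    def test_low_value_bias_enriches_projects(self):
        scene = generate_scene(quick_config(
            rng_seed=3, project_placement_bias="low_value_species"))
        tan = scene.species_fractions["tanoak"]
        proj = scene.all_project_mask()
        assert np.nanmean(tan[proj]) > np.nanmean(tan[~proj])

    def test_bias_restricted_to_owner_class(self):
        scene = generate_scene(quick_config(
            rng_seed=3, n_projects=2,
            project_owner_classes=("large-timber", "other"),
            project_placement_bias="recently_harvested",
            bias_owner_class="large-timber"))
        start = scene.truth.project_start_year
        pre = scene.harvest.window(scene.harvest.years[0], start - 1).values.mean(axis=0)
        by_owner = {p.owner_class: pre[scene.project_masks[p.id]].mean()
                    for p in scene.projects}
        assert by_owner["large-timber"] > pre.mean()


class TestDocuments:
    def test_inflation_one_reports_measured_rate(self):
        scene = generate_scene(quick_config(reporting_inflation=1.0))
        for rec in scene.projects:
            ts = zonal_series(scene.true_carbon, scene.project_masks[rec.id])
            measured = trend(ts.window(rec.start_year, int(ts.years[-1]))).slope
            agl = rec.agl_stocks()
            years = sorted(agl)
            doc_rate = np.polyfit(years, [agl[y] for y in years], 1)[0]
            assert doc_rate == pytest.approx(measured, abs=1e-8)

    def test_inflation_scales_document_rate(self):
        lo = generate_scene(quick_config(reporting_inflation=1.0))
        hi = generate_scene(quick_config(reporting_inflation=2.4))
        for a, b in zip(lo.projects, hi.projects):
            ra = np.polyfit(sorted(a.agl_stocks()),
                            [a.agl_stocks()[y] for y in sorted(a.agl_stocks())], 1)[0]
            rb = np.polyfit(sorted(b.agl_stocks()),
                            [b.agl_stocks()[y] for y in sorted(b.agl_stocks())], 1)[0]
            assert rb / ra == pytest.approx(2.4, rel=1e-6)

    def test_baseline_equal_to_initial_stock_gives_zero_initial_credits(self):
        scene = generate_scene(quick_config(baseline_fraction=1.0))
        for rec in scene.projects:
            first = min(rec.credits_issued)
            assert rec.credits_issued[first] == pytest.approx(0.0, abs=1e-9)

    def test_baseline_below_initial_stock(self, small_scene):
        for rec in small_scene.projects:
            agl = rec.agl_stocks()
            assert rec.baseline_stock <= agl[min(agl)] + 1e-9

    def test_reported_stocks_are_totals(self, small_scene):
        rec = small_scene.projects[0]
        assert rec.reported_is_total
        agl = rec.agl_stocks()
        y = min(agl)
        assert agl[y] == pytest.approx(
            rec.reported_stocks[y] * CONSTANTS.agl_fraction)


def test_config_yaml_round_trip(tmp_path):
    cfg = quick_config(effect_injection=(StopHarvest(2010), GrowthBoost(0.5, 2010)))
    cfg.to_yaml(str(tmp_path / "cfg.yaml"))
    back = LandscapeConfig.from_yaml(str(tmp_path / "cfg.yaml"))
    assert back == cfg
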