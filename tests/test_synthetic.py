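import numpy as np
import pytest

from sarpheno.descriptors import compute_descriptor_field
from sarpheno.phenology import STAGE_ORDER
from sarpheno.preprocess import PreprocessConfig, preprocess_scene
from sarpheno.synthetic import (
    DEFAULT_SCHEDULE,
    StageProfile,
    build_truth,
    default_stage_profiles,
    layout_to_geojson,
    make_plot_layout,
    recovery_report,
    simulate_campaign,
    simulate_scene,
    stage_calendar,
)
from sarpheno.zoning import region_mask_from_polygon


class TestProfiles:
    def test_five_stages_in_calendar_order(self):
        profiles = default_stage_profiles()
        assert tuple(profiles) == STAGE_ORDER

    def test_profile_centers_sit_inside_their_target_zones(self, thresholds):
        """leaf development below the Z2|Z3 cut, maturity above the Z5|Z6 cut,
        the middle stages inside Z3, Z4, Z5."""
        p = default_stage_profiles()
        c = thresholds.q_cuts
        assert p["leaf_development"].q_center < c[1]
        assert c[1] < p["elongation"].q_center < c[2]
        assert c[2] < p["big_trumpet"].q_center < c[3]
        assert c[3] < p["tasseling"].q_center < c[4]
        assert p["maturity"].q_center > c[4]

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="2\\*q_spread"):
            StageProfile("bad", q_center=0.02, q_spread=0.05, vv_center=0.1)
        with pytest.raises(ValueError, match="positive"):
            StageProfile("bad", q_center=0.5, q_spread=0.05, vv_center=0.0)


class TestLayoutAndCalendar:
    def test_default_layout_is_twelve_disjoint_plots(self):
        layout = make_plot_layout()
        assert layout.shape == (400, 600)
        assert layout.plot_ids == list(range(1, 13))
        sizes = [layout.plot_mask(p).sum() for p in layout.plot_ids]
        assert sum(sizes) == 400 * 600  # plots tile the scene

    def test_calendar_starts_at_leaf_development_and_is_monotone(self):
        cal = stage_calendar(DEFAULT_SCHEDULE)
        assert cal[126] == "leaf_development"
        rank = {s: i for i, s in enumerate(STAGE_ORDER)}
        ranks = [rank[cal[d]] for d in DEFAULT_SCHEDULE]
        assert ranks == sorted(ranks) and set(ranks) == set(range(5))

    def test_layout_geojson_rasterizes_back_to_plot_masks(self):
        layout = make_plot_layout(shape=(40, 60))
        gj = layout_to_geojson(layout)
        assert len(gj["features"]) == 12
        feat = gj["features"][0]
        mask = region_mask_from_polygon(feat, layout.shape, layout.geo())
        assert np.array_equal(mask, layout.plot_mask(1))


class TestSpeckle:
    def test_gamma_moments_within_sampling_bands(self):
        """Unit-truth intensity has mean 1 and variance 1/L within 3 sigma."""
        layout = make_plot_layout(shape=(210, 240))
        truth = build_truth(layout=layout, looks=9, seed=3)
        scene = simulate_scene(truth, 126)
        pid = 1
        m = layout.plot_mask(pid)
        x = scene.vv[m] / truth.vv_true[(pid, 126)]  # unit-truth speckle
        n = x.size
        L = 9
        assert abs(x.mean() - 1.0) < 3 * np.sqrt(1.0 / (L * n))
        var = x.var(ddof=1)
        # Var(s^2) for Gamma(L, 1/L): (mu4 - var^2 (n-3)/(n-1))/n, mu4 = 3(L+2)/L^3
        mu4 = 3.0 * (L + 2.0) / L**3
        sd_var = np.sqrt((mu4 - (1.0 / L**2) * (n - 3.0) / (n - 1.0)) / n)
        assert abs(var - 1.0 / L) < 3 * sd_var

    def test_fixed_seed_is_bitwise_reproducible(self):
        layout = make_plot_layout(shape=(30, 40))
        s1, t1 = simulate_campaign(layout=layout, seed=5)
        s2, t2 = simulate_campaign(layout=layout, seed=5)
        assert t1.q_true == t2.q_true
        for (d1, a), (d2, b) in zip(s1, s2):
            assert d1 == d2
            assert np.array_equal(a.vv, b.vv, equal_nan=True)
            assert np.array_equal(a.vh, b.vh, equal_nan=True)

    def test_truth_record_regenerates_scene_bitwise(self):
        layout = make_plot_layout(shape=(30, 40))
        scenes, truth = simulate_campaign(layout=layout, seed=8)
        doy, scene = scenes[4]
        again = simulate_scene(truth, doy)
        assert np.array_equal(scene.vv, again.vv, equal_nan=True)

    def test_vanishing_speckle_recovers_truth_ratio(self):
        layout = make_plot_layout(shape=(30, 40))
        truth = build_truth(layout=layout, looks=10**6, seed=2)
        scene = simulate_scene(truth, 126)
        m = layout.plot_mask(1)
        q_obs = scene.vh[m] / scene.vv[m]
        assert np.allclose(q_obs, truth.q_true[(1, 126)], rtol=0.01)

    def test_unknown_doy_rejected(self):
        truth = build_truth(layout=make_plot_layout(shape=(10, 12)), seed=1)
        with pytest.raises(ValueError, match="not in the campaign schedule"):
            simulate_scene(truth, 999)


class TestTruthTable:
    def test_default_schedule_has_thirteen_scenes(self):
        scenes, truth = simulate_campaign(layout=make_plot_layout(shape=(10, 12)), seed=1)
        assert len(scenes) == 13
        assert truth.schedule == DEFAULT_SCHEDULE

    def test_all_truth_ratios_inside_unit_interval(self):
        truth = build_truth(layout=make_plot_layout(shape=(10, 12)), seed=4)
        qs = np.array(list(truth.q_true.values()))
        assert (qs >= 0).all() and (qs <= 1).all()

    def test_truth_mean_q_nondecreasing_over_stages(self):
        truth = build_truth(layout=make_plot_layout(shape=(10, 12)), seed=9)
        per_stage = {}
        for (pid, doy), q in truth.q_true.items():
            per_stage.setdefault(truth.stages[doy], []).append(q)
        means = [np.mean(per_stage[s]) for s in STAGE_ORDER]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            build_truth(schedule=(126, 126), layout=make_plot_layout(shape=(10, 12)))


class TestRecovery:
    def test_recovery_report_on_small_campaign(self, small_campaign):
        truth, series, _, _ = small_campaign
        rep = recovery_report(truth, series)
        assert rep["n_pairs"] == 13 * 12
        # ~1,300-px plots: looser than the acceptance-scale bound but
        # decisively better than the speckle floor would allow if broken
        assert rep["mean_rel_q_error"] < 0.05
        assert rep["stage_accuracy"] >= 0.9

    def test_noise_free_campaign_recovers_stages_exactly(self, thresholds):
        """L -> 1e6 and near-zero spread: stage accuracy must be 1.0."""
        from sarpheno.phenology import StageRules, build_time_series
        from sarpheno.zoning import assign_zones

        profiles = {
            name: StageProfile(name, p.q_center, 1e-6, p.vv_center)
            for name, p in default_stage_profiles().items()
        }
        layout = make_plot_layout(shape=(40, 60))
        scenes, truth = simulate_campaign(profiles, layout, looks=10**6, seed=7)
        triples = []
        for doy, scene in scenes:
            pre = preprocess_scene(scene, PreprocessConfig())
            f = compute_descriptor_field(pre)
            triples.append((doy, f, assign_zones(f, thresholds)))
        regions = {str(p): layout.plot_mask(p) for p in layout.plot_ids}
        series = build_time_series(triples, regions, rules=StageRules())
        rep = recovery_report(truth, series)
        assert rep["stage_accuracy"] == 1.0
        assert rep["mean_rel_q_error"] < 1e-3

    def test_mismatched_regions_rejected(self, small_campaign, thresholds):
        truth, _, triples, _ = small_campaign
        from sarpheno.phenology import StageRules, build_time_series

        series = build_time_series(triples, None, rules=StageRules())  # region "all" only
        with pytest.raises(ValueError, match="do not cover"):
            recovery_report(truth, series)
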