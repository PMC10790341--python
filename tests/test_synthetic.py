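"""Synthetic-data generators: determinism, phase structure, rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from follisim import (
    AtresiaHazard,
    PopulationConfig,
    SyntheticHistologyConfig,
    fit_li_regression,
    include_follicle,
    labeling_index,
    mural_volume,
    pseudodiameter,
    quantify_mask,
    render_mask,
    render_section_stack,
    sample_population,
    simulate_pulse_chase,
    widest_section,
)
from follisim.synthetic import mean_li_at_diameter


class TestSamplePopulation:
    def test_deterministic_for_fixed_seed(self):
        config = PopulationConfig()
        a = sample_population(config, seed=123)
        b = sample_population(config, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        config = PopulationConfig()
        a = sample_population(config, seed=1)
        b = sample_population(config, seed=2)
        assert not a["li"].equals(b["li"])

    def test_preantral_lis_rarely_above_30_percent(self):
        config = PopulationConfig(
            n_per_stage=(("preantral", 300),), atresia_hazard=None
        )
        pop = sample_population(config, seed=4)
        frac_low = (pop["truth_li"] <= 0.30).mean()
        assert frac_low >= 0.90

    def test_zero_hazard_means_no_atresia(self, no_atresia_config):
        pop = sample_population(no_atresia_config, seed=6)
        assert not pop["atretic"].any()
        flag_cols = [c for c in pop.columns if c.startswith("atresia_")]
        assert not pop[flag_cols].any().any()

    def test_atresia_only_above_onset(self):
        pop = sample_population(PopulationConfig(), seed=8)
        atretic = pop[pop["atretic"]]
        assert (atretic["pseudodiameter_um"] >= 170.0).all()
        # every atretic follicle shows at least one morphological criterion
        flag_cols = [c for c in pop.columns if c.startswith("atresia_")]
        assert atretic[flag_cols].any(axis=1).all()

    def test_diameters_respect_stage_intervals(self):
        pop = sample_population(PopulationConfig(), seed=10)
        for stage, (lo, hi) in [
            ("preantral", (80, 130)),
            ("fsh_sensitive", (130, 170)),
            ("fsh_dependent", (170, 350)),
            ("preovulatory", (350, 462)),
        ]:
            d = pop.loc[pop["stage"] == stage, "pseudodiameter_um"]
            assert ((d >= lo) & (d < hi)).all()

    def test_mean_trajectory_has_four_phases(self):
        config = PopulationConfig()
        d = np.array([100.0, 150.0, 170.0, 260.0, 400.0])
        li = mean_li_at_diameter(d, config)
        assert li[0] == pytest.approx(config.li_preantral_mean)
        assert li[1] > li[0]  # spurt rising
        assert li[2] == pytest.approx(0.57 - 0.0008 * 170.0)
        assert li[2] > li[3] > li[4]  # linear decline beyond 170

    def test_regression_recovers_generating_decline(self):
        config = PopulationConfig(
            n_per_stage=(("fsh_dependent", 150), ("preovulatory", 50)),
            atresia_hazard=None,
        )
        pop = sample_population(config, seed=14)
        res = fit_li_regression(pop)
        se = res.bse[1]
        assert res.slope == pytest.approx(-0.0008, abs=3 * se)


class TestPulseChase:
    def test_2h_design_reads_instantaneous_li(self, no_atresia_config, params):
        pop = sample_population(no_atresia_config, seed=2)
        out = simulate_pulse_chase(pop, "2h", params)
        assert (out["label_li"] == pop["li"]).all()
        assert (out["pseudodiameter_um"] == pop["pseudodiameter_um"]).all()

    def test_48h_zero_li_leaves_diameters_unchanged(self, params):
        df = pd.DataFrame(
            {
                "follicle_id": ["f0", "f1"],
                "animal_id": "a1",
                "cycle_stage": "metestrus",
                "pseudodiameter_um": [200.0, 300.0],
                "li": [0.0, 0.0],
                "truth_li": [0.0, 0.0],
                "atretic": [False, False],
                "included": [True, True],
            }
        )
        out = simulate_pulse_chase(df, "48h", params, days_elapsed=2)
        assert np.allclose(out["pseudodiameter_um"], df["pseudodiameter_um"])

    def test_48h_growth_follows_model(self, params):
        from follisim import simulate_growth

        df = pd.DataFrame(
            {
                "follicle_id": ["f0"],
                "animal_id": "a1",
                "cycle_stage": "metestrus",
                "pseudodiameter_um": [250.0],
                "li": [0.4],
                "truth_li": [0.4],
                "atretic": [False],
                "included": [True],
            }
        )
        out = simulate_pulse_chase(df, "48h", params, days_elapsed=2)
        expected = simulate_growth(250.0, 0.4, 2, params).diameters[-1]
        assert out["pseudodiameter_um"].iloc[0] == pytest.approx(expected)

    def test_48h_with_hazard_enriches_fast_growers(self, params):
        from follisim import StageThresholds

        config = PopulationConfig(
            n_per_stage=(("fsh_dependent", 80),),
            thresholds=StageThresholds(fsh_dependent_min=250.0),
            atresia_hazard=None,
        )
        pop = sample_population(config, cycle_stage="diestrus", seed=33)
        out = simulate_pulse_chase(
            pop, "48h", params, days_elapsed=2, hazard=AtresiaHazard(), seed=33
        )
        survivors = out[(out["pseudodiameter_um"] > 350.0) & ~out["atretic"]]
        assert survivors["label_li"].mean() > pop["li"].mean()

    def test_invalid_design_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_pulse_chase(pd.DataFrame(), "24h", params)


class TestSectionStack:
    def test_centered_sphere_recovers_diameter(self):
        config = SyntheticHistologyConfig.two_hour()
        window = config.series_length * config.section_thickness
        series = render_section_stack(300.0, config, equator_offset=window / 2)
        _, widest_area = widest_section(series)
        # quantization: midplane can miss the equator by half a section
        assert pseudodiameter(widest_area) == pytest.approx(300.0, abs=0.1)

    def test_equator_in_first_section_excluded(self):
        config = SyntheticHistologyConfig.two_hour()
        series = render_section_stack(200.0, config, equator_offset=2.0)
        assert include_follicle(series) is False

    def test_equator_past_last_section_excluded(self):
        config = SyntheticHistologyConfig.two_hour()
        window = config.series_length * config.section_thickness
        series = render_section_stack(200.0, config, equator_offset=window - 1.0)
        assert include_follicle(series) is False

    def test_small_sphere_single_section(self):
        config = SyntheticHistologyConfig.two_hour()
        series = render_section_stack(4.0, config, equator_offset=187.5)
        assert len(series.per_follicle_profile) == 1

    def test_48h_sampling_every_25th(self):
        config = SyntheticHistologyConfig.forty_eight_hour()
        series = render_section_stack(300.0, config, equator_offset=187.5)
        indices = [i for i, _ in series.per_follicle_profile]
        assert all(i % 25 == 0 for i in indices)

    def test_randomized_placements_match_geometry(self):
        # stereology oracle: expected widest sampled section from the
        # analytic sphere-slice area, checked over random placements
        config = SyntheticHistologyConfig.two_hour()
        t = config.section_thickness
        window = config.series_length * t
        rng = np.random.default_rng(77)
        n_checked = 0
        for _ in range(100):
            diameter = rng.uniform(80.0, 460.0)
            offset = rng.uniform(-50.0, window + 50.0)
            series = render_section_stack(diameter, config, offset)
            if not series.per_follicle_profile:
                continue
            r = diameter / 2.0
            truth = {
                k: math.pi * (r**2 - ((k + 0.5) * t - offset) ** 2)
                for k in range(config.series_length)
                if abs((k + 0.5) * t - offset) < r
            }
            expected_widest = max(truth, key=truth.get)
            got_widest, _ = widest_section(series)
            assert got_widest == expected_widest
            expected_included = expected_widest not in (0, config.series_length - 1)
            assert include_follicle(series) is expected_included
            n_checked += 1
        assert n_checked >= 80  # nearly all placements intersect the window


class TestRenderMask:
    def test_li_zero_and_one(self):
        from follisim.histology import CLASS_CODES

        mask0, _, truth0 = render_mask(250.0, 0.0, seed=0)
        assert (mask0 == CLASS_CODES["brdu_pos"]).sum() == 0
        mask1, _, truth1 = render_mask(250.0, 1.0, seed=0)
        mural_pixels = (mask1 == CLASS_CODES["brdu_pos"]).sum()
        assert mural_pixels == truth1["n_mural_pixels"]

    @pytest.mark.parametrize("li", [0.25, 0.4, 0.75])
    def test_round_trip_recovers_planted_li(self, li):
        mask, roi, truth = render_mask(300.0, li, seed=5)
        measured = labeling_index(quantify_mask(mask, roi))
        bound = 1.0 / truth["n_mural_pixels"] + 0.02
        assert measured == pytest.approx(li, abs=bound)

    def test_cumulus_exclusion_matters(self):
        # the cumulus ring is all BrdU-negative granulosa: skipping the
        # exclusion drags the measured LI down
        from follisim import RegionOfInterest

        mask, roi, truth = render_mask(220.0, 0.6, seed=3)
        with_exclusion = labeling_index(quantify_mask(mask, roi))
        no_exclusion = labeling_index(
            quantify_mask(mask, RegionOfInterest(roi.basal_lamina_polygon))
        )
        assert with_exclusion == pytest.approx(truth["li"], abs=0.01)
        assert no_exclusion < with_exclusion

    def test_deterministic_given_seed(self):
        a, _, _ = render_mask(250.0, 0.4, seed=9)
        b, _, _ = render_mask(250.0, 0.4, seed=9)
        assert (a == b).all()

    def test_shell_volume_matches_power_law_within_10_percent(self):
        config = SyntheticHistologyConfig()
        for d in np.linspace(170.0, 450.0, 15):
            r = d / 2.0
            t = config.mural_thickness(d)
            shell = 4.0 / 3.0 * math.pi * (r**3 - (r - t) ** 3)
            assert shell == pytest.approx(mural_volume(d), rel=0.10)
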