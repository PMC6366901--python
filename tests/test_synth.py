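"""Synthetic-data generator: determinism, exact growth laws, mixture
composition, switching-population bookkeeping, annotation and qPCR plates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from microhet import organelle, synth
from microhet.organelle import SwitchingModelParams
from microhet.synth import ColonySpec, MixtureSpec


class TestColonyGrowthLaw:
    def test_zero_rate_area_constant(self):
        c = ColonySpec(colony_id=0, seed_position=(50, 50), initial_area=100,
                       true_rate=0.0)
        assert [c.area_at(t) for t in (0, 1.5, 3, 12)] == [100] * 4

    def test_exponential_law_matches_independent_arithmetic(self):
        # frame k at 1.5 h spacing: round(100 * e^(0.4*1.5k)); frame 2 = 332
        c = ColonySpec(colony_id=0, seed_position=(50, 50), initial_area=100,
                       true_rate=0.4)
        import math
        for k in range(6):
            assert c.area_at(1.5 * k) == round(100 * math.exp(0.4 * 1.5 * k))
        assert c.area_at(3.0) == 332

    def test_lag_delays_growth_and_slowdown_freezes_area(self):
        c = ColonySpec(colony_id=0, seed_position=(0, 0), initial_area=100,
                       true_rate=0.4, lag_duration=3.0, slowdown_onset=6.0)
        assert c.area_at(1.5) == 100
        assert c.area_at(4.5) == round(100 * np.exp(0.4 * 1.5))
        assert c.area_at(9.0) == c.area_at(6.0)


class TestGenerateTimelapse:
    def test_seeded_determinism_byte_identical(self):
        specs = synth.grid_colony_specs(4, (600, 600), rates=0.3, rng_seed=2)
        a = synth.generate_timelapse(specs, n_frames=4, image_shape=(600, 600),
                                     rng_seed=9)
        b = synth.generate_timelapse(specs, n_frames=4, image_shape=(600, 600),
                                     rng_seed=9)
        assert np.array_equal(a.stack, b.stack)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_rendered_pixel_area_equals_growth_law(self):
        # with zero background noise every non-background pixel is colony
        c = ColonySpec(colony_id=0, seed_position=(100, 100), initial_area=100,
                       true_rate=0.4)
        res = synth.generate_timelapse([c], n_frames=5, image_shape=(256, 256),
                                       noise_sd=0.0, rng_seed=0)
        for f in range(5):
            rendered = int(np.sum(res.stack[f] != synth.BACKGROUND_MEAN))
            assert rendered == c.area_at(1.5 * f)

    def test_overlapping_seeds_rejected(self):
        c1 = ColonySpec(colony_id=0, seed_position=(50, 50), initial_area=100,
                        true_rate=0.3)
        c2 = ColonySpec(colony_id=1, seed_position=(52, 50), initial_area=100,
                        true_rate=0.3)
        with pytest.raises(ValueError, match="overlap"):
            synth.generate_timelapse([c1, c2], n_frames=3,
                                     image_shape=(200, 200))

    def test_collision_frame_matches_brute_force_mask_overlap(self):
        # two colonies 33 px apart collide between frames 3 and 4
        c1 = ColonySpec(colony_id=0, seed_position=(100, 100), initial_area=100,
                        true_rate=0.4)
        c2 = ColonySpec(colony_id=1, seed_position=(100, 133), initial_area=100,
                        true_rate=0.4)
        res = synth.generate_timelapse([c1, c2], n_frames=6,
                                       image_shape=(300, 300), rng_seed=1)
        # brute force: rasterize both discs per frame, dilate one by 1 px,
        # find the first frame with any shared pixel
        offsets = synth._sorted_disc_offsets(c1.area_at(7.5) + 8)
        first = None
        for f in range(6):
            masks = []
            for c in (c1, c2):
                n = c.area_at(1.5 * f)
                pix = {(c.seed_position[0] + dr, c.seed_position[1] + dc)
                       for dr, dc in map(tuple, offsets[:n])}
                masks.append(pix)
            dilated = {(r + dr, c + dc) for r, c in masks[0]
                       for dr in (-1, 0, 1) for dc in (-1, 0, 1)}
            if dilated & masks[1]:
                first = f
                break
        assert first == 4
        assert res.contacts.iloc[0]["frame"] == first
        touched = res.ground_truth[res.ground_truth["touched"]]
        assert touched["frame"].min() == first

    def test_colony_exceeding_frame_marked_truncated(self):
        c = ColonySpec(colony_id=0, seed_position=(20, 128), initial_area=300,
                       true_rate=0.5)
        res = synth.generate_timelapse([c], n_frames=8, image_shape=(256, 256),
                                       rng_seed=0)
        assert res.ground_truth["truncated"].any()


class TestRateMixture:
    def test_zero_sd_gives_constant_rates(self):
        spec = MixtureSpec(components=((1.0, 0.3, 0.0),), n_colonies=50,
                           rng_seed=0)
        rates = synth.generate_rate_mixture(spec)["rate"]
        assert np.allclose(rates, 0.3)

    def test_planted_slow_label_fraction_within_binomial_ci(self):
        spec = MixtureSpec(components=synth.WT_MIXTURE, n_colonies=10_000,
                           rng_seed=3)
        df = synth.generate_rate_mixture(spec)
        frac = (df["component"] == 1).mean()
        sd = np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(frac - 0.1) < 3 * sd

    def test_equal_mean_components_are_degenerate_unimodal(self):
        spec = MixtureSpec(components=((0.5, 0.4, 0.01), (0.5, 0.4, 0.01)),
                           n_colonies=2000, rng_seed=5)
        from microhet import hetstats

        slow, fast, _ = hetstats.slow_fast_fraction(
            synth.generate_rate_mixture(spec)["rate"].to_numpy())
        assert slow < 2.0 and fast < 2.0

    def test_rates_truncated_at_zero(self):
        spec = MixtureSpec(components=((1.0, 0.02, 0.05),), n_colonies=3000,
                           rng_seed=1)
        assert (synth.generate_rate_mixture(spec)["rate"] >= 0).all()

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(components=((0.6, 0.4, 0.02), (0.6, 0.15, 0.05)),
                        n_colonies=10)


class TestSwitchingPopulation:
    def test_no_switching_single_state_keeps_composition(self):
        params = SwitchingModelParams(f_low0=0.0, f_slow=1.0, f_fast=0.0,
                                      s_low_to_high=0.0)
        pop = synth.generate_switching_population(params, horizon=12, dt=0.5,
                                                  rng_seed=0, n_initial=500)
        assert pop.state_fraction("slow") == 1.0
        assert pop.state_fraction("low") == 0.0

    def test_dt_halving_statistically_indistinguishable(self):
        from scipy import stats

        params = organelle.HI_BIN_DAY1
        a = [synth.generate_switching_population(params, 24, 0.5, rng_seed=s,
                                                 n_initial=4000).state_fraction("low")
             for s in range(12)]
        b = [synth.generate_switching_population(params, 24, 0.25, rng_seed=100 + s,
                                                 n_initial=4000).state_fraction("low")
             for s in range(12)]
        assert stats.mannwhitneyu(a, b).pvalue > 0.01

    def test_dt_must_divide_horizon(self):
        with pytest.raises(ValueError, match="divide"):
            synth.generate_switching_population(organelle.HI_BIN_DAY1,
                                                horizon=24, dt=0.7)

    def test_cap_subsampling_records_weight(self):
        params = SwitchingModelParams(f_low0=0.0, f_slow=0.0, f_fast=1.0,
                                      s_low_to_high=0.0)
        pop = synth.generate_switching_population(params, horizon=24, dt=1.0,
                                                  rng_seed=0, n_initial=2000,
                                                  cap=5000)
        assert (pop.counts["weight"] > 1.0).all()
        # weighted total still tracks e^(r t) growth in expectation
        assert pop.total == pytest.approx(2000 * np.exp(0.37 * 24), rel=0.25)

    def test_per_step_probability_hazard_conversion(self):
        p24 = 0.1
        p_dt = synth.per_step_probability(p24, 0.5)
        # 48 steps of surviving p_dt reproduce the per-24 h survival exactly
        assert (1 - p_dt) ** 48 == pytest.approx(1 - p24, abs=1e-12)


class TestAnnotation:
    def test_fold_one_matches_background_frequency(self):
        ann, group = synth.generate_annotation(2000, 3, planted=("term00", 300, 1.0),
                                               rng_seed=0)
        in_group = ann[(ann["term"] == "term00") & ann["gene"].isin(group)]
        frac = len(in_group) / 300
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 300)

    def test_planted_fold_two_expected_count(self):
        # fold 2, base 10%, group 100 of 1000 -> expected 20 in-group hits
        ann, group = synth.generate_annotation(1000, 5, planted=("term02", 100, 2.0),
                                               rng_seed=4)
        hits = len(ann[(ann["term"] == "term02") & ann["gene"].isin(group)])
        sd = np.sqrt(100 * 0.2 * 0.8)
        assert abs(hits - 20) < 4 * sd

    def test_infeasible_fold_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            synth.generate_annotation(100, 2, planted=("term00", 10, 20.0))


class TestQpcrPlate:
    def test_reaction_layout_matches_assay(self):
        plate = synth.generate_qpcr_plate(true_copy_ratio=20.0, rng_seed=0)
        samples = plate.data[plate.data["role"] == "sample"]
        standards = plate.data[plate.data["role"] == "standard"]
        assert len(samples) == 30  # 5+5 primers x 3 technical replicates
        assert len(standards) == 60  # 10 primers x 6 dilutions
        by_primer = standards.groupby("primer")["quantity"]
        for _, q in by_primer:
            ratios = np.sort(q.to_numpy())[::-1]
            assert np.allclose(ratios[:-1] / ratios[1:], 4.0)

    def test_noiseless_roundtrip_recovers_ratio_exactly(self):
        plate = synth.generate_qpcr_plate(true_copy_ratio=20.0, ct_noise_sd=0.0,
                                          rng_seed=1)
        res = organelle.mtdna_copy_number(plate)
        assert res.copy_number == pytest.approx(20.0, abs=1e-6)

    def test_noisy_recovery_within_propagated_error(self):
        zs = []
        for seed in range(20):
            plate = synth.generate_qpcr_plate(true_copy_ratio=20.0,
                                              ct_noise_sd=0.2, rng_seed=seed)
            res = organelle.mtdna_copy_number(plate)
            zs.append((res.copy_number - 20.0) / res.sd)
        zs = np.abs(zs)
        assert np.mean(zs) < 2.0
        assert np.mean(zs < 3.0) >= 0.9

    def test_efficiency_bounds_enforced(self):
        with pytest.raises(ValueError, match="efficiency"):
            synth.generate_qpcr_plate(true_copy_ratio=1.0, efficiency=0.5)


class TestPlantedScreen:
    def test_categories_and_shapes(self):
        spec = synth.PlantedScreenSpec(n_strains=7, n_per_replicate=200,
                                       rng_seed=0)
        data = synth.generate_screen(spec)
        assert len(data["wt"]) == spec.wt_replicates
        assert set(d["category"] for d in data["strains"].values()) == set(synth.CATEGORIES)
        for d in data["strains"].values():
            assert len(d["replicates"]) == 3
            assert all(len(r) == 200 for r in d["replicates"])

    def test_mode_shift_planted_in_bulk(self):
        from microhet import hetstats

        spec = synth.PlantedScreenSpec(n_strains=7, n_per_replicate=3000,
                                       rng_seed=1)
        data = synth.generate_screen(spec)
        strain = next(s for s, d in data["strains"].items()
                      if d["category"] == "mode-only")
        mode = hetstats.estimate_mode(data["strains"][strain]["replicates"][0])
        assert mode == pytest.approx(0.407 - spec.mode_shift, abs=0.02)
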