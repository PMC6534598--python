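import math

import numpy as np
import pandas as pd
import pytest

from tcb1kit.cross_model import PlantGenotype, expected_marker_segregation
from tcb1kit.pollination_sim import (
    EarCount,
    ScreenConfig,
    ears_to_frame,
    estimate_leak_and_bias,
    read_ear_table,
    simulate_mixed_pollination,
    simulate_open_pollinated_screen,
    simulate_reversion_experiment,
    write_ear_table,
)


class TestMixedPollination:
    def test_fixed_seed_reproduces_identical_ears(self, neutral_female,
                                                  tcb1_purple_donor,
                                                  tcb1s_yellow_donor):
        kw = dict(test_female=neutral_female, donor_a=tcb1_purple_donor,
                  donor_b=tcb1s_yellow_donor, n_kernels=500, seed=42)
        assert simulate_mixed_pollination(**kw) == simulate_mixed_pollination(**kw)

    def test_neutral_ear_reads_out_the_60_40_bias(self, neutral_female,
                                                  tcb1_purple_donor,
                                                  tcb1s_yellow_donor):
        # equal mix + 60:40 acceptance bias -> ~60% tcb1-sired on the
        # neutral ear, within 3 binomial SE at n=10,000
        n = 10_000
        ears = simulate_mixed_pollination(
            neutral_female, tcb1_purple_donor, tcb1s_yellow_donor,
            mix_weight=0.5, n_kernels=n, seed=7)
        frac = ears["neutral"].n_purple / n
        se = math.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) < 3 * se

    def test_full_barrier_excludes_tcb1_donor_completely(
            self, tcb1_purple_donor, tcb1s_yellow_donor):
        ears = simulate_mixed_pollination(
            PlantGenotype.homozygous("Tcb1-s"), tcb1_purple_donor,
            tcb1s_yellow_donor, leak=0.0, n_kernels=2000, seed=3)
        assert ears["test"].n_purple == 0
        assert ears["tester"].n_purple == 0
        assert ears["neutral"].n_purple > 0

    def test_mix_of_null_and_male_only_pollen_sires_only_male_class(
            self, tcb1_purple_donor):
        # closed form: on a barrier-active ear at leak=0, a 50:50
        # tcb1/Tcb1-m mix yields 100% Tcb1-m-sired kernels
        donor_m = PlantGenotype.homozygous("Tcb1-m", r1="r1-r")
        ears = simulate_mixed_pollination(
            PlantGenotype.homozygous("Tcb1-s"), tcb1_purple_donor, donor_m,
            mix_weight=0.5, leak=0.0, n_kernels=5000, seed=11)
        assert ears["test"].n_purple == 0
        assert ears["test"].n_yellow == 5000

    def test_indistinguishable_donors_rejected(self, neutral_female,
                                               tcb1s_yellow_donor):
        donor_same_color = PlantGenotype.homozygous("tcb1", r1="r1-r")
        with pytest.raises(ValueError, match="r1"):
            simulate_mixed_pollination(neutral_female, donor_same_color,
                                       tcb1s_yellow_donor)

    def test_knockout_test_ear_matches_neutral_in_expectation(
            self, tcb1_purple_donor, tcb1s_yellow_donor):
        # a tcb1-f knockout female (barrier lost, male gene intact) should
        # accept the mix exactly like the neutral ear
        ko_female = PlantGenotype.homozygous("Tcb1-m")
        n = 20_000
        ears = simulate_mixed_pollination(
            ko_female, tcb1_purple_donor, tcb1s_yellow_donor,
            n_kernels=n, seed=5)
        diff = ears["test"].n_purple / n - ears["neutral"].n_purple / n
        se = math.sqrt(2 * 0.6 * 0.4 / n)
        assert abs(diff) < 3 * se

    def test_leak_and_bias_recovered_by_method_of_moments(
            self, tcb1_purple_donor, tcb1s_yellow_donor):
        true_leak = 0.05
        n = 50_000
        ears = simulate_mixed_pollination(
            PlantGenotype.homozygous("Tcb1-s"), tcb1_purple_donor,
            tcb1s_yellow_donor, leak=true_leak, n_kernels=n, seed=19)
        est = estimate_leak_and_bias(ears["test"], ears["neutral"])
        assert est["bias_tcb1"] == pytest.approx(0.6, abs=0.02)
        assert est["leak"] == pytest.approx(true_leak, rel=0.25)


class TestOpenPollinatedScreen:
    def test_barrier_ears_segregate_sugary_at_half_r(self):
        cfg = ScreenConfig(n_plants=2000, kernels_per_ear=300, r=0.06, seed=1)
        ears = simulate_open_pollinated_screen(cfg)
        mean = ears["sugary_fraction"].mean()
        se = math.sqrt(0.03 * 0.97 / (2000 * 300))
        assert abs(mean - expected_marker_segregation(True, 0.06)) < 3 * se

    def test_all_knockout_population_segregates_at_one_quarter(self):
        cfg = ScreenConfig(n_plants=1000, kernels_per_ear=300, r=0.06,
                           knockout_fraction=1.0, seed=2)
        ears = simulate_open_pollinated_screen(cfg)
        mean = ears["sugary_fraction"].mean()
        se = math.sqrt(0.25 * 0.75 / (1000 * 300))
        assert abs(mean - 0.25) < 3 * se
        assert not ears["barrier"].any()

    def test_small_knockout_sector_counts_are_binomial_scale(self):
        # ~45-kernel knockout ears segregate ~one-quarter sugary
        cfg = ScreenConfig(n_plants=400, kernels_per_ear=45,
                           knockout_fraction=1.0, seed=3)
        ears = simulate_open_pollinated_screen(cfg)
        assert ears["n_sugary"].mean() == pytest.approx(45 * 0.25, rel=0.1)

    def test_determinism_and_seed_recorded(self):
        cfg = ScreenConfig(n_plants=100, kernels_per_ear=50, seed=99)
        a = simulate_open_pollinated_screen(cfg)
        b = simulate_open_pollinated_screen(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert a.attrs["seed"] == 99

    def test_zero_kernels_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(kernels_per_ear=0)


class TestReversionExperiment:
    def test_reverted_count_near_binomial_expectation(self):
        df = simulate_reversion_experiment(n_females=500, reversion_prob=0.18,
                                           n_kernels=100, seed=4)
        n_rev = df["reverted"].sum()
        se = math.sqrt(500 * 0.18 * 0.82)
        assert abs(n_rev - 500 * 0.18) < 3 * se

    def test_no_reversion_means_no_barrier_anywhere(self):
        # non-reverted females behave as tcb1: test and control fractions
        # agree in expectation; pool 10 replicate experiments so the mean
        # difference is tested at 3 SE of the pooled estimator
        n_females, n_kernels, n_reps = 20, 200, 10
        diffs = []
        for seed in range(n_reps):
            df = simulate_reversion_experiment(
                n_females=n_females, reversion_prob=0.0,
                n_kernels=n_kernels, seed=seed)
            assert not df["reverted"].any()
            n = n_females * n_kernels
            diffs.append((df["test_purple"].sum() - df["ctrl_purple"].sum()) / n)
        se_mean = math.sqrt(2 * 0.6 * 0.4 / (n_females * n_kernels) / n_reps)
        assert abs(sum(diffs) / n_reps) < 3 * se_mean

    def test_complete_reversion_with_tight_leak_blocks_tcb1_pollen(self):
        df = simulate_reversion_experiment(
            n_females=10, reversion_prob=1.0, leak_band=(0.0, 0.0),
            n_kernels=200, seed=6)
        assert df["reverted"].all()
        assert (df["test_purple"] == 0).all()
        assert (df["ctrl_purple"] > 0).all()


class TestEarTableIO:
    def test_round_trip(self, tmp_path):
        ears = {"test": EarCount("e1", 10, 90, 3, 100),
                "neutral": EarCount("e2", 60, 40, 25, 100)}
        path = tmp_path / "ears.tsv"
        write_ear_table(ears, path)
        back = read_ear_table(path)
        assert back == ears

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EarCount("bad", 10, 10, 3, 100)  # purple+yellow != total
        with pytest.raises(ValueError):
            EarCount("bad", -1, 101, 0, 100)
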