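import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcb1kit.barrier_stats import (
    EarClassification,
    TwoByTwoTable,
    barrier_strength,
    classify_ear,
    cosegregation,
    exact_test_2x2,
    flag_screen_outliers,
)
from tcb1kit.pollination_sim import EarCount, ScreenConfig, simulate_open_pollinated_screen

from _oracles import binomial_upper_tail, fisher_two_tailed

counts = st.integers(0, 40)


class TestExactTest:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((6, 0, 0, 9), 1 / 5005),       # perfect 6/9 split
            ((5, 5, 5, 5), 1.0),            # observed table is the mode
        ],
    )
    def test_known_tables(self, table, expected):
        assert exact_test_2x2(TwoByTwoTable(*table)) == pytest.approx(
            expected, rel=1e-9)

    def test_extreme_table_matches_enumeration(self):
        t = (0, 50, 50, 0)
        assert exact_test_2x2(TwoByTwoTable(*t)) == pytest.approx(
            fisher_two_tailed(*t), rel=1e-9)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(deadline=None, max_examples=150)
    def test_matches_oracle_on_random_tables(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert exact_test_2x2(TwoByTwoTable(a, b, c, d)) == pytest.approx(
            fisher_two_tailed(a, b, c, d), rel=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            exact_test_2x2(TwoByTwoTable(0, 0, 0, 0))

    def test_p_values_conservative_under_simulated_null(self):
        # identical siring odds on both ears: p stochastically >= uniform
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(300):
            x = rng.binomial(120, 0.4)
            y = rng.binomial(120, 0.4)
            pvals.append(exact_test_2x2(TwoByTwoTable(x, 120 - x, y, 120 - y)))
        pvals = np.asarray(pvals)
        for q in (0.01, 0.05, 0.25):
            assert (pvals <= q).mean() <= q + 3 * np.sqrt(q * (1 - q) / 300)


class TestBarrierStrength:
    def test_identical_odds_give_unity(self):
        assert barrier_strength(EarCount("t", 60, 40, 0, 100),
                                EarCount("c", 60, 40, 0, 100)) == 1.0

    def test_odds_ratio_arithmetic(self):
        # test ear 99 compatible : 1 tcb1, control 50:50
        assert barrier_strength(EarCount("t", 1, 99, 0, 100),
                                EarCount("c", 50, 50, 0, 100)) == pytest.approx(99.0)

    def test_zero_cell_gets_haldane_correction(self):
        # EarCount order is (purple, yellow); 100 yellow : 0 purple gives
        # corrected odds (100.5/0.5)/(50.5/50.5) = 201
        assert barrier_strength(EarCount("t", 0, 100, 0, 100),
                                EarCount("c", 50, 50, 0, 100)) == pytest.approx(201.0)
        assert barrier_strength(EarCount("t", 100, 0, 0, 100),
                                EarCount("c", 50, 50, 0, 100)) == pytest.approx(
            1.0 / 201.0)

    @given(a=st.integers(1, 200), b=st.integers(1, 200),
           c=st.integers(1, 200), d=st.integers(1, 200))
    def test_transposition_symmetry(self, a, b, c, d):
        t, ctl = EarCount("t", a, b, 0, a + b), EarCount("c", c, d, 0, c + d)
        assert barrier_strength(t, ctl) == pytest.approx(
            1.0 / barrier_strength(ctl, t))

    @given(a=st.integers(1, 50), b=st.integers(1, 50),
           c=st.integers(1, 50), d=st.integers(1, 50), k=st.integers(2, 5))
    def test_invariant_to_scaling_counts(self, a, b, c, d, k):
        bs1 = barrier_strength(EarCount("t", a, b, 0, a + b),
                               EarCount("c", c, d, 0, c + d))
        bs2 = barrier_strength(EarCount("t", k * a, k * b, 0, k * (a + b)),
                               EarCount("c", k * c, k * d, 0, k * (c + d)))
        assert bs1 == pytest.approx(bs2)


class TestClassifyEar:
    def test_recombinant_geometry_lands_in_partial_tier(self):
        # p = 1/5005 ~ 2e-4 sits between the 1e-4 and 1e-2 thresholds
        cls = classify_ear(EarCount("t", 0, 6, 0, 6),
                           EarCount("c", 9, 0, 0, 9))
        assert cls.p_value == pytest.approx(1 / 5005, rel=1e-9)
        assert cls.tier == "partial"

    def test_identical_ears_are_unclassified(self):
        cls = classify_ear(EarCount("t", 60, 40, 0, 100),
                           EarCount("c", 60, 40, 0, 100))
        assert cls.tier == "none"
        assert cls.barrier_strength == 1.0

    def test_complete_exclusion_is_strong(self):
        # 0 of 200 test kernels tcb1-sired vs 120 of 200 on the control
        cls = classify_ear(EarCount("t", 0, 200, 0, 200),
                           EarCount("c", 120, 80, 0, 200))
        assert cls.tier == "strong"
        assert cls.p_value < 1e-4

    def test_significance_in_wrong_direction_does_not_count(self):
        # significantly MORE tcb1 kernels on the test ear -> tier none
        cls = classify_ear(EarCount("t", 200, 0, 0, 200),
                           EarCount("c", 80, 120, 0, 200))
        assert cls.p_value < 1e-4
        assert cls.tier == "none"

    def test_tier_boundaries_are_the_printed_thresholds(self):
        from tcb1kit.barrier_stats import PARTIAL_P, STRONG_P

        assert STRONG_P == 1e-4
        assert PARTIAL_P == 1e-2


class TestCosegregation:
    def test_perfect_cosegregation_of_6_and_9(self):
        marker = [True] * 6 + [False] * 9
        pheno = [True] * 6 + [False] * 9
        n_con, n_dis, p = cosegregation(marker, pheno)
        assert (n_con, n_dis) == (15, 0)
        assert p == pytest.approx(1 / 5005, rel=1e-9)

    def test_anticorrelated_lists(self):
        marker = [True] * 6 + [False] * 9
        pheno = [False] * 6 + [True] * 9
        n_con, n_dis, p = cosegregation(marker, pheno)
        assert (n_con, n_dis) == (0, 15)
        assert p == pytest.approx(fisher_two_tailed(0, 6, 9, 0), rel=1e-9)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=2, max_size=20))
    def test_concordant_plus_discordant_partitions_the_sample(self, pairs):
        marker, pheno = zip(*pairs)
        n_con, n_dis, _ = cosegregation(list(marker), list(pheno))
        assert n_con + n_dis == len(pairs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cosegregation([True], [True, False])


class TestFlagScreenOutliers:
    def test_knockout_sector_flagged_against_3pct_null(self):
        ears = pd.DataFrame({"ear_id": ["ko", "wt"], "n_kernels": [45, 300],
                             "n_sugary": [11, 9]})
        out = flag_screen_outliers(ears, null_fraction=0.03, alpha=0.05)
        assert bool(out.loc[0, "flagged"])
        assert out.loc[0, "p_value"] == pytest.approx(
            binomial_upper_tail(11, 45, 0.03), rel=1e-9)
        # the wild-type ear sits at the null expectation: not flagged
        assert not bool(out.loc[1, "flagged"])

    def test_simulated_screen_sensitivity_and_specificity(self):
        cfg = ScreenConfig(n_plants=1500, kernels_per_ear=300, r=0.06,
                           knockout_fraction=0.01, seed=13)
        ears = simulate_open_pollinated_screen(cfg)
        out = flag_screen_outliers(ears, null_fraction=0.03, alpha=0.05)
        ko = ~out["barrier"]
        assert ko.sum() > 0
        assert (out["flagged"] & ko).sum() == ko.sum()        # sensitivity 1
        assert (out["flagged"] & ~ko).sum() == 0              # no false flags

    def test_bad_null_rejected(self):
        with pytest.raises(ValueError):
            flag_screen_outliers(pd.DataFrame({"ear_id": [], "n_kernels": [],
                                               "n_sugary": []}),
                                 null_fraction=0.0)
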