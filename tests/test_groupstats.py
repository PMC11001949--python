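"""Nonparametric test dispatch, exact permutation p-values, Bonferroni
contrasts and the compact letter display."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seedscape.groupstats import (
    ContrastPlan,
    GroupedSamples,
    bonferroni_contrasts,
    compare_groups,
    friedman,
    kendall_trend,
    kruskal_wallis,
    letter_display,
    mann_whitney,
    omnibus_test,
    significance_from_letters,
    wilcoxon_signed_rank,
)

from _oracles import (
    perm_friedman_p,
    perm_kruskal_p,
    perm_mannwhitney_p,
    perm_wilcoxon_p,
)


class TestDispatch:
    def test_two_unrelated_goes_to_mann_whitney(self):
        gs = GroupedSamples(("a", "b"), ((1, 2), (3, 4)), "unrelated")
        name, stat, _ = omnibus_test(gs)
        assert name == "mann-whitney-u"
        assert stat == 0.0  # complete separation, U of first group

    def test_two_related_goes_to_wilcoxon(self):
        gs = GroupedSamples(("a", "b"), ((1, 2, 3), (2, 4, 5)), "related")
        assert omnibus_test(gs)[0] == "wilcoxon-signed-ranks"

    def test_three_unrelated_goes_to_kruskal(self):
        gs = GroupedSamples(("a", "b", "c"), ((1, 2), (3, 4), (5, 6)))
        name, h, _ = omnibus_test(gs)
        assert name == "kruskal-wallis-h"
        assert h == pytest.approx(4.571, abs=5e-4)  # hand rank-formula value

    def test_three_related_goes_to_friedman(self):
        gs = GroupedSamples(
            ("a", "b", "c"), ((1, 2, 3, 4), (2, 3, 4, 5), (5, 6, 7, 8)), "related"
        )
        assert omnibus_test(gs)[0] == "friedman"

    def test_identical_groups_p_near_one(self):
        gs = GroupedSamples(("a", "b"), ((1, 2, 3), (1, 2, 3)))
        _, _, p = omnibus_test(gs)
        assert p > 0.9

    def test_related_unequal_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            GroupedSamples(("a", "b"), ((1, 2), (1, 2, 3)), "related")

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            GroupedSamples(("a",), ((1, 2),))


class TestExactAgainstPermutationOracle:
    """Exact small-sample p-values must equal full permutation enumeration."""

    @pytest.mark.parametrize("seed, n, m", [(0, 3, 3), (1, 4, 5), (2, 6, 4), (3, 8, 8)])
    def test_mann_whitney_tie_free(self, seed, n, m):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(0.5, 1, size=m)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(perm_mannwhitney_p(x, y), abs=1e-9)

    def test_mann_whitney_with_ties(self):
        x, y = [1, 2, 2, 3], [2, 3, 3, 4]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(perm_mannwhitney_p(x, y), abs=1e-9)

    @pytest.mark.parametrize("seed, n", [(0, 4), (1, 6), (2, 8)])
    def test_wilcoxon(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = x + rng.normal(0.4, 1, size=n)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(perm_wilcoxon_p(x, y), abs=1e-9)

    def test_wilcoxon_with_zero_differences(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 6.0]
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(perm_wilcoxon_p(x, y), abs=1e-9)

    @pytest.mark.parametrize(
        "samples",
        [
            ((1.2, 3.4), (2.2, 0.1), (5.0, 4.4)),
            ((1, 2, 2), (3, 3, 4), (5, 6)),  # ties across groups
        ],
    )
    def test_kruskal_wallis(self, samples):
        _, p = kruskal_wallis(samples)
        assert p == pytest.approx(perm_kruskal_p(samples), abs=1e-9)

    def test_friedman(self):
        samples = ((1.0, 2.5, 3.0, 2.0), (2.0, 1.5, 4.0, 5.0), (3.0, 4.5, 1.0, 6.0))
        _, p = friedman(samples)
        assert p == pytest.approx(perm_friedman_p(samples), abs=1e-9)

    def test_large_samples_fall_back_to_asymptotic(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=60), rng.normal(size=60)
        _, p = mann_whitney(x, y)
        assert 0 <= p <= 1  # asymptotic path exercised without error


class TestBonferroni:
    def test_plan_arithmetic(self):
        assert ContrastPlan(0.05, 6).alpha_adjusted == pytest.approx(0.05 / 6)
        assert ContrastPlan(0.05, 1).alpha_adjusted == 0.05

    def test_four_groups_give_six_contrasts(self):
        rng = np.random.default_rng(0)
        gs = GroupedSamples(
            tuple("abcd"), tuple(tuple(rng.normal(size=4)) for _ in range(4))
        )
        plan, pw = bonferroni_contrasts(gs, alpha=0.05)
        assert plan.k_comparisons == 6 and len(pw) == 6
        assert plan.alpha_adjusted == pytest.approx(0.008333, abs=1e-6)

    def test_two_groups_unadjusted(self):
        gs = GroupedSamples(("a", "b"), ((1, 2), (3, 4)))
        plan, _ = bonferroni_contrasts(gs)
        assert plan.alpha_adjusted == 0.05

    def test_degenerate_pair_flagged(self):
        gs = GroupedSamples(("a", "b"), ((2.0, 2.0), (2.0, 2.0)))
        _, pw = bonferroni_contrasts(gs)
        assert pw.loc[0, "degenerate"] and pw.loc[0, "p_value"] == 1.0

    def test_well_separated_groups_all_distinct_letters(self):
        # large separations, 8 replicates per group: every pair significant
        rng = np.random.default_rng(1)
        gs = GroupedSamples(
            tuple("abcd"),
            tuple(tuple(10 * i + rng.normal(size=8) * 0.1) for i in range(4)),
        )
        res = compare_groups(gs, alpha=0.05)
        assert sorted(res.letters.values()) == ["a", "b", "c", "d"]


class TestLetterDisplay:
    @staticmethod
    def pairwise_from_bits(groups, bits):
        pairs = list(itertools.combinations(groups, 2))
        return pd.DataFrame(
            [{"group_a": a, "group_b": b, "significant": s}
             for (a, b), s in zip(pairs, bits)]
        )

    def test_no_pairs_significant_single_letter(self):
        pw = self.pairwise_from_bits("abcd", [False] * 6)
        assert set(letter_display(list("abcd"), pw).values()) == {"a"}

    def test_partial_pattern(self):
        # only (g1, g3) significant -> a, ab, b
        pw = self.pairwise_from_bits(["g1", "g2", "g3"], [False, True, False])
        assert letter_display(["g1", "g2", "g3"], pw) == {
            "g1": "a", "g2": "ab", "g3": "b"
        }

    def test_incomplete_matrix_rejected(self):
        pw = self.pairwise_from_bits(["g1", "g2", "g3"], [False, True, False]).iloc[:2]
        with pytest.raises(ValueError, match="every unordered pair"):
            letter_display(["g1", "g2", "g3"], pw)

    def test_inconsistent_matrix_rejected(self):
        pw = pd.DataFrame(
            [
                {"group_a": "a", "group_b": "b", "significant": True},
                {"group_a": "b", "group_b": "a", "significant": False},
            ]
        )
        with pytest.raises(ValueError, match="inconsistent"):
            letter_display(["a", "b"], pw)

    @given(st.integers(2, 5), st.integers(0, 2**10 - 1))
    @settings(max_examples=150, deadline=None)
    def test_round_trip_reconstructs_matrix(self, k, bitmask):
        groups = [f"g{i}" for i in range(k)]
        n_pairs = k * (k - 1) // 2
        bits = [(bitmask >> i) & 1 == 1 for i in range(n_pairs)]
        pw = self.pairwise_from_bits(groups, bits)
        letters = letter_display(groups, pw)
        rebuilt = significance_from_letters(letters)
        for (a, b), sig in zip(itertools.combinations(groups, 2), bits):
            assert rebuilt[frozenset((a, b))] == sig


class TestKendall:
    def test_monotone_series(self):
        tau, _ = kendall_trend([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert tau == pytest.approx(1.0)
        tau, _ = kendall_trend([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert tau == pytest.approx(-1.0)

    def test_hand_counted_example(self):
        # pairs: 1 concordant, 2 discordant -> tau = -1/3
        tau, _ = kendall_trend([1, 2, 3], [3, 1, 2])
        assert tau == pytest.approx(-1 / 3)

    def test_constant_series_undefined(self):
        tau, p = kendall_trend([1, 2, 3, 4], [5, 5, 5, 5])
        assert np.isnan(tau) and np.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kendall_trend([1, 2], [1, 2])
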