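"""Unit tests for the exact binomial tests and the scenario classifier."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retromark import (
    MarkerCounts,
    binom_tail,
    classify_scenario,
    compare_top_two,
    critical_boundaries,
    sl_asymmetry,
    sl_bifurcation,
    sl_one_directional,
)
from retromark.markers import MULTI, ONE
from retromark.markers import TestConfig as SignificanceConfig


def brute_tail(k_min, n, p):
    """Independent oracle: direct summation of the binomial upper tail."""
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(k_min, n + 1))


class TestBinomTail:
    @pytest.mark.parametrize(
        "k,n,p,expected",
        [
            (0, 17, 0.3, 1.0),                       # whole sample space
            (4, 4, 1 / 3, (1 / 3) ** 4),             # all successes
            (8, 13, 0.5, 2380 / 8192),               # brute-force frozen value
            (3, 3, 1 / 3, 3.0 ** -3),
        ],
    )
    def test_known_values(self, k, n, p, expected):
        assert binom_tail(k, n, p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [1 / 3, 0.5, 0.123])
    def test_matches_direct_summation(self, p):
        for n in range(1, 26):
            for k in range(n + 1):
                assert binom_tail(k, n, p) == pytest.approx(brute_tail(k, n, p), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binom_tail(5, 4, 0.5)
        with pytest.raises(ValueError):
            binom_tail(-1, 4, 0.5)
        with pytest.raises(ValueError):
            binom_tail(1, 4, 1.5)


class TestBifurcation:
    @pytest.mark.parametrize(
        "ys,expected",
        [
            ((3, 1, 0), 9 / 81),            # conflict pattern, p = 0.111
            ((8, 2, 0), 201 / 59049),       # rodent pattern, p = 0.0034
            ((3, 0, 0), 3.0 ** -3),
            ((7, 0, 0), 3.0 ** -7),
        ],
    )
    def test_known_values(self, ys, expected):
        counts = MarkerCounts(*ys)
        assert sl_bifurcation(counts) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_winning_count(self):
        n = 30
        tails = [binom_tail(y, n, 1 / 3) for y in range(1, n + 1)]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_refuses_one_directional_counts(self):
        counts = MarkerCounts(5, 2, None, mode=ONE, reference_lineage="A")
        with pytest.raises(ValueError, match="one-directional"):
            sl_bifurcation(counts)


class TestAsymmetry:
    def test_placental_root_value(self):
        # two smallest counts of the (9:8:5) placental-root pattern
        assert sl_asymmetry(8, 5) == pytest.approx(4760 / 8192, abs=1e-12)
        assert round(sl_asymmetry(8, 5), 4) == 0.5811

    @pytest.mark.parametrize("k", [0, 1, 7, 30])
    def test_equal_counts_give_one(self, k):
        assert sl_asymmetry(k, k) == 1.0

    def test_one_sided_extreme(self):
        assert sl_asymmetry(6, 0) == pytest.approx(2 * 2.0 ** -6, abs=1e-15)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 50), st.integers(0, 50))
    def test_symmetric_and_bounded(self, a, b):
        p = sl_asymmetry(a, b)
        assert p == sl_asymmetry(b, a)
        assert 0.0 < p <= 1.0
        if a == b:
            assert p == 1.0

    def test_cap_at_one(self):
        # doubling can exceed 1 for tiny imbalanced counts
        assert sl_asymmetry(1, 0) == 1.0


class TestOneDirectional:
    @pytest.mark.parametrize(
        "hi,lo,expected",
        [(5, 0, 2.0 ** -5), (1, 0, 0.5), (4, 4, 1.0), (0, 0, 1.0)],
    )
    def test_known_values(self, hi, lo, expected):
        assert sl_one_directional(hi, lo) == pytest.approx(expected, abs=1e-12)

    def test_requires_ordered_arguments(self):
        with pytest.raises(ValueError):
            sl_one_directional(2, 5)


class TestCompareTopTwo:
    def test_dominant_top_count(self):
        counts = MarkerCounts(101, 11, 0)
        assert compare_top_two(counts) < 0.001

    def test_tied_top_counts(self):
        assert compare_top_two(MarkerCounts(6, 6, 0)) == 1.0

    def test_carnivore_two_smaller_counts_not_asymmetric(self):
        assert sl_asymmetry(74, 60) > 0.2


class TestCriticalBoundaries:
    def test_three_marker_minimum_multi(self):
        assert critical_boundaries(3, 0.05, "bifurcation") == 3
        assert critical_boundaries(2, 0.05, "bifurcation") is None

    def test_five_marker_minimum_one_directional(self):
        assert critical_boundaries(5, 0.05, "one_directional") == 5
        assert critical_boundaries(4, 0.05, "one_directional") is None

    def test_asymmetry_unattainable_for_tiny_sums(self):
        # (2:0) cannot reach significance: critical value cannot be calculated
        assert critical_boundaries(2, 0.05, "asymmetry") is None
        assert critical_boundaries(6, 0.05, "asymmetry") == 6

    def test_monotone_in_n(self):
        for which in ("bifurcation", "one_directional"):
            crits = [critical_boundaries(n, 0.05, which) for n in range(3, 40)]
            crits = [c for c in crits if c is not None]
            assert all(a <= b for a, b in zip(crits, crits[1:]))

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            critical_boundaries(10, 1.2, "bifurcation")


class TestClassifyScenario:
    def test_placental_root_is_polytomy(self):
        out = classify_scenario(MarkerCounts(9, 8, 5))
        assert out.scenario == "polytomy"
        assert round(out.p_bifurcation, 3) == 0.293
        assert round(out.p_asymmetry, 4) == 0.5811

    def test_rodent_pattern_is_tree_without_hybridization(self):
        out = classify_scenario(
            MarkerCounts(8, 2, 0, label_a="mouse", label_b="guinea pig", label_c="squirrel")
        )
        assert out.scenario == "tree"
        assert round(out.p_bifurcation, 4) == 0.0034
        assert out.supported_pair == ("mouse", "guinea pig")
        assert out.p_asymmetry > 0.05
        # too few conflicting markers: asymmetry critical cannot be calculated
        assert out.critical_diff_05 is None

    def test_nishihara_pattern_is_polytomy(self):
        assert classify_scenario(MarkerCounts(25, 22, 21)).scenario == "polytomy"

    def test_carnivore_pattern_is_strong_tree(self):
        out = classify_scenario(MarkerCounts(192, 74, 60))
        assert out.scenario == "tree"
        assert out.p_bifurcation < 3.3e-21
        assert out.p_asymmetry > 0.2

    def test_tree_with_hybridization_signal(self):
        out = classify_scenario(MarkerCounts(101, 11, 0))
        assert out.scenario == "tree_with_hybridization_signal"
        assert out.p_asymmetry < 0.001
        assert out.supported_pair == ("A", "B")
        assert out.hybrid_lineage == "A"

    def test_hybridization_when_top_pair_indistinguishable(self):
        out = classify_scenario(MarkerCounts(20, 18, 2))
        assert out.scenario == "hybridization"
        # larger-count pairs are AB and AC: the shared lineage A is the hybrid
        assert out.hybrid_lineage == "A"

    def test_tie_for_largest_count_warns(self):
        out = classify_scenario(MarkerCounts(15, 15, 0))
        assert out.scenario == "hybridization"
        assert any("tie" in w for w in out.warnings)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="no informative markers"):
            classify_scenario(MarkerCounts(0, 0, 0))

    def test_one_directional_outcome(self):
        counts = MarkerCounts(4, 0, None, mode=ONE, reference_lineage="A")
        out = classify_scenario(counts)
        assert out.scenario == "undetermined_one_directional"
        assert out.p_one_directional == pytest.approx(2.0 ** -4)
        assert out.supported_pair is None  # 0.0625 > 0.05
        assert len(out.warnings) >= 2

    def test_one_directional_significant(self):
        counts = MarkerCounts(6, 0, None, mode=ONE, reference_lineage="A")
        out = classify_scenario(counts)
        assert out.supported_pair == ("A", "B")
        assert out.p_one_directional <= 0.05

    def test_alpha_changes_call(self):
        counts = MarkerCounts(4, 0, 0)  # p_bif = 1/81 + small tail
        strict = classify_scenario(counts, SignificanceConfig(alpha=0.001))
        loose = classify_scenario(counts, SignificanceConfig(alpha=0.05))
        assert loose.scenario == "tree"
        assert strict.scenario == "polytomy"


class TestMarkerCountsValidation:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            MarkerCounts(3, -1, 0)

    def test_one_directional_missing_slot_enforced(self):
        with pytest.raises(ValueError):
            MarkerCounts(3, 2, 1, mode=ONE, reference_lineage="A")
        # unobserved stored as missing, never zero
        counts = MarkerCounts(3, 2, None, mode=ONE, reference_lineage="A")
        assert counts.n == 5

    def test_multi_requires_all_counts(self):
        with pytest.raises(ValueError):
            MarkerCounts(3, 2, None, mode=MULTI)
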