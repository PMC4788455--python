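"""Exact binomial significance tests for marker-count triplets.

All tests reduce to upper tails of binomial distributions, evaluated through
the regularized incomplete beta function::

    P(X >= k | X ~ Binom(n, p)) = I_p(k, n - k + 1)

Three tests are available:

* **bifurcation** — is the largest sharing count significantly above the
  polytomy expectation n/3?  Rejecting the null (all pattern probabilities
  equal, or the winning one at most 1/3) supports a resolved internal branch.
* **asymmetry** — are the two smallest counts significantly unequal?  Under
  any bifurcating tree or polytomy the two discordant categories are
  exchangeable (incomplete lineage sorting is symmetric), so a significant
  two-sided imbalance signals ancestral hybridization.
* **one-directional** — a fair-coin comparison of the only two observable
  counts when markers were ascertained from a single reference genome.

``classify_scenario`` combines the tests into the scenario decision rule.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.special import betainc

from .markers import (
    HYBRIDIZATION,
    MULTI,
    POLYTOMY,
    TREE,
    TREE_WITH_HYBRIDIZATION,
    UNDETERMINED_ONE_DIR,
    MarkerCounts,
    TestConfig,
    TestOutcome,
)

__all__ = [
    "binom_tail",
    "sl_bifurcation",
    "sl_asymmetry",
    "sl_one_directional",
    "compare_top_two",
    "classify_scenario",
    "critical_boundaries",
]

ONE_DIR_CAVEATS = [
    "one-directional screen: the tree topology not involving the reference "
    "lineage cannot be tested",
    "one-directional screen: the hybridization probability cannot be calculated",
    "a significant one-directional difference does not distinguish a "
    "bifurcated tree from hybridization",
]


def _check_count(name: str, value) -> int:
    if value is None or int(value) != value or value < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    return int(value)


def binom_tail(k_min: int, n_trials: int, p: float) -> float:
    """Upper binomial tail P(X >= k_min) for X ~ Binom(n_trials, p).

    Uses the identity with the regularized incomplete beta function,
    ``I_p(k_min, n_trials - k_min + 1)``; exact to floating precision.
    """
    k_min = _check_count("k_min", k_min)
    n_trials = _check_count("n_trials", n_trials)
    if k_min > n_trials:
        raise ValueError(f"k_min={k_min} exceeds n_trials={n_trials}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if k_min == 0:
        return 1.0
    return float(betainc(k_min, n_trials - k_min + 1, p))


def sl_bifurcation(counts: MarkerCounts, winning_index: Optional[int] = None) -> float:
    """Significance level of the bifurcation-vs-polytomy test.

    The winning count Y (default: the largest of the triplet) is compared to
    the total n; the level is ``max_{p<=1/3} P(eta >= Y) = I_{1/3}(Y, n-Y+1)``.
    Only defined for multi-directional counts.
    """
    if counts.mode != MULTI:
        raise ValueError(
            "bifurcation test is undefined for one-directional counts; "
            "use sl_one_directional"
        )
    ys = counts.values
    if winning_index is None:
        y_win = max(ys)
    else:
        if winning_index not in (1, 2, 3):
            raise ValueError("winning_index must be 1, 2 or 3")
        y_win = ys[winning_index - 1]
    return binom_tail(y_win, counts.n, 1.0 / 3.0)


def sl_asymmetry(y_small_a: int, y_small_b: int) -> float:
    """Two-sided symmetry test on the two smallest counts of a triplet.

    Under the exchangeability null the conditional distribution of either
    count given their sum is Binom(sum, 1/2); the two-sided level is
    ``2 * I_{1/2}(max, min + 1)``, capped at 1, and exactly 1 when the counts
    are equal.  Rejection signals hybridization-type asymmetry.
    """
    a = _check_count("y_small_a", y_small_a)
    b = _check_count("y_small_b", y_small_b)
    if a == b:
        return 1.0
    hi, lo = max(a, b), min(a, b)
    return min(1.0, 2.0 * binom_tail(hi, hi + lo, 0.5))


def sl_one_directional(y_larger: int, y_smaller: int) -> float:
    """One-directional comparison of the two observable sharing counts.

    Returns ``P(Binom(y_larger + y_smaller, 1/2) >= y_larger)``; equals 1
    when the counts are equal (the null is certainly accepted).  A
    significant result cannot distinguish a bifurcating tree from
    hybridization.
    """
    hi = _check_count("y_larger", y_larger)
    lo = _check_count("y_smaller", y_smaller)
    if hi < lo:
        raise ValueError("y_larger must be >= y_smaller")
    if hi == lo:
        return 1.0
    return binom_tail(hi, hi + lo, 0.5)


def compare_top_two(counts: MarkerCounts) -> float:
    """One-sided comparison of the two largest counts of a triplet.

    Used to separate *hybridization* (top two counts statistically
    indistinguishable) from a *tree with hybridization signal* (the top count
    dominates).
    """
    if counts.mode != MULTI:
        raise ValueError("compare_top_two requires multi-directional counts")
    top, second, _ = sorted(counts.values, reverse=True)
    return sl_one_directional(top, second)


def critical_boundaries(n: int, alpha: float, which: str) -> Optional[int]:
    """Smallest count (or count difference) reaching significance at ``alpha``.

    Parameters
    ----------
    n
        Total marker count (bifurcation) or pair-sum (asymmetry,
        one_directional).
    which
        ``"bifurcation"``: smallest Y with ``I_{1/3}(Y, n-Y+1) <= alpha``.
        ``"one_directional"``: smallest Y with ``I_{1/2}(Y, n-Y+1) <= alpha``.
        ``"asymmetry"``: smallest *realizable* difference d such that the
        split of the fixed sum n with that difference is significant in the
        two-sided symmetry test.  Only differences with the parity of n are
        realizable by integer splits, so the search steps through those.

    Returns ``None`` when no count within range is significant (the web-style
    report then states that the critical value cannot be calculated).
    """
    n = _check_count("n", n)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n == 0:
        return None
    if which in ("bifurcation", "one_directional"):
        p = 1.0 / 3.0 if which == "bifurcation" else 0.5
        ys = np.arange(1, n + 1)
        tails = betainc(ys, n - ys + 1, p)
        hits = np.nonzero(tails <= alpha)[0]
        return int(ys[hits[0]]) if hits.size else None
    if which == "asymmetry":
        start = 2 if n % 2 == 0 else 1
        for d in range(start, n + 1, 2):
            hi = (n + d) // 2
            lo = n - hi
            if sl_asymmetry(hi, lo) <= alpha:
                return d
        return None
    raise ValueError(f"unknown test type {which!r}")


def _hybrid_lineage(counts: MarkerCounts, smallest_pair: tuple[str, str]) -> str:
    """Lineage shared by the two larger-count pairs.

    Equivalently, the lineage absent from the smallest-count pair: under a
    fusion scenario the sharing category that excludes the hybrid lineage's
    two parents jointly is the rarest.
    """
    labels = {counts.label_a, counts.label_b, counts.label_c}
    (absent,) = labels - set(smallest_pair)
    return absent


def _classify_multi(counts: MarkerCounts, config: TestConfig) -> TestOutcome:
    n = counts.n
    ranked = sorted(counts.observed_pairs, key=lambda item: item[0], reverse=True)
    (y0, pair0), (y1, pair1), (y2, pair2) = ranked
    tie_top = y0 == y1

    p_bif = binom_tail(y0, n, 1.0 / 3.0)
    p_asym = sl_asymmetry(y1, y2)
    p_top = sl_one_directional(y0, y1)

    alpha = config.alpha
    warnings: list[str] = []
    supported_pair = None
    hybrid = None

    if p_asym > alpha:
        if p_bif <= alpha and not tie_top:
            scenario = TREE
            supported_pair = pair0
        else:
            scenario = POLYTOMY
            if p_bif <= alpha and tie_top:
                warnings.append(
                    "largest count significant against polytomy but tied: "
                    "no unique tree can be called"
                )
    else:
        if tie_top or p_top > alpha:
            scenario = HYBRIDIZATION
            hybrid = _hybrid_lineage(counts, pair2)
            if tie_top:
                warnings.append("two largest counts tied: no unique tree")
        elif p_bif <= alpha:
            scenario = TREE_WITH_HYBRIDIZATION
            supported_pair = pair0
            hybrid = _hybrid_lineage(counts, pair2)
        else:
            scenario = HYBRIDIZATION
            hybrid = _hybrid_lineage(counts, pair2)
            warnings.append(
                "top pair dominates its runner-up but the largest count is "
                "not significant against the total; treating as hybridization"
            )
    if tie_top:
        warnings.append("tie for the largest count: tree topology ambiguous")

    pair_sum = y1 + y2
    return TestOutcome(
        scenario=scenario,
        p_bifurcation=p_bif,
        p_asymmetry=p_asym,
        p_top_pair=p_top,
        supported_pair=supported_pair,
        hybrid_lineage=hybrid,
        critical_y1_05=critical_boundaries(n, 0.05, "bifurcation"),
        critical_y1_01=critical_boundaries(n, 0.01, "bifurcation"),
        critical_diff_05=critical_boundaries(pair_sum, 0.05, "asymmetry"),
        critical_diff_01=critical_boundaries(pair_sum, 0.01, "asymmetry"),
        warnings=warnings,
    )


def _classify_one_directional(counts: MarkerCounts, config: TestConfig) -> TestOutcome:
    observed = counts.observed_pairs
    (ya, pair_a), (yb, pair_b) = observed
    if ya >= yb:
        hi, lo, hi_pair = ya, yb, pair_a
    else:
        hi, lo, hi_pair = yb, ya, pair_b
    p = sl_one_directional(hi, lo)
    supported = hi_pair if p <= config.alpha else None
    pair_sum = hi + lo
    return TestOutcome(
        scenario=UNDETERMINED_ONE_DIR,
        p_one_directional=p,
        supported_pair=supported,
        critical_y1_05=critical_boundaries(pair_sum, 0.05, "one_directional"),
        critical_y1_01=critical_boundaries(pair_sum, 0.01, "one_directional"),
        warnings=list(ONE_DIR_CAVEATS),
    )


def classify_scenario(counts: MarkerCounts, config: TestConfig = TestConfig()) -> TestOutcome:
    """Run all applicable exact tests and call the evolutionary scenario.

    Multi-directional decision rule at level alpha:

    * ``tree`` — bifurcation test significant, asymmetry test not;
    * ``polytomy`` — neither test significant (polytomy cannot be rejected);
    * ``hybridization`` — asymmetry significant and the two largest counts
      statistically indistinguishable;
    * ``tree_with_hybridization_signal`` — bifurcation and asymmetry both
      significant and the top count dominates its runner-up.

    One-directional counts only admit the pairwise comparison; the scenario
    is reported as undetermined with fixed caveats.

    Raises ``ValueError`` when all observed counts are zero (no informative
    markers).
    """
    if counts.n == 0:
        raise ValueError("no informative markers: all observed counts are zero")
    if counts.mode == MULTI:
        return _classify_multi(counts, config)
    return _classify_one_directional(counts, config)
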