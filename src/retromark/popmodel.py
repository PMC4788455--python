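"""Neutral-drift probability model for three-lineage insertion patterns.

The model follows a Wright-Fisher population of constant size through two
successive splits.  Insertions arise neutrally, one locus each, at rate
``n0`` per generation in the ancestral population and ``n1`` on the internal
branch between the splits, and each eventually fixes or is lost.  Among the
*informative* loci (present in exactly two of the three lineages) the
probability that a locus supports the true sister pair of a resolved
"C-tree" ((A,B),C) is

    p1 = 1 - (2/3) * Psi(tau),    p2 = p3 = (1/3) * Psi(tau)

where ``tau = T1 / (2 N1)`` is the drift time of the internal branch (length
``T1`` generations, ``N1`` diploid individuals) and

    Psi(tau) = exp(-tau) / (1 + (n1/n0) * (tau + exp(-tau) - 1)).

``Psi`` decreases from 1 at ``tau = 0`` (instantaneous second split: the
hallmark 1/3:1/3:1/3 polytomy pattern of incomplete lineage sorting) towards
0 for long internal branches (all informative markers concordant).  With
equal insertion rates (``n1/n0 = 1``) the discordance probability
``(2/3) * Psi`` reduces to the classical coalescent expression.

A hybrid (fusion) origin of the middle lineage instead predicts that the
sharing category pairing the two *parental* lineages is strictly the rarest
(``p1 > p2`` and ``p3 > p2`` for a B-fusion); only this inequality signature
is modelled here, not a closed form for the fusion probabilities.

Counts are multinomial given the pattern probabilities, so the winning count
is a binomial sufficient statistic for ``p1``; drift-time estimation inverts
the monotone map ``tau -> p1`` and transports exact Clopper-Pearson binomial
confidence bounds on ``p1`` through it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist
from scipy.stats import multinomial

from .markers import MULTI, MarkerCounts

__all__ = [
    "DriftParameters",
    "TreeProbabilities",
    "FusionParameters",
    "DriftEstimate",
    "psi",
    "tree_probabilities",
    "pattern_log_likelihood",
    "fusion_consistency",
    "invert_winning_probability",
    "estimate_drift_time",
]

# bisection domain for tau; Psi is far below resolvable probabilities beyond this
TAU_MAX = 50.0
PSI_FLOOR = 1e-20


@dataclass(frozen=True)
class DriftParameters:
    """Drift time and insertion-rate ratio of the internal branch.

    ``tau`` is in units of 2*N1 generations; ``rate_ratio`` is n1/n0, the
    internal-branch over ancestral insertion rate.  ``N1``/``T1`` are
    optional and, when both are given, must satisfy ``tau = T1 / (2 N1)``.
    """

    tau: float
    rate_ratio: float = 1.0
    N1: Optional[float] = None
    T1: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.rate_ratio < 0:
            raise ValueError(f"rate_ratio must be >= 0, got {self.rate_ratio}")
        if self.N1 is not None and self.T1 is not None:
            implied = self.T1 / (2.0 * self.N1)
            if not math.isclose(implied, self.tau, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    f"inconsistent parameters: T1/(2 N1) = {implied} != tau = {self.tau}"
                )

    @classmethod
    def from_census(cls, T1: float, N1: float, rate_ratio: float = 1.0) -> "DriftParameters":
        return cls(tau=T1 / (2.0 * N1), rate_ratio=rate_ratio, N1=N1, T1=T1)


@dataclass(frozen=True)
class TreeProbabilities:
    """Pattern probabilities (p1, p2, p3) among informative loci."""

    p1: float
    p2: float
    p3: float
    scenario: str = "C-tree"

    def __post_init__(self) -> None:
        ps = (self.p1, self.p2, self.p3)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in ps):
            raise ValueError(f"probabilities outside [0, 1]: {ps}")
        if abs(sum(ps) - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {sum(ps)}")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3])


@dataclass(frozen=True)
class FusionParameters:
    """Admixture proportions of the two parental populations of a hybrid."""

    gamma1: float
    gamma2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma1 <= 1.0 and 0.0 <= self.gamma2 <= 1.0):
            raise ValueError("admixture proportions must lie in [0, 1]")
        if abs(self.gamma1 + self.gamma2 - 1.0) > 1e-12:
            raise ValueError("gamma1 + gamma2 must equal 1")


@dataclass(frozen=True)
class DriftEstimate:
    """Point estimate and confidence interval for the drift time tau."""

    tau_hat: float
    ci_low: float
    ci_high: float
    conf_level: float
    p1_hat: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.tau_hat:
            raise ValueError("interval must satisfy 0 <= ci_low <= tau_hat")
        if self.tau_hat > self.ci_high:
            raise ValueError("interval must satisfy tau_hat <= ci_high")


def psi(tau: float, rate_ratio: float = 1.0) -> float:
    """Drift-time kernel Psi(tau) = e^(-tau) / (1 + r (tau + e^(-tau) - 1)).

    Strictly decreasing from Psi(0) = 1; ``rate_ratio`` r = n1/n0 weights the
    contribution of internal-branch insertions.  r = 0 gives the
    standing-variation-only limit e^(-tau).
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if rate_ratio < 0:
        raise ValueError(f"rate_ratio must be >= 0, got {rate_ratio}")
    value = math.exp(-tau) / (1.0 + rate_ratio * (tau + math.exp(-tau) - 1.0))
    return 0.0 if value < PSI_FLOOR else value


def tree_probabilities(params: DriftParameters, topology: str = "C") -> TreeProbabilities:
    """Pattern probabilities under a resolved tree or polytomy.

    ``topology`` names the outgroup lineage of the resolved tree ("C" means
    (A,B),C so the AB-sharing category wins) or ``"polytomy"``.
    """
    if topology == "polytomy":
        third = 1.0 / 3.0
        return TreeProbabilities(third, third, third, scenario="polytomy")
    if topology not in ("A", "B", "C"):
        raise ValueError(f"topology must be A, B, C or polytomy, got {topology!r}")
    psi_val = psi(params.tau, params.rate_ratio)
    win = 1.0 - (2.0 / 3.0) * psi_val
    lose = psi_val / 3.0
    if topology == "C":  # (A,B),C : AB category wins
        ps = (win, lose, lose)
    elif topology == "B":  # (A,C),B : AC category wins
        ps = (lose, win, lose)
    else:  # (B,C),A : BC category wins
        ps = (lose, lose, win)
    return TreeProbabilities(*ps, scenario=f"{topology}-tree")


def pattern_log_likelihood(counts: MarkerCounts, probs: TreeProbabilities) -> float:
    """Multinomial log-likelihood of an observed triplet under given probabilities.

    Returns ``-inf`` when a category with zero probability has a nonzero
    count.
    """
    if counts.mode != MULTI:
        raise ValueError("pattern likelihood requires multi-directional counts")
    ys = np.array(counts.values)
    ps = probs.as_array
    bad = (ps == 0) & (ys > 0)
    if bad.any():
        return float("-inf")
    # renormalise away zero-probability empty categories for scipy
    keep = ps > 0
    return float(multinomial.logpmf(ys[keep], n=int(ys[keep].sum()), p=ps[keep] / ps[keep].sum()))


def fusion_consistency(
    values: Union[TreeProbabilities, MarkerCounts, Sequence[float]],
) -> Optional[str]:
    """Classify an ordering signature as a fusion class, or ``None``.

    A hybrid origin of one lineage makes the sharing category pairing its two
    parents strictly the rarest: ``b_fusion`` when the middle (AC) category
    is the strict minimum, ``c_fusion`` when AB is, ``a_fusion`` when BC is.
    Ties for the minimum (tree- or polytomy-like shapes) return ``None``.
    Accepts pattern probabilities, marker counts, or any length-3 sequence.
    """
    if isinstance(values, TreeProbabilities):
        v = list(values.as_array)
    elif isinstance(values, MarkerCounts):
        v = list(values.values)
    else:
        v = list(values)
        if len(v) != 3:
            raise ValueError("expected exactly three values")
    order = np.argsort(v)
    lo, mid = v[order[0]], v[order[1]]
    if lo == mid:
        return None
    return {0: "c_fusion", 1: "b_fusion", 2: "a_fusion"}[int(order[0])]


def invert_winning_probability(p1: float, rate_ratio: float = 1.0) -> float:
    """Solve ``1 - (2/3) Psi(tau) = p1`` for tau (monotone inversion).

    Returns 0 for ``p1 <= 1/3`` (polytomy boundary) and ``inf`` when ``p1``
    is so close to 1 that the required Psi lies below the numerical floor.
    """
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"p1 must lie in [0, 1], got {p1}")
    target = 1.5 * (1.0 - p1)  # required value of Psi(tau)
    if target >= 1.0:
        return 0.0
    if target <= psi(TAU_MAX, rate_ratio):
        return float("inf")
    return float(brentq(lambda t: psi(t, rate_ratio) - target, 0.0, TAU_MAX, xtol=1e-10))


def estimate_drift_time(
    counts: MarkerCounts,
    rate_ratio: float = 1.0,
    conf_level: float = 0.95,
) -> DriftEstimate:
    """Drift-time estimate for the internal branch from a marker triplet.

    The winning (largest) count Y out of n is binomial with success
    probability p1; ``tau_hat`` inverts ``p1(tau)`` at ``p1_hat = Y/n`` (0
    when the observed fraction does not exceed 1/3).  The confidence interval
    maps exact Clopper-Pearson bounds for p1 through the same monotone
    inversion; the upper bound is infinite when the p1 interval reaches 1.
    """
    if counts.mode != MULTI:
        raise ValueError("drift-time estimation requires multi-directional counts")
    if rate_ratio <= 0:
        raise ValueError(f"rate_ratio must be > 0, got {rate_ratio}")
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must lie in (0, 1), got {conf_level}")
    n = counts.n
    if n == 0:
        raise ValueError("no informative markers: cannot estimate drift time")
    y = max(counts.values)
    p1_hat = y / n
    a = 1.0 - conf_level
    p_low = 0.0 if y == 0 else float(beta_dist.ppf(a / 2.0, y, n - y + 1))
    p_high = 1.0 if y == n else float(beta_dist.ppf(1.0 - a / 2.0, y + 1, n - y))
    return DriftEstimate(
        tau_hat=invert_winning_probability(p1_hat, rate_ratio),
        ci_low=invert_winning_probability(p_low, rate_ratio),
        ci_high=invert_winning_probability(p_high, rate_ratio),
        conf_level=conf_level,
        p1_hat=p1_hat,
    )
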