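"""Forward-time Wright-Fisher simulation of neutral insertion loci.

Each locus is an independent biallelic site (free recombination) in diploid
populations of ``n_diploid`` individuals (2N chromosomes).  New insertion
loci appear as Poisson events per generation, each on a single uniformly
chosen chromosome (initial frequency 1/(2N)), and evolve by binomial
resampling of the allele count each generation.  Insertions are
irreversible: once fixed a locus stays fixed.

Three scenarios are simulated (the middle lineage of the triplet is B):

* ``c_tree`` — the ancestral population splits into the (A,B) ancestor and
  C; the internal branch runs for ``internal_branch_gens`` generations with
  insertion rate ``insertion_rate_internal`` before the A/B split.
* ``polytomy`` — all three lineages split simultaneously
  (``internal_branch_gens`` is ignored and treated as 0).
* ``b_fusion`` — the ancestor splits into the two parental populations of A
  and C; after ``internal_branch_gens`` generations lineage B is founded by
  blending their allele frequencies with weights ``gamma1``/``1 - gamma1``.
  Insertions arising in the parental populations between split and fusion
  are ignored (only ancestral standing variation is tracked), so the
  analytic standing-variation limit (rate ratio 0) applies.

After ``terminal_gens`` generations on the terminal branches each locus is
scored fixed or lost per lineage; loci fixed in exactly two lineages are
tallied into the sharing counts (y_ab, y_ac, y_bc) and loci still
polymorphic anywhere are counted as residual and excluded.

The companion experiment helpers draw multinomial marker triplets directly
from the scenario's analytic pattern probabilities to measure test error
rates and drift-time interval coverage at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exact import binom_tail, sl_asymmetry
from .markers import MULTI, MarkerCounts
from .popmodel import DriftParameters, TreeProbabilities, estimate_drift_time, tree_probabilities

__all__ = [
    "SimulationConfig",
    "SimulatedCounts",
    "simulate_counts",
    "empirical_probabilities",
    "results_frame",
    "type_one_error_experiment",
    "ci_coverage_experiment",
    "ExperimentResult",
]

SCENARIOS = ("c_tree", "polytomy", "b_fusion")


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one batch of forward simulations.

    ``burn_in_gens`` defaults to 8N and ``terminal_gens`` to 20N; the former
    lets the ancestral standing variation reach insertion-drift equilibrium,
    the latter lets essentially every locus fix or be lost before scoring.
    Insertion rates are expected new loci per generation; they only scale
    the number of loci tracked, not the per-locus dynamics.
    """

    n_diploid: int = 100
    internal_branch_gens: int = 200
    insertion_rate_ancestral: float = 10.0
    insertion_rate_internal: float = 10.0
    burn_in_gens: Optional[int] = None
    terminal_gens: Optional[int] = None
    scenario: str = "c_tree"
    gamma1: float = 0.5
    seed: int = 0
    replicates: int = 100

    def __post_init__(self) -> None:
        if self.n_diploid < 1:
            raise ValueError("n_diploid must be a positive integer")
        if self.internal_branch_gens < 0:
            raise ValueError("internal_branch_gens must be >= 0")
        if self.insertion_rate_ancestral <= 0:
            raise ValueError("insertion_rate_ancestral must be > 0")
        if self.insertion_rate_internal < 0:
            raise ValueError("insertion_rate_internal must be >= 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if not 0.0 <= self.gamma1 <= 1.0:
            raise ValueError("gamma1 must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def two_n(self) -> int:
        return 2 * self.n_diploid

    @property
    def burn_in(self) -> int:
        return 8 * self.n_diploid if self.burn_in_gens is None else self.burn_in_gens

    @property
    def terminal(self) -> int:
        return 20 * self.n_diploid if self.terminal_gens is None else self.terminal_gens

    @property
    def realized_tau(self) -> float:
        return self.internal_branch_gens / (2.0 * self.n_diploid)

    @property
    def rate_ratio(self) -> float:
        return self.insertion_rate_internal / self.insertion_rate_ancestral

    def analytic_probabilities(self) -> TreeProbabilities:
        """Pattern probabilities the analytic model predicts for this config."""
        if self.scenario == "polytomy":
            return tree_probabilities(DriftParameters(0.0), "polytomy")
        if self.scenario == "c_tree":
            params = DriftParameters(self.realized_tau, self.rate_ratio)
            return tree_probabilities(params, "C")
        raise ValueError("no closed-form pattern probabilities for fusion scenarios")


@dataclass(frozen=True)
class SimulatedCounts:
    """Sharing counts from one replicate plus bookkeeping."""

    y1: int  # shared by A and B
    y2: int  # shared by A and C
    y3: int  # shared by B and C
    n_residual_polymorphic: int
    realized_tau: float

    @property
    def n(self) -> int:
        return self.y1 + self.y2 + self.y3


def _drift_step(rng: np.random.Generator, counts: np.ndarray, two_n: int) -> np.ndarray:
    """One generation of binomial resampling of allele counts (in place-ish)."""
    return rng.binomial(two_n, counts / two_n)


def _evolve_ancestral(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Burn-in of the ancestral population; returns segregating allele counts.

    Loci fixed during burn-in would be present in all three lineages
    (phylogenetically uninformative) and are dropped along with lost loci.
    """
    two_n = cfg.two_n
    counts = np.empty(0, dtype=np.int64)
    for _ in range(cfg.burn_in):
        k = rng.poisson(cfg.insertion_rate_ancestral)
        if k:
            counts = np.concatenate([counts, np.ones(k, dtype=np.int64)])
        counts = _drift_step(rng, counts, two_n)
        counts = counts[(counts > 0) & (counts < two_n)]
    return counts


def _terminal_fix(
    rng: np.random.Generator, pops: list[np.ndarray], two_n: int, gens: int
) -> tuple[np.ndarray, np.ndarray]:
    """Drift each lineage until absorption or ``gens`` generations.

    Returns (presence matrix of shape (len(pops), L) with entries
    1 fixed / 0 lost, residual mask of loci still polymorphic anywhere).
    """
    state = [p.copy() for p in pops]
    for _ in range(gens):
        any_poly = False
        for i, counts in enumerate(state):
            poly = (counts > 0) & (counts < two_n)
            if poly.any():
                any_poly = True
                counts[poly] = rng.binomial(two_n, counts[poly] / two_n)
        if not any_poly:
            break
    mat = np.stack(state)
    residual = ((mat > 0) & (mat < two_n)).any(axis=0)
    presence = (mat == two_n).astype(np.int8)
    return presence, residual


def _score(presence: np.ndarray, residual: np.ndarray) -> tuple[int, int, int, int]:
    """Tally loci fixed in exactly two of (A, B, C); exclude residuals."""
    ok = ~residual
    a, b, c = presence[0, ok], presence[1, ok], presence[2, ok]
    total = a + b + c
    two = total == 2
    y1 = int(np.sum(two & (c == 0)))
    y2 = int(np.sum(two & (b == 0)))
    y3 = int(np.sum(two & (a == 0)))
    return y1, y2, y3, int(residual.sum())


def _replicate_c_tree(rng: np.random.Generator, cfg: SimulationConfig) -> SimulatedCounts:
    two_n = cfg.two_n
    anc = _evolve_ancestral(rng, cfg)
    # internal branch: (A,B) ancestor receives new insertions; C drifts in parallel
    branch = anc.copy()
    lineage_c = anc.copy()
    new = np.empty(0, dtype=np.int64)
    for _ in range(cfg.internal_branch_gens):
        k = rng.poisson(cfg.insertion_rate_internal) if cfg.insertion_rate_internal > 0 else 0
        if k:
            new = np.concatenate([new, np.ones(k, dtype=np.int64)])
        branch = _drift_step(rng, branch, two_n)
        lineage_c = _drift_step(rng, lineage_c, two_n)
        new = _drift_step(rng, new, two_n)
        new = new[new > 0]
        # ancestral loci dead in both daughters, or fixed in both, are settled:
        # absent everywhere / present everywhere -> uninformative either way
        dead = (branch == 0) & (lineage_c == 0)
        done = (branch == two_n) & (lineage_c == two_n)
        keep = ~(dead | done)
        branch, lineage_c = branch[keep], lineage_c[keep]
    # second split: A and B copy the internal branch (ancestral + branch-new loci)
    pool = np.concatenate([branch, new])
    f_a, f_b = pool.copy(), pool.copy()
    f_c = np.concatenate([lineage_c, np.zeros(new.size, dtype=np.int64)])
    presence, residual = _terminal_fix(rng, [f_a, f_b, f_c], two_n, cfg.terminal)
    y1, y2, y3, n_res = _score(presence, residual)
    return SimulatedCounts(y1, y2, y3, n_res, cfg.realized_tau)


def _replicate_polytomy(rng: np.random.Generator, cfg: SimulationConfig) -> SimulatedCounts:
    anc = _evolve_ancestral(rng, cfg)
    pops = [anc.copy(), anc.copy(), anc.copy()]
    presence, residual = _terminal_fix(rng, pops, cfg.two_n, cfg.terminal)
    y1, y2, y3, n_res = _score(presence, residual)
    return SimulatedCounts(y1, y2, y3, n_res, 0.0)


def _replicate_b_fusion(rng: np.random.Generator, cfg: SimulationConfig) -> SimulatedCounts:
    two_n = cfg.two_n
    anc = _evolve_ancestral(rng, cfg)
    donor_a = anc.copy()
    donor_c = anc.copy()
    for _ in range(cfg.internal_branch_gens):
        donor_a = _drift_step(rng, donor_a, two_n)
        donor_c = _drift_step(rng, donor_c, two_n)
        keep = ~(((donor_a == 0) & (donor_c == 0)) | ((donor_a == two_n) & (donor_c == two_n)))
        donor_a, donor_c = donor_a[keep], donor_c[keep]
    # one-generation deterministic frequency blend founding lineage B
    blend = cfg.gamma1 * donor_a / two_n + (1.0 - cfg.gamma1) * donor_c / two_n
    f_b = rng.binomial(two_n, blend)
    presence, residual = _terminal_fix(rng, [donor_a, f_b, donor_c], two_n, cfg.terminal)
    y1, y2, y3, n_res = _score(presence, residual)
    return SimulatedCounts(y1, y2, y3, n_res, cfg.realized_tau)


_REPLICATE = {
    "c_tree": _replicate_c_tree,
    "polytomy": _replicate_polytomy,
    "b_fusion": _replicate_b_fusion,
}


def simulate_counts(config: SimulationConfig) -> list[SimulatedCounts]:
    """Run ``config.replicates`` independent forward simulations.

    A single generator seeded with ``config.seed`` is streamed through all
    replicates, so results are reproducible bit-for-bit and replicates never
    share random states.
    """
    rng = np.random.default_rng(config.seed)
    step = _REPLICATE[config.scenario]
    return [step(rng, config) for _ in range(config.replicates)]


def empirical_probabilities(results: list[SimulatedCounts]) -> tuple[TreeProbabilities, np.ndarray]:
    """Pooled relative pattern frequencies with Monte-Carlo standard errors.

    Returns (TreeProbabilities tagged "empirical", per-component binomial SE
    array).  Raises if no informative locus was pooled.
    """
    ys = np.array([[r.y1, r.y2, r.y3] for r in results], dtype=float).sum(axis=0)
    n = ys.sum()
    if n == 0:
        raise ValueError("no informative loci pooled across replicates")
    ps = ys / n
    se = np.sqrt(ps * (1.0 - ps) / n)
    return TreeProbabilities(*ps, scenario="empirical"), se


def results_frame(config: SimulationConfig, results: list[SimulatedCounts]) -> pd.DataFrame:
    """One row per replicate, TSV-ready."""
    return pd.DataFrame(
        {
            "scenario": config.scenario,
            "seed": config.seed,
            "replicate": np.arange(len(results)),
            "y1": [r.y1 for r in results],
            "y2": [r.y2 for r in results],
            "y3": [r.y3 for r in results],
            "n_residual_polymorphic": [r.n_residual_polymorphic for r in results],
            "realized_tau": [r.realized_tau for r in results],
        }
    )


@dataclass(frozen=True)
class ExperimentResult:
    """Monte-Carlo estimate of a rate with its binomial standard error."""

    rate: float
    se: float
    reps: int

    @property
    def ci(self) -> tuple[float, float]:
        return (max(0.0, self.rate - 2 * self.se), min(1.0, self.rate + 2 * self.se))


def _multinomial_draws(
    rng: np.random.Generator, probs: TreeProbabilities, n_markers: int, reps: int
) -> np.ndarray:
    return rng.multinomial(n_markers, probs.as_array, size=reps)


def type_one_error_experiment(
    config: SimulationConfig,
    n_markers: int,
    alpha: float = 0.05,
    reps: int = 2000,
) -> ExperimentResult:
    """Empirical type-I error of the test matching the config's null scenario.

    Marker triplets are drawn multinomially from the scenario's analytic
    pattern probabilities.  Each test's type-I error is defined for the
    hypothesis it addresses, which names its categories in advance:
    ``polytomy`` exercises the bifurcation test on the first category's count
    (is p1 > 1/3?), and ``c_tree`` exercises the two-sided asymmetry test on
    the two discordant categories (p2 = p3 holds under any resolved tree).
    Both exact tests are discrete, hence conservative: the rejection rate
    should not exceed alpha beyond Monte-Carlo noise.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    probs = config.analytic_probabilities()
    rng = np.random.default_rng(config.seed)
    draws = _multinomial_draws(rng, probs, n_markers, reps)
    if config.scenario == "polytomy":
        y1s = draws[:, 0]
        lookup = {
            int(y): binom_tail(int(y), n_markers, 1.0 / 3.0) for y in np.unique(y1s)
        }
        rejections = np.array([lookup[int(y)] <= alpha for y in y1s])
    elif config.scenario == "c_tree":
        cache: dict[tuple[int, int], float] = {}
        rejections = np.empty(reps, dtype=bool)
        for i, (_, y2, y3) in enumerate(draws):
            key = (int(y2), int(y3))
            if key not in cache:
                cache[key] = sl_asymmetry(*key)
            rejections[i] = cache[key] <= alpha
    else:
        raise ValueError("type-I error experiment requires a null scenario (polytomy or c_tree)")
    rate = float(rejections.mean())
    se = math.sqrt(rate * (1.0 - rate) / reps)
    return ExperimentResult(rate=rate, se=se, reps=reps)


def ci_coverage_experiment(
    config: SimulationConfig,
    n_markers: int,
    conf_level: float = 0.95,
    reps: int = 1000,
) -> ExperimentResult:
    """Coverage of the drift-time confidence interval at the config's true tau.

    Draws multinomial triplets from the C-tree probabilities at
    ``realized_tau``, estimates tau with its Clopper-Pearson-based interval
    for each, and reports the fraction of intervals covering the truth.
    Clopper-Pearson conservativeness should keep coverage at or above the
    nominal level up to Monte-Carlo noise.
    """
    if config.scenario != "c_tree":
        raise ValueError("coverage experiment requires a c_tree scenario with known tau")
    tau_true = config.realized_tau
    probs = config.analytic_probabilities()
    rng = np.random.default_rng(config.seed)
    draws = _multinomial_draws(rng, probs, n_markers, reps)
    # the estimate depends on the draw only through its largest count
    cache: dict[int, tuple[float, float]] = {}
    covered = np.empty(reps, dtype=bool)
    for i, row in enumerate(draws):
        y_win = int(row.max())
        if y_win not in cache:
            counts = MarkerCounts(int(row[0]), int(row[1]), int(row[2]), mode=MULTI)
            est = estimate_drift_time(counts, rate_ratio=config.rate_ratio, conf_level=conf_level)
            cache[y_win] = (est.ci_low, est.ci_high)
        lo, hi = cache[y_win]
        covered[i] = lo <= tau_true <= hi
    rate = float(covered.mean())
    se = math.sqrt(rate * (1.0 - rate) / reps)
    return ExperimentResult(rate=rate, se=se, reps=reps)
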