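# Methods

## Scope and data model

The package analyses triplets of lineages (A, B, C) scored for retroposon
presence/absence at orthologous loci. Only loci with the insertion present
in exactly two lineages are informative; the three sharing categories are
counted as (y₁, y₂, y₃) = (A–B, A–C, B–C) with total n. Counts are taken
as given: orthology curation (target-site duplications, truncation
diagnostics) happens upstream and is out of scope, as is any correction
for testing many triplets across a larger tree.

Two ascertainment modes are distinguished. A *multi-directional* screen
(markers discovered from at least two of the genomes) observes all three
categories. A *one-directional* screen observes only the two categories
involving the reference genome; the third is stored as missing, never as
zero, and the multi-directional tests refuse such data rather than
silently mis-applying.

## Probability model

Conditional on n, the counts are multinomial(n; p₁, p₂, p₃). A resolved
tree ((A,B),C) whose internal branch has length T₁ generations in a
Wright–Fisher population of N₁ diploids gives

    p₁ = 1 − (2/3)Ψ(τ),  p₂ = p₃ = (1/3)Ψ(τ),  τ = T₁/(2N₁),
    Ψ(τ) = e^(−τ) / (1 + r(τ + e^(−τ) − 1)),

with r = n₁/n₀ the ratio of the internal-branch to ancestral insertion
rates (expected new loci per generation). Ψ mixes two sources of
informative loci: ancestral standing variation that sorts incompletely
(the e^(−τ) part; at r = 0, Ψ = e^(−τ) recovers the classical coalescent
discordance factor), and insertions arising on the internal branch, which
can only support the true sister pair (the r(τ + e^(−τ) − 1) weight).
`rate_ratio` defaults to 1 (constant insertion rate), the assumption under
which the model reduces to the standard marker-system formulation.
Polytomy is the τ = 0 boundary (all pᵢ = 1/3). A hybrid (fusion) origin of
a lineage predicts that the category pairing its two parental lineages is
strictly the smallest (e.g. p₁ > p₂ and p₃ > p₂ when B is the hybrid); no
closed form for the fusion probabilities is implemented — only this
inequality signature plus the simulator.

## Exact tests

All tests are binomial tails computed through the regularized incomplete
beta identity P(X ≥ k) = I_p(k, n − k + 1), exact to floating precision.

* **Bifurcation**: the winning count Y against total n at the least
  favourable null p = 1/3; SL₁ = I_{1/3}(Y, n − Y + 1).
* **Asymmetry** (hybridization signal): conditional on their sum, either
  of the two smallest counts is Binom(sum, 1/2) under any resolved tree or
  polytomy; the two-sided level is 2·I_{1/2}(max, min + 1), defined as 1
  when the counts are equal and capped at 1 (the doubling can exceed 1 for
  tiny counts).
* **One-directional**: the same fair-coin comparison applied to the only
  two observable counts; a significant result cannot distinguish a
  resolved tree from hybridization, and reports carry that caveat
  unconditionally.

### Scenario classification

At level α (default 0.05), with the triplet sorted descending:

| bifurcation | asymmetry | top-pair comparison | call |
|---|---|---|---|
| ≤ α | > α | — | tree (winning pair) |
| > α | > α | — | polytomy not rejected |
| — | ≤ α | > α (or tie for largest) | hybridization |
| ≤ α | ≤ α | ≤ α | tree with hybridization signal |

The top-pair comparison reuses the one-directional statistic on the two
largest counts; it separates a genuinely ambiguous topology (hybridization
proper) from a dominant topology that merely carries an asymmetry signal.
The putative hybrid is the lineage shared by the two larger-count pairs.
Ties for the largest count never yield a tree call; they are classified by
the asymmetry test with an explicit warning. The rare corner where the
top pair separates but the bifurcation test does not is reported as
hybridization with a warning. All-zero triplets are an error (no
informative markers).

### Critical boundaries

For the report columns, exact critical values are found by direct search:
the smallest winning count with SL₁ ≤ α given n, and the smallest
*realizable* difference of the two smallest counts at fixed sum (only
differences with the parity of the sum correspond to integer splits; the
search steps through those). When no value in range is significant the
boundary is reported as not calculable — e.g. the asymmetry test can
never reach p < 0.05 below 12 total markers.

## Normal approximations

Continuity-corrected normal tails give closed-form boundaries, rounded up
to the next integer (an exactly integral bound is used as is):

* bifurcation: Y ≥ n/3 + 1/2 + z_α√(2n)/3,
* asymmetry: |Y₂ − Y₃| ≥ 1 + z_{α/2}√(Y₂+Y₃) — note the *two-sided*
  quantile (1.960 at α = 0.05), while the one-sided tests use z_α (1.645),
* one-directional: Y₁ ≥ (Y₁ + Y₂ + 1 + z_α√(Y₁+Y₂))/2.

z-quantiles come from the normal quantile function, never from a
transcribed table. Regenerated tables (`retromark tables`) carry exact and
approximate values side by side; they agree within ±1 marker for all
n ≤ 30 at α ∈ {0.05, 0.01}.

## Drift-time estimation

The winning count is binomial(n, p₁), and τ ↦ p₁(τ) is strictly
increasing, so the point estimate inverts p₁ at the observed fraction
(τ̂ = 0 whenever the fraction is ≤ 1/3). Inversion uses bracketed
root-finding on τ ∈ [0, 50] with tolerance 1e−10; Ψ below 1e−20 is
treated as 0, and fractions requiring smaller Ψ map to an infinite τ.
Confidence bounds transport an exact Clopper–Pearson interval for p₁
through the same inversion; the upper bound is infinite when the p₁
interval reaches 1. This construction is deliberately conservative
(discrete exact interval through a monotone map), and its coverage is
checked by simulation rather than asserted. Converting τ to census
quantities uses only the identity τ = T₁/(2N₁); no effective-population-
size inference is attempted beyond it.

## Wright–Fisher simulator

The simulator is locus-based: each insertion locus is an independent
biallelic site (free recombination, no selection, no recurrent insertion
or precise excision) with allele counts resampled binomially in
populations of 2N chromosomes; new loci appear as Poisson events per
generation on one random chromosome. Scenarios: a resolved tree with an
internal branch (new insertions at rate n₁), a simultaneous three-way
split, and a fusion in which the middle lineage is founded by a
deterministic γ/(1−γ) frequency blend of the two parental populations —
insertions arising in the parental populations between split and fusion
are ignored, so the fusion scenario tracks ancestral standing variation
only.

Defaults and their rationale:

* `n_diploid` = 100 — small enough for desk-scale runs, large enough that
  discrete-population deviations from the diffusion-based Ψ are well below
  Monte-Carlo resolution at the pooled sample sizes used;
* `burn_in_gens` = 8N — several times the absorption timescale, so the
  ancestral standing variation is at insertion–drift equilibrium at the
  first split;
* `terminal_gens` = 20N — long enough that virtually every locus is fixed
  or lost when scored; loci still polymorphic in any lineage are counted
  and excluded (`n_residual_polymorphic`), and that count is reported so
  users can confirm it is negligible;
* insertion rates default to 10 loci/generation — the per-locus dynamics
  are independent of the rate, which only scales how many informative loci
  a replicate pools (roughly 10–16 at these settings).

A single seeded generator is streamed through all replicates, so runs are
bit-for-bit reproducible and replicates cannot collide. Validation runs
in the test suite pool ≥ 5000 informative loci per condition (550/500/
400/250 replicates at τ = 0.25/0.5/1/2, N = 100) and require agreement
with the analytic (p₁, p₂, p₃) within 3 Monte-Carlo standard errors.

### Error-rate and coverage experiments

`type_one_error_experiment` and `ci_coverage_experiment` draw multinomial
triplets directly from the scenario's analytic pattern probabilities
rather than running a forward simulation per draw; the forward machinery
is validated separately, and the experiments then measure properties of
the *tests* at realistic marker counts. The type-I error is defined per
hypothesis, so each test is applied to the categories its null names in
advance (the first category for the bifurcation test under polytomy; the
two discordant categories for the asymmetry test under a resolved tree).
Applying the bifurcation test to the data-selected maximum instead
triples the rejection rate under polytomy — a selection effect that is a
property of the screening procedure, not of the test.

## What the simulations do and do not show

The generator emulates neutral, irreversible, independent insertion loci
in constant-size panmictic populations with clean presence/absence calls.
Real data additionally contain orthology errors, rare parallel insertions
and precise excisions, lineage-specific rate variation, population
structure and ascertainment filters — none of which are modelled, so
passing validation demonstrates internal consistency of model, tests and
simulator, not robustness to curation noise. The tests themselves are
exact and conservative for any data meeting the multinomial assumption.

## Numerical choices and limitations

* Binomial tails via `scipy.special.betainc`; equivalence with direct
  summation is enforced to 1e−12 for n ≤ 60.
* Rounding of approximate boundaries is a strict ceiling with a 1e−9
  guard against float noise just below an integral bound.
* P-values below 1e−16 print as "< 1e−16" in human reports; machine
  output keeps full precision. Infinite drift-time bounds serialize as
  JSON null.
* Restricted to exactly three lineages; multi-lineage generalizations and
  a quantitative hybridization-level estimate are out of scope.
* The multinomial likelihood is exposed for model studies but the
  scenario decision is test-based, not likelihood-ratio-based.
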