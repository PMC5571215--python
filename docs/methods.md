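# Methods

## Model

A haploid population of constant size *N* evolves in discrete,
non-overlapping generations. Each individual carries one of two heritable
strategies. During its lifetime it experiences *E* independent decision
events; a risk-averse individual earns the constant payoff *M* = 10 per
event, a risk-prone individual earns *H* with probability *p* and *L*
otherwise. Its fitness-determining character is the accumulated payoff,
the sum over the *E* events. At the end of the generation the whole
population is replaced: each of the *N* offspring picks its parent
independently, with probabilities given by the selection scheme's weight
vector over the parents' accumulated payoffs, and inherits the parent's
strategy exactly. There is no mutation or migration, so the risk-prone
count *k* is a Markov chain on {0, …, N} with absorbing boundaries, and
every run ends in fixation with probability one whenever all weights stay
positive.

All standard scenarios are *mean-matched* (`p·H + (1−p)·L = M`), so the
strategies differ only in payoff variance and distribution shape. The
two-point distribution with given mean *m* and variance *v* is unique:
`H = m + sqrt(v(1−p)/p)`, `L = m − sqrt(v·p/(1−p))`; this is how the
constant-variance asymmetric family (m = 10, v = 25, p ∈ {0.1, …, 0.8})
is constructed. At p = 0.8 the formula gives L = 0 exactly; zero payoffs
are therefore legal (they receive zero weight under proportional/power
selection), while negative payoffs are rejected. The extreme scheme
5-10-500 is specified by its payoffs, with p solved from the equal-mean
constraint: p = (10−5)/(500−5) = 5/495.

## Selection schemes

* **Proportional**: weightᵢ = payoffᵢ / Σ payoffs.
* **Rank truncation**: the k = max(1, round(T·N)) highest-payoff
  individuals (round half up) each get weight 1/k. Payoff ties spanning
  the cutoff are pervasive with two-point payoffs, so tied individuals
  are admitted uniformly at random (implemented by sorting on an
  iid-uniform secondary key). Unbiased tie-breaking is what makes T = 50%
  with the symmetric 5-10-15 scheme exactly neutral.
* **Absolute truncation**: equal weight on individuals whose accumulated
  payoff reaches a fixed value. A generation can leave the eligible set
  empty; there is no principled default for that population's fate, so
  the scheme exposes a policy: `error` (default) or `uniform` (neutral
  resampling for that generation).
* **Power**: weightᵢ ∝ payoffᵢᶻ. The z = 1 branch routes through the
  proportional code path so the identity is bit-exact.
* **Sigmoid**: payoffs are renormalized *every generation* by that
  generation's maximum (the best individual has pₙ = 1), then passed
  through the logistic with steepness ξ and inflection β; weights are the
  normalized transforms. The weight depends only on the payoff value,
  never on rank.

Proportional, power and sigmoid weights are functions of payoff values;
only rank truncation uses rank order. Rank-based variants of the other
schemes are out of scope.

## Engine and random-number protocol

`step_generation` draws the payoff vector, computes the weight vector and
draws the next risk-prone count as Binomial(N, W_rp), where W_rp is the
summed weight of risk-prone individuals — equivalent to N independent
parent draws because individuals within a strategy are exchangeable. The
per-individual reference implementation (explicit parent choice for every
offspring) lives in the test suite and is checked against the exact
transition row.

`run_replicates` gives replicate *r* the *r*-th spawned child of
`SeedSequence(base_seed)`: results are bit-reproducible and independent of
execution order. `run_replicates_batch` — used by the scenario registry
and the acceptance script — advances all unfixed replicates in lockstep on
one stream, which is what makes vectorization possible; it is equally
deterministic in (config, base_seed) but has a different stream layout, so
the two runners agree in distribution (tested against the exact oracle),
not draw-for-draw. For proportional selection the batch step uses an
exact count-space shortcut: W_rp depends only on the strategies' payoff
totals, and the risk-prone total is `L·k·E + (H−L)·Binomial(kE, p)`. All
other schemes build the full replicate × individual payoff matrix. The
`max_generations` guard (default 10⁶) exists to catch configuration
errors; fixation is almost sure in every supported configuration. Odd N
starts at k = ⌊N/2⌋.

## Exact oracle

For E = 1 and N ≲ 12 the transition matrix is enumerated exactly: given
*k*, the number *h* of risk-prone individuals drawing the high payoff is
Binomial(k, p); given (k, h) the weight vector is deterministic for the
value-based schemes, and for rank truncation the boundary tie-break is
averaged analytically by a hypergeometric allocation of the remaining
slots among tied individuals. Each realization contributes a
Binomial(N, W_rp(h)) row; note the transition is this *mixture*, not a
binomial at the mean weight — offspring are correlated through the shared
payoff realization. Fixation probabilities solve the absorbing-chain
linear system `(I − Q)x = b`. E = 1 suffices because one generation's
mechanics are independent of E given the payoff vector; multi-event
claims are tested by simulation. At N = 2 with 5-10-15 and proportional
selection the chain gives risk-prone fixation 53/121 ≈ 0.438.

## Statistics

Fixation proportions are summarized with a Wilson 95% CI (stable near 0
and 1, where truncation scenarios live; Wald would not be) and tested
with the one-sample proportion z-test using the null-based standard
error, z = (p̂ − p₀)/sqrt(p₀(1−p₀)/n); one- and two-tailed p-values are
both reported because published usage mixes the two, and the significance
flag uses α = 0.001. On binary fixation outcomes a t-test is equivalent
to the z-test up to the n−1 divisor, so the z-test is the single
implementation. No multiple-testing correction is applied across sweep
grids.

In tests that compare a simulated proportion with a *published* Monte
Carlo proportion, the band is three two-sample binomial standard errors,
`3·sqrt(p(1−p)(1/n_sim + 1/n_pub))`, with n_pub the published replicate
count: both numbers are finite simulations, and treating the published
one as exact would undersize the band.

## Scenario registry and tipping points

Replicate counts default to 5000 where the source scenario states them
and 2000 otherwise, overridable everywhere; the pytest suite further
reduces counts (300–5000 per cell) to keep the default run fast, sizes
chosen so the tested effects (often 40+ percentage points) dwarf binomial
noise. Where the published truncation-threshold grid is not recoverable,
the registry declares its own grid bracketing the symmetric-scheme
tipping threshold (0.47/0.50/0.53 plus deciles). The "variance free"
p_high family fixes L = 5 and the mean at 10 and lets the variance follow;
the sigmoid family with the high payoff pinned at 15 sets
L = (10 − 15p)/(1 − p), keeping the normalization anchor constant across
the family.

`locate_tipping_point` simulates the grid, interpolates the 0.5 crossing
of the risk-prone fixation proportion linearly on the logit scale (smooth
and near-linear around 1/2), and bootstraps the binomial counts for an
uncertainty interval. Proportions are clipped to [10⁻⁶, 1−10⁻⁶] before
the logit; with saturated grid ends the bootstrap interval can collapse
to the grid resolution.

## What the generator does and does not emulate

The simulator *is* the study system: synthetic populations with exactly
two strategies, two-point risk, constant N, and lifetime-accumulated
payoffs translated to reproduction once per generation. It does not
emulate state-dependent behavior, payoff distributions with more than two
outcomes, survival selection between events, overlapping generations,
mutation, or evolving reproduction dynamics — conclusions from passing
tests are claims about this idealized model, not about any natural
population.

## Known limitations and numerical notes

* The exact oracle is limited to E = 1 and N ≤ 12 (combinatorial growth);
  larger configurations rely on Monte Carlo plus the distributional
  equivalence established at small N.
* At N = 10 with power z = 1.26 the exact risk-prone fixation probability
  is 0.5057, while the published Monte-Carlo estimate is 52.5% — about
  2.7 of its own binomial standard errors away at 5000 replicates. The
  simulation here reproduces its exact value; the residual gap to the
  published point estimate is within the sampling error of two finite
  simulations.
* Weight vectors are validated to sum to 1 within 1e-12; the sigmoid's
  exp overflow for extreme steepness is harmless (weight underflows to
  zero) and silenced locally.
* Payoff totals in the proportional count-space shortcut are clipped into
  [0, 1] after division to absorb rounding at the L = 0 boundary.
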