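"""Generational loop: non-overlapping generations to fixation.

The population is haploid and of constant size N; strategies are
inherited exactly (no mutation, no migration), so the number k of
risk-prone individuals is a Markov chain on {0, ..., N} with absorbing
states 0 and N.  One generation:

1. every individual accumulates its lifetime payoff (payoff_model),
2. payoffs are mapped to a parenthood weight vector (selection),
3. each of the N offspring independently picks a parent with those
   weights and inherits its strategy.

Because individuals within a strategy are exchangeable, the next
generation's risk-prone count given the realized payoffs is simply
Binomial(N, W_rp) where W_rp is the summed weight of the risk-prone
individuals.  The batch runner exploits this to advance thousands of
replicate populations in lockstep; ``run_replicates`` instead gives each
replicate its own child random stream (deterministically spawned from
the base seed) so results are bit-reproducible and independent of
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .payoff_model import (
    RISK_AVERSE,
    RISK_PRONE,
    PayoffScheme,
    sample_population_payoffs,
)
from .selection import Proportional, SelectionScheme

__all__ = [
    "PopulationState",
    "RunResult",
    "ExperimentConfig",
    "step_generation",
    "run_to_fixation",
    "run_replicates",
    "run_replicates_batch",
    "fixation_counts",
    "NonFixationError",
]

MAX_GENERATIONS_DEFAULT = 1_000_000


class NonFixationError(RuntimeError):
    """The max-generation guard tripped before either strategy fixed."""


@dataclass(frozen=True)
class PopulationState:
    """Count summary of one generation: N and the risk-prone count k."""

    N: int
    k_risk_prone: int
    generation: int = 0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError(f"population size must be positive, got {self.N}")
        if not 0 <= self.k_risk_prone <= self.N:
            raise ValueError(
                f"k_risk_prone must be in [0, {self.N}], got {self.k_risk_prone}"
            )

    @property
    def absorbed(self) -> bool:
        return self.k_risk_prone in (0, self.N)

    @property
    def fixed_strategy(self) -> str | None:
        if self.k_risk_prone == 0:
            return RISK_AVERSE
        if self.k_risk_prone == self.N:
            return RISK_PRONE
        return None


@dataclass(frozen=True)
class RunResult:
    fixed_strategy: str
    generations_to_fixation: int
    seed: int


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one replicate set needs: scheme, dynamics, sizes, seeds."""

    scheme: PayoffScheme
    selection: SelectionScheme = field(default_factory=Proportional)
    N: int = 100
    initial_k: int | None = None  # default N // 2 (50/50 start)
    replicates: int = 2000
    base_seed: int = 0
    max_generations: int = MAX_GENERATIONS_DEFAULT

    def __post_init__(self):
        if self.initial_k is None:
            object.__setattr__(self, "initial_k", self.N // 2)
        if not 0 <= self.initial_k <= self.N:
            raise ValueError(f"initial_k must be in [0, {self.N}], got {self.initial_k}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def initial_state(self) -> PopulationState:
        return PopulationState(self.N, self.initial_k)


def step_generation(
    state: PopulationState,
    scheme: PayoffScheme,
    selection: SelectionScheme,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance one (non-absorbed) population by one generation."""
    if state.absorbed:
        raise ValueError("population already absorbed; cannot step")
    payoffs = sample_population_payoffs(state, scheme, rng)
    weights = selection.weights(payoffs, rng)
    w_rp = float(weights[: state.k_risk_prone].sum())
    k_new = int(rng.binomial(state.N, min(1.0, max(0.0, w_rp))))
    return PopulationState(state.N, k_new, state.generation + 1)


def run_to_fixation(config: ExperimentConfig, seed) -> RunResult:
    """Iterate generations from the initial state until k hits 0 or N."""
    rng = np.random.default_rng(seed)
    state = config.initial_state()
    while not state.absorbed:
        if state.generation >= config.max_generations:
            raise NonFixationError(
                f"no fixation within {config.max_generations} generations"
            )
        state = step_generation(state, config.scheme, config.selection, rng)
    seed_int = seed if isinstance(seed, int) else config.base_seed
    return RunResult(state.fixed_strategy, state.generation, seed_int)


def run_replicates(config: ExperimentConfig) -> list[RunResult]:
    """Run every replicate on its own spawned random stream.

    Replicate r uses the r-th child of SeedSequence(base_seed), so the
    full result list is a pure function of (config, base_seed) and does
    not depend on execution order.
    """
    children = np.random.SeedSequence(config.base_seed).spawn(config.replicates)
    out = []
    for r, child in enumerate(children):
        res = run_to_fixation(config, child)
        out.append(replace(res, seed=r))
    return out


def _batch_step_proportional(
    k: np.ndarray, config: ExperimentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Exact count-space step for proportional selection.

    The summed risk-prone weight depends on the payoff realization only
    through the strategies' payoff totals, and the risk-prone total is
    low*k*E plus (high-low) times a Binomial(k*E, p_high) count of high
    outcomes, so no per-individual payoffs are needed.
    """
    s = config.scheme
    n_high = rng.binomial(k * s.events, s.p_high)
    total_rp = k * s.events * s.low + (s.high - s.low) * n_high
    total_ra = (config.N - k) * s.events * s.risk_averse
    w_rp = np.clip(total_rp / (total_rp + total_ra), 0.0, 1.0)
    return rng.binomial(config.N, w_rp)


def _batch_step_general(
    k: np.ndarray, config: ExperimentConfig, rng: np.random.Generator
) -> np.ndarray:
    """One generation for R replicate populations via a payoff matrix."""
    s = config.scheme
    r, n = k.shape[0], config.N
    prone = np.arange(n)[None, :] < k[:, None]
    n_high = rng.binomial(s.events, s.p_high, size=(r, n))
    payoffs = np.where(
        prone,
        n_high * s.high + (s.events - n_high) * s.low,
        float(s.events) * s.risk_averse,
    )
    weights = config.selection.weight_matrix(payoffs, rng)
    w_rp = np.where(prone, weights, 0.0).sum(axis=1)
    return rng.binomial(n, np.clip(w_rp, 0.0, 1.0))


def run_replicates_batch(config: ExperimentConfig) -> list[RunResult]:
    """Advance all replicates in lockstep; same model, vectorized.

    Deterministic in (config, base_seed) like ``run_replicates`` but with
    a shared random stream across replicates, which is what makes the
    vectorization possible.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.base_seed))
    n_rep = config.replicates
    k = np.full(n_rep, config.initial_k, dtype=np.int64)
    gens = np.zeros(n_rep, dtype=np.int64)
    fixed_k = np.full(n_rep, -1, dtype=np.int64)
    active = np.flatnonzero((k != 0) & (k != config.N))
    fixed_k[(k == 0) | (k == config.N)] = config.initial_k
    step = (
        _batch_step_proportional
        if isinstance(config.selection, Proportional)
        else _batch_step_general
    )
    generation = 0
    while active.size:
        if generation >= config.max_generations:
            raise NonFixationError(
                f"{active.size} replicates unfixed after {generation} generations"
            )
        generation += 1
        k_active = step(k[active], config, rng)
        k[active] = k_active
        done = (k_active == 0) | (k_active == config.N)
        idx_done = active[done]
        gens[idx_done] = generation
        fixed_k[idx_done] = k_active[done]
        active = active[~done]
    return [
        RunResult(
            RISK_PRONE if fixed_k[i] == config.N else RISK_AVERSE,
            int(gens[i]),
            config.base_seed,
        )
        for i in range(n_rep)
    ]


def fixation_counts(results: list[RunResult]) -> tuple[int, int]:
    """(risk_averse fixations, risk_prone fixations)."""
    n_ra = sum(r.fixed_strategy == RISK_AVERSE for r in results)
    return n_ra, len(results) - n_ra
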