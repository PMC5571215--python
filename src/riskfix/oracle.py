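"""Exact fixation probabilities for small populations.

For E = 1 the per-generation payoff configuration of a population with k
risk-prone individuals is fully described by the number h of risk-prone
individuals that drew the high payoff, h ~ Binomial(k, p_high).  For each
realization the parenthood weight vector is deterministic (up to rank-
truncation tie-breaking, which is averaged analytically with
hypergeometric slot allocation), so the next-generation risk-prone count
is Binomial(N, W_rp(h)) and the transition matrix over k in {0..N} is an
exact finite mixture.  Fixation probabilities follow from the standard
absorbing-chain linear system.

This enumeration is the brute-force correctness oracle for the Monte
Carlo engine: one generation's mechanics are independent of E given the
payoff vector, so pinning them exactly at E = 1 validates the machinery
used at every E.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .payoff_model import PayoffScheme
from .selection import (
    Power,
    Proportional,
    SelectionScheme,
    Sigmoid,
    TruncationAbsolute,
    TruncationRank,
    truncation_count,
)

__all__ = ["TransitionModel", "build_transition_matrix", "exact_fixation_probability"]

ENUMERATION_BOUND = 12


@dataclass(frozen=True)
class TransitionModel:
    N: int
    scheme: PayoffScheme
    selection: SelectionScheme
    matrix: np.ndarray  # (N+1, N+1) row-stochastic; rows 0, N absorbing


def _value_groups(h: int, k: int, n: int, scheme: PayoffScheme):
    """Realized payoff values with per-strategy counts, merged on ties.

    Returns [(value, n_risk_prone, n_risk_averse)] sorted by value
    descending.  Handles coincidences such as low == risk_averse.
    """
    groups: dict[float, list[int]] = {}
    for value, n_rp, n_ra in (
        (scheme.high, h, 0),
        (scheme.low, k - h, 0),
        (scheme.risk_averse, 0, n - k),
    ):
        if n_rp or n_ra:
            g = groups.setdefault(value, [0, 0])
            g[0] += n_rp
            g[1] += n_ra
    return sorted(((v, c[0], c[1]) for v, c in groups.items()), reverse=True)


def _risk_prone_weight_mixture(
    h: int, k: int, n: int, scheme: PayoffScheme, selection: SelectionScheme
) -> list[tuple[float, float]]:
    """[(probability, summed risk-prone weight W_rp)] given the realization h."""
    groups = _value_groups(h, k, n, scheme)
    if isinstance(selection, Proportional):
        selection = Power(1.0)
    if isinstance(selection, Power):
        tot_rp = h * scheme.high**selection.z + (k - h) * scheme.low**selection.z
        tot = tot_rp + (n - k) * scheme.risk_averse**selection.z
        return [(1.0, tot_rp / tot)]
    if isinstance(selection, Sigmoid):
        vmax = groups[0][0]  # maximum *realized* payoff normalizes

        def sig(v: float) -> float:
            return 1.0 / (1.0 + np.exp(-selection.xi * (v / vmax - selection.beta)))

        tot_rp = h * sig(scheme.high) + (k - h) * sig(scheme.low)
        tot = tot_rp + (n - k) * sig(scheme.risk_averse)
        return [(1.0, tot_rp / tot)]
    if isinstance(selection, TruncationAbsolute):
        e_rp = sum(c_rp for v, c_rp, _ in groups if v >= selection.threshold)
        e_ra = sum(c_ra for v, _, c_ra in groups if v >= selection.threshold)
        if e_rp + e_ra == 0:
            if selection.on_empty == "uniform":
                return [(1.0, k / n)]
            raise ValueError(
                "no individual reaches the absolute truncation threshold"
            )
        return [(1.0, e_rp / (e_rp + e_ra))]
    if isinstance(selection, TruncationRank):
        slots = truncation_count(n, selection.t)
        filled_rp = 0
        remaining = slots
        for v, c_rp, c_ra in groups:
            size = c_rp + c_ra
            if size <= remaining:
                filled_rp += c_rp
                remaining -= size
                if remaining == 0:
                    break
            else:
                # boundary group: `remaining` slots shared uniformly at
                # random among the tied individuals -> hypergeometric
                # split between strategies
                out = []
                lo = max(0, remaining - c_ra)
                hi = min(remaining, c_rp)
                denom = comb(size, remaining)
                for e in range(lo, hi + 1):
                    p = comb(c_rp, e) * comb(c_ra, remaining - e) / denom
                    out.append((p, (filled_rp + e) / slots))
                return out
        return [(1.0, filled_rp / slots)]
    raise TypeError(f"unsupported selection scheme {selection!r}")


def build_transition_matrix(
    N: int, scheme: PayoffScheme, selection: SelectionScheme
) -> TransitionModel:
    """Enumerate the exact k -> k' transition matrix (E = 1 only)."""
    if N > ENUMERATION_BOUND:
        raise ValueError(f"exact enumeration supports N <= {ENUMERATION_BOUND}")
    if scheme.events != 1:
        raise ValueError("exact enumeration requires a single event per lifetime")
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = 1.0
    P[N, N] = 1.0
    ks = np.arange(N + 1)
    for k in range(1, N):
        h_pmf = stats.binom.pmf(np.arange(k + 1), k, scheme.p_high)
        for h, ph in enumerate(h_pmf):
            if ph == 0.0:
                continue
            for p_tie, w_rp in _risk_prone_weight_mixture(h, k, N, scheme, selection):
                P[k] += ph * p_tie * stats.binom.pmf(ks, N, w_rp)
    return TransitionModel(N, scheme, selection, P)


def exact_fixation_probability(model: TransitionModel, initial_k: int) -> float:
    """Probability that the risk-prone strategy fixes, starting from k."""
    N, P = model.N, model.matrix
    if not 0 <= initial_k <= N:
        raise ValueError(f"initial_k must be in [0, {N}]")
    if initial_k == 0:
        return 0.0
    if initial_k == N:
        return 1.0
    interior = np.arange(1, N)
    Q = P[np.ix_(interior, interior)]
    b = P[interior, N]
    x = np.linalg.solve(np.eye(N - 1) - Q, b)
    return float(x[initial_k - 1])
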