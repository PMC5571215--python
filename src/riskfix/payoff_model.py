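"""Payoff schemes for the two behavioral strategies.

A *payoff scheme* defines what the two heritable strategies earn per
decision event: a risk-averse individual receives a constant payoff
``risk_averse`` every event, while a risk-prone individual receives
``high`` with probability ``p_high`` and ``low`` otherwise.  Each
individual experiences ``events`` independent events per lifetime and
its fitness-determining character is the *accumulated payoff*, the sum
over those events.

Schemes are usually *mean-matched*: the expected per-event payoff of the
risk-prone strategy equals the risk-averse payoff, so selection acts on
payoff variance (and higher distributional detail), never on the mean.
The shorthand ``"L-M-H"`` denotes low = L, risk-averse = M, high = H
with the high/low outcomes equiprobable; e.g. ``"5-10-15"`` is the
baseline symmetric scheme.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PayoffScheme",
    "scheme_from_moments",
    "parse_scheme",
    "sample_lifetime_payoff",
    "sample_population_payoffs",
]

#: strategies, by convention: risk-prone individuals occupy the first k slots
RISK_AVERSE = "risk_averse"
RISK_PRONE = "risk_prone"

MEAN_MATCH_TOL = 1e-6


@dataclass(frozen=True)
class PayoffScheme:
    """Bimodal risk-prone payoff distribution plus the constant risk-averse payoff.

    Parameters
    ----------
    low, high
        The two possible per-event payoffs of the risk-prone strategy,
        ``low <= high``.
    risk_averse
        Constant per-event payoff of the risk-averse strategy (10 in all
        standard scenarios).
    p_high
        Probability of the high outcome per event, in [0, 1].
    events
        Number of decision events per lifetime, ``E >= 1``.
    """

    low: float
    high: float
    risk_averse: float = 10.0
    p_high: float = 0.5
    events: int = 1

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise ValueError(f"low ({self.low}) must not exceed high ({self.high})")
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError(f"p_high must be in [0, 1], got {self.p_high}")
        if self.events < 1 or int(self.events) != self.events:
            raise ValueError(f"events must be a positive integer, got {self.events}")
        object.__setattr__(self, "events", int(self.events))
        if not self.is_mean_matched:
            warnings.warn(
                f"scheme is not mean-matched: risk-prone mean {self.mean():g} "
                f"!= risk-averse payoff {self.risk_averse:g}",
                stacklevel=3,
            )

    def mean(self) -> float:
        """Expected per-event payoff of the risk-prone strategy."""
        return self.p_high * self.high + (1.0 - self.p_high) * self.low

    def variance(self) -> float:
        """Per-event payoff variance of the risk-prone strategy."""
        m = self.mean()
        return (
            self.p_high * (self.high - m) ** 2
            + (1.0 - self.p_high) * (self.low - m) ** 2
        )

    @property
    def is_mean_matched(self) -> bool:
        return abs(self.mean() - self.risk_averse) < MEAN_MATCH_TOL

    def with_events(self, events: int) -> "PayoffScheme":
        """Same per-event distribution with a different lifetime event count."""
        return PayoffScheme(self.low, self.high, self.risk_averse, self.p_high, events)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.low:g}-{self.risk_averse:g}-{self.high:g}"
            f" (p_high={self.p_high:g}, E={self.events})"
        )


def scheme_from_moments(
    p_high: float,
    mean: float,
    variance: float,
    risk_averse: float = 10.0,
    events: int = 1,
) -> PayoffScheme:
    """Construct the bimodal scheme with given mean and variance.

    The two-point distribution with success probability ``p_high``, mean
    ``m`` and variance ``v`` is unique:

        high = m + sqrt(v (1 - p) / p),   low = m - sqrt(v p / (1 - p)).

    Used to build constant-variance asymmetric schemes, e.g. the family
    with mean 10 and variance 25 at p_high in {0.1, ..., 0.8} (p_high =
    0.1 gives the 8.333-10-25 scheme; the printed 8.333 is a rounding of
    10 - 5/3).
    """
    if variance < 0:
        raise ValueError(f"variance must be nonnegative, got {variance}")
    if not 0.0 < p_high < 1.0:
        if variance > 0:
            raise ValueError(
                f"p_high={p_high} puts all mass on one outcome; "
                "a positive variance is unattainable"
            )
        return PayoffScheme(mean, mean, risk_averse, p_high, events)
    high = mean + math.sqrt(variance * (1.0 - p_high) / p_high)
    low = mean - math.sqrt(variance * p_high / (1.0 - p_high))
    # snap rounding dust to an exact zero payoff (e.g. p_high=0.8 with
    # mean 10, variance 25 has low = 10 - sqrt(100) = 0)
    scale = abs(mean) + math.sqrt(variance)
    if abs(low) < 1e-12 * scale:
        low = 0.0
    return PayoffScheme(low, high, risk_averse, p_high, events)


def parse_scheme(spec: str | dict, events: int | None = None) -> PayoffScheme:
    """Parse a payoff-scheme description.

    Accepts the shorthand string ``"L-M-H"`` (low-riskaverse-high,
    ``p_high`` solved from the equal-mean constraint, i.e. 0.5 when the
    outcomes are symmetric around M, and e.g. 5/495 for "5-10-500"), or a
    mapping with either ``{low, high, p_high?, risk_averse, events?}`` or
    the moment form ``{p_high, mean, variance, risk_averse, events?}``.
    """
    if isinstance(spec, str):
        parts = spec.split("-")
        if len(parts) != 3:
            raise ValueError(f"expected 'low-riskaverse-high', got {spec!r}")
        low, mid, high = (float(p) for p in parts)
        if high == low:
            p_high = 0.5
        else:
            # equal-mean constraint: p*high + (1-p)*low = risk_averse
            p_high = (mid - low) / (high - low)
        return PayoffScheme(low, high, mid, p_high, events or 1)
    spec = dict(spec)
    if events is not None:
        spec.setdefault("events", events)
    if "mean" in spec or "variance" in spec:
        return scheme_from_moments(
            p_high=spec["p_high"],
            mean=spec["mean"],
            variance=spec["variance"],
            risk_averse=spec.get("risk_averse", 10.0),
            events=spec.get("events", 1),
        )
    kwargs = {k: spec[k] for k in ("low", "high") if k in spec}
    for k in ("risk_averse", "p_high", "events"):
        if k in spec:
            kwargs[k] = spec[k]
    unknown = set(spec) - set(kwargs)
    if unknown:
        raise ValueError(f"unknown payoff-scheme keys: {sorted(unknown)}")
    if "p_high" not in kwargs and kwargs["high"] != kwargs["low"]:
        ra = kwargs.get("risk_averse", 10.0)
        kwargs["p_high"] = (ra - kwargs["low"]) / (kwargs["high"] - kwargs["low"])
    return PayoffScheme(**kwargs)


def sample_lifetime_payoff(
    strategy: str, scheme: PayoffScheme, rng: np.random.Generator
) -> float:
    """Accumulated payoff of one individual over its E lifetime events.

    Deterministic ``E * risk_averse`` for the risk-averse strategy; for
    the risk-prone strategy a sum of E independent high/low draws.
    """
    if strategy == RISK_AVERSE:
        return scheme.events * scheme.risk_averse
    if strategy == RISK_PRONE:
        n_high = rng.binomial(scheme.events, scheme.p_high)
        return n_high * scheme.high + (scheme.events - n_high) * scheme.low
    raise ValueError(f"unknown strategy {strategy!r}")


def sample_population_payoffs(
    state, scheme: PayoffScheme, rng: np.random.Generator
) -> np.ndarray:
    """Accumulated payoffs for one generation, as a length-N vector.

    The first ``state.k_risk_prone`` entries are risk-prone individuals
    (iid lifetime sums); the remainder are risk-averse individuals, each
    with the deterministic payoff ``E * risk_averse``.  Individuals
    within a strategy are exchangeable, so this fixed ordering carries
    the strategy labels.
    """
    k, n = state.k_risk_prone, state.N
    payoffs = np.full(n, float(scheme.events) * scheme.risk_averse)
    if k:
        n_high = rng.binomial(scheme.events, scheme.p_high, size=k)
        payoffs[:k] = n_high * scheme.high + (scheme.events - n_high) * scheme.low
    return payoffs
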