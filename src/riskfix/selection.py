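"""Reproduction dynamics: mapping accumulated payoffs to parenthood weights.

Each generation the whole population is replaced; every offspring picks
its parent independently according to a *weight vector* computed from
the accumulated payoffs of the current generation.  Five dynamics are
implemented:

``proportional``
    weight_i ∝ payoff_i — the default in most evolutionary models.
``truncation_rank``
    only the top T fraction by payoff *rank* reproduce, all with equal
    weight; ties spanning the cutoff are broken uniformly at random.
``truncation_absolute``
    as above but the cutoff is a fixed accumulated-payoff value rather
    than a rank quantile.
``power``
    weight_i ∝ payoff_i ** z; z > 1 is a convex payoff-to-fitness map
    (favoring risk), z < 1 concave, and z = 1 recovers proportional
    selection exactly.
``sigmoid``
    payoffs are normalized by the generation's maximum (so the best
    individual scores p_n = 1) and passed through the logistic
    1 / (1 + exp(-xi * (p_n - beta))); weight_i ∝ the transformed value.
    Unlike rank truncation, the weight depends only on the payoff value,
    not on its rank.

All functions operate row-wise on a 2-D array of payoffs (one row per
replicate population), which is what the batch engine feeds them; the
1-D convenience wrappers are the module's primary public surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionScheme",
    "Proportional",
    "TruncationRank",
    "TruncationAbsolute",
    "Power",
    "Sigmoid",
    "proportional_weights",
    "truncation_rank_weights",
    "truncation_absolute_weights",
    "power_weights",
    "sigmoid_weights",
    "truncation_count",
    "selection_from_dict",
]


def truncation_count(n: int, t: float) -> int:
    """Number of reproducing individuals under rank truncation.

    k = max(1, round(T*N)) with round-half-up, so at least one parent
    always exists.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError(f"truncation fraction must be in (0, 1], got {t}")
    return max(1, int(np.floor(t * n + 0.5)))


def _as_matrix(payoffs) -> np.ndarray:
    p = np.asarray(payoffs, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    return p


def _proportional_matrix(p: np.ndarray) -> np.ndarray:
    # zero payoffs are legal (weight 0; the mean-10/variance-25 family
    # reaches low = 0 at p_high = 0.8); negative payoffs are not
    if np.any(p < 0):
        raise ValueError("proportional selection requires nonnegative payoffs")
    tot = p.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("proportional selection requires a positive payoff total")
    return p / tot


def _power_matrix(p: np.ndarray, z: float) -> np.ndarray:
    if z < 0:
        raise ValueError(f"exponent z must be nonnegative, got {z}")
    if np.any(p < 0):
        raise ValueError("power selection requires nonnegative payoffs")
    w = p**z
    tot = w.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("power selection requires a positive weight total")
    return w / tot


def _sigmoid_matrix(p: np.ndarray, xi: float, beta: float) -> np.ndarray:
    if xi <= 0:
        raise ValueError(f"steepness xi must be positive, got {xi}")
    pmax = p.max(axis=1, keepdims=True)
    if np.any(pmax <= 0):
        raise ValueError("sigmoid selection requires a positive maximum payoff")
    pn = p / pmax
    with np.errstate(over="ignore"):  # exp overflow -> weight 0, intended
        w = 1.0 / (1.0 + np.exp(-xi * (pn - beta)))
    return w / w.sum(axis=1, keepdims=True)


def _truncation_rank_matrix(
    p: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    n = p.shape[1]
    k = truncation_count(n, t)
    # secondary iid-uniform key breaks payoff ties uniformly at random;
    # lexsort uses the last key as primary
    jitter = rng.random(p.shape)
    order = np.lexsort((jitter, -p), axis=-1)
    w = np.zeros_like(p)
    np.put_along_axis(w, order[:, :k], 1.0 / k, axis=1)
    return w


def _truncation_absolute_matrix(
    p: np.ndarray, threshold: float, on_empty: str = "error"
) -> np.ndarray:
    if not np.isfinite(threshold):
        raise ValueError("absolute truncation threshold must be finite")
    eligible = p >= threshold
    counts = eligible.sum(axis=1)
    if np.any(counts == 0):
        if on_empty == "uniform":
            # fallback policy: a generation with no survivor reproduces
            # uniformly (neutral resampling)
            empty = counts == 0
            eligible = eligible | empty[:, None]
            counts = eligible.sum(axis=1)
        else:
            raise EmptyParentSetError(
                "no individual reaches the absolute truncation threshold "
                f"{threshold!r} in at least one population"
            )
    return eligible / counts[:, None]


class EmptyParentSetError(RuntimeError):
    """Absolute truncation left no eligible parent."""


# -- 1-D public wrappers ---------------------------------------------------


def proportional_weights(payoffs) -> np.ndarray:
    """weight_i = payoff_i / sum(payoffs); e.g. payoffs (10, 5) -> (2/3, 1/3)."""
    return _proportional_matrix(_as_matrix(payoffs))[0]


def power_weights(payoffs, z: float) -> np.ndarray:
    """weight_i ∝ payoff_i**z; z=1 is proportional, z=0 uniform."""
    return _power_matrix(_as_matrix(payoffs), z)[0]


def sigmoid_weights(payoffs, xi: float, beta: float) -> np.ndarray:
    """Logistic payoff-to-fitness map on max-normalized payoffs."""
    return _sigmoid_matrix(_as_matrix(payoffs), xi, beta)[0]


def truncation_rank_weights(payoffs, t: float, rng: np.random.Generator) -> np.ndarray:
    """Equal weight 1/k on the k highest-payoff individuals, random tie-break."""
    return _truncation_rank_matrix(_as_matrix(payoffs), t, rng)[0]


def truncation_absolute_weights(payoffs, threshold: float) -> np.ndarray:
    """Equal weight on individuals whose payoff reaches a fixed threshold."""
    return _truncation_absolute_matrix(_as_matrix(payoffs), threshold)[0]


# -- tagged-union scheme objects ------------------------------------------


@dataclass(frozen=True)
class SelectionScheme:
    """Base class; concrete schemes carry only the parameters they need."""

    kind = "abstract"

    def weight_matrix(self, payoffs: np.ndarray, rng: np.random.Generator):
        raise NotImplementedError

    def weights(self, payoffs, rng: np.random.Generator | None = None) -> np.ndarray:
        return self.weight_matrix(_as_matrix(payoffs), rng)[0]


@dataclass(frozen=True)
class Proportional(SelectionScheme):
    kind = "proportional"

    def weight_matrix(self, payoffs, rng=None):
        return _proportional_matrix(payoffs)


@dataclass(frozen=True)
class TruncationRank(SelectionScheme):
    t: float  # top fraction allowed to reproduce, in (0, 1]
    kind = "truncation_rank"

    def __post_init__(self):
        truncation_count(1, self.t)  # validates range

    def weight_matrix(self, payoffs, rng=None):
        if rng is None:
            raise ValueError("rank truncation needs an rng for tie-breaking")
        return _truncation_rank_matrix(payoffs, self.t, rng)


@dataclass(frozen=True)
class TruncationAbsolute(SelectionScheme):
    threshold: float  # accumulated-payoff cutoff
    on_empty: str = "error"  # or "uniform": neutral resampling if no survivor
    kind = "truncation_absolute"

    def __post_init__(self):
        if self.on_empty not in ("error", "uniform"):
            raise ValueError(f"on_empty must be 'error' or 'uniform', got {self.on_empty!r}")

    def weight_matrix(self, payoffs, rng=None):
        return _truncation_absolute_matrix(payoffs, self.threshold, self.on_empty)


@dataclass(frozen=True)
class Power(SelectionScheme):
    z: float
    kind = "power"

    def __post_init__(self):
        if self.z < 0:
            raise ValueError(f"exponent z must be nonnegative, got {self.z}")

    def weight_matrix(self, payoffs, rng=None):
        if self.z == 1.0:
            return _proportional_matrix(payoffs)
        return _power_matrix(payoffs, self.z)


@dataclass(frozen=True)
class Sigmoid(SelectionScheme):
    xi: float
    beta: float
    kind = "sigmoid"

    def __post_init__(self):
        if self.xi <= 0:
            raise ValueError(f"steepness xi must be positive, got {self.xi}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"inflection beta must be in (0, 1], got {self.beta}")

    def weight_matrix(self, payoffs, rng=None):
        return _sigmoid_matrix(payoffs, self.xi, self.beta)


_KINDS = {
    "proportional": (Proportional, (), ()),
    "truncation_rank": (TruncationRank, ("t",), ()),
    "truncation_absolute": (TruncationAbsolute, ("threshold",), ("on_empty",)),
    "power": (Power, ("z",), ()),
    "sigmoid": (Sigmoid, ("xi", "beta"), ()),
}


def selection_from_dict(spec: dict) -> SelectionScheme:
    """Build a scheme from ``{kind, <exactly its parameters>}``.

    Strict: missing or extraneous parameters for the kind are rejected.
    """
    spec = dict(spec)
    try:
        kind = spec.pop("kind")
    except KeyError:
        raise ValueError("selection spec needs a 'kind' key") from None
    try:
        cls, params, optional = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown selection kind {kind!r}; expected one of {sorted(_KINDS)}"
        ) from None
    missing = set(params) - set(spec)
    extra = set(spec) - set(params) - set(optional)
    if missing or extra:
        raise ValueError(
            f"selection kind {kind!r} takes parameters {list(params)}; "
            f"missing {sorted(missing)}, extraneous {sorted(extra)}"
        )
    return cls(**spec)
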