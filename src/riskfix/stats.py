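"""Fixation-probability estimation and proportion tests.

Each replicate ends with one of two strategies fixed, so an experiment
yields a Bernoulli sample.  The estimate is summarized with a Wilson 95%
confidence interval (well-behaved near 0 and 1, where many scenarios
live) and tested against a null fixation probability with the one-sample
proportion z-test, z = (p̂ - p0) / sqrt(p0 (1 - p0) / n).  Significance
is declared at alpha = 0.001; on 0/1 data a t-test and the z-test
coincide asymptotically, so the z-test is the primary implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .engine import RunResult, fixation_counts
from .payoff_model import RISK_AVERSE

__all__ = ["FixationEstimate", "summarize_fixation", "compare_to_null_band"]

ALPHA_DEFAULT = 0.001


@dataclass(frozen=True)
class FixationEstimate:
    """Proportion of replicates in which the risk-averse strategy fixed."""

    n_replicates: int
    n_fixed_risk_averse: int
    proportion: float
    ci_low: float
    ci_high: float
    z: float
    p_one_tailed: float
    p_two_tailed: float
    null_proportion: float
    alpha: float

    @property
    def proportion_risk_prone(self) -> float:
        return 1.0 - self.proportion

    @property
    def significant(self) -> bool:
        """One-tailed test (in the observed direction) at alpha."""
        return self.p_one_tailed < self.alpha

    @property
    def significant_two_tailed(self) -> bool:
        return self.p_two_tailed < self.alpha


def summarize_fixation(
    results_or_count: list[RunResult] | int,
    n: int | None = None,
    null_proportion: float = 0.5,
    alpha: float = ALPHA_DEFAULT,
) -> FixationEstimate:
    """Estimate the risk-averse fixation probability and test it.

    Accepts either a list of ``RunResult`` or a pre-tallied
    ``(n_fixed_risk_averse, n)`` pair.
    """
    if isinstance(results_or_count, int):
        if n is None:
            raise ValueError("pass n alongside a pre-tallied count")
        count, n_tot = results_or_count, n
    else:
        if not results_or_count:
            raise ValueError("need at least one replicate")
        count, _ = fixation_counts(results_or_count)
        n_tot = len(results_or_count)
    if not 0 < n_tot or not 0 <= count <= n_tot:
        raise ValueError(f"invalid tally {count}/{n_tot}")
    prop = count / n_tot
    ci_low, ci_high = proportion_confint(count, n_tot, alpha=0.05, method="wilson")
    se0 = math.sqrt(null_proportion * (1.0 - null_proportion) / n_tot)
    z = 0.0 if se0 == 0 else (prop - null_proportion) / se0
    p_one = float(norm.sf(abs(z)))
    return FixationEstimate(
        n_replicates=n_tot,
        n_fixed_risk_averse=count,
        proportion=prop,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        z=z,
        p_one_tailed=p_one,
        p_two_tailed=min(1.0, 2.0 * p_one),
        null_proportion=null_proportion,
        alpha=alpha,
    )


def compare_to_null_band(
    estimate: FixationEstimate, target: float, tolerance_se_multiplier: float = 3.0
) -> bool:
    """Is the estimate within m binomial standard errors of a target?

    The band half-width is m * sqrt(target (1 - target) / n), the
    sampling error a simulation of the same size would have if the true
    fixation probability were ``target``.
    """
    half = tolerance_se_multiplier * math.sqrt(
        target * (1.0 - target) / estimate.n_replicates
    )
    return abs(estimate.proportion - target) <= half
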