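"""Bayesian beta-binomial monitoring for a single-arm phase-2 trial.

The clinical-benefit probability ``p`` carries a conjugate Beta prior.  At
the interim look the trial stops for futility when the posterior probability
that ``p`` lies below a reference rate exceeds a threshold, i.e.

    stop  iff  P(p < p_ref | data) > threshold.

With the study prior Beta(0.5, 9.5) (prior mean 0.05, ten hypothetical
patients), reference rate 0.05 and threshold 0.95, the futility boundary at
a 29-patient interim is 0 successes: only a completely benefit-free first
stage stops the trial.

The posterior tail probability is the regularized incomplete beta function,
evaluated by :func:`scipy.special.betainc` (continued-fraction accuracy).
The s = 0 case sits within ~2.5e-3 of the 0.95 threshold, so a coarse
quadrature would be unsafe here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import special, stats

__all__ = [
    "BetaDistribution",
    "MonitoringRule",
    "Decision",
    "InterimResult",
    "OperatingCharacteristics",
    "OCMode",
    "prior_summary",
    "posterior_update",
    "prob_below",
    "stopping_boundary",
    "interim_decision",
    "operating_characteristics",
]


@dataclass(frozen=True)
class BetaDistribution:
    """Beta(alpha, beta_) distribution over a response probability.

    ``alpha`` counts pseudo-successes and ``beta_`` pseudo-failures; the
    trailing underscore avoids shadowing the distribution family name.
    """

    alpha: float
    beta_: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta_ > 0):
            raise ValueError(
                f"Beta parameters must be positive, got ({self.alpha}, {self.beta_})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta_)

    @property
    def ess(self) -> float:
        """Effective (prior) sample size alpha + beta_."""
        return self.alpha + self.beta_


class Decision(str, Enum):
    STOP = "STOP"
    CONTINUE = "CONTINUE"


class OCMode(str, Enum):
    EXACT = "EXACT"
    MONTECARLO = "MONTECARLO"


@dataclass(frozen=True)
class MonitoringRule:
    """Futility-monitoring rule: stop iff P(p < p_ref | data) > threshold."""

    prior: BetaDistribution = field(
        default_factory=lambda: BetaDistribution(0.5, 9.5)
    )
    p_ref: float = 0.05
    threshold: float = 0.95
    interim_n: int = 29
    total_n: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.p_ref < 1:
            raise ValueError(f"p_ref must lie in (0,1), got {self.p_ref}")
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must lie in (0,1), got {self.threshold}")
        if not 0 < self.interim_n <= self.total_n:
            raise ValueError(
                f"need 0 < interim_n <= total_n, got {self.interim_n}, {self.total_n}"
            )


@dataclass(frozen=True)
class InterimResult:
    n_observed: int
    successes: int
    posterior: BetaDistribution
    prob_below_ref: float
    decision: Decision


@dataclass(frozen=True)
class OperatingCharacteristics:
    true_p: float
    prob_early_stop: float
    expected_sample_size: float
    prob_reach_full_accrual: float


def prior_summary(prior: BetaDistribution) -> dict[str, float]:
    """Prior mean and effective sample size of a Beta prior."""
    return {"mean": prior.mean, "ess": prior.ess}


def posterior_update(prior: BetaDistribution, successes: int, n: int) -> BetaDistribution:
    """Conjugate update: Beta(a, b) + s successes in n → Beta(a+s, b+n−s)."""
    if n < 0 or successes < 0 or successes > n:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    return BetaDistribution(prior.alpha + successes, prior.beta_ + n - successes)


def prob_below(dist: BetaDistribution, p_ref: float) -> float:
    """P(p < p_ref) under ``dist``, the regularized incomplete beta I_x(a, b)."""
    if not 0 <= p_ref <= 1:
        raise ValueError(f"p_ref must lie in [0,1], got {p_ref}")
    return float(special.betainc(dist.alpha, dist.beta_, p_ref))


def stopping_boundary(rule: MonitoringRule) -> int:
    """Largest success count r at the interim for which the stop criterion holds.

    The trial stops at the interim iff observed successes ≤ r.  Because the
    posterior tail probability is strictly decreasing in the success count,
    the boundary is the run length of consecutive passes starting at s = 0.
    Returns −1 when even s = 0 fails the criterion (no futility boundary).
    """
    r = -1
    for s in range(rule.interim_n + 1):
        post = posterior_update(rule.prior, s, rule.interim_n)
        if prob_below(post, rule.p_ref) > rule.threshold:
            r = s
        else:
            break
    return r


def interim_decision(rule: MonitoringRule, successes: int, n_observed: int) -> InterimResult:
    """Evaluate the stop criterion on the actually observed interim data.

    ``n_observed`` need not equal ``rule.interim_n``: the study's first stage
    over-enrolled by one patient, and the decision is taken on the data seen.
    """
    post = posterior_update(rule.prior, successes, n_observed)
    tail = prob_below(post, rule.p_ref)
    decision = Decision.STOP if tail > rule.threshold else Decision.CONTINUE
    return InterimResult(
        n_observed=n_observed,
        successes=successes,
        posterior=post,
        prob_below_ref=tail,
        decision=decision,
    )


def operating_characteristics(
    rule: MonitoringRule,
    true_p: float,
    mode: OCMode | str = OCMode.EXACT,
    n_sims: int = 100_000,
    seed: int = 0,
) -> OperatingCharacteristics:
    """Early-stop probability and expected sample size at a true response rate.

    EXACT mode evaluates P(X ≤ r) for X ~ Binomial(interim_n, true_p) with
    r the futility boundary; MONTECARLO estimates the same by seeded
    simulation of interim success counts.
    """
    if not 0 <= true_p <= 1:
        raise ValueError(f"true_p must lie in [0,1], got {true_p}")
    mode = OCMode(mode)
    r = stopping_boundary(rule)
    if mode is OCMode.EXACT:
        p_stop = 0.0 if r < 0 else float(stats.binom.cdf(r, rule.interim_n, true_p))
    else:
        if n_sims <= 0:
            raise ValueError(f"n_sims must be positive, got {n_sims}")
        rng = np.random.default_rng(seed)
        x = rng.binomial(rule.interim_n, true_p, size=n_sims)
        p_stop = 0.0 if r < 0 else float(np.mean(x <= r))
    p_full = 1.0 - p_stop
    e_n = rule.interim_n * p_stop + rule.total_n * p_full
    return OperatingCharacteristics(
        true_p=true_p,
        prob_early_stop=p_stop,
        expected_sample_size=e_n,
        prob_reach_full_accrual=p_full,
    )
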