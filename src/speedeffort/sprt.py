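"""Sequential probability ratio test with effort-dependent perceptual noise.

An agent must classify a binary world state (a tree is "good" or "bad") from
a stream of binary samples (fruit husks that read green or pale).  Under a
good tree a husk is green with probability ``eps_good``; under a bad tree,
with probability ``eps_bad < eps_good``.  Perception is imperfect: each husk
is read correctly with probability ``phi`` (the effort level) and otherwise
replaced by a fair coin flip, so the *effective* sample distributions are

    eps'_g = phi * eps_good + (1 - phi) / 2
    eps'_b = phi * eps_bad  + (1 - phi) / 2.

A self-aware agent runs the SPRT on these adjusted distributions: a green
reading adds ``w+ = log(eps'_g / eps'_b)`` to the decision variable, a pale
reading adds ``w- = log((1 - eps'_g) / (1 - eps'_b))``, and the agent stops
the first time the running sum leaves ``(-A, A)`` with
``A = log(theta / (1 - theta))``.  Time is measured in samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "THRESHOLD_TOL",
    "EnvironmentParams",
    "Policy",
    "EffectivePerception",
    "TrialRecord",
    "EnsembleSummary",
    "adjusted_params",
    "perceive_sample",
    "decide",
    "log_odds_threshold",
    "run_trial",
    "simulate_ensemble",
]

#: Absolute slack used when comparing the decision variable against the
#: stopping boundaries.  Lattice-aligned parameterizations (threshold an
#: exact multiple of the step size) land bit-exactly on the boundary, where
#: raw floating-point comparison is a coin flip; the slack makes the
#: comparison stable and is shared with the absorption oracle so simulator
#: and oracle classify identically.
THRESHOLD_TOL = 1e-9

GOOD = 1
BAD = 0

Decision = Literal["good", "bad", "undecided", "continue"]


@dataclass(frozen=True)
class EnvironmentParams:
    """The world an agent makes decisions in.

    Parameters
    ----------
    eps_good : float
        Probability a husk under a good tree is green. Must exceed ``eps_bad``.
    eps_bad : float
        Probability a husk under a bad tree is green.
    prior_good : float
        Probability the true state is good (default 0.5: states drawn 50/50).
    benefit : float
        Fitness benefit ``B`` of a correct decision.
    c_time : float
        Baseline fitness cost ``C_t`` per sample, independent of effort.
    """

    eps_good: float
    eps_bad: float
    prior_good: float = 0.5
    benefit: float = 0.0
    c_time: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.eps_bad < self.eps_good < 1.0:
            raise ValueError(
                "require 0 < eps_bad < eps_good < 1, got "
                f"eps_bad={self.eps_bad}, eps_good={self.eps_good}"
            )
        if not 0.0 < self.prior_good < 1.0:
            raise ValueError(f"prior_good must be in (0, 1), got {self.prior_good}")
        if self.benefit < 0:
            raise ValueError(f"benefit must be >= 0, got {self.benefit}")
        if self.c_time < 0:
            raise ValueError(f"c_time must be >= 0, got {self.c_time}")


@dataclass(frozen=True)
class Policy:
    """An agent's strategy: decision threshold and effort level.

    ``theta`` in (0.5, 1) sets the symmetric stopping boundaries at
    ``±log(theta/(1-theta))``; the closer to 1, the more evidence is
    gathered.  ``phi`` in [0, 1) is the probability a sample is perceived
    error-free; ``phi = 1`` is excluded because perfect perception has
    infinite effort cost.
    """

    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.5 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0.5, 1), got {self.theta}")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phi must be in [0, 1), got {self.phi}")


@dataclass(frozen=True)
class EffectivePerception:
    """Effective sample distributions and SPRT weights after perceptual noise."""

    eps_good_eff: float
    eps_bad_eff: float
    w_plus: float
    w_minus: float


@dataclass(frozen=True)
class TrialRecord:
    """One simulated decision trial.

    ``correct`` is ``None`` for undecided (truncated) trials, which occur
    only when the sample budget ``t_max`` is exhausted.
    """

    true_state: int
    decision: Decision
    n_samples: int
    correct: bool | None


@dataclass(frozen=True)
class EnsembleSummary:
    """Aggregate of an ensemble of trials under one (environment, policy) pair.

    ``p_correct`` is the fraction of *decided* trials that were correct
    (NaN if every trial was truncated); ``mean_decision_time`` averages
    over all trials, counting truncated trials at ``t_max``.
    """

    p_correct: float
    mean_decision_time: float
    n_trials: int
    n_truncated: int
    n_true_good: int = field(default=0)


def adjusted_params(phi: float, env: EnvironmentParams) -> EffectivePerception:
    """Effective sample distributions and log-likelihood weights at effort ``phi``.

    With probability ``1 - phi`` a reading is a fair coin flip, so the
    effective green probabilities are the ``phi``-mixture of the true
    distribution with 1/2.  At ``phi = 0`` the stream is pure noise and both
    weights are zero.
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    eg = phi * env.eps_good + (1.0 - phi) / 2.0
    eb = phi * env.eps_bad + (1.0 - phi) / 2.0
    w_plus = math.log(eg / eb)
    w_minus = math.log((1.0 - eg) / (1.0 - eb))
    return EffectivePerception(eg, eb, w_plus, w_minus)


def perceive_sample(true_husk: int, phi: float, rng: np.random.Generator) -> int:
    """Read one husk through a noisy channel.

    Returns the true value with probability ``phi``; otherwise a fair coin
    flip (so the overall probability of reading the truth is
    ``phi + (1 - phi)/2``).
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    if rng.random() < phi:
        return int(true_husk)
    return int(rng.random() < 0.5)


def log_odds_threshold(theta: float) -> float:
    """Stopping boundary magnitude ``A = log(theta / (1 - theta))``."""
    if not 0.5 < theta < 1.0:
        raise ValueError(f"theta must be in (0.5, 1), got {theta}")
    return math.log(theta / (1.0 - theta))


def decide(y: float, theta: float) -> Decision:
    """Apply the SPRT stopping rule to the decision variable ``y``.

    Returns "good" if ``y`` has reached the upper boundary, "bad" at the
    lower boundary, "continue" otherwise.  Boundary comparison uses
    :data:`THRESHOLD_TOL` slack.
    """
    a = log_odds_threshold(theta)
    if y >= a - THRESHOLD_TOL:
        return "good"
    if y <= -a + THRESHOLD_TOL:
        return "bad"
    return "continue"


def run_trial(
    env: EnvironmentParams,
    policy: Policy,
    rng: np.random.Generator,
    t_max: int = 10_000,
) -> TrialRecord:
    """Simulate a single SPRT decision trial.

    Draws the true state from the prior, then repeatedly draws a husk from
    the state's distribution, perceives it through the ``phi`` channel, and
    accumulates the corresponding weight until a boundary is crossed or
    ``t_max`` samples are spent (decision "undecided").  At ``phi = 0`` the
    weights are zero and the trial always truncates; this is reported, not
    raised.
    """
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    perc = adjusted_params(policy.phi, env)
    true_state = GOOD if rng.random() < env.prior_good else BAD
    eps = env.eps_good if true_state == GOOD else env.eps_bad
    y = 0.0
    for t in range(1, t_max + 1):
        husk = int(rng.random() < eps)
        sample = perceive_sample(husk, policy.phi, rng)
        y += perc.w_plus if sample == 1 else perc.w_minus
        d = decide(y, policy.theta)
        if d != "continue":
            correct = (d == "good") == (true_state == GOOD)
            return TrialRecord(true_state, d, t, correct)
    return TrialRecord(true_state, "undecided", t_max, None)


def simulate_ensemble(
    env: EnvironmentParams,
    policy: Policy,
    n_trials: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    t_max: int = 10_000,
) -> EnsembleSummary:
    """Simulate an ensemble of independent trials and aggregate.

    Vectorized across trials: at each time step only still-undecided trials
    draw a husk and a perception event, so total work scales with the sum of
    decision times.  Reproducible: a fixed ``seed`` gives a bit-identical
    summary.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perc = adjusted_params(policy.phi, env)
    a = log_odds_threshold(policy.theta)

    true_good = rng.random(n_trials) < env.prior_good
    eps = np.where(true_good, env.eps_good, env.eps_bad)

    y = np.zeros(n_trials)
    n_samples = np.full(n_trials, t_max, dtype=np.int64)
    dec_good = np.zeros(n_trials, dtype=bool)
    decided = np.zeros(n_trials, dtype=bool)
    active = np.arange(n_trials)

    if perc.w_plus > 0.0:  # phi = 0 gives zero weights: nothing ever decides
        for t in range(1, t_max + 1):
            m = active.size
            husk = rng.random(m) < eps[active]
            keep = rng.random(m) < policy.phi
            flip = rng.random(m) < 0.5
            sample = np.where(keep, husk, flip)
            y[active] += np.where(sample, perc.w_plus, perc.w_minus)
            hi = y[active] >= a - THRESHOLD_TOL
            lo = y[active] <= -a + THRESHOLD_TOL
            done = hi | lo
            if done.any():
                idx = active[done]
                n_samples[idx] = t
                dec_good[idx] = hi[done]
                decided[idx] = True
                active = active[~done]
                if active.size == 0:
                    break

    n_truncated = int(n_trials - decided.sum())
    correct = decided & (dec_good == true_good)
    n_decided = int(decided.sum())
    p_correct = float(correct.sum() / n_decided) if n_decided else float("nan")
    return EnsembleSummary(
        p_correct=p_correct,
        mean_decision_time=float(n_samples.mean()),
        n_trials=n_trials,
        n_truncated=n_truncated,
        n_true_good=int(true_good.sum()),
    )
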