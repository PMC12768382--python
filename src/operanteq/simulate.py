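"""Stochastic simulation of the operant-learning Markov process.

Two-choice process: the state x ∈ [0, 1] is the current probability of one
response; each trial applies the transition operator g₁ with probability x
(the response occurred) and g₂ otherwise.  With the classical boundary
conditions g₁(1) = 1, g₂(0) = 0, the endpoints are absorbing and the
probability of ultimately fixating at 1, as a function of the start state,
solves the discrete functional equation f(x) = x f(g₁(x)) + (1−x) f(g₂(x))
by first-step analysis.  When g₁(x) = (1−a)x + a and g₂(x) = (1−a)x with
equal rates, the state is a martingale and f(x) = x in closed form — the
simulator's primary calibration check.

Four-outcome process: per trial one of four outcomes is drawn with
probabilities p·x, (1−p)·x, p·(1−x), (1−p)·(1−x) at the current state x
and the matched operator ℰᵢ is applied.  No absorbing structure is
asserted; trajectories and censoring are reported as observed.

Replicate reproducibility: each replicate's generator is derived from the
master seed and the replicate index through ``numpy.random.SeedSequence``
(counter-based spawning), so runs are bit-for-bit reproducible and
replicates are independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DiscreteModel, ResponseOperator
from .numeric import GridFunction, solve_discrete

__all__ = [
    "TrialPath",
    "SimulationSummary",
    "simulate_two_choice",
    "estimate_fixation_probability",
    "simulate_four_outcome",
    "compare_to_solution",
]

# the model itself defines no stopping rule; fixation bands plus a horizon
# make "final probability" operational without biasing either class
DEFAULT_EPS = 1e-6
DEFAULT_MAX_STEPS = 100_000


@dataclass
class TrialPath:
    """One simulated trajectory of the state x.

    ``outcome`` is "fixated_high" when the final state enters [1−eps, 1],
    "fixated_low" for [0, eps], and "censored" when the horizon ran out
    with the state still interior.
    """

    states: np.ndarray
    outcome: str
    steps: int
    seed: int

    @property
    def final_state(self) -> float:
        return float(self.states[-1])


@dataclass
class SimulationSummary:
    """Monte-Carlo fixation estimate with its binomial standard error.

    Censored paths are excluded from the p_hat denominator and counted
    separately, never silently assigned to either class.
    """

    n_reps: int
    x0: float
    p_hat: float
    se: float
    censored_count: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "x0": self.x0,
            "p_hat": self.p_hat,
            "se": self.se,
            "n": self.n_reps,
            "censored": self.censored_count,
            "seed": self.seed,
        }


def _rng_for(seed: int, rep: int | None = None) -> np.random.Generator:
    key = (int(seed),) if rep is None else (int(seed), int(rep))
    return np.random.default_rng(np.random.SeedSequence(key))


def _classify(x: float, eps: float) -> str | None:
    if x >= 1.0 - eps:
        return "fixated_high"
    if x <= eps:
        return "fixated_low"
    return None


def simulate_two_choice(
    model: DiscreteModel,
    x0: float,
    seed: int,
    max_steps: int = DEFAULT_MAX_STEPS,
    eps: float = DEFAULT_EPS,
) -> TrialPath:
    """Simulate one two-choice path from x0, recording every state.

    Per trial: with probability x apply g₁, else g₂; stop on entering a
    fixation band [0, eps] or [1−eps, 1], or censor at max_steps.
    """
    if not (0.0 <= x0 <= 1.0):
        raise ValueError(f"x0={x0} outside [0, 1]")
    if not (0.0 < eps < 0.5):
        raise ValueError(f"eps={eps} outside (0, 1/2)")
    rng = _rng_for(seed)
    x = float(x0)
    states = [x]
    outcome = _classify(x, eps)
    steps = 0
    while outcome is None and steps < max_steps:
        if rng.random() < x:
            x = float(model.g1(x))
        else:
            x = float(model.g2(x))
        x = min(1.0, max(0.0, x))
        states.append(x)
        steps += 1
        outcome = _classify(x, eps)
    return TrialPath(
        states=np.asarray(states),
        outcome=outcome or "censored",
        steps=steps,
        seed=int(seed),
    )


def estimate_fixation_probability(
    model: DiscreteModel,
    x0: float,
    n_reps: int,
    seed: int,
    max_steps: int = DEFAULT_MAX_STEPS,
    eps: float = DEFAULT_EPS,
) -> SimulationSummary:
    """Monte-Carlo estimate of the fixation probability f(x0).

    Each replicate consumes its own counter-derived generator stream
    (master seed, replicate index), so replicates are independent and the
    whole estimate is reproducible bit-for-bit from the master seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0.0 <= x0 <= 1.0):
        raise ValueError(f"x0={x0} outside [0, 1]")
    if not (0.0 < eps < 0.5):
        raise ValueError(f"eps={eps} outside (0, 1/2)")

    high = low = censored = 0
    for rep in range(n_reps):
        rng = _rng_for(seed, rep)
        x = float(x0)
        outcome = _classify(x, eps)
        steps = 0
        while outcome is None and steps < max_steps:
            if rng.random() < x:
                x = float(model.g1(x))
            else:
                x = float(model.g2(x))
            x = min(1.0, max(0.0, x))
            steps += 1
            outcome = _classify(x, eps)
        if outcome == "fixated_high":
            high += 1
        elif outcome == "fixated_low":
            low += 1
        else:
            censored += 1

    n_eff = high + low
    p_hat = high / n_eff if n_eff else float("nan")
    se = sqrt(p_hat * (1.0 - p_hat) / n_eff) if n_eff else float("nan")
    return SimulationSummary(
        n_reps=n_reps,
        x0=float(x0),
        p_hat=p_hat,
        se=se,
        censored_count=censored,
        seed=int(seed),
    )


def simulate_four_outcome(
    p: float,
    ops: Sequence[ResponseOperator],
    x0: float,
    seed: int,
    max_steps: int = DEFAULT_MAX_STEPS,
    eps: float = DEFAULT_EPS,
) -> TrialPath:
    """Simulate the four-outcome reward process.

    Outcome probabilities at state x are (p·x, (1−p)·x, p·(1−x), (1−p)·(1−x)),
    which sum to one for every (p, x); the drawn outcome's operator is
    applied to the state.  Absorption is not assumed: paths that reach a
    fixation band stop, all others are censored at the horizon.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p={p} outside [0, 1]")
    if len(ops) != 4:
        raise ValueError("exactly four response operators required")
    if not (0.0 <= x0 <= 1.0):
        raise ValueError(f"x0={x0} outside [0, 1]")
    rng = _rng_for(seed)
    x = float(x0)
    states = [x]
    outcome = _classify(x, eps)
    steps = 0
    while outcome is None and steps < max_steps:
        probs = (p * x, (1.0 - p) * x, p * (1.0 - x), (1.0 - p) * (1.0 - x))
        u = rng.random()
        acc = 0.0
        chosen = 3
        for i, q in enumerate(probs):
            acc += q
            if u < acc:
                chosen = i
                break
        x = min(1.0, max(0.0, float(ops[chosen](x))))
        states.append(x)
        steps += 1
        outcome = _classify(x, eps)
    return TrialPath(
        states=np.asarray(states),
        outcome=outcome or "censored",
        steps=steps,
        seed=int(seed),
    )


def compare_to_solution(
    model: DiscreteModel,
    x_grid: Sequence[float],
    n_reps: int,
    seed: int,
    n_points: int = 1001,
    max_steps: int = DEFAULT_MAX_STEPS,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Cross-validate the discrete solver against Monte-Carlo fixation rates.

    Returns a table with columns x0, f_solved, p_hat, se, z (=|diff|/SE)
    and a boolean ``flagged`` for points with |diff| > 3·SE.  n_reps = 0
    yields an empty table.
    """
    columns = ["x0", "f_solved", "p_hat", "se", "z", "flagged"]
    if n_reps == 0:
        return pd.DataFrame(columns=columns)
    solved = solve_discrete(model, n_points=n_points)
    rows = []
    for i, x0 in enumerate(x_grid):
        f_val = float(solved.solution.interp(np.asarray([x0]))[0])
        summary = estimate_fixation_probability(
            model, x0, n_reps, seed=int(seed) + i, max_steps=max_steps, eps=eps
        )
        diff = abs(summary.p_hat - f_val)
        z = diff / summary.se if summary.se > 0 else float("inf") * (diff > 0)
        rows.append(
            {
                "x0": float(x0),
                "f_solved": f_val,
                "p_hat": summary.p_hat,
                "se": summary.se,
                "z": float(z),
                "flagged": bool(z > 3.0),
            }
        )
    return pd.DataFrame(rows, columns=columns)
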