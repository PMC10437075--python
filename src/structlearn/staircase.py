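"""Two-down one-up adaptive staircase with a simulated observer.

The visual working-memory covariate task adapts set size (number of dots,
integer >= 2, starting at 2): after two consecutive correct responses at a
level the display gets one dot harder, after a single error one dot easier.
This rule converges on the difficulty where P(correct) = sqrt(0.5) = 70.7%.
A run ends after 10 reversals; the threshold of a run is the mean of the
last two-thirds (ceil(2k/3)) of its reversal levels, and a participant's
score averages 3 runs.  Within a session the first run starts at two dots
and later runs continue from the level the previous run adapted to, so the
ascent toward threshold is paid only once.

The observer is a logistic psychometric function decreasing in set size with
a guess-rate floor of 0.5 (the task is a same/different judgment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ObserverModel",
    "StaircaseState",
    "step",
    "run_staircase",
    "run_session",
    "threshold",
    "convergence_accuracy",
    "converged_level",
    "stationary_accuracy",
]

MIN_LEVEL = 2
TARGET_ACCURACY = math.sqrt(0.5)  # ~0.7071, the 2-down/1-up equilibrium


@dataclass(frozen=True)
class ObserverModel:
    """Logistic observer: P(correct | level) falls from ~1 toward the guess
    rate as set size grows.  ``midpoint`` is the level of the inflection
    point and ``width`` its scale in dots."""

    midpoint: float = 6.0
    width: float = 1.5
    guess_rate: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValueError("guess_rate must lie in [0, 1)")
        if self.width <= 0:
            raise ValueError("width must be positive")

    def p_correct(self, level: float) -> float:
        return self.guess_rate + (1.0 - self.guess_rate) * float(
            expit(-(level - self.midpoint) / self.width)
        )


def converged_level(observer: ObserverModel) -> float:
    """The (continuous) level where the observer performs at 70.7% correct —
    the staircase's theoretical convergence point."""
    g = observer.guess_rate
    if TARGET_ACCURACY <= g:
        raise ValueError("observer never falls to the 70.7% equilibrium")
    frac = (TARGET_ACCURACY - g) / (1.0 - g)
    return observer.midpoint + observer.width * math.log((1.0 - frac) / frac)


@dataclass
class StaircaseState:
    level: int = MIN_LEVEL
    history: list[tuple[int, bool]] = field(default_factory=list)
    reversals: list[int] = field(default_factory=list)
    reversal_trials: list[int] = field(default_factory=list)
    rule: str = "two_down_one_up"
    runs: int = 1
    _streak: int = 0
    _last_direction: int = 0


def step(state: StaircaseState, observer: ObserverModel, rng: np.random.Generator) -> StaircaseState:
    """One trial: sample correctness at the current level and apply the
    two-down one-up rule (floor at 2 dots).

    A direction change records the pre-move level as a reversal; a down-step
    clipped at the floor still counts as downward movement.
    """
    correct = bool(rng.random() < observer.p_correct(state.level))
    state.history.append((state.level, correct))
    direction = 0
    if correct:
        state._streak += 1
        if state._streak == 2:
            direction = +1
            state._streak = 0
    else:
        direction = -1
        state._streak = 0
    if direction != 0:
        if state._last_direction != 0 and direction != state._last_direction:
            state.reversals.append(state.level)
            state.reversal_trials.append(len(state.history))
        state._last_direction = direction
        state.level = max(MIN_LEVEL, state.level + direction)
    return state


def run_staircase(
    observer: ObserverModel,
    rng: np.random.Generator,
    n_reversals: int = 10,
    start_level: int = MIN_LEVEL,
    max_trials: int = 2000,
) -> StaircaseState:
    """Run one staircase until ``n_reversals`` reversals (or the trial cap,
    which only degenerate observers hit)."""
    state = StaircaseState(level=start_level)
    while len(state.reversals) < n_reversals and len(state.history) < max_trials:
        step(state, observer, rng)
    return state


def run_session(
    observer: ObserverModel,
    rng: np.random.Generator,
    n_runs: int = 3,
    n_reversals: int = 10,
    carryover: bool = True,
) -> list[StaircaseState]:
    """A session of staircase runs.

    The first run starts at the two-dot display; with ``carryover`` (the
    default) each later run continues from the preceding run's final level,
    so only the first run spends trials climbing from the easy start toward
    threshold.
    """
    states: list[StaircaseState] = []
    level = MIN_LEVEL
    for r in range(n_runs):
        state = run_staircase(observer, rng, n_reversals=n_reversals, start_level=level)
        state.runs = r + 1
        states.append(state)
        if carryover:
            level = state.level
    return states


def stationary_accuracy(observer: ObserverModel, max_level: int = 200) -> float:
    """Exact asymptotic trial-weighted accuracy of the two-down one-up rule.

    Level moves form a birth-death chain with up-rate p(L)^2 and down-rate
    1 - p(L)^2 per decision epoch; a decision at level L spends 1 + p(L)
    trials on average.  The trial-weighted mean of p over the stationary
    level distribution is the long-run proportion correct, which sits at
    sqrt(0.5) for any psychometric function crossing that value.
    """
    levels = np.arange(MIN_LEVEL, max_level + 1)
    p = np.array([observer.p_correct(l) for l in levels])
    up = np.clip(p**2, 1e-300, 1.0)
    down = np.clip(1.0 - p**2, 1e-300, 1.0)
    log_pi = np.concatenate([[0.0], np.cumsum(np.log(up[:-1]) - np.log(down[1:]))])
    pi = np.exp(log_pi - log_pi.max())
    dwell = pi * (1.0 + p)
    dwell /= dwell.sum()
    return float(dwell @ p)


def threshold(state_list: list[StaircaseState], fraction: float = 2.0 / 3.0) -> float:
    """Score across runs: per run, the mean of the last ceil(fraction*k)
    reversal levels; the final score averages the runs."""
    per_run = []
    for state in state_list:
        k = len(state.reversals)
        if k < 3:
            raise ValueError(f"run has only {k} reversals; need at least 3")
        take = math.ceil(fraction * k)
        per_run.append(float(np.mean(state.reversals[-take:])))
    return float(np.mean(per_run))


def convergence_accuracy(state_list: list[StaircaseState], skip_reversals: int = 3) -> float:
    """Mean proportion correct over post-convergence trials (those after the
    ``skip_reversals``-th reversal), averaged across runs."""
    per_run = []
    for state in state_list:
        if len(state.reversal_trials) < skip_reversals:
            raise ValueError("run has fewer reversals than the burn-in")
        start = state.reversal_trials[skip_reversals - 1]
        tail = [c for _, c in state.history[start:]]
        if tail:
            per_run.append(float(np.mean(tail)))
    if not per_run:
        raise ValueError("no post-convergence trials")
    return float(np.mean(per_run))
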