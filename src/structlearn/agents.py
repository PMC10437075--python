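"""Synthetic participants for the sequence-prediction task.

Policies span the strategy continuum the analysis is built to detect:

* ``random`` — uniform over the four symbols,
* ``matching`` — probability matching: respond with the contingency
  probabilities themselves,
* ``maximizing`` — always pick the most likely target for the context,
* ``interpolated`` — (1-λ)·matching + λ·maximizing, the ground-truth dial
  used for parameter recovery,
* ``learning`` — a pseudo-count (Dirichlet-style) tally of observed
  context→target transitions, read out through matching or maximizing.
  This is an explicit stand-in mechanism: the experiments it emulates do
  not commit to a participant model, only to the behavioural readout.

Lapses: with probability ``p_null`` an agent emits a null response, which is
registered as a uniform 0.25 vector over the four symbols — the same rule
the prediction task applies to timed-out human responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .markov_design import (
    N_SYMBOLS,
    SYMBOL_INDEX,
    SYMBOLS,
    MarkovModel,
    TrialSequence,
)

__all__ = [
    "POLICIES",
    "AgentConfig",
    "BeliefState",
    "ResponseRecord",
    "policy_distribution",
    "respond",
    "update_belief",
]

POLICIES = ("random", "matching", "maximizing", "interpolated", "learning")
UNIFORM = np.full(N_SYMBOLS, 0.25)


@dataclass(frozen=True)
class AgentConfig:
    policy: str = "matching"
    lambda_mix: float | None = None
    p_null: float = 0.0
    learn_rate: float = 1.0
    feedback_sensitivity: float = 0.0
    readout: str = "matching"  # learning policy only: matching | maximizing
    tie_break: str = "error"  # maximizing argmax ties: error | lexicographic
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; expected one of {POLICIES}")
        if not 0.0 <= self.p_null <= 1.0:
            raise ValueError(f"p_null must lie in [0, 1], got {self.p_null}")
        if self.policy == "interpolated":
            if self.lambda_mix is None or not 0.0 <= self.lambda_mix <= 1.0:
                raise ValueError("interpolated policy requires lambda_mix in [0, 1]")
        elif self.lambda_mix is not None:
            raise ValueError("lambda_mix is defined only for the interpolated policy")
        if self.learn_rate < 0:
            raise ValueError("learn_rate must be nonnegative")
        if self.readout not in ("matching", "maximizing"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.tie_break not in ("error", "lexicographic"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class BeliefState:
    """Pseudo-count tally of observed context→target transitions."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((N_SYMBOLS, N_SYMBOLS)))
    prior_weight: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_SYMBOLS, N_SYMBOLS):
            raise ValueError("belief counts must be 4x4")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("belief counts must be finite and nonnegative")

    @property
    def conditionals(self) -> np.ndarray:
        """Posterior-mean conditionals (counts + prior) / row totals."""
        smoothed = self.counts + self.prior_weight
        return smoothed / smoothed.sum(axis=1, keepdims=True)


@dataclass
class ResponseRecord:
    """One response: a point mass on the chosen symbol, or the uniform 0.25
    vector for a null (lapse) response."""

    trial_id: int
    block_id: int
    context: str
    response_vector: np.ndarray
    chosen: str | None
    feedback: str = "none"  # correct | incorrect | none
    rt_proxy: float | None = None


def _table_for(model_or_belief: MarkovModel | BeliefState | np.ndarray) -> np.ndarray:
    if isinstance(model_or_belief, MarkovModel):
        return model_or_belief.transitions
    if isinstance(model_or_belief, BeliefState):
        return model_or_belief.conditionals
    return np.asarray(model_or_belief, dtype=float)


def _argmax_point_mass(row: np.ndarray, tie_break: str) -> np.ndarray:
    top = row.max()
    winners = np.flatnonzero(row >= top - 1e-12)
    if len(winners) > 1 and tie_break == "error":
        raise ValueError(
            f"maximizing policy hit an argmax tie between {[SYMBOLS[i] for i in winners]}; "
            "configure tie_break='lexicographic' to break ties"
        )
    out = np.zeros(N_SYMBOLS)
    out[winners[0]] = 1.0
    return out


def policy_distribution(
    agent: AgentConfig,
    context: str | int,
    model_or_belief: MarkovModel | BeliefState | np.ndarray,
) -> np.ndarray:
    """Choice distribution over the four symbols for one context."""
    c = SYMBOL_INDEX[context] if isinstance(context, str) else int(context)
    if agent.policy == "random":
        return UNIFORM.copy()
    table = _table_for(model_or_belief)
    row = table[c]
    if agent.policy == "matching":
        return row.copy()
    if agent.policy == "maximizing":
        return _argmax_point_mass(row, agent.tie_break)
    if agent.policy == "interpolated":
        lam = float(agent.lambda_mix)
        return (1.0 - lam) * row + lam * _argmax_point_mass(row, agent.tie_break)
    # learning: read the belief conditionals through the configured readout
    if not isinstance(model_or_belief, BeliefState):
        raise ValueError("learning policy requires a BeliefState")
    if agent.readout == "matching":
        return row.copy()
    return _argmax_point_mass(row, "lexicographic")


def respond(
    agent: AgentConfig,
    trial: TrialSequence,
    model_or_belief: MarkovModel | BeliefState | np.ndarray,
    rng: np.random.Generator,
    trial_id: int = -1,
    block_id: int = -1,
) -> ResponseRecord:
    """Sample one response to a trial; lapses yield the null record."""
    if agent.p_null > 0 and rng.random() < agent.p_null:
        return ResponseRecord(
            trial_id=trial_id,
            block_id=block_id,
            context=trial.context,
            response_vector=UNIFORM.copy(),
            chosen=None,
        )
    dist = policy_distribution(agent, trial.context, model_or_belief)
    choice = int(np.searchsorted(np.cumsum(dist), rng.random()))
    choice = min(choice, N_SYMBOLS - 1)  # guard against cumsum rounding
    vec = np.zeros(N_SYMBOLS)
    vec[choice] = 1.0
    return ResponseRecord(
        trial_id=trial_id,
        block_id=block_id,
        context=trial.context,
        response_vector=vec,
        chosen=SYMBOLS[choice],
    )


def update_belief(
    belief: BeliefState,
    trial: TrialSequence,
    record: ResponseRecord,
    feedback_mode: str,
    agent: AgentConfig,
    rng: np.random.Generator | None = None,
) -> BeliefState:
    """Return the belief after one trial.

    Exposure: every within-sequence (context, target) pair adds
    ``learn_rate`` to its cell.  Trial feedback: a "correct" outcome adds a
    bonus of ``feedback_sensitivity * learn_rate`` to (context, chosen);
    uncorrelated feedback applies the same bonus to a random cell, which
    injects noise rather than signal.  Block feedback and no feedback carry
    no trial-level learning signal beyond exposure.
    """
    if agent.learn_rate < 0:
        raise ValueError("learn_rate must be nonnegative")
    counts = belief.counts.copy()
    idx = [SYMBOL_INDEX[s] for s in trial.symbols]
    for prev, nxt in zip(idx[:-1], idx[1:]):
        counts[prev, nxt] += agent.learn_rate
    bonus = agent.feedback_sensitivity * agent.learn_rate
    if bonus > 0 and record.feedback == "correct":
        if feedback_mode == "trial" and record.chosen is not None:
            counts[SYMBOL_INDEX[record.context], SYMBOL_INDEX[record.chosen]] += bonus
        elif feedback_mode == "uncorrelated":
            if rng is None:
                raise ValueError("uncorrelated feedback updates need an rng")
            counts[rng.integers(N_SYMBOLS), rng.integers(N_SYMBOLS)] += bonus
    return BeliefState(counts=counts, prior_weight=belief.prior_weight)
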