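"""End-to-end experiment simulation.

Six group designs vary the contingency probability, the ISI schedule and the
feedback regime:

====== ======= ====== ==============
group  p_high  ISI    feedback
====== ======= ====== ==============
1      0.8     fixed  block
2      0.6     fixed  block
3      0.8     jitter block
4      0.8     fixed  trial-by-trial
5      0.8     fixed  none
6      0.8     fixed  uncorrelated
====== ======= ====== ==============

Each simulated participant runs a pre-training test session (structured,
random, structured blocks of 40 trials, no feedback), 23 training blocks of
60 structured trials under the group's feedback regime, and an identical
post-training test session; an optional retest session replicates the
post-test.  The four training "days" are bookkeeping only — blocks are
indexed 1-23 and no forgetting process is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agents import AgentConfig, BeliefState, ResponseRecord, respond, update_belief
from .markov_design import (
    DEFAULT_LENGTH_RANGE,
    SYMBOLS,
    MarkovModel,
    TrialSequence,
    build_default_model,
    generate_random_trial,
    generate_trial,
)

__all__ = [
    "FEEDBACK_MODES",
    "GROUP_PRESETS",
    "ExperimentConfig",
    "build_group_config",
    "emit_feedback",
    "run_experiment",
    "model_for_config",
]

FEEDBACK_MODES = ("block", "trial", "none", "uncorrelated")

GROUP_PRESETS: dict[int, dict] = {
    1: dict(p_high=0.8, isi_mode="fixed", feedback_mode="block"),
    2: dict(p_high=0.6, isi_mode="fixed", feedback_mode="block"),
    3: dict(p_high=0.8, isi_mode="jitter", feedback_mode="block"),
    4: dict(p_high=0.8, isi_mode="fixed", feedback_mode="trial"),
    5: dict(p_high=0.8, isi_mode="fixed", feedback_mode="none"),
    6: dict(p_high=0.8, isi_mode="fixed", feedback_mode="uncorrelated"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    group_id: int
    p_high: float
    isi_mode: str
    feedback_mode: str
    n_training_blocks: int = 23
    trials_per_training_block: int = 60
    test_block_plan: tuple[str, ...] = ("structured", "random", "structured")
    trials_per_test_block: int = 40
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
    retest: bool = False
    uncorrelated_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.p_high <= 1.0:
            raise ValueError(f"p_high must lie in (0.5, 1], got {self.p_high}")
        if self.isi_mode not in ("fixed", "jitter"):
            raise ValueError(f"unknown isi_mode {self.isi_mode!r}")
        if self.feedback_mode not in FEEDBACK_MODES:
            raise ValueError(
                f"unknown feedback_mode {self.feedback_mode!r}; "
                f"expected one of {FEEDBACK_MODES}"
            )
        if not set(self.test_block_plan) <= {"structured", "random"}:
            raise ValueError("test blocks must be 'structured' or 'random'")
        if not 0.0 <= self.uncorrelated_p <= 1.0:
            raise ValueError("uncorrelated_p must lie in [0, 1]")


def build_group_config(group_id: int, **overrides) -> ExperimentConfig:
    """Preset design for groups 1-6, with field-by-field overrides."""
    if group_id not in GROUP_PRESETS:
        raise ValueError(f"unknown group {group_id!r}; expected 1..6")
    params = dict(GROUP_PRESETS[group_id], group_id=group_id)
    params.update(overrides)
    return ExperimentConfig(**params)


def model_for_config(config: ExperimentConfig) -> MarkovModel:
    return build_default_model(config.p_high)


def emit_feedback(
    record: ResponseRecord,
    trial: TrialSequence,
    mode: str,
    rng: np.random.Generator,
    uncorrelated_p: float = 0.5,
) -> str:
    """Trial-level feedback outcome.

    Trial mode scores the choice against the hidden sampled target (a null
    response counts as incorrect — no symbol was selected); uncorrelated
    mode flips a coin independent of the response; block and no-feedback
    modes give no trial-level signal.
    """
    if mode == "trial":
        return "correct" if record.chosen == trial.hidden_target else "incorrect"
    if mode == "uncorrelated":
        return "correct" if rng.random() < uncorrelated_p else "incorrect"
    if mode in ("block", "none"):
        return "none"
    raise ValueError(f"unknown feedback mode {mode!r}")


def _run_block(
    rows: list,
    config: ExperimentConfig,
    agent: AgentConfig,
    model: MarkovModel,
    belief: BeliefState | None,
    session: str,
    block_id: int,
    block_kind: str,
    n_trials: int,
    feedback_mode: str,
    rng: np.random.Generator,
    agent_id: int,
    policy_table: np.ndarray | None = None,
) -> BeliefState | None:
    learning = agent.policy == "learning"
    for t in range(1, n_trials + 1):
        if block_kind == "structured":
            trial = generate_trial(model, config.length_range, rng, config.isi_mode)
        else:
            trial = generate_random_trial(config.length_range, rng, config.isi_mode)
        if learning:
            basis = belief
        elif policy_table is not None:
            basis = policy_table
        else:
            basis = model
        rec = respond(agent, trial, basis, rng, trial_id=t, block_id=block_id)
        rec.feedback = emit_feedback(rec, trial, feedback_mode, rng, config.uncorrelated_p)
        if learning:
            belief = update_belief(belief, trial, rec, feedback_mode, agent, rng)
        rows.append(
            (
                config.group_id,
                agent_id,
                session,
                block_id,
                block_kind,
                t,
                rec.context,
                rec.chosen if rec.chosen is not None else "",
                trial.hidden_target,
                *rec.response_vector,
                rec.feedback,
                float(np.mean(trial.isi_ms)),
                config.seed,
            )
        )
    return belief


_LOG_COLUMNS = [
    "group_id",
    "agent_id",
    "session",
    "block_id",
    "block_kind",
    "trial_id",
    "context",
    "chosen",
    "hidden_target",
    *[f"p_resp_{s}" for s in SYMBOLS],
    "feedback",
    "isi_summary",
    "seed",
]


def run_experiment(
    config: ExperimentConfig,
    agent: AgentConfig,
    rng: np.random.Generator | None = None,
    agent_id: int = 0,
    policy_table: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one participant through the full session plan.

    Returns the trial log: one row per trial with the response vector, the
    hidden target and the feedback outcome.  Test sessions never carry
    feedback.  A learning agent's belief is updated by exposure in every
    session and by feedback bonuses only during training (feedback exists
    nowhere else).  ``policy_table`` substitutes the agent's internal
    conditional table for the true model (an imperfect internal estimate);
    ignored by learning agents.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = model_for_config(config)
    belief = BeliefState() if agent.policy == "learning" else None
    rows: list = []

    def test_session(name: str) -> None:
        nonlocal belief
        for b, kind in enumerate(config.test_block_plan, start=1):
            belief = _run_block(
                rows, config, agent, model, belief, name, b, kind,
                config.trials_per_test_block, "none", rng, agent_id, policy_table,
            )

    test_session("pre")
    for b in range(1, config.n_training_blocks + 1):
        belief = _run_block(
            rows, config, agent, model, belief, "training", b, "structured",
            config.trials_per_training_block, config.feedback_mode, rng, agent_id,
            policy_table,
        )
    test_session("post")
    if config.retest:
        test_session("retest")
    return pd.DataFrame(rows, columns=_LOG_COLUMNS)
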