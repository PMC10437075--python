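"""Performance Index (PI) machinery.

The PI between a response table P_resp and a presented-target table P_pres
is the context-weighted minimum overlap

    PI = sum_c P(c) * sum_t min(P_resp(t|c), P_pres(t|c)),

which is 1 iff the two conditional tables agree on every weighted context.
The random-guess baseline PI_rand is the PI of a uniform-0.25 responder
against the generative model (0.45 for 80/20 contingencies, 0.50 for 60/40);
PI_normalized = PI − PI_rand, so 0 means random guessing.  A simulated or
human participant counts as a learner when post-training PI_normalized is at
least 0.10 (inclusive).

P_pres defaults to the generative model rows rather than a per-block
empirical tally: only the model-based choice reproduces the closed-form
baselines exactly.  An empirical table can be passed wherever a
ConditionalDistribution is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import ResponseRecord
from .markov_design import (
    N_SYMBOLS,
    SYMBOL_INDEX,
    SYMBOLS,
    ContextWeights,
    MarkovModel,
    stationary_distribution,
)

__all__ = [
    "LEARNER_CRITERION",
    "ConditionalDistribution",
    "PIResult",
    "estimate_conditionals",
    "conditionals_from_frame",
    "as_conditional",
    "performance_index",
    "random_baseline",
    "normalize_and_classify",
    "expected_hit_rate",
    "renormalized_weights",
]

#: Learner criterion: post-training normalized PI >= 10 percentage points.
LEARNER_CRITERION = 0.10


@dataclass(frozen=True)
class ConditionalDistribution:
    """Empirical P(target | context) with per-context support counts.

    Rows with zero support are flagged (all-zero rows) and must be excluded
    from weighting by the caller via :func:`renormalized_weights`.
    """

    table: np.ndarray
    support_counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        n = np.asarray(self.support_counts, dtype=float)
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "support_counts", n)
        if t.shape != (N_SYMBOLS, N_SYMBOLS) or n.shape != (N_SYMBOLS,):
            raise ValueError("conditional table must be 4x4 with 4 support counts")
        for c in range(N_SYMBOLS):
            if n[c] > 0 and abs(t[c].sum() - 1.0) > 1e-9:
                raise ValueError(f"supported row {SYMBOLS[c]} does not sum to 1")

    @property
    def supported(self) -> np.ndarray:
        return self.support_counts > 0


def as_conditional(table: np.ndarray | MarkovModel) -> ConditionalDistribution:
    """Wrap a full 4x4 conditional table (e.g. model rows or a policy table)
    as a fully supported ConditionalDistribution."""
    if isinstance(table, MarkovModel):
        table = table.transitions
    return ConditionalDistribution(
        table=np.asarray(table, dtype=float), support_counts=np.ones(N_SYMBOLS)
    )


def estimate_conditionals(records: list[ResponseRecord]) -> ConditionalDistribution:
    """Average the per-trial response vectors within each context.

    Null responses contribute their registered uniform 0.25 vector, exactly
    as the task logs a timed-out response.
    """
    if not records:
        raise ValueError("cannot estimate conditionals from an empty record list")
    sums = np.zeros((N_SYMBOLS, N_SYMBOLS))
    counts = np.zeros(N_SYMBOLS)
    for rec in records:
        c = SYMBOL_INDEX[rec.context]
        sums[c] += rec.response_vector
        counts[c] += 1
    table = np.zeros((N_SYMBOLS, N_SYMBOLS))
    mask = counts > 0
    table[mask] = sums[mask] / counts[mask, None]
    return ConditionalDistribution(table=table, support_counts=counts)


def conditionals_from_frame(df: pd.DataFrame) -> ConditionalDistribution:
    """Estimate a response table from trial-log rows (p_resp_A..D columns)."""
    if len(df) == 0:
        raise ValueError("cannot estimate conditionals from an empty log")
    cols = [f"p_resp_{s}" for s in SYMBOLS]
    sums = np.zeros((N_SYMBOLS, N_SYMBOLS))
    counts = np.zeros(N_SYMBOLS)
    for ctx, grp in df.groupby("context"):
        c = SYMBOL_INDEX[ctx]
        sums[c] = grp[cols].to_numpy(dtype=float).sum(axis=0)
        counts[c] = len(grp)
    table = np.zeros((N_SYMBOLS, N_SYMBOLS))
    mask = counts > 0
    table[mask] = sums[mask] / counts[mask, None]
    return ConditionalDistribution(table=table, support_counts=counts)


@dataclass(frozen=True)
class PIResult:
    per_context: np.ndarray
    overall: float
    pi_rand: float | None
    normalized: float | None
    weights: ContextWeights


def renormalized_weights(weights: ContextWeights, supported: np.ndarray) -> ContextWeights:
    """Zero out unsupported contexts and renormalize the remaining weights."""
    w = weights.weights * supported
    if w.sum() <= 0:
        raise ValueError("no supported context carries weight")
    return ContextWeights(weights=w / w.sum())


def performance_index(
    p_resp: ConditionalDistribution | np.ndarray,
    p_pres: ConditionalDistribution | np.ndarray | MarkovModel,
    weights: ContextWeights,
    pi_rand: float | None = None,
) -> PIResult:
    """Context-weighted minimum overlap between response and target tables.

    Raises if any positively weighted context is unsupported in either
    table; callers drop such contexts with :func:`renormalized_weights`.
    """
    r = p_resp if isinstance(p_resp, ConditionalDistribution) else as_conditional(p_resp)
    p = p_pres if isinstance(p_pres, ConditionalDistribution) else as_conditional(p_pres)
    w = weights.weights
    bad = (w > 0) & ~(r.supported & p.supported)
    if bad.any():
        names = [SYMBOLS[i] for i in np.flatnonzero(bad)]
        raise ValueError(
            f"contexts {names} carry weight but have no observations; "
            "renormalize the weights first"
        )
    per_context = np.minimum(r.table, p.table).sum(axis=1)
    overall = float(w @ per_context)
    normalized = None if pi_rand is None else overall - pi_rand
    return PIResult(
        per_context=per_context,
        overall=overall,
        pi_rand=pi_rand,
        normalized=normalized,
        weights=weights,
    )


def random_baseline(model: MarkovModel, weights: ContextWeights | None = None) -> float:
    """PI_rand: closed-form PI of the uniform-0.25 responder against the
    generative rows, sum_c w_c sum_t min(0.25, P(t|c))."""
    if weights is None:
        weights = stationary_distribution(model)
    return float(weights.weights @ np.minimum(0.25, model.transitions).sum(axis=1))


def normalize_and_classify(
    pre_pi: PIResult, post_pi: PIResult, criterion: float = LEARNER_CRITERION
) -> tuple[float, str]:
    """PI improvement (post minus pre normalized PI) and the learner label.

    The criterion is inclusive: post normalized PI exactly at the threshold
    counts as a learner.
    """
    if pre_pi.pi_rand is None or post_pi.pi_rand is None:
        raise ValueError("both PI results need a random baseline")
    if abs(pre_pi.pi_rand - post_pi.pi_rand) > 1e-12:
        raise ValueError(
            f"mismatched baselines: pre {pre_pi.pi_rand} vs post {post_pi.pi_rand}"
        )
    improvement = post_pi.normalized - pre_pi.normalized
    label = "learner" if post_pi.normalized >= criterion else "weak_learner"
    return improvement, label


def expected_hit_rate(
    policy_table: np.ndarray,
    model: MarkovModel,
    weights: ContextWeights | None = None,
) -> float:
    """Probability that a single sampled choice equals the sampled hidden
    target: sum_c w_c sum_t policy(t|c) * P(t|c).

    Matching on the 80/20 design gives 0.68; maximizing gives 0.80.
    """
    if weights is None:
        weights = stationary_distribution(model)
    pol = np.asarray(policy_table, dtype=float)
    return float(weights.weights @ (pol * model.transitions).sum(axis=1))
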