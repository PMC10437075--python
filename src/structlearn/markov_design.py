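"""First-order (level-1) Markov sequence design.

A trial presents a short stream of 9-13 symbols drawn from a 4-state Markov
chain in which each context (the most recent symbol) admits exactly two
successors: one frequent (probability ``p_high``) and one infrequent
(``1 - p_high``).  The observer's task downstream is to predict the symbol
that would follow the stream; the model also samples that hidden target so
trial-level feedback can be scored against it.

This module owns the generative side: transition matrices, stationary
context weights, structured and random trial streams, and the
inter-stimulus-interval (ISI) schedules (fixed 400 ms, or jittered uniformly
over 100-700 ms in 20 ms bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SYMBOLS",
    "N_SYMBOLS",
    "SYMBOL_INDEX",
    "ISI_FIXED_MS",
    "ISI_JITTER_GRID_MS",
    "DEFAULT_LENGTH_RANGE",
    "MarkovModel",
    "ContextWeights",
    "TrialSequence",
    "build_default_model",
    "stationary_distribution",
    "generate_trial",
    "generate_random_trial",
    "make_isi_schedule",
    "model_to_text",
    "model_from_text",
]

#: The four abstract stimulus identities.  The mapping from these labels to
#: on-screen glyphs is presentation metadata and never enters computation.
SYMBOLS: tuple[str, ...] = ("A", "B", "C", "D")
N_SYMBOLS = 4
SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(SYMBOLS)}

ISI_FIXED_MS = 400
#: Jittered ISIs are drawn uniformly from this 20 ms grid (31 values).
ISI_JITTER_GRID_MS = tuple(range(100, 701, 20))
#: Streams contain 9-13 symbols, uniform over the range.
DEFAULT_LENGTH_RANGE: tuple[int, int] = (9, 13)

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class MarkovModel:
    """A 4-state level-1 Markov model P(target | context).

    ``transitions`` rows are contexts, columns targets.  When ``p_high`` is
    given, every row must place exactly ``p_high`` and ``1 - p_high`` on two
    targets (a single point mass when ``p_high == 1``); when ``p_high`` is
    None any row-stochastic matrix is accepted (used for hand-built chains).
    """

    transitions: np.ndarray
    p_high: float | None = None
    symbols: tuple[str, ...] = SYMBOLS
    order: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, dtype=float)
        object.__setattr__(self, "transitions", t)
        if t.shape != (N_SYMBOLS, N_SYMBOLS):
            raise ValueError(f"transition matrix must be 4x4, got {t.shape}")
        if len(set(self.symbols)) != N_SYMBOLS:
            raise ValueError("model requires exactly 4 distinct symbols")
        if np.any(t < 0):
            raise ValueError("transition probabilities must be nonnegative")
        rows = t.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError(f"each row must sum to 1, got sums {rows}")
        if self.p_high is not None:
            p = float(self.p_high)
            if not 0.5 < p <= 1.0:
                raise ValueError(
                    f"p_high must lie in (0.5, 1], got {p} "
                    "(0.5 is a tie; the frequent target must dominate)"
                )
            if 1.0 - p <= _ROW_TOL:  # the low entry vanishes numerically
                expected = {round(p, 12)}
            else:
                expected = {round(p, 12), round(1.0 - p, 12)}
            for c, row in enumerate(t):
                nz = {round(v, 12) for v in row[row > _ROW_TOL]}
                if nz != expected:
                    raise ValueError(
                        f"row {self.symbols[c]} nonzero entries {sorted(nz)} do not "
                        f"match the contingency pattern {sorted(expected)}"
                    )

    def row(self, context: str | int) -> np.ndarray:
        """Conditional target distribution for one context."""
        c = SYMBOL_INDEX[context] if isinstance(context, str) else int(context)
        return self.transitions[c]


@dataclass(frozen=True)
class ContextWeights:
    """Probability vector over the 4 contexts used to aggregate per-context
    quantities (performance index, KL divergence)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (N_SYMBOLS,):
            raise ValueError("context weights must have length 4")
        if np.any(w < 0):
            raise ValueError("context weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"context weights must sum to 1, got {w.sum()}")


@dataclass(frozen=True)
class TrialSequence:
    """One trial's symbol stream.

    ``context`` is the final symbol before the prediction cue and
    ``hidden_target`` the model-sampled successor, which is never displayed
    but scores trial-level feedback.
    """

    symbols: tuple[str, ...]
    context: str
    hidden_target: str
    isi_ms: tuple[int, ...]
    kind: str  # "structured" | "random"


def build_default_model(p_high: float) -> MarkovModel:
    """Default cyclic contingency topology.

    A -> {B: p, C: 1-p}, B -> {C: p, D: 1-p}, C -> {D: p, A: 1-p},
    D -> {A: p, B: 1-p}.  Every symbol appears once as a frequent and once
    as an infrequent target, so the matrix is doubly stochastic and the
    stationary context distribution is exactly uniform.
    """
    p = float(p_high)
    if not 0.5 < p <= 1.0:
        raise ValueError(f"p_high must lie in (0.5, 1], got {p}")
    q = 1.0 - p
    t = np.array(
        [
            [0.0, p, q, 0.0],  # A -> B (high), C (low)
            [0.0, 0.0, p, q],  # B -> C, D
            [q, 0.0, 0.0, p],  # C -> D, A
            [p, q, 0.0, 0.0],  # D -> A, B
        ]
    )
    return MarkovModel(transitions=t, p_high=p)


def _reachable(adj: np.ndarray, start: int) -> np.ndarray:
    seen = np.zeros(N_SYMBOLS, dtype=bool)
    stack = [start]
    while stack:
        i = stack.pop()
        if seen[i]:
            continue
        seen[i] = True
        stack.extend(np.flatnonzero(adj[i] & ~seen).tolist())
    return seen


def stationary_distribution(model: MarkovModel) -> ContextWeights:
    """Unique stationary distribution of an irreducible chain.

    Solves w(P - I) = 0 with the normalisation constraint appended; raises
    naming the unreachable states if the chain is reducible.
    """
    t = model.transitions
    adj = t > 0
    for s in range(N_SYMBOLS):
        seen = _reachable(adj, s)
        if not seen.all():
            missing = [model.symbols[i] for i in np.flatnonzero(~seen)]
            raise ValueError(
                f"chain is reducible: states {missing} unreachable from "
                f"{model.symbols[s]}"
            )
    a = np.vstack([t.T - np.eye(N_SYMBOLS), np.ones(N_SYMBOLS)])
    b = np.zeros(N_SYMBOLS + 1)
    b[-1] = 1.0
    w, *_ = np.linalg.lstsq(a, b, rcond=None)
    w = np.clip(w, 0.0, None)
    return ContextWeights(weights=w / w.sum())


def make_isi_schedule(mode: str, n_intervals: int, rng: np.random.Generator) -> list[int]:
    """ISI schedule in milliseconds: fixed 400 ms, or jittered on the
    {100, 120, ..., 700} ms grid."""
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if mode == "fixed":
        return [ISI_FIXED_MS] * n_intervals
    if mode == "jitter":
        grid = np.asarray(ISI_JITTER_GRID_MS)
        return grid[rng.integers(0, len(grid), size=n_intervals)].tolist()
    raise ValueError(f"unknown ISI mode {mode!r}; expected 'fixed' or 'jitter'")


def _check_length_range(length_range: tuple[int, int]) -> tuple[int, int]:
    lo, hi = int(length_range[0]), int(length_range[1])
    if hi < lo:
        raise ValueError(f"empty length range [{lo}, {hi}]")
    if lo < 2:
        raise ValueError("trials need at least 2 symbols (a context requires one)")
    return lo, hi


def generate_trial(
    model: MarkovModel,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    rng: np.random.Generator | None = None,
    isi_mode: str = "fixed",
) -> TrialSequence:
    """Sample one structured trial.

    The first symbol is drawn from the stationary distribution (so context
    frequencies match the model weights from the first trial on); every
    later symbol and the hidden target follow the current context's row.
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = _check_length_range(length_range)
    length = int(rng.integers(lo, hi + 1))
    stat = stationary_distribution(model).weights
    cum_rows = np.cumsum(model.transitions, axis=1)
    u = rng.random(length + 1)
    idx = np.empty(length, dtype=int)
    idx[0] = np.searchsorted(np.cumsum(stat), u[0])
    for i in range(1, length):
        idx[i] = np.searchsorted(cum_rows[idx[i - 1]], u[i])
    hidden = int(np.searchsorted(cum_rows[idx[-1]], u[length]))
    syms = tuple(SYMBOLS[i] for i in idx)
    return TrialSequence(
        symbols=syms,
        context=syms[-1],
        hidden_target=SYMBOLS[hidden],
        isi_ms=tuple(make_isi_schedule(isi_mode, length, rng)),
        kind="structured",
    )


def generate_random_trial(
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    rng: np.random.Generator | None = None,
    isi_mode: str = "fixed",
) -> TrialSequence:
    """Sample one random trial: i.i.d. uniform symbols (repeats allowed) and
    a uniform hidden target.  Used in the test-session random blocks."""
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = _check_length_range(length_range)
    length = int(rng.integers(lo, hi + 1))
    idx = rng.integers(0, N_SYMBOLS, size=length + 1)
    syms = tuple(SYMBOLS[i] for i in idx[:-1])
    return TrialSequence(
        symbols=syms,
        context=syms[-1],
        hidden_target=SYMBOLS[idx[-1]],
        isi_ms=tuple(make_isi_schedule(isi_mode, length, rng)),
        kind="random",
    )


# --- plain-text serialization -------------------------------------------------

def model_to_text(model: MarkovModel) -> str:
    """Serialize a model to a plain-text block that round-trips exactly."""
    lines = [f"symbols: {' '.join(model.symbols)}"]
    lines.append(f"p_high: {'' if model.p_high is None else repr(model.p_high)}")
    for s, row in zip(model.symbols, model.transitions):
        lines.append(f"row {s}: " + " ".join(repr(float(v)) for v in row))
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> MarkovModel:
    symbols: tuple[str, ...] | None = None
    p_high: float | None = None
    rows: dict[str, list[float]] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "symbols":
            symbols = tuple(value.split())
        elif key == "p_high":
            p_high = float(value) if value else None
        elif key.startswith("row "):
            rows[key[4:].strip()] = [float(v) for v in value.split()]
        else:
            raise ValueError(f"unknown key {key!r} in model block")
    if symbols is None or set(rows) != set(symbols):
        raise ValueError("model block must list symbols and one row per symbol")
    t = np.array([rows[s] for s in symbols])
    return MarkovModel(transitions=t, p_high=p_high, symbols=symbols)
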