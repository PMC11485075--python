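"""Latent-state multinomial processing tree (MPT) model of word-list recall.

The model describes episodic memory for a single list item during a
word-list recall test with three immediate free-recall (IFR) tasks, each
preceded by a presentation of the full list, followed by one delayed
free-recall (DFR) task after a filled delay with no re-presentation.

At any observation the item occupies one of three storage states:

* ``P`` — pre-task storage: the word is known semantically but holds no
  episodic trace of this test; no recall is possible from ``P``.
* ``T`` — transient storage: a temporary episodic trace that supports
  immediate free recall only.
* ``D`` — durable storage: a consolidated trace that additionally
  supports delayed free recall.

Seven probabilities govern the item's trajectory.  Four encoding
parameters act at presentations and retrievals: one-shot encoding ``N1``
(P→D), transient encoding ``N2`` (P→T), consolidation ``N3`` (T→D at a
re-presentation on a task after the one that put the item in T), and the
testing effect ``N4`` (T→D triggered by a successful retrieval from T).
Three retrieval parameters govern emission of a recall: ``R1`` from T on
IFR, ``R2`` from D on IFR, and ``R3`` from D on DFR.

Recall-ability scores ``M1``/``M2``/``M3`` recombine branches of the
processing tree into generalized per-task recall rates: recall routed
through T on IFR, through D on IFR, and through D on DFR respectively.
A participant with ``M3 = 0.71`` is expected to recall 7.1 words of a
10-word list on an average DFR task.

Branch conventions that the text of the model leaves open (the order of
the competing N1/N2 encodings from P, the timing of N3) are documented
on :func:`advance_presentation` and kept out of the rest of the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "PARAM_NAMES",
    "SCORE_NAMES",
    "N_IFR_TASKS",
    "N_RECALL_SLOTS",
    "StorageState",
    "TaskType",
    "DCBParameters",
    "PositionEffects",
    "RecallSequence",
    "DCBScores",
    "advance_presentation",
    "recall_emission",
    "post_recall_transition",
    "word_likelihood",
    "forward_likelihoods",
    "compute_scores",
    "scores_from_arrays",
    "expected_recalled_words",
    "simulate_word",
    "simulate_patterns",
    "all_recall_patterns",
]

#: Canonical parameter order used by every array interface in the package.
PARAM_NAMES = ("N1", "N2", "N3", "N4", "R1", "R2", "R3")

#: Derived-score order used by :func:`scores_from_arrays`.
SCORE_NAMES = ("M1", "M2", "M3", "N_avg", "R_avg", "M_avg")

N_IFR_TASKS = 3
N_RECALL_SLOTS = 4  # 3 IFR + 1 DFR


class StorageState(Enum):
    """The three storage states; P holds no episodic trace and cannot emit."""

    P = "P"
    T = "T"
    D = "D"


class TaskType(Enum):
    IFR = "IFR"
    DFR = "DFR"


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class DCBParameters:
    """The seven latent probabilities for one participant.

    Encoding: N1 (one-shot P→D), N2 (transient P→T), N3 (consolidation
    T→D at re-presentation), N4 (testing effect T→D on retrieval from T).
    Retrieval: R1 (T, IFR), R2 (D, IFR), R3 (D, DFR).
    """

    N1: float
    N2: float
    N3: float
    N4: float
    R1: float
    R2: float
    R3: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "DCBParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (7,):
            raise ValueError(f"expected 7 parameters, got shape {values.shape}")
        return cls(*values)


@dataclass
class PositionEffects:
    """Additive logit-scale adjustments to the encoding probabilities.

    ``offsets`` maps ``(list_id, presentation_position)`` to an offset
    applied to the logits of N1 and N2 at that presentation only.  A
    missing key means no adjustment.  Word lists differ in difficulty by
    position (primacy/recency), which these offsets absorb.
    """

    offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.offsets.items():
            if not np.isfinite(value):
                raise ValueError(f"position offset for {key!r} must be finite")

    def offset(self, list_id, position: int) -> float:
        return float(self.offsets.get((list_id, int(position)), 0.0))

    def for_sequence(self, seq: "RecallSequence") -> np.ndarray:
        """Offsets at the word's three presentation positions, shape (3,)."""
        return np.array(
            [self.offset(seq.list_id, p) for p in seq.positions], dtype=float
        )


@dataclass(frozen=True)
class RecallSequence:
    """One word's observed recall indicators and presentation positions.

    ``positions`` are the 1-based positions at which the word appeared in
    each of the three IFR presentations (order is varied across tasks);
    ``recalls`` are the binary outcomes at (IFR1, IFR2, IFR3, DFR).
    """

    word_id: str
    list_id: str
    positions: tuple
    recalls: tuple
    list_length: int = 10

    def __post_init__(self) -> None:
        positions = tuple(int(p) for p in self.positions)
        recalls = tuple(int(r) for r in self.recalls)
        if len(positions) != N_IFR_TASKS:
            raise ValueError(f"need {N_IFR_TASKS} presentation positions, got {positions!r}")
        if len(recalls) != N_RECALL_SLOTS:
            raise ValueError(f"need {N_RECALL_SLOTS} recall indicators, got {recalls!r}")
        if any(r not in (0, 1) for r in recalls):
            raise ValueError(f"recall indicators must be 0/1, got {recalls!r}")
        if any(not (1 <= p <= self.list_length) for p in positions):
            raise ValueError(
                f"positions must lie in 1..{self.list_length}, got {positions!r}"
            )
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "recalls", recalls)


@dataclass(frozen=True)
class DCBScores:
    """Derived recall-ability scores and the three biomarker averages."""

    M1: float
    M2: float
    M3: float
    N_avg: float
    R_avg: float
    M_avg: float

    def expected_recalled_words(self, n_words: int = 10) -> float:
        """Expected number of words recalled on an average DFR task."""
        return self.M3 * n_words


def expected_recalled_words(m: float, n_words: int = 10) -> float:
    """Expected words recalled on a list of ``n_words`` at recall rate ``m``."""
    return _check_prob("m", m) * int(n_words)


# ---------------------------------------------------------------------------
# Single-state reference operations
# ---------------------------------------------------------------------------

def _adjusted(p: float | np.ndarray, offset: float | np.ndarray):
    """Apply an additive logit-scale offset to a probability.

    Degenerate probabilities 0 and 1 are fixed points (their logits are
    infinite, so any finite offset leaves them unchanged).
    """
    with np.errstate(divide="ignore"):
        return expit(logit(p) + offset)


def advance_presentation(
    state: StorageState,
    params: DCBParameters,
    position_offset: float = 0.0,
) -> dict:
    """Transition distribution applied when the list is (re-)presented.

    Branch convention for the competing encodings from P: the one-shot
    branch N1 is taken first; transient encoding N2 applies on the
    complementary branch, giving P→D = N1', P→T = (1−N1')·N2',
    P→P = (1−N1')(1−N2'), with N1', N2' the position-adjusted values.
    This nested ordering is the usual way an MPT resolves competing
    encodings and is isolated here.  From T, consolidation N3 applies
    (it can only matter at a re-presentation, since T is unoccupied at
    the first one); D is absorbing.
    """
    if not np.isfinite(position_offset):
        raise ValueError("position offset must be finite")
    if state is StorageState.P:
        n1 = float(_adjusted(params.N1, position_offset))
        n2 = float(_adjusted(params.N2, position_offset))
        return {
            StorageState.D: n1,
            StorageState.T: (1.0 - n1) * n2,
            StorageState.P: (1.0 - n1) * (1.0 - n2),
        }
    if state is StorageState.T:
        return {
            StorageState.D: params.N3,
            StorageState.T: 1.0 - params.N3,
            StorageState.P: 0.0,
        }
    return {StorageState.D: 1.0, StorageState.T: 0.0, StorageState.P: 0.0}


def recall_emission(
    state: StorageState, task_type: TaskType, params: DCBParameters
) -> float:
    """Probability of emitting a recall from ``state`` on a task.

    P never emits; T supports immediate recall only (R1); D supports
    immediate (R2) and delayed (R3) recall.
    """
    if not isinstance(task_type, TaskType):
        raise TypeError(f"task_type must be TaskType, got {task_type!r}")
    if state is StorageState.T and task_type is TaskType.IFR:
        return params.R1
    if state is StorageState.D:
        return params.R2 if task_type is TaskType.IFR else params.R3
    return 0.0


def post_recall_transition(
    state: StorageState, recalled: int, params: DCBParameters
) -> dict:
    """Transition applied after a recall attempt (the testing effect).

    A successful retrieval from T consolidates the trace to D with
    probability N4; every other feasible combination is the identity.
    """
    recalled = int(recalled)
    if recalled not in (0, 1):
        raise ValueError(f"recalled must be 0/1, got {recalled!r}")
    if recalled == 1 and state is StorageState.P:
        raise ValueError("recall from pre-task storage is infeasible")
    dist = {StorageState.P: 0.0, StorageState.T: 0.0, StorageState.D: 0.0}
    if state is StorageState.T and recalled == 1:
        dist[StorageState.D] = params.N4
        dist[StorageState.T] = 1.0 - params.N4
    else:
        dist[state] = 1.0
    return dist


# ---------------------------------------------------------------------------
# Vectorized forward recursion
# ---------------------------------------------------------------------------

def forward_likelihoods(
    params: np.ndarray, recalls: np.ndarray, offsets: np.ndarray | None = None
) -> np.ndarray:
    """Exact marginal probability of observed recall patterns, batched.

    Parameters
    ----------
    params
        Array of shape ``(..., 7)`` in :data:`PARAM_NAMES` order; leading
        axes broadcast against the leading axes of ``recalls``.
    recalls
        Binary array of shape ``(..., W, 4)``: W words, 4 recall slots.
    offsets
        Logit offsets of shape broadcastable to ``(..., W, 3)`` (one per
        presentation); ``None`` means no positional adjustment.

    Returns
    -------
    Array of shape ``(..., W)`` with the exact marginal probability of
    each word's 4-slot pattern under a forward recursion over the
    3-state space (present → recall → testing effect, three times, then
    the delayed recall).
    """
    params = np.asarray(params, dtype=float)
    recalls = np.asarray(recalls, dtype=float)
    n1, n2, n3, n4, r1, r2, r3 = (params[..., i] for i in range(7))
    if offsets is None:
        offsets = np.zeros(recalls.shape[:-1] + (N_IFR_TASKS,))
    else:
        offsets = np.asarray(offsets, dtype=float)

    shape = np.broadcast_shapes(recalls.shape[:-1], n1.shape)
    a_p = np.ones(shape)
    a_t = np.zeros(shape)
    a_d = np.zeros(shape)
    for t in range(N_IFR_TASKS):
        off = offsets[..., t]
        n1t = np.where(off == 0.0, n1, _adjusted(n1, off))
        n2t = np.where(off == 0.0, n2, _adjusted(n2, off))
        # presentation
        new_d = a_d + a_p * n1t + a_t * n3
        new_t = a_p * (1.0 - n1t) * n2t + a_t * (1.0 - n3)
        new_p = a_p * (1.0 - n1t) * (1.0 - n2t)
        # recall emission conditioned on the observed indicator
        r = recalls[..., t]
        a_p = new_p * (1.0 - r)
        a_t = new_t * (r * r1 + (1.0 - r) * (1.0 - r1))
        a_d = new_d * (r * r2 + (1.0 - r) * (1.0 - r2))
        # testing effect after a successful recall from T
        move = a_t * n4 * r
        a_t = a_t - move
        a_d = a_d + move
    r = recalls[..., 3]
    return a_p * (1.0 - r) + a_t * (1.0 - r) + a_d * (r * r3 + (1.0 - r) * (1.0 - r3))


def word_likelihood(
    seq: RecallSequence,
    params: DCBParameters,
    effects: PositionEffects | None = None,
) -> float:
    """Exact marginal probability of one word's observed recall pattern."""
    effects = effects if effects is not None else PositionEffects()
    offs = effects.for_sequence(seq)
    lik = forward_likelihoods(
        params.as_array(),
        np.asarray(seq.recalls, dtype=float)[None, :],
        offs[None, :],
    )
    return float(lik[0])


def all_recall_patterns() -> np.ndarray:
    """All 16 possible 4-slot recall patterns, shape (16, 4)."""
    grid = np.indices((2, 2, 2, 2)).reshape(4, 16).T
    return grid.astype(float)


# ---------------------------------------------------------------------------
# Derived scores
# ---------------------------------------------------------------------------

def scores_from_arrays(params: np.ndarray) -> np.ndarray:
    """Derived scores for an array of parameter vectors.

    M1/M2 are the route-attributed marginal recall probabilities on an
    IFR task (through T and through D respectively), averaged over the
    three IFR tasks at zero position offset; M3 is the marginal DFR
    recall probability (necessarily through D).  The recursion tracks
    state occupancy marginally over recall outcomes, so the testing
    effect contributes T→D with probability R1·N4 at each IFR task.

    Parameters of shape ``(..., 7)`` give scores of shape ``(..., 6)``
    in :data:`SCORE_NAMES` order.
    """
    params = np.asarray(params, dtype=float)
    n1, n2, n3, n4 = (params[..., i] for i in range(4))
    r1, r2, r3 = (params[..., i] for i in range(4, 7))
    occ_p = np.ones_like(n1)
    occ_t = np.zeros_like(n1)
    occ_d = np.zeros_like(n1)
    t_sum = np.zeros_like(n1)
    d_sum = np.zeros_like(n1)
    for _ in range(N_IFR_TASKS):
        occ_d, occ_t, occ_p = (
            occ_d + occ_p * n1 + occ_t * n3,
            occ_p * (1.0 - n1) * n2 + occ_t * (1.0 - n3),
            occ_p * (1.0 - n1) * (1.0 - n2),
        )
        t_sum = t_sum + occ_t
        d_sum = d_sum + occ_d
        move = occ_t * r1 * n4
        occ_t = occ_t - move
        occ_d = occ_d + move
    m1 = r1 * t_sum / N_IFR_TASKS
    m2 = r2 * d_sum / N_IFR_TASKS
    m3 = r3 * occ_d
    n_avg = (n1 + n2 + n3 + n4) / 4.0
    r_avg = (r1 + r2 + r3) / 3.0
    m_avg = (m1 + m2 + m3) / 3.0
    return np.stack([m1, m2, m3, n_avg, r_avg, m_avg], axis=-1)


def compute_scores(
    params: DCBParameters, effects: PositionEffects | None = None
) -> DCBScores:
    """Recall-ability scores M1/M2/M3 and the averages N, R, M.

    The scores are defined at zero position offset (they are properties
    of the participant, not of a particular word list), so ``effects``
    is accepted for interface symmetry but does not enter the scores.
    """
    del effects
    values = scores_from_arrays(params.as_array())
    return DCBScores(*(float(v) for v in values))


# ---------------------------------------------------------------------------
# Generative counterpart
# ---------------------------------------------------------------------------

_STATE_ORDER = (StorageState.P, StorageState.T, StorageState.D)


def simulate_word(
    params: DCBParameters,
    effects: PositionEffects | None,
    seq_template: RecallSequence,
    rng: np.random.Generator | int,
) -> RecallSequence:
    """Draw one word's recall pattern from the exact generative model.

    ``seq_template`` supplies word/list identity and presentation
    positions; its recall slots are ignored.  Passing an integer seeds a
    fresh generator, making the draw reproducible bit-for-bit.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    effects = effects if effects is not None else PositionEffects()
    state = StorageState.P
    recalls = []
    for t in range(N_IFR_TASKS):
        off = effects.offset(seq_template.list_id, seq_template.positions[t])
        dist = advance_presentation(state, params, off)
        state = _sample_state(dist, rng)
        p_rec = recall_emission(state, TaskType.IFR, params)
        recalled = int(rng.random() < p_rec)
        recalls.append(recalled)
        state = _sample_state(post_recall_transition(state, recalled, params), rng)
    p_rec = recall_emission(state, TaskType.DFR, params)
    recalls.append(int(rng.random() < p_rec))
    return RecallSequence(
        word_id=seq_template.word_id,
        list_id=seq_template.list_id,
        positions=seq_template.positions,
        recalls=tuple(recalls),
        list_length=seq_template.list_length,
    )


def _sample_state(dist: Mapping, rng: np.random.Generator) -> StorageState:
    probs = np.array([dist[s] for s in _STATE_ORDER])
    return _STATE_ORDER[int(rng.choice(3, p=probs / probs.sum()))]


def simulate_patterns(
    params: np.ndarray,
    n_words: int,
    rng: np.random.Generator | int,
    offsets: np.ndarray | None = None,
    return_states: bool = False,
):
    """Vectorized simulation of many words' recall patterns.

    Parameters may be a single 7-vector (shared by all words) or an
    array of shape ``(n_words, 7)``.  Returns recalls of shape
    ``(n_words, 4)``; with ``return_states=True`` also the storage state
    (0=P, 1=T, 2=D) occupied at each of the four recall attempts, which
    lets a caller attribute each recall to its route (T vs D).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    params = np.atleast_2d(np.asarray(params, dtype=float))
    if params.shape[0] == 1:
        params = np.broadcast_to(params, (n_words, 7))
    n1, n2, n3, n4 = (params[:, i] for i in range(4))
    r1, r2, r3 = (params[:, i] for i in range(4, 7))
    if offsets is None:
        offsets = np.zeros((n_words, N_IFR_TASKS))
    state = np.zeros(n_words, dtype=np.int8)  # 0=P, 1=T, 2=D
    recalls = np.zeros((n_words, N_RECALL_SLOTS), dtype=np.int8)
    states_at = np.zeros((n_words, N_RECALL_SLOTS), dtype=np.int8)
    for t in range(N_IFR_TASKS):
        n1t = np.where(offsets[:, t] == 0.0, n1, _adjusted(n1, offsets[:, t]))
        n2t = np.where(offsets[:, t] == 0.0, n2, _adjusted(n2, offsets[:, t]))
        u = rng.random(n_words)
        from_p = state == 0
        to_d = from_p & (u < n1t)
        to_t = from_p & ~to_d & (u < n1t + (1.0 - n1t) * n2t)
        consolidate = (state == 1) & (rng.random(n_words) < n3)
        state = np.where(to_d | consolidate, 2, np.where(to_t, 1, state)).astype(np.int8)
        p_rec = np.where(state == 1, r1, np.where(state == 2, r2, 0.0))
        rec = rng.random(n_words) < p_rec
        recalls[:, t] = rec
        states_at[:, t] = state
        testing = rec & (state == 1) & (rng.random(n_words) < n4)
        state = np.where(testing, 2, state).astype(np.int8)
    p_rec = np.where(state == 2, r3, 0.0)
    recalls[:, 3] = rng.random(n_words) < p_rec
    states_at[:, 3] = state
    if return_states:
        return recalls, states_at
    return recalls
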