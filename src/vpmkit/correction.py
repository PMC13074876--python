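"""Post-detection anatomical sequence correction.

Detections along a cranio-caudal sweep must carry strictly increasing
vertebral labels (T1 -> T12 -> L1 -> L5).  Raw per-crop classifications
violate this routinely — adjacent thoracic vertebrae look alike in
ultrasound and a crop discards global position, so high-confidence
misclassifications (e.g. a mid-thoracic vertebra labelled T1 at 0.99) are
common.  This layer reconciles labels with anatomy by solving a
maximum-weight monotone assignment: each detection is either assigned a
level (levels strictly increasing in position order) or suppressed, and the
assignment maximises

    sum over assigned items of
        w_label * confidence * [predicted label == assigned level]
      + w_pos * prior(position, level)
    - suppression_penalty * (number suppressed)

where ``prior(position, level) = 1 - |rank-normalised position -
(ordinal - 0.5)/17|``.  The rank-normalised position of the i-th of n items
is ``(i - 0.5)/n``, so the prior needs no physical calibration and works
equally for sweep indices and pixel coordinates.  The optimum is found
exactly by dynamic programming over (item, level) states in O(n * 17).

The layer never invents detections: every input item ends up either
assigned or suppressed.  Missing levels are reported as *interior* gaps
(inside the assigned span) or *uncovered* levels (outside it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import LEVELS, N_LEVELS, VertebralLevel
from .geometry import BBox

__all__ = [
    "SequenceItem",
    "OrderedDetectionSequence",
    "CorrectionResult",
    "correct_sequence",
    "infer_missing",
    "corrected_vpm",
]

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class SequenceItem:
    """One detection along the sweep: position, raw label (or None), confidence."""

    position: float
    predicted_level: Optional[VertebralLevel]
    confidence: float
    bbox: Optional[BBox] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class OrderedDetectionSequence:
    """Detections sorted by strictly increasing cranio-caudal position."""

    items: tuple[SequenceItem, ...]

    def __post_init__(self) -> None:
        pos = [it.position for it in self.items]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_items(cls, items: Sequence[SequenceItem]) -> "OrderedDetectionSequence":
        return cls(items=tuple(sorted(items, key=lambda it: it.position)))


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of the monotone assignment.

    ``assigned`` pairs each kept item index with its final level, strictly
    increasing in position order; ``suppressed`` holds the remaining
    indices.  ``inferred_missing_interior`` are unassigned levels inside the
    assigned span; ``uncovered`` are levels outside it.
    """

    assigned: tuple[tuple[int, VertebralLevel], ...]
    suppressed: tuple[int, ...]
    inferred_missing_interior: frozenset[VertebralLevel]
    uncovered: frozenset[VertebralLevel]
    objective_value: float

    @property
    def final_levels(self) -> dict[int, VertebralLevel]:
        return dict(self.assigned)


def _position_prior(rank_pos: float, ordinal: int) -> float:
    return 1.0 - abs(rank_pos - (ordinal - 0.5) / N_LEVELS)


def _score_matrix(
    seq: OrderedDetectionSequence, w_label: float, w_pos: float
) -> np.ndarray:
    n = len(seq)
    score = np.zeros((n, N_LEVELS))
    for i, item in enumerate(seq.items):
        rank_pos = (i + 0.5) / n
        for v in range(N_LEVELS):
            s = w_pos * _position_prior(rank_pos, v + 1)
            if item.predicted_level is not None and item.predicted_level.ordinal == v + 1:
                s += w_label * item.confidence
            score[i, v] = s
    return score


def correct_sequence(
    seq: OrderedDetectionSequence,
    w_label: float = 1.0,
    w_pos: float = 1.0,
    suppression_penalty: float = 0.05,
    max_gap: Optional[int] = None,
) -> CorrectionResult:
    """Exact maximum-weight monotone assignment of detections to levels.

    ``max_gap``, when set, forbids skipping more than that many levels
    between consecutive assigned items (a hard jump constraint; by default
    large jumps are discouraged only through the positional prior).

    Ties are broken deterministically: higher objective, then more items
    assigned, then the level sequence that is smaller earliest.
    """
    if w_label < 0 or w_pos < 0:
        raise ValueError("weights must be nonnegative")
    if suppression_penalty < 0:
        raise ValueError("suppression_penalty must be nonnegative")
    n = len(seq)
    if n == 0:
        return CorrectionResult(
            assigned=(),
            suppressed=(),
            inferred_missing_interior=frozenset(),
            uncovered=frozenset(LEVELS),
            objective_value=0.0,
        )

    score = _score_matrix(seq, w_label, w_pos)
    # Each assigned item contributes score + penalty relative to suppressing
    # it; maximising total gain and subtracting penalty * n gives the stated
    # objective.
    gain = score + suppression_penalty

    # DP state: best monotone prefix assignment ending with item i at level v.
    # A state is (total gain, count, level sequence, item indices); storing
    # the sequences keeps tie-breaking and reconstruction trivial at O(n)
    # extra memory per state, which is negligible at 17 levels.
    def better(a, b) -> bool:
        """True when candidate a beats b under objective/count/lex tie-break."""
        if b is None:
            return True
        if a[0] > b[0] + _TIE_EPS:
            return True
        if a[0] < b[0] - _TIE_EPS:
            return False
        if a[1] != b[1]:
            return a[1] > b[1]
        return a[2] < b[2]

    empty = (0.0, 0, (), ())
    # best_prefix[v] = best state over items processed so far whose last
    # assigned level is <= v (plus the empty assignment).
    best_prefix = [empty] * (N_LEVELS + 1)
    states: list[list] = []  # states[i][v]

    for i in range(n):
        row: list = [None] * N_LEVELS
        for v in range(N_LEVELS):
            if max_gap is None:
                prev = best_prefix[v]  # any last level < v+1
            else:
                # empty predecessor always allowed; otherwise the previous
                # level u must satisfy (v+1) - u - 1 <= max_gap.
                prev = empty
                for u in range(max(0, v - max_gap), v):
                    for j in range(i):
                        cand = states[j][u]
                        if cand is not None and better(cand, prev):
                            prev = cand
            row[v] = (
                prev[0] + gain[i, v],
                prev[1] + 1,
                prev[2] + (v + 1,),
                prev[3] + (i,),
            )
        states.append(row)
        new_prefix = list(best_prefix)
        running = None
        for v in range(N_LEVELS):
            if running is None or better(row[v], running):
                running = row[v]
            if better(running, new_prefix[v + 1]):
                new_prefix[v + 1] = running
        best_prefix = new_prefix

    best = empty
    for i in range(n):
        for v in range(N_LEVELS):
            if better(states[i][v], best):
                best = states[i][v]

    total_gain, count, level_seq, item_seq = best
    objective = total_gain - suppression_penalty * n
    assigned = [
        (i, VertebralLevel(v)) for i, v in zip(item_seq, level_seq)
    ]
    assigned_idx = set(item_seq)
    suppressed = tuple(i for i in range(n) if i not in assigned_idx)
    interior, uncovered = _gap_sets([lvl for _, lvl in assigned])
    return CorrectionResult(
        assigned=tuple(assigned),
        suppressed=suppressed,
        inferred_missing_interior=interior,
        uncovered=uncovered,
        objective_value=float(objective),
    )


def _gap_sets(
    levels: Sequence[VertebralLevel],
) -> tuple[frozenset[VertebralLevel], frozenset[VertebralLevel]]:
    if not levels:
        return frozenset(), frozenset(LEVELS)
    ordinals = {lvl.ordinal for lvl in levels}
    lo, hi = min(ordinals), max(ordinals)
    interior = frozenset(
        VertebralLevel(o) for o in range(lo + 1, hi) if o not in ordinals
    )
    uncovered = frozenset(
        VertebralLevel(o) for o in range(1, N_LEVELS + 1) if o < lo or o > hi
    )
    return interior, uncovered


def infer_missing(
    result: CorrectionResult,
) -> tuple[frozenset[VertebralLevel], frozenset[VertebralLevel]]:
    """Missing levels of a corrected sequence: (interior gaps, uncovered span)."""
    return result.inferred_missing_interior, result.uncovered


def corrected_vpm(result: CorrectionResult) -> np.ndarray:
    """Presence vector implied by the corrected assignment."""
    vec = np.zeros(N_LEVELS, dtype=np.int8)
    for _, lvl in result.assigned:
        vec[lvl.ordinal - 1] = 1
    return vec
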