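"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import settings

from vpmkit.core import N_LEVELS, VertebralLevel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from vpmkit.correction import OrderedDetectionSequence, SequenceItem


def oracle_score_matrix(seq, w_label, w_pos):
    """Item x level scores recomputed straight from the objective definition."""
    n = len(seq.items)
    score = np.zeros((n, N_LEVELS))
    for i, item in enumerate(seq.items):
        rank_pos = (i + 0.5) / n
        for v in range(1, N_LEVELS + 1):
            s = w_pos * (1.0 - abs(rank_pos - (v - 0.5) / N_LEVELS))
            if item.predicted_level is not None and item.predicted_level.ordinal == v:
                s += w_label * item.confidence
            score[i, v - 1] = s
    return score


def brute_force_objective(seq, w_label=1.0, w_pos=1.0, suppression_penalty=0.05,
                          max_gap=None):
    """Exhaustive maximum over all monotone partial assignments (n <= ~7).

    Enumerates every subset of items and every strictly increasing level
    tuple of matching size, vectorised over level combinations.
    """
    n = len(seq.items)
    score = oracle_score_matrix(seq, w_label, w_pos)
    best = -suppression_penalty * n  # assign nothing
    for k in range(1, n + 1):
        level_combos = np.array(list(combinations(range(N_LEVELS), k)))
        if max_gap is not None:
            gaps = np.diff(level_combos, axis=1) - 1
            level_combos = level_combos[(gaps <= max_gap).all(axis=1)]
            if len(level_combos) == 0:
                continue
        for items in combinations(range(n), k):
            totals = score[np.array(items)[None, :], level_combos].sum(axis=1)
            cand = totals.max() - suppression_penalty * (n - k)
            if cand > best:
                best = cand
    return float(best)


def random_sequence(rng: np.random.Generator, n_items: int) -> OrderedDetectionSequence:
    positions = np.sort(rng.uniform(0.0, 100.0, size=n_items))
    while len(np.unique(positions)) < n_items:  # pragma: no cover
        positions = np.sort(rng.uniform(0.0, 100.0, size=n_items))
    items = []
    for pos in positions:
        level = (
            None
            if rng.random() < 0.1
            else VertebralLevel(int(rng.integers(1, N_LEVELS + 1)))
        )
        items.append(
            SequenceItem(
                position=float(pos),
                predicted_level=level,
                confidence=float(np.round(rng.random(), 6)),
            )
        )
    return OrderedDetectionSequence(items=tuple(items))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
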