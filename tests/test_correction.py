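"""Anatomical sequence correction: exactness, invariants, worked example."""

import numpy as np
import pytest

from conftest import brute_force_objective, random_sequence

from vpmkit.core import VertebralLevel, level_from_name
from vpmkit.correction import (
    OrderedDetectionSequence,
    SequenceItem,
    correct_sequence,
    corrected_vpm,
    infer_missing,
)
from vpmkit.synthetic import SWEEP_CORRUPTIONS, corrupted_sweep_fixture


def seq_of(labels_confs, positions=None):
    positions = positions or list(range(1, len(labels_confs) + 1))
    items = [
        SequenceItem(
            position=float(p),
            predicted_level=level_from_name(name) if name else None,
            confidence=c,
        )
        for p, (name, c) in zip(positions, labels_confs)
    ]
    return OrderedDetectionSequence(items=tuple(items))


class TestBasics:
    def test_already_monotone_is_identity(self):
        seq = seq_of([("T1", 0.9), ("T2", 0.9), ("T3", 0.9)])
        res = correct_sequence(seq)
        assert [(i, l.name) for i, l in res.assigned] == [(0, "T1"), (1, "T2"), (2, "T3")]
        assert res.suppressed == ()

    def test_unsortable_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            OrderedDetectionSequence(
                items=(
                    SequenceItem(1.0, VertebralLevel.T1, 0.5),
                    SequenceItem(1.0, VertebralLevel.T2, 0.5),
                )
            )

    def test_empty_sequence(self):
        res = correct_sequence(OrderedDetectionSequence(items=()))
        assert res.assigned == () and res.suppressed == ()
        assert len(res.uncovered) == 17
        assert corrected_vpm(res).sum() == 0

    def test_out_of_order_label_suppressed(self):
        """T3-T6-T4 admits no level strictly between T3 and T4 for the middle
        item, so the best label-only objective drops it."""
        seq = seq_of([("T3", 0.9), ("T6", 0.8), ("T4", 0.9)])
        res = correct_sequence(seq, w_pos=0.0, suppression_penalty=0.0)
        assert res.objective_value == pytest.approx(
            brute_force_objective(seq, w_label=1.0, w_pos=0.0, suppression_penalty=0.0)
        )
        final = res.final_levels
        assert final[0] == VertebralLevel.T3
        assert final[2] == VertebralLevel.T4
        assert res.suppressed == (1,)

    def test_max_gap_constrains_jumps(self):
        seq = seq_of([("T1", 0.9), ("L5", 0.9)])
        free = correct_sequence(seq, w_pos=0.0, suppression_penalty=0.0)
        assert {l.name for _, l in free.assigned} == {"T1", "L5"}
        capped = correct_sequence(seq, w_pos=0.0, suppression_penalty=0.0, max_gap=3)
        levels = sorted(l.ordinal for _, l in capped.assigned)
        if len(levels) == 2:
            assert levels[1] - levels[0] - 1 <= 3


class TestWorkedSweepExample:
    """A 17-crop sweep with five recorded high-confidence misclassifications
    must come back relabelled purely by anatomical position."""

    def test_all_corruptions_restored(self):
        res = correct_sequence(corrupted_sweep_fixture())
        final = res.final_levels
        assert res.suppressed == ()
        for true_name, pred_name, _conf in SWEEP_CORRUPTIONS:
            idx = level_from_name(true_name).ordinal - 1  # sweep position
            assert final[idx].name == true_name != pred_name

    def test_restored_sequence_is_complete_and_monotone(self):
        res = correct_sequence(corrupted_sweep_fixture())
        levels = [l.ordinal for _, l in res.assigned]
        assert levels == list(range(1, 18))
        assert corrected_vpm(res).tolist() == [1] * 17
        interior, uncovered = infer_missing(res)
        assert interior == frozenset() and uncovered == frozenset()


class TestInferMissing:
    def test_single_gap(self):
        seq = seq_of([(f"T{i}", 0.9) for i in range(1, 7)]
                     + [(f"T{i}", 0.9) for i in range(8, 13)]
                     + [(f"L{i}", 0.9) for i in range(1, 6)])
        res = correct_sequence(seq)
        interior, uncovered = infer_missing(res)
        assert interior == {VertebralLevel.T7}
        assert uncovered == frozenset()

    def test_span_definition(self):
        seq = seq_of([("T3", 0.99), ("T5", 0.99)], positions=[2.4, 4.6])
        res = correct_sequence(seq, w_pos=0.0)
        interior, uncovered = infer_missing(res)
        assert interior == {VertebralLevel.T4}
        assert uncovered == frozenset(
            level_from_name(n) for n in
            ["T1", "T2", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
             "L1", "L2", "L3", "L4", "L5"]
        )


class TestExactnessAndInvariants:
    N_INSTANCES = 220

    def test_dp_matches_brute_force(self, rng):
        """The DP objective equals exhaustive enumeration over every monotone
        partial assignment, across random instances with up to 6 items."""
        for _ in range(self.N_INSTANCES):
            n = int(rng.integers(1, 7))
            seq = random_sequence(rng, n)
            w_label = float(rng.uniform(0, 2))
            w_pos = float(rng.uniform(0, 2))
            pen = float(rng.uniform(0, 0.5))
            res = correct_sequence(
                seq, w_label=w_label, w_pos=w_pos, suppression_penalty=pen
            )
            oracle = brute_force_objective(
                seq, w_label=w_label, w_pos=w_pos, suppression_penalty=pen
            )
            assert res.objective_value == pytest.approx(oracle, abs=1e-9)

    def test_output_monotone_and_conserving(self, rng):
        for _ in range(60):
            n = int(rng.integers(0, 12))
            seq = random_sequence(rng, n)
            res = correct_sequence(seq)
            levels = [l.ordinal for _, l in res.assigned]
            items = [i for i, _ in res.assigned]
            assert levels == sorted(levels) and len(set(levels)) == len(levels)
            assert items == sorted(items)
            # conservation: nothing invented, nothing lost
            assert sorted(items + list(res.suppressed)) == list(range(n))

    def test_idempotence(self, rng):
        """Re-running on the corrected labels reproduces the same assignment."""
        for _ in range(60):
            n = int(rng.integers(1, 12))
            seq = random_sequence(rng, n)
            res = correct_sequence(seq)
            final = res.final_levels
            relabelled = OrderedDetectionSequence(
                items=tuple(
                    SequenceItem(
                        position=item.position,
                        predicted_level=final.get(i, item.predicted_level),
                        confidence=item.confidence,
                    )
                    for i, item in enumerate(seq.items)
                )
            )
            res2 = correct_sequence(relabelled)
            assert res2.assigned == res.assigned
            assert res2.suppressed == res.suppressed

    def test_label_permutation_keeps_feasible_set(self, rng):
        """Permuting predicted labels changes scores, never feasibility: the
        corrected output is always strictly monotone regardless of labels."""
        seq = random_sequence(rng, 8)
        labels = [it.predicted_level for it in seq.items]
        perm = list(rng.permutation(len(labels)))
        permuted = OrderedDetectionSequence(
            items=tuple(
                SequenceItem(it.position, labels[perm[i]], it.confidence)
                for i, it in enumerate(seq.items)
            )
        )
        for s in (seq, permuted):
            res = correct_sequence(s)
            levels = [l.ordinal for _, l in res.assigned]
            assert levels == sorted(set(levels))
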