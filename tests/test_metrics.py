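"""Metric definitions, printed-table worked examples, and oracle equivalences."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smokereg.corpus import STATUS_ORDER, SmokingStatus
from smokereg.metrics import (
    ConfusionMatrix,
    f1,
    merge_ever,
    micro_f1,
    per_class_report,
    two_by_two_eval,
)


def _cm_from_correct(correct: dict[SmokingStatus, tuple[int, int]]) -> ConfusionMatrix:
    """Build a matrix with the given per-class (correct, gold size); misses
    are spread deterministically over the other classes."""
    n = len(STATUS_ORDER)
    counts = np.zeros((n, n), dtype=int)
    for i, cls in enumerate(STATUS_ORDER):
        tp, size = correct[cls]
        counts[i, i] = tp
        remaining = size - tp
        j = (i + 1) % n
        while remaining > 0:
            counts[i, j] += 1
            remaining -= 1
            j = (j + 1) % n
            if j == i:
                j = (j + 1) % n
    return ConfusionMatrix(classes=STATUS_ORDER, counts=counts)


class TestF1:
    @pytest.mark.parametrize(
        "precision,recall,expected",
        [
            (0.83, 0.98, 0.90),  # never-smoker row, locally trained analysis
            (0.73, 0.73, 0.73),  # former-smoker row, challenge-corpus analysis
            (0.62, 0.73, 0.67),  # current-smoker row, challenge-corpus analysis
            (0.0, 0.0, 0.0),
        ],
    )
    def test_harmonic_mean_reproduces_reported_cells(self, precision, recall, expected):
        assert round(f1(precision, recall), 2) == expected

    @given(p=st.floats(min_value=0, max_value=1))
    def test_equal_arguments_are_a_fixed_point(self, p):
        assert f1(p, p) == pytest.approx(p)

    @given(
        p=st.floats(min_value=0, max_value=1),
        r=st.floats(min_value=0, max_value=1),
    )
    def test_symmetric_and_bounded_by_max(self, p, r):
        assert f1(p, r) == pytest.approx(f1(r, p))
        assert f1(p, r) <= max(p, r) + 1e-12

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            f1(*bad)


class TestMicroF1:
    def test_diagonal_matrix_scores_one(self):
        cm = ConfusionMatrix(classes=STATUS_ORDER, counts=np.diag([3, 1, 4, 1, 5]))
        assert micro_f1(cm) == 1.0

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(classes=STATUS_ORDER, counts=np.zeros((5, 5), int))
        with pytest.raises(ValueError):
            micro_f1(cm)

    @pytest.mark.parametrize(
        "per_class_correct,expected",
        [
            # challenge-corpus test set: per-class correct = round(recall x n)
            # over class sizes 16/11/11/3/63 (104 notes)
            ({"never": (15, 16), "former": (8, 11), "current": (8, 11),
              "smoker": (0, 3), "unknown": (63, 63)}, 0.90),
            # hospital-corpus test set: sizes 51/30/31/3/108 (223 notes)
            ({"never": (50, 51), "former": (25, 30), "current": (26, 31),
              "smoker": (1, 3), "unknown": (99, 108)}, 0.90),
            # cross-corpus analysis: trained on hospital, tested on challenge
            ({"never": (15, 16), "former": (7, 11), "current": (6, 11),
              "smoker": (0, 3), "unknown": (63, 63)}, 0.88),
        ],
    )
    def test_reconstructed_test_sets_reproduce_reported_micro_f1(
        self, per_class_correct, expected
    ):
        cm = _cm_from_correct(
            {SmokingStatus.parse(k): v for k, v in per_class_correct.items()}
        )
        assert round(micro_f1(cm), 2) == expected

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_equals_accuracy_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(5, 5))
        if counts.sum() == 0:
            counts[0, 0] = 1
        cm = ConfusionMatrix(classes=STATUS_ORDER, counts=counts)
        assert micro_f1(cm) == pytest.approx(np.trace(counts) / counts.sum())


class TestPerClassReport:
    def test_perfect_predictions_score_one_everywhere(self):
        cm = ConfusionMatrix(classes=STATUS_ORDER, counts=np.diag([2, 2, 2, 2, 2]))
        report = per_class_report(cm)
        for m in report.per_class.values():
            assert (m.precision, m.recall, m.f1_score) == (1.0, 1.0, 1.0)
            assert (m.sensitivity, m.specificity) == (1.0, 1.0)

    def test_class_absent_from_gold_has_absent_recall_not_zero(self):
        counts = np.zeros((5, 5), int)
        counts[0, 0] = 4  # only never-smokers in gold
        report = per_class_report(ConfusionMatrix(classes=STATUS_ORDER, counts=counts))
        former = report.per_class[SmokingStatus.FORMER]
        assert former.recall is None
        assert former.n == 0

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_sensitivity_is_recall_and_cross_checks_sklearn(self, seed):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(seed)
        gold = rng.integers(0, 5, size=60)
        pred = rng.integers(0, 5, size=60)
        cm = ConfusionMatrix.from_pairs(
            [STATUS_ORDER[g] for g in gold], [STATUS_ORDER[p] for p in pred]
        )
        report = per_class_report(cm)
        p, r, f, _ = precision_recall_fscore_support(
            gold, pred, labels=range(5), zero_division=np.nan
        )
        for i, cls in enumerate(STATUS_ORDER):
            m = report.per_class[cls]
            assert m.sensitivity == m.recall
            for ours, theirs in ((m.precision, p[i]), (m.recall, r[i])):
                if ours is None:
                    assert np.isnan(theirs)
                else:
                    assert ours == pytest.approx(theirs)


class TestMergeEver:
    def test_cross_smoker_confusions_become_correct(self):
        counts = np.zeros((5, 5), int)
        idx = {c: i for i, c in enumerate(STATUS_ORDER)}
        counts[idx[SmokingStatus.FORMER], idx[SmokingStatus.CURRENT]] = 5
        counts[idx[SmokingStatus.CURRENT], idx[SmokingStatus.FORMER]] = 4
        counts[idx[SmokingStatus.NEVER], idx[SmokingStatus.NEVER]] = 10
        _, sensitivity, _ = merge_ever(ConfusionMatrix(classes=STATUS_ORDER, counts=counts))
        assert sensitivity == 1.0

    def test_no_gold_smokers_gives_absent_sensitivity(self):
        counts = np.zeros((5, 5), int)
        counts[0, 0] = 3
        counts[4, 4] = 2
        _, sensitivity, specificity = merge_ever(
            ConfusionMatrix(classes=STATUS_ORDER, counts=counts)
        )
        assert sensitivity is None
        assert specificity == 1.0

    def test_merging_never_decreases_correct_count_exhaustively(self):
        """Brute force over small matrices: merged correct >= unmerged correct."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            counts = rng.integers(0, 3, size=(5, 5))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(classes=STATUS_ORDER, counts=counts)
            box, _, _ = merge_ever(cm)
            assert box.tp + box.tn >= np.trace(counts)
            assert box.tp + box.tn + box.fp + box.fn == counts.sum()


class TestTwoByTwo:
    def test_pack_year_extraction_table(self):
        """Presence/absence crosstab of the pack-year rules on the hospital test set."""
        gold = [True] * 36 + [False] * 187
        found = [True] * 33 + [False] * 3 + [True] * 8 + [False] * 179
        box, sensitivity, specificity = two_by_two_eval(gold, found)
        assert (box.tp, box.fn, box.fp, box.tn) == (33, 3, 8, 179)
        assert round(sensitivity * 100, 1) == 91.7
        assert round(specificity * 100, 1) == 95.7  # 179/187 from the printed cells

    def test_cessation_extraction_table(self):
        gold = [True] * 19 + [False] * 204
        found = [True] * 12 + [False] * 7 + [True] * 11 + [False] * 193
        box, sensitivity, specificity = two_by_two_eval(gold, found)
        assert (box.tp, box.fn, box.fp, box.tn) == (12, 7, 11, 193)
        assert round(sensitivity * 100, 1) == 63.2
        assert round(specificity * 100, 1) == 94.6

    def test_all_correct_flags(self):
        _, sensitivity, specificity = two_by_two_eval(
            [True, False, True], [True, False, True]
        )
        assert (sensitivity, specificity) == (1.0, 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            two_by_two_eval([True], [True, False])
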