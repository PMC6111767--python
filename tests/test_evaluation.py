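"""Confusion counting, metric identities, group summaries, kappa."""

import numpy as np
import pytest

from lmr import (
    ACTIVE,
    EXCLUDED,
    REST_HEAD_DOWN,
    REST_HEAD_UP,
    ConfusionCounts,
    StateSeries,
    aggregate_subjects,
    cohens_kappa,
    compute_metrics,
    confusion,
)
from lmr.core import AlignmentError, DataError
from lmr.data import reference_cohort


def series(labels):
    return StateSeries(1.0, np.array(labels, dtype=object))


def random_series(rng, n, labels=(ACTIVE, REST_HEAD_DOWN)):
    return series(rng.choice(labels, size=n))


class TestConfusion:
    def test_perfect_agreement(self):
        truth = series([REST_HEAD_DOWN] * 8 + [ACTIVE] * 12)
        c = confusion(truth, truth, REST_HEAD_DOWN)
        assert (c.tp, c.tn, c.fp, c.fn) == (8, 12, 0, 0)

    def test_all_positive_prediction(self):
        truth = series([REST_HEAD_DOWN] * 8 + [ACTIVE] * 12)
        pred = series([REST_HEAD_DOWN] * 20)
        c = confusion(pred, truth, REST_HEAD_DOWN)
        assert (c.tp, c.fp, c.tn, c.fn) == (8, 12, 0, 0)

    def test_excluded_epochs_skipped(self):
        truth = series([REST_HEAD_DOWN, EXCLUDED, ACTIVE])
        pred = series([REST_HEAD_DOWN, REST_HEAD_DOWN, EXCLUDED])
        c = confusion(pred, truth, REST_HEAD_DOWN)
        assert c.total == 1 and c.tp == 1

    def test_grid_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            confusion(series([ACTIVE] * 3), series([ACTIVE] * 4), ACTIVE)

    def test_counts_match_bruteforce_loop(self):
        rng = np.random.default_rng(31)
        pred = random_series(rng, 300, (ACTIVE, REST_HEAD_DOWN, REST_HEAD_UP, EXCLUDED))
        truth = random_series(rng, 300, (ACTIVE, REST_HEAD_DOWN, REST_HEAD_UP, EXCLUDED))
        c = confusion(pred, truth, REST_HEAD_DOWN)
        tp = fp = tn = fn = 0
        for p, t in zip(pred.values, truth.values):
            if p == EXCLUDED or t == EXCLUDED:
                continue
            if p == REST_HEAD_DOWN and t == REST_HEAD_DOWN:
                tp += 1
            elif p == REST_HEAD_DOWN:
                fp += 1
            elif t == REST_HEAD_DOWN:
                fn += 1
            else:
                tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)


class TestMetrics:
    def test_worked_arithmetic_example(self):
        m = compute_metrics(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert m.ppv == pytest.approx(0.90)
        assert m.npv == pytest.approx(0.80)
        assert m.spc == pytest.approx(8 / 9)
        assert m.sen == pytest.approx(9 / 11)
        assert m.acc == pytest.approx(0.85)

    def test_perfect_counts_give_unit_metrics(self):
        m = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (m.ppv, m.npv, m.spc, m.sen, m.acc) == (1, 1, 1, 1, 1)

    def test_zero_denominator_reports_not_available(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=8, fn=2))
        assert np.isnan(m.ppv)
        assert m.npv == pytest.approx(0.8)

    def test_label_swap_symmetry_on_random_tables(self):
        rng = np.random.default_rng(32)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            # swapping positive/negative swaps TP<->TN and FP<->FN
            s = compute_metrics(ConfusionCounts(tn, fn, tp, fp))
            assert m.sen == pytest.approx(s.spc)
            assert m.spc == pytest.approx(s.sen)
            assert m.ppv == pytest.approx(s.npv)
            assert m.npv == pytest.approx(s.ppv)
            assert m.acc == pytest.approx(s.acc)


class TestGroupSummary:
    def test_reference_rest_from_low_movement_column(self):
        df = reference_cohort()
        s = aggregate_subjects(df["acc_rest_ess"].tolist(), "acc_rest_ess")
        assert (s.mean, s.sd) == (0.86, 0.08)

    def test_reference_rest_from_posture_column(self):
        df = reference_cohort()
        s = aggregate_subjects(df["acc_rest_posture"].tolist(), "acc_rest_posture")
        assert (s.mean, s.sd) == (0.89, 0.06)

    def test_identical_reports_have_zero_sd(self):
        s = aggregate_subjects([0.9, 0.9, 0.9], "acc")
        assert s.mean == 0.9 and s.sd == 0.0

    def test_not_available_subjects_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            s = aggregate_subjects([0.8, float("nan"), 0.9], "acc")
        assert s.n_subjects == 2

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(DataError):
            aggregate_subjects([0.9], "acc")


class TestKappa:
    def test_identical_series_is_one(self):
        a = series([ACTIVE, REST_HEAD_DOWN, REST_HEAD_UP, ACTIVE])
        assert cohens_kappa(a, a) == pytest.approx(1.0)

    def test_constant_equal_raters_defined_as_one(self):
        a = series([ACTIVE] * 10)
        assert cohens_kappa(a, a) == 1.0

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(33)
        a = random_series(rng, 10_000, (ACTIVE, REST_HEAD_DOWN, REST_HEAD_UP))
        b = random_series(rng, 10_000, (ACTIVE, REST_HEAD_DOWN, REST_HEAD_UP))
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_two_state_agreement_table_hand_computation(self):
        # 45/5; 5/45 agreement table: p_o = 0.9, p_e = 0.5, kappa = 0.8
        a = series([ACTIVE] * 50 + [REST_HEAD_DOWN] * 50)
        b = series(
            [ACTIVE] * 45 + [REST_HEAD_DOWN] * 5 + [ACTIVE] * 5 + [REST_HEAD_DOWN] * 45
        )
        assert cohens_kappa(a, b) == pytest.approx(0.8)

    def test_invariant_under_state_relabelling(self):
        rng = np.random.default_rng(34)
        a = random_series(rng, 500, (ACTIVE, REST_HEAD_DOWN, REST_HEAD_UP))
        b = random_series(rng, 500, (ACTIVE, REST_HEAD_DOWN, REST_HEAD_UP))
        relabel = {ACTIVE: REST_HEAD_UP, REST_HEAD_UP: REST_HEAD_DOWN, REST_HEAD_DOWN: ACTIVE}
        a2 = series([relabel[v] for v in a.values])
        b2 = series([relabel[v] for v in b.values])
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(a2, b2))
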