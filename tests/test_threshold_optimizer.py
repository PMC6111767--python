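"""ROC sweeps, crossing points and group best-fit thresholds."""

import numpy as np
import pytest

from lmr import (
    ACTIVE,
    REST_HEAD_DOWN,
    REST_HEAD_UP,
    StateSeries,
    crossing_point,
    fit_thresholds,
    group_best_fit,
    roc_sweep,
    simulate_cohort,
)
from lmr.core import DegenerateRocError
from lmr.simulator import SimConfig
from lmr.threshold_optimizer import RocCurve


def truth_series(labels, epoch_length_s=1.0):
    return StateSeries(epoch_length_s, np.array(labels, dtype=object))


SEPARABLE_STAT = np.array([0.01] * 5 + [0.10] * 5)
SEPARABLE_TRUTH = truth_series([REST_HEAD_DOWN] * 5 + [ACTIVE] * 5)


class TestRocSweep:
    def test_separable_statistic_enumerated_outcomes(self):
        curve = roc_sweep(
            SEPARABLE_STAT, SEPARABLE_TRUTH, REST_HEAD_DOWN,
            grid=np.array([0.005, 0.05, 0.5]), rule="le",
        )
        assert list(zip(curve.sen, curve.spc)) == [(0.0, 1.0), (1.0, 1.0), (1.0, 0.0)]

    def test_threshold_below_all_values_gives_zero_sensitivity(self):
        curve = roc_sweep(
            SEPARABLE_STAT, SEPARABLE_TRUTH, REST_HEAD_DOWN,
            grid=np.array([0.001]), rule="le",
        )
        assert curve.sen[0] == 0.0

    def test_chance_level_statistic_has_sen_plus_spc_near_one(self):
        rng = np.random.default_rng(41)
        n = 10_000
        stat = rng.uniform(0, 1, n)
        truth = truth_series(rng.choice([REST_HEAD_DOWN, ACTIVE], n))
        curve = roc_sweep(stat, truth, REST_HEAD_DOWN, np.array([0.2, 0.5, 0.8]))
        assert np.all(np.abs(curve.sen + curve.spc - 1.0) < 0.05)

    def test_single_class_truth_raises(self):
        with pytest.raises(DegenerateRocError):
            roc_sweep(
                SEPARABLE_STAT, truth_series([ACTIVE] * 10), REST_HEAD_DOWN,
                np.array([0.05]),
            )

    def test_sen_monotone_and_spc_antitone_in_delta(self):
        rng = np.random.default_rng(42)
        stat = np.concatenate([rng.normal(0.01, 0.004, 200), rng.normal(0.06, 0.02, 200)])
        truth = truth_series([REST_HEAD_DOWN] * 200 + [ACTIVE] * 200)
        curve = roc_sweep(stat, truth, REST_HEAD_DOWN, np.linspace(0.001, 0.1, 50))
        assert np.all(np.diff(curve.sen) >= 0)
        assert np.all(np.diff(curve.spc) <= 0)


class TestCrossingPoint:
    def test_exact_crossing_selected(self):
        curve = RocCurve(
            thresholds=np.array([0.01, 0.05, 0.09]),
            sen=np.array([0.2, 1.0, 1.0]),
            spc=np.array([1.0, 1.0, 0.3]),
            acc=np.array([0.6, 1.0, 0.65]),
        )
        assert crossing_point(curve) == 0.05

    def test_separable_example_picks_middle_threshold(self):
        curve = roc_sweep(
            SEPARABLE_STAT, SEPARABLE_TRUTH, REST_HEAD_DOWN,
            grid=np.array([0.005, 0.05, 0.5]),
        )
        assert crossing_point(curve) == 0.05

    def test_all_tied_points_fall_back_to_median_threshold(self):
        curve = RocCurve(
            thresholds=np.array([1.0, 2.0, 3.0]),
            sen=np.array([0.6, 0.6, 0.6]),
            spc=np.array([0.6, 0.6, 0.6]),
            acc=np.array([0.6, 0.6, 0.6]),
        )
        assert crossing_point(curve) == 2.0


class TestGroupBestFit:
    def test_single_subject_reduces_to_crossing_point(self):
        grid = np.array([0.005, 0.05, 0.5])
        fitted, curves = group_best_fit(
            [(SEPARABLE_STAT, SEPARABLE_TRUTH)], grid, REST_HEAD_DOWN
        )
        assert fitted == crossing_point(curves[0])

    def test_duplicated_subject_changes_nothing(self):
        grid = np.array([0.005, 0.05, 0.5])
        once, _ = group_best_fit([(SEPARABLE_STAT, SEPARABLE_TRUTH)], grid, REST_HEAD_DOWN)
        twice, _ = group_best_fit(
            [(SEPARABLE_STAT, SEPARABLE_TRUTH)] * 2, grid, REST_HEAD_DOWN
        )
        assert once == twice

    def test_degenerate_subject_excluded_with_warning(self):
        grid = np.array([0.005, 0.05, 0.5])
        with pytest.warns(UserWarning):
            fitted, curves = group_best_fit(
                [
                    (SEPARABLE_STAT, SEPARABLE_TRUTH),
                    (SEPARABLE_STAT, truth_series([ACTIVE] * 10)),
                ],
                grid,
                REST_HEAD_DOWN,
            )
        assert len(curves) == 1

    def test_fitted_threshold_beats_all_others_by_bruteforce(self):
        rng = np.random.default_rng(43)
        grid = np.linspace(0.001, 0.1, 34)
        subjects = []
        for _ in range(3):
            stat = np.concatenate(
                [rng.normal(0.012, 0.006, 150), rng.normal(0.05, 0.02, 150)]
            )
            subjects.append(
                (stat, truth_series([REST_HEAD_DOWN] * 150 + [ACTIVE] * 150))
            )
        fitted, curves = group_best_fit(subjects, grid, REST_HEAD_DOWN)
        mean_diff = np.mean([np.abs(c.sen - c.spc) for c in curves], axis=0)
        assert mean_diff[np.where(grid == fitted)[0][0]] == pytest.approx(
            mean_diff.min()
        )


class TestCohortRecovery:
    def test_fitted_thresholds_recover_generating_separation(self):
        cohort = simulate_cohort(
            5,
            SimConfig(
                duration_s=1200.0,
                incline_headup_sd_deg=3.0,
                incline_headdown_sd_deg=3.0,
            ),
            seed=44,
        )
        traces = [t for t, _ in cohort]
        truths = [a for _, a in cohort]
        fitted = fit_thresholds(traces, truths)
        assert 0.008 < fitted.delta_g < 0.2
        assert 5.0 <= fitted.omega_deg <= 25.0
        # steady-state head-state accuracy at the fitted omega: score the
        # incline stage per subject on rest windows away from transitions
        from lmr import StateSeries, epoch_accuracy, transition_mask
        from lmr.threshold_optimizer import subject_statistics

        for trace, truth in zip(traces, truths):
            _, _, inc_stat, inc_truth = subject_statistics(trace, truth)
            pred_vals = np.where(
                inc_stat >= fitted.omega_deg, REST_HEAD_UP, REST_HEAD_DOWN
            ).astype(object)
            pred = StateSeries(inc_truth.epoch_length_s, pred_vals)
            acc = epoch_accuracy(pred, inc_truth, transition_mask(inc_truth))
            assert acc >= 0.95
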