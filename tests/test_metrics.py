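import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef

from somnoseq import (ConfusionMatrix, Hypnogram, classifier_metrics,
                      clinical_metrics, confusion, mae_of_metrics, scheme,
                      sleep_onset_latency, sleep_transition_index)


def _hyp(labels, sch="three"):
    return Hypnogram.from_labels(labels, sch)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        h = _hyp(["W", "NREM", "REM", "NREM", "W"])
        cm = confusion(h, h)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.counts.sum() == 5

    def test_hand_counted_two_class(self):
        pred = _hyp(["W", "W", "Sleep", "Sleep", "W", "Sleep", "W", "Sleep", "Sleep", "W"], "two")
        true = _hyp(["W", "Sleep", "Sleep", "W", "W", "Sleep", "Sleep", "Sleep", "W", "W"], "two")
        cm = confusion(pred, true)
        # rows predicted, columns true, enumerated by hand
        np.testing.assert_array_equal(cm.counts, [[3, 2], [2, 3]])

    def test_column_normalization_sums_to_100(self):
        rng = np.random.default_rng(0)
        pred = Hypnogram(rng.integers(0, 3, 1000), scheme("three"))
        true = Hypnogram(rng.integers(0, 3, 1000), scheme("three"))
        cm = confusion(pred, true)
        np.testing.assert_allclose(cm.column_normalized().sum(axis=0), 100.0)

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(_hyp(["W"]), _hyp(["W", "W"]))
        with pytest.raises(ValueError):
            confusion(_hyp(["W"]), _hyp(["W"], "four"))


class TestClassifierMetrics:
    def test_perfect_prediction(self):
        m = classifier_metrics(ConfusionMatrix(np.diag([30, 50, 20])))
        assert m["accuracy"] == 1.0
        assert m["weighted_f1"] == pytest.approx(1.0)
        assert m["macro_mcc"] == pytest.approx(1.0)

    def test_binary_closed_form(self):
        # [[40, 10], [10, 40]]: accuracy 0.8, MCC 0.6 by the 2x2 formula
        m = classifier_metrics(ConfusionMatrix(np.array([[40, 10], [10, 40]])))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["macro_mcc"] == pytest.approx(0.6)
        assert m["per_class"]["mcc"][0] == pytest.approx(0.6)

    def test_all_one_class_prediction(self):
        cm = ConfusionMatrix(np.array([[60, 40], [0, 0]]))
        m = classifier_metrics(cm)
        # every epoch predicted class 0 -> class-0 specificity is 0
        assert m["per_class"]["specificity"][0] == 0.0
        assert m["per_class"]["sensitivity"][0] == 1.0

    def test_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(1)
        c = rng.integers(0, 50, (4, 4))
        m = classifier_metrics(ConfusionMatrix(c))
        assert m["accuracy"] == pytest.approx(np.trace(c) / c.sum())

    def test_macro_mcc_matches_sklearn_one_vs_rest(self):
        """Macro MCC equals per-class binarized MCC computed independently."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            K = rng.integers(2, 5)
            n = rng.integers(20, 60)
            pred = rng.integers(0, K, n)
            true = rng.integers(0, K, n)
            cm = np.zeros((K, K), dtype=int)
            np.add.at(cm, (pred, true), 1)
            if np.any(cm.sum(axis=0) == 0):
                continue
            m = classifier_metrics(ConfusionMatrix(cm))
            ref = np.mean([matthews_corrcoef(true == k, pred == k)
                           for k in range(K)])
            assert m["macro_mcc"] == pytest.approx(ref, abs=1e-9)

    def test_weighted_f1_matches_sklearn(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 3, 500)
        true = rng.integers(0, 3, 500)
        cm = np.zeros((3, 3), dtype=int)
        np.add.at(cm, (pred, true), 1)
        m = classifier_metrics(ConfusionMatrix(cm))
        assert m["weighted_f1"] == pytest.approx(
            f1_score(true, pred, average="weighted"), abs=1e-9)


class TestOnsetLatency:
    def test_hand_counted_example(self):
        # first run of 3 consecutive sleep epochs starts at epoch 4 (0-based)
        h = _hyp(["W", "W", "NREM", "W", "NREM", "NREM", "NREM", "W"])
        assert sleep_onset_latency(h) == pytest.approx(2.0)

    def test_immediate_sleep(self):
        assert sleep_onset_latency(_hyp(["NREM"] * 10)) == 0.0

    def test_all_wake_is_undefined(self):
        assert sleep_onset_latency(_hyp(["W"] * 10)) is None

    def test_short_runs_do_not_count(self):
        h = _hyp(["NREM", "NREM", "W"] * 5)
        assert sleep_onset_latency(h) is None


class TestTransitionIndex:
    def test_constant_sleep_is_zero(self):
        h = _hyp(["W", "NREM", "NREM", "NREM", "NREM"])
        assert sleep_transition_index(h) == 0.0

    def test_hand_counted_example(self):
        # post-onset [N, N, R, R, N, N]: 2 changes over 6 sleep epochs
        h = _hyp(["W", "NREM", "NREM", "REM", "REM", "NREM", "NREM"])
        assert sleep_transition_index(h) == pytest.approx(2 / 6)

    def test_alternating_stages_approach_one(self):
        h = _hyp(["NREM", "REM"] * 50)
        assert sleep_transition_index(h) == pytest.approx(99 / 100)

    def test_no_onset_is_undefined(self):
        assert sleep_transition_index(_hyp(["W", "NREM", "W", "NREM"])) is None


class TestClinicalMetrics:
    def test_tst_and_efficiency_arithmetic(self):
        codes = np.zeros(960, dtype=int)
        codes[120:840] = 1  # 720 sleep epochs
        h = Hypnogram(codes, scheme("two"))
        cm = clinical_metrics(h)
        assert cm.total_sleep_time_h == pytest.approx(6.0)
        assert cm.sleep_efficiency == pytest.approx(0.75)
        assert cm.recording_time_h == pytest.approx(8.0)

    def test_no_wake_after_onset_means_zero_fragmentation(self):
        h = _hyp(["W", "W"] + ["NREM"] * 20)
        assert clinical_metrics(h).sleep_fragmentation == 0.0

    def test_handcrafted_night_fully_hand_computed(self):
        # 20 epochs: WW NNN R W NNN RRR W NNNN W W (0-based onset at 2)
        labels = ["W", "W", "NREM", "NREM", "NREM", "REM", "W", "NREM", "NREM",
                  "NREM", "REM", "REM", "REM", "W", "NREM", "NREM", "NREM",
                  "NREM", "W", "W"]
        h = _hyp(labels)
        m = clinical_metrics(h)
        assert m.sleep_onset_latency_min == pytest.approx(1.0)      # 2 epochs
        assert m.total_sleep_time_h == pytest.approx(14 * 30 / 3600)  # 14 sleep
        assert m.sleep_efficiency == pytest.approx(14 / 20)
        # post-onset changes: N->R,R->W,W->N,N->R,R->W,W->N,N->W (7); 14 sleep ep.
        assert m.sleep_transition_index == pytest.approx(7 / 14)
        # sleep->wake transitions post-onset: epochs 5->6, 12->13, 17->18 (3)
        assert m.sleep_fragmentation == pytest.approx(3 / (14 * 30 / 3600))
        assert m.stage_time_h["NREM"] == pytest.approx(10 * 30 / 3600)
        assert m.stage_fraction["REM"] == pytest.approx(4 / 14)
        # stage times over all stages sum to the recording duration
        assert sum(m.stage_time_h.values()) == pytest.approx(m.recording_time_h)

    def test_all_wake_night_sentinels(self):
        m = clinical_metrics(_hyp(["W"] * 10))
        assert m.sleep_onset_latency_min is None
        assert m.sleep_transition_index is None
        assert m.total_sleep_time_h == 0.0


class TestMAE:
    def test_identical_metrics_zero_error(self):
        h = _hyp(["W", "NREM", "NREM", "NREM", "REM"])
        m = clinical_metrics(h)
        out = mae_of_metrics([m], [m])
        assert out["total_sleep_time_h"]["mae"] == 0.0
        assert out["total_sleep_time_h"]["sd"] == 0.0

    def test_two_subject_arithmetic(self):
        # TST absolute errors of 0.1 h and 0.3 h -> MAE 0.2, sample SD 0.141
        ref = [clinical_metrics(_hyp(["NREM"] * 24)),   # 0.2 h
               clinical_metrics(_hyp(["NREM"] * 24))]
        pred = [clinical_metrics(_hyp(["NREM"] * 12 + ["W"] * 12)),  # 0.1 h
                clinical_metrics(_hyp(["NREM"] * 60))]               # 0.5 h
        out = mae_of_metrics(pred, ref)["total_sleep_time_h"]
        assert out["mae"] == pytest.approx(0.2)
        assert out["sd"] == pytest.approx(0.141, abs=1e-3)
        assert out["n"] == 2

    def test_single_subject_sd_is_zero(self):
        ref = [clinical_metrics(_hyp(["NREM"] * 24))]
        pred = [clinical_metrics(_hyp(["NREM"] * 12 + ["W"] * 12))]
        out = mae_of_metrics(pred, ref)["total_sleep_time_h"]
        assert out["mae"] == pytest.approx(0.1)
        assert out["sd"] == 0.0

    def test_undefined_values_excluded_pairwise(self):
        pred = [clinical_metrics(_hyp(["W"] * 10)),
                clinical_metrics(_hyp(["NREM"] * 10))]
        ref = [clinical_metrics(_hyp(["NREM"] * 10)),
               clinical_metrics(_hyp(["NREM"] * 10))]
        out = mae_of_metrics(pred, ref)
        assert out["sleep_onset_latency_min"]["n"] == 1
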