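"""Detection-evaluation metrics: matching, R/P/F1, AP/mAP, confusion."""

import numpy as np
import pandas as pd
import pytest

from benthotrend import detection_eval as de
from benthotrend import synthetic_data as sd


def boxes(rows, with_conf=False):
    cols = ["image_id", "label", "x", "y", "w", "h"] + (["confidence"] if with_conf else [])
    return pd.DataFrame(rows, columns=cols)


def ap_bruteforce(pred_match: pd.DataFrame, n_truth: int) -> float:
    """Oracle: enumerate every distinct confidence as a threshold and
    integrate the precision step function over recall increments."""
    pm = pred_match.sort_values("confidence", ascending=False, kind="stable")
    confs = pm["confidence"].to_numpy()
    steps = []
    for thr in sorted(set(confs), reverse=True):
        kept = pm[pm["confidence"] >= thr]
        tp = kept["is_tp"].sum()
        p = tp / len(kept) if len(kept) else 0.0
        r = tp / n_truth if n_truth else 0.0
        steps.append((r, p))
    ap, prev_r = 0.0, 0.0
    for r, p in steps:
        ap += p * (r - prev_r)
        prev_r = r
    return ap


class TestMatching:
    def test_identical_boxes_all_tp(self):
        truths = boxes([("a", "X", 0, 0, 10, 10), ("a", "Y", 50, 50, 10, 10)])
        preds = truths.assign(confidence=1.0)
        m = de.match_predictions(preds, truths)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_prediction_matches_higher_overlap_truth(self):
        # one prediction straddling two truths: greedy must pick the one
        # with larger IoU, leaving the other as a false negative
        truths = boxes([("a", "X", 0, 0, 10, 10), ("a", "X", 8, 0, 10, 10)])
        preds = boxes([("a", "X", 7, 0, 10, 10, 0.9)], with_conf=True)
        m = de.match_predictions(preds, truths, iou_min=0.05)
        ious = [de.iou(np.array([7, 0, 10, 10]), t) for t in ([0, 0, 10, 10], [8, 0, 10, 10])]
        best = int(np.argmax(ious))
        assert m.pred_match.at[0, "matched_truth"] == best
        assert m.fn == 1

    def test_wrong_class_is_fp_and_fn(self):
        truths = boxes([("a", "X", 0, 0, 10, 10)])
        preds = boxes([("a", "Y", 0, 0, 10, 10, 1.0)], with_conf=True)
        m = de.match_predictions(preds, truths)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_one_to_one_assignment(self):
        truths = boxes([("a", "X", 0, 0, 10, 10)])
        preds = boxes(
            [("a", "X", 0, 0, 10, 10, 0.9), ("a", "X", 1, 0, 10, 10, 0.8)], with_conf=True
        )
        m = de.match_predictions(preds, truths)
        assert m.tp == 1 and m.fp == 1

    def test_iou_min_validation(self):
        truths = boxes([("a", "X", 0, 0, 10, 10)])
        with pytest.raises(ValueError, match="iou_min"):
            de.match_predictions(truths.assign(confidence=1.0), truths, iou_min=0.0)


class TestRocMetrics:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (3, 0, 1, (0.75, 1.0, 6 / 7)),
            (1, 1, 1, (0.5, 0.5, 0.5)),  # P=R=0.5 -> F1=0.5 harmonic fixed point
            (0, 0, 5, (0.0, 0.0, 0.0)),  # degenerate conventions
            (0, 0, 0, (0.0, 0.0, 0.0)),
        ],
    )
    def test_formulas_and_conventions(self, tp, fp, fn, expected):
        assert de.roc_metrics(tp, fp, fn) == pytest.approx(expected)


class TestRocCurves:
    def test_perfect_predictions_constant_recall(self):
        truths, preds = sd.simulate_detection_benchmark(10, 2, seed=0)
        curves = de.roc_curves(preds, truths, grid=[0.0, 0.5, 1.0])
        assert (curves.mean["recall"] == 1.0).all()

    def test_precision_rises_past_planted_fp_confidence(self):
        truths, preds = sd.simulate_detection_benchmark(
            8, 1, {"n_fp": 2, "fp_confidence": 0.3}, seed=1
        )
        curves = de.roc_curves(preds, truths, grid=[0.2, 0.5])
        prec = curves.mean.set_index("confidence")["precision"]
        assert prec[0.2] == pytest.approx(0.8)
        assert prec[0.5] == pytest.approx(1.0)

    def test_recall_at_zero_threshold_equals_full_match(self):
        truths, preds = sd.simulate_detection_benchmark(12, 3, {"n_fn": 3}, seed=2)
        m = de.match_predictions(preds, truths)
        curves = de.roc_curves(preds, truths, grid=[0.0])
        full_recall = m.tp / (m.tp + m.fn)
        # micro recall of the full match equals the per-class mean here
        # because every class has the same planted recall structure only
        # approximately; compare the pooled number instead
        per = curves.per_class
        tp = fn = 0
        for lab in per["label"].unique():
            t = truths[truths["label"] == lab]
            p = preds[preds["label"] == lab]
            mm = de.match_predictions(p, t)
            tp, fn = tp + mm.tp, fn + mm.fn
        assert tp / (tp + fn) == pytest.approx(full_recall)

    def test_recall_monotone_in_threshold(self):
        truths, preds = sd.simulate_detection_benchmark(
            20, 3, {"n_fp": 5, "n_swap": 3, "fp_confidence": 0.4}, seed=3
        )
        preds = preds.assign(
            confidence=np.random.default_rng(0).uniform(0.2, 1.0, len(preds)).round(3)
        )
        curves = de.roc_curves(preds, truths, grid=np.linspace(0, 1, 21))
        for _, g in curves.per_class.groupby("label"):
            assert (np.diff(g.sort_values("confidence")["recall"]) <= 1e-12).all()

    def test_empty_grid_rejected(self):
        truths, preds = sd.simulate_detection_benchmark(3, 1, seed=0)
        with pytest.raises(ValueError, match="grid"):
            de.roc_curves(preds, truths, grid=[])


class TestAveragePrecision:
    def test_perfect_detector(self):
        truths, preds = sd.simulate_detection_benchmark(10, 1, seed=0)
        m = de.match_predictions(preds, truths)
        assert de.average_precision_from_match(m, len(truths)) == pytest.approx(1.0)

    def test_worked_example_tp_fp_tp(self):
        # 2 truths; preds (.9 TP), (.8 FP), (.7 TP):
        # steps (R=.5, P=1), (R=1, P=2/3) -> AP = .5 + .5 * 2/3
        truths = boxes([("a", "X", 0, 0, 10, 10), ("b", "X", 0, 0, 10, 10)])
        preds = boxes(
            [
                ("a", "X", 0, 0, 10, 10, 0.9),
                ("c", "X", 0, 0, 10, 10, 0.8),
                ("b", "X", 0, 0, 10, 10, 0.7),
            ],
            with_conf=True,
        )
        m = de.match_predictions(preds, truths)
        ap = de.average_precision_from_match(m, 2)
        assert ap == pytest.approx(0.5 + 0.5 * 2 / 3, abs=1e-12)
        assert ap == pytest.approx(ap_bruteforce(m.pred_match, 2), abs=1e-12)

    def test_no_tp_gives_zero(self):
        truths = boxes([("a", "X", 0, 0, 10, 10)])
        preds = boxes([("b", "X", 0, 0, 10, 10, 0.9)], with_conf=True)
        m = de.match_predictions(preds, truths)
        assert de.average_precision_from_match(m, 1) == 0.0

    def test_decreasing_recall_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            de.average_precision([1.0, 1.0], [0.5, 0.4])

    def test_matches_bruteforce_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(3, 25))
            truths, preds = sd.simulate_detection_benchmark(
                n,
                int(rng.integers(1, 4)),
                {
                    "n_fp": int(rng.integers(0, 5)),
                    "n_fn": int(rng.integers(0, n // 3 + 1)),
                    "fp_confidence": float(rng.uniform(0.1, 0.9)),
                },
                seed=rng,
            )
            preds = preds.assign(confidence=rng.uniform(0.05, 1.0, len(preds)).round(3))
            m = de.match_predictions(preds, truths)
            ap = de.average_precision_from_match(m, len(truths))
            assert ap == pytest.approx(ap_bruteforce(m.pred_match, len(truths)), abs=1e-12)


class TestMeanAveragePrecision:
    def test_mean_and_invariance(self):
        assert de.mean_average_precision([1.0, 0.5]) == pytest.approx(0.75)
        aps = [0.3, 0.9, 0.6]
        assert de.mean_average_precision(aps) == de.mean_average_precision(aps[::-1])

    def test_constant_aps(self):
        assert de.mean_average_precision([0.4] * 17) == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            de.mean_average_precision([])


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        truths, preds = sd.simulate_detection_benchmark(30, 3, seed=4)
        mat = de.confusion_matrix(preds, truths)
        labels = [c for c in mat.columns if c != de.BACKGROUND]
        assert np.allclose(np.diag(mat.loc[labels, labels]), 1.0)

    def test_systematic_swap_lands_in_cross_cell(self):
        truths = boxes([("a", "A", i * 120, 0, 20, 20) for i in range(5)])
        preds = truths.assign(label="B", confidence=1.0)
        mat = de.confusion_matrix(preds, truths)
        assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        truths, preds = sd.simulate_detection_benchmark(
            40, 4, {"n_fp": 6, "n_fn": 5, "n_swap": 8}, seed=5
        )
        mat = de.confusion_matrix(preds, truths)
        sums = mat.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)

    def test_planted_swap_rate_recovered(self):
        rng = np.random.default_rng(11)
        n = 400
        truths = boxes(
            [(f"i{k // 10}", "A", (k % 10) * 120, (k // 10 % 10) * 120, 30, 30) for k in range(n)]
        )
        preds = truths.assign(confidence=1.0)
        swap = rng.uniform(size=n) < 0.10
        preds.loc[swap, "label"] = "B"
        mat = de.confusion_matrix(preds, truths)
        assert mat.loc["A", "B"] == pytest.approx(0.10, abs=3 * np.sqrt(0.1 * 0.9 / n))
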