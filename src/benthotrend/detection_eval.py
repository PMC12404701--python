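"""Object-detection evaluation: recall, precision, F1, AP, mAP, confusion.

Ground truths and predictions are tables with one bounding box per row
(columns ``image_id, label, x, y, w, h`` and, for predictions,
``confidence``). Matching is greedy in descending confidence with a
one-to-one assignment of predictions to same-class truths at an
intersection-over-union of at least ``iou_min`` (default 0.5, the
community convention; the matching rule is configurable because archived
evaluation protocols rarely state it).

Conventions for degenerate ratios: P = 0 when TP+FP = 0, R = 0 when
TP+FN = 0, F1 = 0 when P+R = 0, so every curve stays bounded in [0, 1]
at extreme confidence thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRUTH_COLUMNS = ["image_id", "label", "x", "y", "w", "h"]
PRED_COLUMNS = TRUTH_COLUMNS + ["confidence"]

BACKGROUND = "background"


def iou(box_a: np.ndarray, box_b: np.ndarray) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchResult:
    """Outcome of matching predictions to ground truths.

    ``pred_match`` has one row per prediction (original order) with columns
    ``is_tp`` and ``matched_truth`` (index into the truth table, or -1);
    ``truth_matched`` is a boolean array over truths. Unmatched truths are
    the false negatives.
    """

    pred_match: pd.DataFrame
    truth_matched: np.ndarray
    iou_min: float

    @property
    def tp(self) -> int:
        return int(self.pred_match["is_tp"].sum())

    @property
    def fp(self) -> int:
        return int((~self.pred_match["is_tp"]).sum())

    @property
    def fn(self) -> int:
        return int((~self.truth_matched).sum())


def _check_boxes(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns: {missing}")
    if len(df) and ((df["w"] <= 0) | (df["h"] <= 0)).any():
        raise ValueError(f"{name} table has non-positive box extents")
    if "confidence" in cols and len(df):
        conf = df["confidence"]
        if ((conf < 0) | (conf > 1)).any():
            raise ValueError("confidences must lie in [0, 1]")
    return df.reset_index(drop=True)


def match_predictions(
    preds: pd.DataFrame,
    truths: pd.DataFrame,
    iou_min: float = 0.5,
    *,
    class_agnostic: bool = False,
) -> MatchResult:
    """Greedily match predictions to truths in descending confidence.

    Each prediction claims the unmatched truth (same image, same class
    unless ``class_agnostic``) with the highest IoU >= ``iou_min``; a
    prediction that claims nothing is a false positive, a truth never
    claimed is a false negative.
    """
    if not (0.0 < iou_min <= 1.0):
        raise ValueError(f"iou_min must lie in (0, 1], got {iou_min}")
    preds = _check_boxes(preds, PRED_COLUMNS, "prediction")
    truths = _check_boxes(truths, TRUTH_COLUMNS, "truth")

    order = np.argsort(-preds["confidence"].to_numpy(), kind="stable")
    truth_matched = np.zeros(len(truths), dtype=bool)
    is_tp = np.zeros(len(preds), dtype=bool)
    matched_truth = np.full(len(preds), -1, dtype=int)

    t_boxes = truths[["x", "y", "w", "h"]].to_numpy(dtype=float)
    p_boxes = preds[["x", "y", "w", "h"]].to_numpy(dtype=float)
    t_img = truths["image_id"].to_numpy()
    t_lab = truths["label"].to_numpy()

    for pi in order:
        cand = (t_img == preds.at[pi, "image_id"]) & ~truth_matched
        if not class_agnostic:
            cand &= t_lab == preds.at[pi, "label"]
        best_iou, best_ti = 0.0, -1
        for ti in np.flatnonzero(cand):
            ov = iou(p_boxes[pi], t_boxes[ti])
            if ov >= iou_min and ov > best_iou:
                best_iou, best_ti = ov, ti
        if best_ti >= 0:
            truth_matched[best_ti] = True
            is_tp[pi] = True
            matched_truth[pi] = best_ti

    pm = pd.DataFrame(
        {
            "label": preds["label"],
            "confidence": preds["confidence"],
            "is_tp": is_tp,
            "matched_truth": matched_truth,
        }
    )
    return MatchResult(pred_match=pm, truth_matched=truth_matched, iou_min=iou_min)


def roc_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Recall, precision and F1 from true/false positive and negative counts.

    R = TP/(TP+FN), P = TP/(TP+FP), F1 = 2PR/(P+R), with the 0/0
    conventions documented in the module docstring.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    r = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    p = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return r, p, f1


@dataclass
class RocCurves:
    """Recall/precision/F1 against confidence threshold, per class and mean."""

    grid: np.ndarray
    per_class: pd.DataFrame  # columns: label, confidence, recall, precision, f1
    mean: pd.DataFrame  # columns: confidence, recall, precision, f1
    best_f1_confidence: float = field(default=np.nan)


def roc_curves(
    preds: pd.DataFrame,
    truths: pd.DataFrame,
    iou_min: float = 0.5,
    grid: np.ndarray | list[float] | None = None,
) -> RocCurves:
    """Recompute R/P/F1 at each confidence threshold in ``grid``.

    Predictions below the threshold are discarded and matching is rerun,
    so precision can rise as low-confidence false positives drop out. The
    mean curve is the unweighted average over classes present in either
    table; ``best_f1_confidence`` is the grid point maximising mean F1.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.005), 6)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("confidence grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("confidence grid must be sorted ascending")

    labels = sorted(set(truths["label"]) | set(preds["label"]))
    rows = []
    for thr in grid:
        kept = preds[preds["confidence"] >= thr]
        m = match_predictions(kept, truths, iou_min)
        for lab in labels:
            sel = m.pred_match["label"] == lab
            tp = int(m.pred_match.loc[sel, "is_tp"].sum())
            fp = int(sel.sum()) - tp
            fn = int(((truths["label"].to_numpy() == lab) & ~m.truth_matched).sum())
            r, p, f1 = roc_metrics(tp, fp, fn)
            rows.append((lab, thr, r, p, f1))
    per_class = pd.DataFrame(rows, columns=["label", "confidence", "recall", "precision", "f1"])
    mean = (
        per_class.groupby("confidence", as_index=False)[["recall", "precision", "f1"]]
        .mean()
        .sort_values("confidence", ignore_index=True)
    )
    best = float(mean.loc[mean["f1"].idxmax(), "confidence"]) if len(mean) else np.nan
    return RocCurves(grid=grid, per_class=per_class, mean=mean, best_f1_confidence=best)


def precision_recall_pairs(match: MatchResult, n_truth: int) -> pd.DataFrame:
    """Cumulative (precision, recall) at each distinct confidence.

    Predictions sharing a confidence enter together (the threshold cannot
    separate them), so each tie group contributes one pair; the sequence
    then integrates to the same AP as explicit threshold enumeration.
    """
    pm = match.pred_match.sort_values("confidence", ascending=False, kind="stable")
    conf = pm["confidence"].to_numpy()
    tp_cum = pm["is_tp"].to_numpy(dtype=float).cumsum()
    k = np.arange(1, len(pm) + 1, dtype=float)
    last_of_group = np.ones(len(pm), dtype=bool)
    if len(pm) > 1:
        last_of_group[:-1] = conf[:-1] != conf[1:]
    precision = (tp_cum / k)[last_of_group]
    tp_sel = tp_cum[last_of_group]
    recall = tp_sel / n_truth if n_truth > 0 else np.zeros_like(tp_sel)
    return pd.DataFrame(
        {"confidence": conf[last_of_group], "precision": precision, "recall": recall}
    )


def average_precision(precision, recall) -> float:
    """AP = sum over steps of precision times the recall increment.

    ``precision`` and ``recall`` are the cumulative pairs in descending
    confidence order (recall non-decreasing). Precision is used raw at
    each step: no 11-point sampling, no monotone interpolation.
    """
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    if precision.shape != recall.shape:
        raise ValueError("precision and recall must have equal length")
    if recall.size == 0:
        return 0.0
    if np.any(np.diff(recall) < -1e-12):
        raise ValueError("recall must be non-decreasing along the sequence")
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum(precision * (recall - prev)))


def average_precision_from_match(match: MatchResult, n_truth: int) -> float:
    pr = precision_recall_pairs(match, n_truth)
    return average_precision(pr["precision"], pr["recall"])


def per_class_average_precision(
    preds: pd.DataFrame, truths: pd.DataFrame, iou_min: float = 0.5
) -> pd.Series:
    """AP for every class in the truth table (classes never predicted get 0)."""
    labels = sorted(set(truths["label"]))
    aps = {}
    for lab in labels:
        p = preds[preds["label"] == lab]
        t = truths[truths["label"] == lab]
        m = match_predictions(p, t, iou_min)
        aps[lab] = average_precision_from_match(m, len(t))
    return pd.Series(aps, name="AP")


def mean_average_precision(aps) -> float:
    """Unweighted arithmetic mean of per-class AP values."""
    aps = np.asarray(list(aps), dtype=float)
    if aps.size == 0:
        raise ValueError("mAP requires at least one class AP")
    return float(aps.mean())


def confusion_matrix(
    preds: pd.DataFrame,
    truths: pd.DataFrame,
    iou_min: float = 0.5,
    *,
    normalize: bool = True,
) -> pd.DataFrame:
    """Normalized confusion matrix with a background row/column.

    A first same-class matching pass fixes the diagonal; a second,
    class-agnostic pass over the leftovers attributes cross-class
    confusions; predictions still unmatched count against background
    (false positives) and truths still unmatched count as background
    predictions (false negatives). With ``normalize`` each non-empty true
    row is scaled to sum to 1.
    """
    preds = _check_boxes(preds, PRED_COLUMNS, "prediction")
    truths = _check_boxes(truths, TRUTH_COLUMNS, "truth")
    labels = sorted(set(truths["label"]) | set(preds["label"]))
    idx = labels + [BACKGROUND]
    mat = pd.DataFrame(0.0, index=idx, columns=idx)

    first = match_predictions(preds, truths, iou_min)
    for _, row in first.pred_match[first.pred_match["is_tp"]].iterrows():
        mat.loc[row["label"], row["label"]] += 1

    leftover_p = preds[~first.pred_match["is_tp"]].reset_index(drop=True)
    leftover_t = truths[~first.truth_matched].reset_index(drop=True)
    second = match_predictions(leftover_p, leftover_t, iou_min, class_agnostic=True)
    for pi, row in second.pred_match.iterrows():
        if row["is_tp"]:
            true_lab = leftover_t.at[row["matched_truth"], "label"]
            mat.loc[true_lab, row["label"]] += 1
        else:
            mat.loc[BACKGROUND, row["label"]] += 1
    for ti in np.flatnonzero(~second.truth_matched):
        mat.loc[leftover_t.at[ti, "label"], BACKGROUND] += 1

    if normalize:
        sums = mat.sum(axis=1)
        nonzero = sums > 0
        mat.loc[nonzero] = mat.loc[nonzero].div(sums[nonzero], axis=0)
    return mat
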