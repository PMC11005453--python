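"""Pixel-level segmentation metrics and stratified reporting.

Five metrics are computed per image and aggregated per condition group and
overall: Dice overlap, accuracy, recall, precision, and the area under the
pixel-wise ROC curve (equal to the Mann-Whitney statistic: the probability
that a randomly chosen foreground pixel outscores a randomly chosen
background pixel, ties counted one half). Aggregation defaults to the
unweighted mean of per-image values (macro); a pixel-pooled micro mode is
available. Tables are reported in percent, rows = condition group,
columns = metric, with a CSV and a JSON serialisation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "dice",
    "confusion_metrics",
    "roc_auc",
    "mask_from_probs",
    "MetricReport",
    "METRIC_NAMES",
]

METRIC_NAMES = ("dice", "acc", "recall", "precision", "auc")


def _check_pair(pred: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred, true = np.asarray(pred), np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    return pred.astype(bool), true.astype(bool)


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap ``2|A & B| / (|A| + |B|)``; 1.0 when both masks are empty."""
    a, b = _check_pair(pred_mask, true_mask)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def confusion_metrics(pred_mask: np.ndarray,
                      true_mask: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, recall, precision) from the pixel confusion counts.

    A zero-denominator ratio is 1 when the set it asks about is also empty
    (nothing to find and nothing claimed) and 0 otherwise.
    """
    a, b = _check_pair(pred_mask, true_mask)
    tp = np.logical_and(a, b).sum()
    fp = np.logical_and(a, ~b).sum()
    fn = np.logical_and(~a, b).sum()
    tn = a.size - tp - fp - fn
    acc = (tp + tn) / a.size
    if tp + fn == 0:
        recall = 1.0 if a.sum() == 0 else 0.0
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        precision = 1.0 if b.sum() == 0 else 0.0
    else:
        precision = tp / (tp + fp)
    return float(acc), float(recall), float(precision)


def roc_auc(prob_map: np.ndarray, true_mask: np.ndarray) -> float | None:
    """Pixel-wise ROC AUC; ``None`` when the mask has a single class."""
    prob_map = np.asarray(prob_map, dtype=float)
    _, b = _check_pair(prob_map, true_mask)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    flat = b.ravel()
    if flat.all() or not flat.any():
        return None
    return float(roc_auc_score(flat, prob_map.ravel()))


def mask_from_probs(prob_fg: np.ndarray) -> np.ndarray:
    """Binarise a foreground-probability map by the two-channel argmax rule."""
    return np.asarray(prob_fg) > 0.5


class MetricReport:
    """Per-image metrics with condition tags and group/overall aggregation."""

    def __init__(self, per_image: pd.DataFrame):
        self.per_image = per_image

    @classmethod
    def compute(cls, prob_maps, true_masks, tags=None, names=None,
                pred_masks=None) -> "MetricReport":
        """Build a report from foreground-probability maps and truth masks.

        ``pred_masks`` overrides the default argmax binarisation; ``tags``
        are free-form condition labels (e.g. clear/occluded/blurred).
        """
        n = len(true_masks)
        tags = list(tags) if tags is not None else ["all"] * n
        names = list(names) if names is not None else [f"img{i:04d}" for i in range(n)]
        rows = []
        for i in range(n):
            prob = np.asarray(prob_maps[i], dtype=float)
            truth = np.asarray(true_masks[i]).astype(bool)
            pred = (np.asarray(pred_masks[i]).astype(bool)
                    if pred_masks is not None else mask_from_probs(prob))
            acc, rec, pre = confusion_metrics(pred, truth)
            rows.append({
                "image": names[i], "tag": tags[i],
                "dice": dice(pred, truth), "acc": acc, "recall": rec,
                "precision": pre, "auc": roc_auc(prob, truth),
                "tp": int(np.logical_and(pred, truth).sum()),
                "fp": int(np.logical_and(pred, ~truth).sum()),
                "fn": int(np.logical_and(~pred, truth).sum()),
                "tn": int(np.logical_and(~pred, ~truth).sum()),
            })
        return cls(pd.DataFrame(rows))

    def aggregate(self, average: str = "macro") -> pd.DataFrame:
        """Percent table, rows = condition group plus an overall row.

        ``macro`` averages per-image values (images without a defined AUC are
        excluded from the AUC mean); ``micro`` pools pixel counts first.
        """
        if average not in ("macro", "micro"):
            raise ValueError(f"average must be macro or micro, got {average!r}")
        groups = list(dict.fromkeys(self.per_image["tag"])) + ["all"]
        rows = {}
        for g in groups:
            sub = (self.per_image if g == "all"
                   else self.per_image[self.per_image["tag"] == g])
            if average == "macro":
                vals = {m: 100.0 * sub[m].dropna().mean() for m in METRIC_NAMES}
            else:
                tp, fp, fn, tn = (sub[k].sum() for k in ("tp", "fp", "fn", "tn"))
                denom = 2 * tp + fp + fn
                vals = {
                    "dice": 100.0 * (2 * tp / denom if denom else 1.0),
                    "acc": 100.0 * (tp + tn) / max(tp + fp + fn + tn, 1),
                    "recall": 100.0 * (tp / (tp + fn) if tp + fn else 1.0),
                    "precision": 100.0 * (tp / (tp + fp) if tp + fp else 1.0),
                    "auc": 100.0 * self.per_image["auc"].dropna().mean(),
                }
            rows[g] = vals
        return pd.DataFrame(rows).T[list(METRIC_NAMES)]

    def to_csv(self, path, average: str = "macro") -> None:
        self.aggregate(average).to_csv(path, index_label="group")

    def to_json(self, path, average: str = "macro") -> None:
        table = self.aggregate(average)
        payload = {
            "aggregate": {g: {m: (None if pd.isna(v) else round(float(v), 4))
                              for m, v in row.items()}
                          for g, row in table.iterrows()},
            "per_image": json.loads(
                self.per_image.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=2))
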