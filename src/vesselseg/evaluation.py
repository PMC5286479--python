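"""FOV-restricted segmentation metrics and experiment drivers.

All confusion counts are taken over FOV pixels only.  Metrics follow the
standard definitions:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)

SEN (resp. SPE) is reported as missing when the ground truth contains no
vessel (resp. no background) pixels inside the FOV.  Means over images are
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float | None
    specificity: float | None


def evaluate(
    segmentation: np.ndarray, ground_truth: np.ndarray, fov: np.ndarray
) -> tuple[ConfusionCounts, Metrics]:
    """Confusion counts and ACC/SEN/SPE of one segmentation over the FOV."""
    seg = np.asarray(segmentation, dtype=bool)
    truth = np.asarray(ground_truth, dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    if not (seg.shape == truth.shape == fov.shape):
        raise ValueError("segmentation, ground truth and FOV shapes differ")
    s, t = seg[fov], truth[fov]
    tp = int(np.count_nonzero(s & t))
    fp = int(np.count_nonzero(s & ~t))
    fn = int(np.count_nonzero(~s & t))
    tn = int(np.count_nonzero(~s & ~t))
    counts = ConfusionCounts(tp, fp, tn, fn)
    acc = (tp + tn) / counts.total
    sen = tp / (tp + fn) if (tp + fn) > 0 else None
    spe = tn / (tn + fp) if (tn + fp) > 0 else None
    return counts, Metrics(acc, sen, spe)


def _metrics_row(image_id, counts: ConfusionCounts, metrics: Metrics) -> dict:
    return {
        "image": image_id,
        "tp": counts.tp,
        "fp": counts.fp,
        "tn": counts.tn,
        "fn": counts.fn,
        "accuracy": metrics.accuracy,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
    }


def run_loocv(dataset, estimator_factory) -> pd.DataFrame:
    """Leave-one-out over a dataset of (image, ground-truth) pairs.

    Each image in turn is held out, a fresh estimator from
    ``estimator_factory()`` is fitted on the rest and evaluated on it.  The
    returned frame has one row per image plus a ``mean`` row with the
    unweighted column means.
    """
    dataset = list(dataset)
    if len(dataset) < 2:
        raise ValueError("leave-one-out needs at least 2 images")
    rows = []
    for i, (img, truth) in enumerate(dataset):
        est = estimator_factory()
        rest = [pair for j, pair in enumerate(dataset) if j != i]
        est.fit([p[0] for p in rest], [p[1] for p in rest])
        result = est.predict(img)
        counts, metrics = evaluate(result.vessels, truth, img.fov)
        rows.append(_metrics_row(i, counts, metrics))
    frame = pd.DataFrame(rows)
    mean = frame.drop(columns="image").mean(numeric_only=True)
    mean["image"] = "mean"
    return pd.concat([frame, mean.to_frame().T], ignore_index=True)


def cross_evaluate(train_set, test_set, estimator_factory) -> pd.DataFrame:
    """Train on one dataset and evaluate on another (cross-training)."""
    est = estimator_factory()
    est.fit([p[0] for p in train_set], [p[1] for p in train_set])
    rows = []
    for i, (img, truth) in enumerate(test_set):
        result = est.predict(img)
        counts, metrics = evaluate(result.vessels, truth, img.fov)
        rows.append(_metrics_row(i, counts, metrics))
    frame = pd.DataFrame(rows)
    mean = frame.drop(columns="image").mean(numeric_only=True)
    mean["image"] = "mean"
    return pd.concat([frame, mean.to_frame().T], ignore_index=True)


def sweep_s(dataset, s_values, estimator_factory) -> pd.DataFrame:
    """Mean leave-one-out accuracy for each line-search threshold S.

    ``estimator_factory(s)`` must return an estimator configured with that
    threshold.  Returns a frame with columns ``s`` and ``mean_accuracy``.
    """
    rows = []
    for s in s_values:
        frame = run_loocv(dataset, lambda: estimator_factory(s))
        mean_acc = float(frame.loc[frame["image"] == "mean", "accuracy"].iloc[0])
        rows.append({"s": s, "mean_accuracy": mean_acc})
    return pd.DataFrame(rows)
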