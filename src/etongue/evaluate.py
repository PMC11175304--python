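"""Metrics, repeated-split evaluation, ablation, majority vote and ANOVA.

Classification quality is assessed from one-vs-rest confusion counts::

    Recall = TP / (TP + FN)        Precision = TP / (TP + FP)
    F1 = 2·TP / (2·TP + FP + FN)   Accuracy = fraction of correct predictions

with Recall/Precision/F1 macro-averaged over classes (classes are balanced
in the study design, so macro ≈ micro).  The evaluation protocol repeats a
random 70/30 instance split ``n_runs`` times (default 100); each run refits
the training-set-dependent preprocessing statistics and the classifier on
the training portion only, then averages the per-run metrics.

A measurement-level decision is obtained a posteriori by majority vote over
the predicted classes of a measurement's constituent scan instances.  The
sensor-ablation study removes one sensor's feature block end to end.  The
one-way ANOVA on per-replicate glucose+fructose sums mirrors the reference
chemical cross-validation of the class separation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import (
    ClassifierSpec,
    ComparatorUnavailableError,
    fit_comparator,
    fit_projection_classifier,
    predict,
)
from .preprocess import FeatureInstance, PreparedDataset, feature_matrix, prepare_dataset
from .syndata import Measurement

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "RunReport",
    "confusion_counts",
    "metrics",
    "train_test_indices",
    "evaluate_split",
    "repeated_evaluation",
    "majority_vote",
    "ablate_sensor",
    "anova_monosaccharides",
]

logger = logging.getLogger("etongue")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion table for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


@dataclass(frozen=True)
class Metrics:
    """Macro-averaged metrics, as percentages, with the per-class breakdown."""

    recall: float
    precision: float
    f1: float
    accuracy: float
    per_class: dict[str, ConfusionCounts] = field(default_factory=dict)


def confusion_counts(
    y_true, y_pred, classes: list[str] | None = None
) -> dict[str, ConfusionCounts]:
    """One-vs-rest TP/FP/FN/TN per class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and equal-length")
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    out = {}
    for cls in classes:
        t = y_true == cls
        p = y_pred == cls
        out[str(cls)] = ConfusionCounts(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
            tn=int(np.sum(~t & ~p)),
        )
    return out


def metrics(y_true, y_pred, classes: list[str] | None = None) -> Metrics:
    """Macro-averaged Recall/Precision/F1 plus fraction-correct Accuracy (%)."""
    counts = confusion_counts(y_true, y_pred, classes)
    y_true = np.asarray(y_true)
    for cls, c in counts.items():
        if c.tp + c.fn == 0:
            logger.warning("class %r absent from y_true; its recall reported as 0", cls)
    n_cls = len(counts)
    return Metrics(
        recall=100.0 * sum(c.recall for c in counts.values()) / n_cls,
        precision=100.0 * sum(c.precision for c in counts.values()) / n_cls,
        f1=100.0 * sum(c.f1 for c in counts.values()) / n_cls,
        accuracy=100.0 * float(np.mean(y_true == np.asarray(y_pred))),
        per_class=counts,
    )


def majority_vote(
    y_pred,
    keys,
    y_true=None,
) -> tuple[dict, float | None]:
    """Measurement-level labels by modal vote over scan-level predictions.

    ``keys[i]`` is the measurement key of prediction ``i`` (for the default
    acquisition design, the (cultivar, electrode slot) pair).  Ties resolve
    to the lowest class index and are logged.  When per-scan true labels are
    supplied, the fraction of correctly labeled measurements is returned as
    a percentage (true labels must be constant within each measurement).
    """
    y_pred = list(y_pred)
    keys = list(keys)
    if not y_pred or len(y_pred) != len(keys):
        raise ValueError("predictions and keys must be non-empty and equal-length")
    groups: dict = {}
    truth: dict = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(y_pred[i])
        if y_true is not None:
            truth.setdefault(key, set()).add(y_true[i])
    labels = {}
    for key, votes in groups.items():
        counts = Counter(votes)
        best = max(counts.values())
        winners = sorted(cls for cls, n in counts.items() if n == best)
        if len(winners) > 1:
            logger.info(
                "majority-vote tie for measurement %s among %s; "
                "resolved to %r (lowest index)", key, winners, winners[0],
            )
        labels[key] = winners[0]
    accuracy = None
    if y_true is not None:
        for key, classes in truth.items():
            if len(classes) > 1:
                raise ValueError(f"measurement {key} has mixed true labels {classes}")
        correct = sum(labels[key] == next(iter(truth[key])) for key in labels)
        accuracy = 100.0 * correct / len(labels)
    return labels, accuracy


@dataclass
class RunReport:
    """Per-run and averaged metrics of a repeated-split evaluation."""

    method: str
    n_runs: int
    test_fraction: float
    base_seed: int
    per_run: pd.DataFrame       # run, recall, precision, f1, accuracy, measurement_accuracy
    n_skipped: int = 0
    split_by: str = "instance"
    sensors: tuple[str, ...] = ()

    def mean(self, metric: str) -> float:
        return float(self.per_run[metric].mean())

    @property
    def summary(self) -> dict[str, float]:
        return {
            m: self.mean(m)
            for m in ("recall", "precision", "f1", "accuracy", "measurement_accuracy")
        }


def train_test_indices(
    prep: PreparedDataset,
    test_fraction: float,
    rng: np.random.Generator,
    split_by: str = "instance",
) -> tuple[np.ndarray, np.ndarray]:
    """One random train/test split of the prepared instances.

    ``split_by="instance"`` splits at the scan-triple level (the study's
    protocol, which can place scans of one electrode in both sets);
    ``split_by="electrode"`` keeps each (cultivar, electrode) group whole.
    """
    n = prep.n_instances
    if split_by == "instance":
        perm = rng.permutation(n)
        n_test = int(round(test_fraction * n))
        if not 0 < n_test < n:
            raise ValueError(f"test_fraction={test_fraction} leaves an empty split")
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    if split_by == "electrode":
        mkeys = prep.measurement_keys()
        unique_keys = sorted(set(mkeys))
        perm = rng.permutation(len(unique_keys))
        n_test = int(round(test_fraction * len(unique_keys)))
        if not 0 < n_test < len(unique_keys):
            raise ValueError("test_fraction leaves an empty electrode split")
        test_keys = {unique_keys[i] for i in perm[:n_test]}
        mask = np.array([key in test_keys for key in mkeys])
        return np.flatnonzero(~mask), np.flatnonzero(mask)
    raise ValueError(f"unknown split granularity {split_by!r}")


def evaluate_split(
    prep: PreparedDataset,
    spec: ClassifierSpec,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    sensors: tuple[str, ...] | None = None,
    seed: int = 0,
):
    """Fit on one training split and score the held-out instances.

    Returns ``(Metrics, measurement_accuracy, model)``; ``model`` is the
    fitted ProjectionModel for projection methods, else the sklearn
    estimator.
    """
    sensors = sensors or prep.sensors
    X, _ = feature_matrix(prep, train_idx, sensors)
    y = prep.labels
    method = spec.method.upper()
    if method in ("LDA_KMEANS", "PCA_KMEANS"):
        hp = spec.hyperparameters
        model = fit_projection_classifier(
            X[train_idx], y[train_idx],
            method=method.split("_")[0],
            c=hp.get("c"),
            n_clusters=hp.get("n_clusters"),
            seed=seed,
            block_lengths={s: prep.blocks[s].shape[1] for s in sensors},
        )
        y_pred = predict(X[test_idx], model)
    else:
        model = fit_comparator(
            X[train_idx], y[train_idx],
            ClassifierSpec(method, dict(spec.hyperparameters), seed),
        )
        y_pred = np.asarray(model.predict(X[test_idx]))
    classes = sorted(np.unique(y).tolist())
    scores = metrics(y[test_idx], y_pred, classes=classes)
    mkeys = prep.measurement_keys()
    _, maj_acc = majority_vote(
        y_pred,
        [mkeys[i] for i in test_idx],
        y_true=y[test_idx],
    )
    return scores, maj_acc, model


def repeated_evaluation(
    data: PreparedDataset | list[Measurement],
    spec: ClassifierSpec,
    n_runs: int = 100,
    test_fraction: float = 0.3,
    base_seed: int = 0,
    k: int = 35,
    sensors: tuple[str, ...] | None = None,
    split_by: str = "instance",
) -> RunReport:
    """Average metrics over ``n_runs`` independent random splits.

    Run ``r`` splits with seed ``base_seed + r``, refits the equalization
    statistics and the classifier on its training portion only, and scores
    the test portion.  Runs whose training split misses a class are skipped
    with a warning and excluded from the averages.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    prep = data if isinstance(data, PreparedDataset) else prepare_dataset(data, k)
    sensors = sensors or prep.sensors
    classes = set(np.unique(prep.labels).tolist())

    rows = []
    n_skipped = 0
    for r in range(n_runs):
        rng = np.random.default_rng(base_seed + r)
        train_idx, test_idx = train_test_indices(prep, test_fraction, rng, split_by)
        if set(prep.labels[train_idx].tolist()) != classes:
            logger.warning("run %d: a class is absent from the training split; skipped", r)
            n_skipped += 1
            continue
        scores, maj_acc, _ = evaluate_split(
            prep, spec, train_idx, test_idx, sensors=sensors, seed=base_seed + r
        )
        rows.append({
            "run": r,
            "recall": scores.recall,
            "precision": scores.precision,
            "f1": scores.f1,
            "accuracy": scores.accuracy,
            "measurement_accuracy": maj_acc,
        })
    if not rows:
        raise RuntimeError("every run was skipped; no class-complete training split")
    return RunReport(
        method=spec.method,
        n_runs=len(rows),
        test_fraction=test_fraction,
        base_seed=base_seed,
        per_run=pd.DataFrame(rows),
        n_skipped=n_skipped,
        split_by=split_by,
        sensors=tuple(sensors),
    )


def ablate_sensor(
    instances: list[FeatureInstance], sensor: str
) -> list[FeatureInstance]:
    """Remove one sensor's feature block from every instance."""
    if not instances:
        raise ValueError("no instances to ablate")
    lengths = instances[0].block_lengths
    if sensor not in lengths:
        raise KeyError(
            f"unknown sensor {sensor!r}; blocks present: {list(lengths)}"
        )
    if len(lengths) == 1:
        raise ValueError("ablating the last remaining sensor block leaves no features")
    out = []
    for inst in instances:
        if inst.block_lengths != lengths:
            raise ValueError("instances have inconsistent block lengths")
        start = 0
        kept_parts = []
        kept_lengths = {}
        for s, length in lengths.items():
            if s != sensor:
                kept_parts.append(inst.features[start:start + length])
                kept_lengths[s] = length
            start += length
        out.append(FeatureInstance(
            features=np.concatenate(kept_parts),
            label=inst.label,
            group_key=inst.group_key,
            block_lengths=kept_lengths,
        ))
    return out


def anova_monosaccharides(groups) -> tuple[float, float]:
    """One-way ANOVA on per-replicate glucose+fructose sums.

    ``groups`` is a mapping name → replicate values or a sequence of arrays
    (>= 2 groups of >= 2 replicates).  Returns ``(F, p)``.  Degenerate
    zero-variance inputs are handled explicitly: identical constants across
    all groups give ``F = 0, p = 1``; distinct constant groups give
    ``F = inf, p = 0``.
    """
    arrays = [np.asarray(v, dtype=float) for v in
              (groups.values() if isinstance(groups, dict) else groups)]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if within == 0.0:
        means = [a.mean() for a in arrays]
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        return float("inf"), 0.0
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)
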