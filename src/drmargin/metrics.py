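"""Embedding-quality and classification metrics.

Two families:

* **alignment / uniformity** — hypersphere diagnostics for contrastive
  representations.  Alignment is the mean squared distance between members
  of positive pairs (lower = semantically matched views embed together);
  uniformity is the log of the mean Gaussian kernel ``exp(-2‖x−y‖²)`` over
  i.i.d. embedding pairs (more negative = better spread over the sphere).
* **classification suite** — accuracy, precision, recall, F1 and AUC,
  expressed in percent, with binary and macro (unweighted one-vs-rest)
  averaging.  AUC uses the rank statistic with midranks for ties, so it is
  invariant under strictly monotone score transforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionTally",
    "ClassificationReport",
    "alignment",
    "uniformity",
    "confusion_tally",
    "precision_recall_f1",
    "accuracy",
    "auc",
    "classification_report",
]


def alignment(first: np.ndarray, second: np.ndarray) -> float:
    """Mean squared Euclidean distance over positive pairs.

    ``first[k]`` and ``second[k]`` are the two unit-norm embeddings of the
    k-th positive pair.
    """
    first = np.atleast_2d(np.asarray(first, dtype=np.float64))
    second = np.atleast_2d(np.asarray(second, dtype=np.float64))
    if first.size == 0:
        raise ValueError("alignment needs at least one pair")
    if first.shape != second.shape:
        raise ValueError("pair members must have matching shapes")
    return float(np.mean(np.sum((first - second) ** 2, axis=1)))


def uniformity(points: np.ndarray, t: float = 2.0) -> float:
    """log E exp(−t‖x−y‖²) over all ordered i.i.d. pairs (self-pairs included).

    With M points the expectation runs over all M² ordered pairs; the
    self-pairs contribute kernel value 1, so the value is ≤ 0 and equals 0
    only for a fully collapsed set.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[0] < 2:
        raise ValueError("uniformity needs at least two points")
    sq = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.log(np.mean(np.exp(-t * sq))))


@dataclass(frozen=True)
class ConfusionTally:
    """One-vs-rest TP/FP/FN/TN counts per class."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_samples: int


def confusion_tally(
    predicted: np.ndarray, truth: np.ndarray, n_classes: int
) -> ConfusionTally:
    """Count one-vs-rest outcomes for each class."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if predicted.size == 0:
        raise ValueError("no samples to tally")
    for name, arr in (("predicted", predicted), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels out of range [0, {n_classes})")
    tp = np.array([np.sum((predicted == c) & (truth == c)) for c in range(n_classes)])
    fp = np.array([np.sum((predicted == c) & (truth != c)) for c in range(n_classes)])
    fn = np.array([np.sum((predicted != c) & (truth == c)) for c in range(n_classes)])
    tn = len(truth) - tp - fp - fn
    return ConfusionTally(tp, fp, fn, tn, len(truth))


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    bad = den == 0
    if np.any(bad):
        warnings.warn(f"{what}: zero denominator for class(es) "
                      f"{np.flatnonzero(bad).tolist()}; reporting 0", stacklevel=3)
    np.divide(num, den, out=out, where=~bad)
    return out


def precision_recall_f1(tally: ConfusionTally, mode: str = "binary") -> tuple[float, float, float]:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = their harmonic mean.

    Binary mode evaluates the positive class (index 1); macro mode averages
    the per-class one-vs-rest values without weighting.  All in percent.
    Classes with a zero denominator contribute 0.
    """
    if tally.n_samples == 0:
        raise ValueError("empty tally")
    prec = _safe_div(tally.tp, tally.tp + tally.fp, "precision")
    rec = _safe_div(tally.tp, tally.tp + tally.fn, "recall")
    f1 = _safe_div(2 * prec * rec, prec + rec, "f1")
    if mode == "binary":
        if len(tally.tp) != 2:
            raise ValueError("binary mode requires a two-class tally")
        return 100 * float(prec[1]), 100 * float(rec[1]), 100 * float(f1[1])
    if mode == "macro":
        return 100 * float(prec.mean()), 100 * float(rec.mean()), 100 * float(f1.mean())
    raise ValueError(f"unknown averaging mode {mode!r}")


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of samples predicted correctly."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("length mismatch between predictions and truth")
    if predicted.size == 0:
        raise ValueError("no samples")
    return 100.0 * float(np.mean(predicted == truth))


def auc(scores: np.ndarray, truth: np.ndarray, mode: str = "binary") -> float:
    """Area under the ROC curve, in percent.

    Binary mode takes one positive-class score per sample.  Macro mode takes
    a (n, K) score matrix and averages one-vs-rest AUCs over the classes
    present in the truth; absent classes are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=int)
    if mode == "binary":
        if scores.ndim != 1 or scores.shape != truth.shape:
            raise ValueError("binary AUC needs one score per sample")
        if len(np.unique(truth)) < 2:
            raise ValueError("binary AUC undefined with a single class in truth")
        return 100.0 * float(roc_auc_score(truth, scores))
    if mode != "macro_ovr":
        raise ValueError(f"unknown AUC mode {mode!r}")
    if scores.ndim != 2 or scores.shape[0] != len(truth):
        raise ValueError("macro AUC needs a (n_samples, n_classes) score matrix")
    vals = []
    for c in range(scores.shape[1]):
        mask = truth == c
        if not mask.any() or mask.all():
            warnings.warn(f"class {c} absent from truth (or the only class); "
                          "skipped in macro AUC", stacklevel=2)
            continue
        vals.append(roc_auc_score(mask.astype(int), scores[:, c]))
    if not vals:
        raise ValueError("no class with both positives and negatives")
    return 100.0 * float(np.mean(vals))


@dataclass(frozen=True)
class ClassificationReport:
    """Accuracy / precision / recall / F1 / AUC bundle, all in percent."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    mode: str  # "binary" | "macro"
    per_class: dict | None = None

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc + "\n")
        return doc


def classification_report(
    scores: np.ndarray,
    predicted: np.ndarray,
    truth: np.ndarray,
    task: str = "multiclass",
) -> ClassificationReport:
    """Bundle the five metrics for a binary or multiclass task."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    if task == "binary":
        n_classes, mode, auc_mode = 2, "binary", "binary"
        auc_scores = scores if scores.ndim == 1 else scores[:, 1]
    elif task == "multiclass":
        n_classes = scores.shape[1] if scores.ndim == 2 else int(truth.max()) + 1
        mode, auc_mode = "macro", "macro_ovr"
        auc_scores = scores
    else:
        raise ValueError(f"unknown task {task!r}")
    tally = confusion_tally(predicted, truth, n_classes)
    prec, rec, f1 = precision_recall_f1(tally, mode)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec_c = _safe_div(tally.tp, tally.tp + tally.fp, "precision")
        rec_c = _safe_div(tally.tp, tally.tp + tally.fn, "recall")
        f1_c = _safe_div(2 * prec_c * rec_c, prec_c + rec_c, "f1")
    try:
        auc_val = auc(auc_scores, truth, auc_mode)
    except ValueError:
        warnings.warn("AUC undefined on this row set; reporting 0", stacklevel=2)
        auc_val = 0.0
    per_class = {
        str(c): {
            "tp": int(tally.tp[c]), "fp": int(tally.fp[c]),
            "fn": int(tally.fn[c]), "tn": int(tally.tn[c]),
            "precision": 100 * float(prec_c[c]),
            "recall": 100 * float(rec_c[c]),
            "f1": 100 * float(f1_c[c]),
        }
        for c in range(n_classes)
    }
    return ClassificationReport(
        accuracy=accuracy(predicted, truth),
        precision=prec, recall=rec, f1=f1, auc=auc_val,
        mode=mode, per_class=per_class,
    )
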