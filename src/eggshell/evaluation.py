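"""Confusion-matrix metrics, noise robustness, and throughput timing.

Metrics follow the usual multi-class conventions: accuracy is the trace of
the confusion matrix over its total; per-class precision divides the
diagonal by the predicted-class total and recall by the actual-class total;
F1 is their harmonic mean; Cohen's kappa corrects accuracy for the chance
agreement Pe implied by the marginals.  Macro averages run over the classes
for which the quantity is defined (a class never predicted has undefined
precision and is excluded from the macro mean).

Noise sensitivity perturbs the test inputs only — the model stays fixed —
with independent Gaussian noise scaled to a fraction of each feature's
test-set SD, and reports the mean error rate over repetitions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Dataset, ValidationError


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are actual classes, columns predicted."""

    labels: np.ndarray
    counts: np.ndarray  # g x g

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion(actual, predicted) -> ConfusionMatrix:
    """Count matrix over the sorted union of observed labels."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape or actual.ndim != 1 or len(actual) == 0:
        raise ValidationError("actual/predicted must be equal-length vectors")
    labels = np.unique(np.concatenate([actual, predicted]))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


@dataclass
class MetricsReport:
    n: int
    accuracy: float
    per_class_precision: pd.Series
    per_class_recall: pd.Series
    per_class_f1: pd.Series
    macro_precision: float
    macro_recall: float
    macro_f1: float
    pe: float
    kappa: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "pe": self.pe,
            "kappa": self.kappa,
        }


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class and macro P/R/F1, chance agreement and kappa."""
    total = cm.total
    if total == 0:
        raise ValidationError("empty confusion matrix")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    actual_tot = counts.sum(axis=1)
    pred_tot = counts.sum(axis=0)
    accuracy = float(diag.sum() / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, diag / pred_tot, np.nan)
        recall = np.where(actual_tot > 0, diag / actual_tot, np.nan)
        pr_sum = precision + recall
        f1 = np.where(pr_sum > 0, 2 * precision * recall / pr_sum, 0.0)
        f1 = np.where(np.isnan(precision) | np.isnan(recall), np.nan, f1)
    pe = float((actual_tot * pred_tot).sum() / total**2)
    kappa = float((accuracy - pe) / (1.0 - pe)) if pe < 1.0 else 1.0
    return MetricsReport(
        n=total,
        accuracy=accuracy,
        per_class_precision=pd.Series(precision, index=cm.labels),
        per_class_recall=pd.Series(recall, index=cm.labels),
        per_class_f1=pd.Series(f1, index=cm.labels),
        macro_precision=float(np.nanmean(precision)),
        macro_recall=float(np.nanmean(recall)),
        macro_f1=float(np.nanmean(f1)),
        pe=pe,
        kappa=kappa,
    )


def evaluate_predictions(actual, predicted) -> MetricsReport:
    """Convenience wrapper: confusion + metrics in one call."""
    return metrics(confusion(actual, predicted))


# ---------------------------------------------------------------------------
# Noise sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    fraction: float = 0.10  # of each feature's SD
    repetitions: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.fraction < 0:
            raise ValidationError("noise fraction must be >= 0")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")


def noise_sensitivity(model, test: Dataset, spec: NoiseSpec) -> float:
    """Mean prediction error rate under repeated feature perturbation.

    model must expose ``predict(X) -> labels``.  Noise per repetition is
    N(0, (fraction * SD_feature)^2), independent per feature, added to the
    test colors; the SD is the test set's own per-feature sample SD
    (a zero-variance feature simply receives no noise).  At fraction 0 the
    result equals 1 - clean test accuracy exactly.
    """
    if len(test) == 0:
        raise ValidationError("empty test set")
    X = test.colors
    y = test.aveobs.astype(str)
    sds = X.std(axis=0, ddof=1) if len(test) > 1 else np.zeros(X.shape[1])
    scale = spec.fraction * sds
    rng = np.random.default_rng(spec.seed)
    errors = []
    for _ in range(spec.repetitions):
        noisy = X + rng.standard_normal(X.shape) * scale[None, :]
        pred = np.asarray(model.predict(noisy)).astype(str)
        # 1 - accuracy (not mean of !=) so the fraction-0 identity is exact
        errors.append(1.0 - float(np.mean(pred == y)))
    return float(np.mean(errors))


# ---------------------------------------------------------------------------
# Throughput
# ---------------------------------------------------------------------------


def throughput(model, ds: Dataset, mode: str = "predict", seed: int = 0) -> float:
    """Samples per second for training or prediction (wall clock).

    Hardware-dependent by nature: reported for comparison between
    algorithms on the same machine, never asserted against published
    figures.
    """
    if len(ds) == 0:
        raise ValidationError("empty dataset")
    X = ds.colors
    y = ds.aveobs.astype(str)
    t0 = time.perf_counter()
    if mode == "train":
        from .classification import fit_comparator

        fit_comparator(model.spec, ds, seed=seed)
    elif mode == "predict":
        model.predict(X)
    else:
        raise ValidationError("mode must be 'train' or 'predict'")
    elapsed = time.perf_counter() - t0
    return len(ds) / max(elapsed, 1e-9)
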