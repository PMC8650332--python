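"""Evaluation: nested leave-one-subject-out CV, metrics, McNemar comparison.

Metrics follow the standard confusion-matrix definitions with pre-FOG as the
positive class; the overall figure reported for a cross-validation run is the
macro (per-subject) mean accuracy with its sample standard deviation. The
nested cross-validation holds out one subject per outer fold and tunes
hyperparameters by an inner leave-one-subject-out loop over the remaining
subjects, so no information from a held-out subject reaches model selection
or training (preprocessing is strictly per-cycle, so no statistics leak
either).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .model import (
    GaitCycleCNN,
    Hyperparameters,
    LinearSVMBaseline,
    tune_hyperparameters,
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Cycle-level confusion counts; positive class = pre-FOG."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(truth, predictions) -> ConfusionCounts:
    """Count TP/FP/TN/FN from 0/1 labels (1 = pre-FOG)."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(predictions, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    return ConfusionCounts(
        tp=int(((truth == 1) & (pred == 1)).sum()),
        fp=int(((truth == 0) & (pred == 1)).sum()),
        tn=int(((truth == 0) & (pred == 0)).sum()),
        fn=int(((truth == 1) & (pred == 0)).sum()),
    )


def _ratio_pct(num: int, den: int):
    """Percentage ratio, or None when the denominator is zero (undefined)."""
    if den == 0:
        return None
    return 100.0 * num / den


@dataclass
class MetricsReport:
    """Percent metrics (raw values; ``rounded()`` gives 1-decimal reporting).

    Undefined ratios (zero denominators) are None, never silently zero.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    counts: ConfusionCounts | None = None
    per_subject: dict = field(default_factory=dict)

    def rounded(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, 1)
        return out


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV and NPV from confusion counts."""
    if c.total == 0:
        raise ValueError("no evaluated cycles")
    return MetricsReport(
        accuracy=_ratio_pct(c.tp + c.tn, c.total),
        sensitivity=_ratio_pct(c.tp, c.tp + c.fn),
        specificity=_ratio_pct(c.tn, c.tn + c.fp),
        ppv=_ratio_pct(c.tp, c.tp + c.fp),
        npv=_ratio_pct(c.tn, c.tn + c.fn),
        counts=c,
    )


def macro_summary(per_subject_accuracies):
    """Unweighted mean and sample SD (n-1) of per-subject accuracies."""
    acc = np.asarray(list(per_subject_accuracies), dtype=float)
    if acc.size == 0:
        raise ValueError("no per-subject accuracies")
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1)) if acc.size >= 2 else float("nan")
    return mean, sd


@dataclass
class CVResult:
    """Out-of-fold predictions and per-fold selections of a nested LOSO run."""

    predictions: pd.DataFrame  # cycle-level: subject, truth, pred, p_prefog
    fold_hyperparameters: dict  # held-out subject -> Hyperparameters
    per_subject_accuracy: dict

    def macro_accuracy(self):
        return macro_summary(self.per_subject_accuracy.values())

    def overall_metrics(self) -> MetricsReport:
        c = confusion_counts(self.predictions["truth"], self.predictions["pred"])
        report = classification_metrics(c)
        report.per_subject = dict(self.per_subject_accuracy)
        return report

    def summary(self) -> str:
        mean, sd = self.macro_accuracy()
        lines = ["Nested leave-one-subject-out cross-validation", "=" * 50]
        for s, a in self.per_subject_accuracy.items():
            lines.append(f"  {s:12s}{a:6.1f}")
        lines.append("-" * 50)
        lines.append(f"  Mean accuracy ± SD: {mean:.1f} ± {sd:.1f}")
        return "\n".join(lines)

    def per_subject_table(self) -> pd.DataFrame:
        rows = []
        for s, a in self.per_subject_accuracy.items():
            mine = self.predictions[self.predictions["subject"] == s]
            rows.append({
                "subject": s,
                "n_prefog": int((mine["truth"] == 1).sum()),
                "n_fgc": int((mine["truth"] == 0).sum()),
                "accuracy": round(a, 1),
            })
        return pd.DataFrame(rows)


def nested_loso_cv(X, y, subjects, space=None, budget: int = 4, seed: int = 0,
                   base: Hyperparameters | None = None,
                   estimator: str = "cnn") -> CVResult:
    """Nested leave-one-subject-out cross-validation.

    Outer loop: hold out each subject in turn. Inner loop: tune
    hyperparameters by leave-one-subject-out over the remaining subjects
    (CNN only; the SVM baseline has its fixed C), retrain on all inner
    subjects, predict the held-out subject. Every cycle is predicted exactly
    once, by a model that never saw its subject.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    subjects = np.asarray(subjects, dtype=object)
    unique_subjects = list(pd.unique(subjects))
    if len(unique_subjects) < 3:
        raise ValueError("nested LOSO CV needs at least 3 subjects")

    rows = []
    fold_h: dict = {}
    per_subject: dict = {}
    for fold_idx, held in enumerate(unique_subjects):
        test = subjects == held
        if test.sum() == 0:
            warnings.warn(f"subject {held} has zero cycles; skipped", stacklevel=2)
            continue
        train = ~test
        if len(np.unique(y[train])) < 2:
            warnings.warn(
                f"fold {held}: training folds lack a class; skipped", stacklevel=2
            )
            continue
        if estimator == "cnn":
            h = tune_hyperparameters(
                X[train], y[train], subjects[train], space=space, budget=budget,
                seed=int(seed) * 1000 + fold_idx, base=base,
            )
            res = GaitCycleCNN(X[train], y[train], hyperparameters=h).fit()
            proba, pred = res.predict(X[test])
            p_prefog = proba[:, 1]
            fold_h[held] = h
        elif estimator == "svm":
            res = LinearSVMBaseline(X[train], y[train], seed=int(seed)).fit()
            pred = res.predict(X[test])
            p_prefog = np.full(int(test.sum()), np.nan)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        acc = 100.0 * float((pred == y[test]).mean())
        per_subject[held] = acc
        rows.append(pd.DataFrame({
            "subject": held,
            "index": np.flatnonzero(test),
            "truth": y[test],
            "pred": pred,
            "p_prefog": p_prefog,
        }))
    predictions = pd.concat(rows, ignore_index=True)
    return CVResult(predictions=predictions, fold_hyperparameters=fold_h,
                    per_subject_accuracy=per_subject)


def mcnemar_test(pred_a, pred_b, truth):
    """Paired comparison of two classifiers via McNemar's test.

    Builds the 2x2 correct/incorrect contingency table; uses the exact
    binomial test when the discordant count b + c < 25 and the
    continuity-corrected chi-square otherwise. Returns a dict with the
    discordant counts, the statistic and the two-sided p-value.
    """
    pred_a = np.asarray(pred_a, dtype=int)
    pred_b = np.asarray(pred_b, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("prediction and truth vectors must be aligned")
    a_ok = pred_a == truth
    b_ok = pred_b == truth
    b = int((a_ok & ~b_ok).sum())  # A correct, B wrong
    c = int((~a_ok & b_ok).sum())  # A wrong, B correct
    both = int((a_ok & b_ok).sum())
    neither = int((~a_ok & ~b_ok).sum())
    if b + c == 0:
        return {"b": b, "c": c, "statistic": 0.0, "p_value": 1.0, "exact": True}
    exact = (b + c) < 25
    table = [[both, b], [c, neither]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return {
        "b": b,
        "c": c,
        "statistic": float(res.statistic),
        "p_value": float(min(1.0, res.pvalue)),
        "exact": exact,
    }


def cross_cohort_evaluate(results, cycles_or_X, subjects=None) -> MetricsReport:
    """Evaluate a trained model on an all-functional-gait cohort.

    The cohort must contain only FGC cycles; accuracy is the fraction
    predicted FGC. With ``subjects`` given, a per-subject accuracy breakdown
    is attached.
    """
    from .preprocessing import GaitCycle, dataset_arrays

    if hasattr(cycles_or_X, "__len__") and len(cycles_or_X) and isinstance(
        cycles_or_X[0], GaitCycle
    ):
        cycles = list(cycles_or_X)
        if any(c.label != "FGC" for c in cycles):
            raise ValueError("cross-cohort evaluation expects only FGC cycles")
        X, y, subjects = dataset_arrays(cycles)
    else:
        X = np.asarray(cycles_or_X, dtype=float)
        y = np.zeros(X.shape[0], dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty cohort")
    pred = results.predict(X)
    if isinstance(pred, tuple):
        pred = pred[1]
    pred = np.asarray(pred, dtype=int)
    c = confusion_counts(y, pred)
    report = classification_metrics(c)
    if subjects is not None:
        subjects = np.asarray(subjects, dtype=object)
        report.per_subject = {
            s: 100.0 * float((pred[subjects == s] == 0).mean())
            for s in pd.unique(subjects)
        }
    return report
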