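"""Diagnostic metrics, operating points, bootstrap CIs, stratified splits
and model-agreement statistics.

AUROC/AUPR delegate to scikit-learn (trapezoidal ROC integration, equal to
the Mann-Whitney pair statistic with ties counted one half).  The operating
point follows the screening convention: the largest probability cutoff whose
validation sensitivity still meets the target (0.85 for reporting, 0.95 for
workflow analysis).  Confidence intervals are 2.5/97.5 percentiles over
1000 joint resamples of the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auroc(scores, labels) -> float:
    """Area under the ROC curve (ties counted 1/2)."""
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (average precision)."""
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def confusion_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Accuracy, sensitivity and specificity at a probability threshold.

    A sample is called positive iff ``score >= threshold`` (boundary
    inclusive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    return {
        "accuracy": (tp + tn) / len(labels) if len(labels) else np.nan,
        "sensitivity": tp / n_pos if n_pos else np.nan,
        "specificity": tn / n_neg if n_neg else np.nan,
    }


@dataclass
class OperatingPoint:
    threshold: float
    target_sensitivity: float
    achieved_sensitivity: float


def choose_threshold(val_scores, val_labels,
                     target_sensitivity: float = 0.85) -> OperatingPoint:
    """Largest threshold whose validation sensitivity meets the target.

    Candidates are the observed score values; if no candidate reaches the
    target the minimum observed score is returned (sensitivity 1 there since
    calls are boundary-inclusive).
    """
    scores = np.asarray(val_scores, dtype=float)
    labels = np.asarray(val_labels).astype(int)
    if not (labels == 1).any():
        raise ValueError("validation set has no positives")
    best = None
    for cand in np.unique(scores)[::-1]:  # descending
        sens = confusion_metrics(scores, labels, cand)["sensitivity"]
        if sens >= target_sensitivity:
            best = (float(cand), float(sens))
            break
    if best is None:
        cand = float(scores.min())
        best = (cand, confusion_metrics(scores, labels, cand)["sensitivity"])
    return OperatingPoint(threshold=best[0],
                          target_sensitivity=target_sensitivity,
                          achieved_sensitivity=best[1])


def bootstrap_ci(metric_fn: Callable, scores, labels, n_boot: int = 1000,
                 seed: int = 0, rng: Optional[np.random.Generator] = None
                 ) -> tuple[float, float]:
    """2.5/97.5 percentile bootstrap of ``metric_fn(scores, labels)``.

    Samples are resampled jointly with replacement to the original size.
    Resamples where the metric is undefined (e.g. a single-class draw for
    AUROC) are skipped with a counted warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    if rng is None:
        rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric_fn(scores[idx], labels[idx]))
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped}/{n_boot} degenerate resamples",
                      stacklevel=2)
    if not values:
        raise ValueError("all bootstrap resamples were degenerate")
    lo, hi = np.percentile(values, (2.5, 97.5))
    return float(lo), float(hi)


@dataclass
class MetricSet:
    """Point estimates with bootstrap CIs at a fixed operating point."""

    auroc: float
    aupr: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def metric_set(scores, labels, threshold: float = 0.5, n_boot: int = 1000,
               seed: int = 0) -> MetricSet:
    """All reported metrics at ``threshold`` with percentile-bootstrap CIs."""
    point = confusion_metrics(scores, labels, threshold)
    result = MetricSet(
        auroc=auroc(scores, labels), aupr=aupr(scores, labels),
        accuracy=point["accuracy"], sensitivity=point["sensitivity"],
        specificity=point["specificity"], threshold=threshold)
    rng = np.random.default_rng(seed)
    fns = {
        "auroc": auroc,
        "aupr": aupr,
        "accuracy": lambda s, l: confusion_metrics(s, l, threshold)["accuracy"],
        "sensitivity": lambda s, l: _defined(
            confusion_metrics(s, l, threshold)["sensitivity"]),
        "specificity": lambda s, l: _defined(
            confusion_metrics(s, l, threshold)["specificity"]),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, fn in fns.items():
            result.ci[name] = bootstrap_ci(fn, scores, labels, n_boot, rng=rng)
    return result


def _defined(value: float) -> float:
    if np.isnan(value):
        raise ValueError("metric undefined on this resample")
    return value


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def stratified_splits(labels: pd.DataFrame, n_folds: int = 4,
                      test_fraction: float = 0.2, seed: int = 0,
                      strata: Sequence[str] = ("label", "pathway"),
                      id_column: str = "slide_id") -> pd.DataFrame:
    """Assign each slide to the test set or to one of ``n_folds`` dev folds.

    The test set is drawn first within each stratum (largest-remainder
    rounding keeps per-stratum proportions within one sample), then the
    remaining slides are dealt round-robin into folds per stratum.  With the
    defaults this yields the 60:20:20 train/validation/test split of
    four-fold cross-validation on an 80:20 split.

    Returns a frame with columns (id, split, fold): split is "test" or
    "dev"; fold is the validation-fold index for dev rows, -1 for test.
    """
    df = labels.drop_duplicates(subset=id_column)
    cols = [c for c in strata if c in df.columns]
    rng = np.random.default_rng(seed)
    rows = []
    groups = df.groupby(cols, sort=True) if cols else [((), df)]
    for _, group in groups:
        ids = group[id_column].to_numpy()
        rng.shuffle(ids)
        n_test = int(round(len(ids) * test_fraction))
        for sid in ids[:n_test]:
            rows.append({id_column: sid, "split": "test", "fold": -1})
        # random starting fold per stratum so remainders do not all pile
        # onto fold 0 across strata
        start = int(rng.integers(0, n_folds))
        for j, sid in enumerate(ids[n_test:]):
            rows.append({id_column: sid, "split": "dev",
                         "fold": int((start + j) % n_folds)})
    return pd.DataFrame(rows, columns=[id_column, "split", "fold"])


# ---------------------------------------------------------------------------
# agreement and cohort summaries
# ---------------------------------------------------------------------------

def jaccard_agreement(false_set_a, false_set_b) -> float:
    """Jaccard index of two models' false-prediction sets (1.0 if both empty)."""
    a, b = set(false_set_a), set(false_set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def cohort_summary(datasets: dict[str, pd.DataFrame] | pd.DataFrame,
                   label_column: str = "label") -> pd.DataFrame:
    """Per-dataset counts and positive percentages, with an overall row.

    Percentages are reported to one decimal place.
    """
    if isinstance(datasets, pd.DataFrame):
        datasets = {"dataset": datasets}
    rows = []
    total_n = total_pos = 0
    for name, df in datasets.items():
        n = len(df)
        n_pos = int(df[label_column].sum()) if n else 0
        rows.append({"dataset": name, "n": n, "n_pos": n_pos,
                     "n_neg": n - n_pos,
                     "pct_pos": round(100.0 * n_pos / n, 1) if n else np.nan})
        total_n += n
        total_pos += n_pos
    if rows:
        rows.append({"dataset": "total", "n": total_n, "n_pos": total_pos,
                     "n_neg": total_n - total_pos,
                     "pct_pos": round(100.0 * total_pos / total_n, 1)
                     if total_n else np.nan})
    return pd.DataFrame(rows, columns=["dataset", "n", "n_pos", "n_neg",
                                       "pct_pos"])
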