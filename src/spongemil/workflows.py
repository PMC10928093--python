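"""Semi-automated screening workflows over (H&E model, TFF3 model,
pathologist) decision tables.

Fourteen Boolean workflows combine the two model calls with manual
pathologist review.  Evaluation uses short-circuit semantics with the H&E
model evaluated first: the pathologist is only invoked when the Boolean
expression still needs their call, and TFF3 staining is only required when
either the TFF3 model's call or a pathologist review (which reads the TFF3
slide) is needed.  Samples are importance-reweighted so the effective
positive prevalence matches a screening population (8% by default), and all
reported fractions carry percentile-bootstrap confidence intervals.

Ground truth equals the pathologist's diagnosis, so every workflow whose
automatic negatives are model-negative has specificity 1 by construction:
the pathologist overturns all model false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

TARGET_PREVALENCE = 0.08


@dataclass(frozen=True)
class WorkflowSpec:
    """Boolean rules of one workflow.

    Each rule maps vectors (he, tff3, path) of binary calls to a binary
    vector: ``final`` is the workflow's diagnosis, ``review`` whether the
    pathologist is invoked, ``tff3`` whether TFF3 staining is required.
    ``review`` and ``tff3`` depend only on the model calls (short-circuit
    order decides them before the pathologist acts).
    """

    name: str
    final: Callable
    review: Callable
    tff3: Callable


def _ones(he):
    return np.ones_like(he)


def _zeros(he):
    return np.zeros_like(he)


WORKFLOWS: dict[str, WorkflowSpec] = {}


def _register(name, final, review, tff3):
    WORKFLOWS[name] = WorkflowSpec(name=name, final=final, review=review,
                                   tff3=tff3)


# status quo: pathologist reviews and stains everything
_register("Pathologist",
          final=lambda he, tf, pa: pa,
          review=lambda he, tf: _ones(he),
          tff3=lambda he, tf: _ones(he))
_register("H&E only",
          final=lambda he, tf, pa: he,
          review=lambda he, tf: _zeros(he),
          tff3=lambda he, tf: _zeros(he))
_register("TFF3 only",
          final=lambda he, tf, pa: tf,
          review=lambda he, tf: _zeros(he),
          tff3=lambda he, tf: _ones(he))
_register("H&E and TFF3",
          final=lambda he, tf, pa: he & tf,
          review=lambda he, tf: _zeros(he),
          tff3=lambda he, tf: he)
_register("H&E or TFF3",
          final=lambda he, tf, pa: he | tf,
          review=lambda he, tf: _zeros(he),
          tff3=lambda he, tf: 1 - he)
_register("H&E and Pathologist",  # "Pathologist reviews H&E model positives"
          final=lambda he, tf, pa: he & pa,
          review=lambda he, tf: he,
          tff3=lambda he, tf: he)
_register("H&E or Pathologist",
          final=lambda he, tf, pa: he | pa,
          review=lambda he, tf: 1 - he,
          tff3=lambda he, tf: 1 - he)
_register("TFF3 and Pathologist",
          final=lambda he, tf, pa: tf & pa,
          review=lambda he, tf: tf,
          tff3=lambda he, tf: _ones(he))
_register("TFF3 or Pathologist",
          final=lambda he, tf, pa: tf | pa,
          review=lambda he, tf: 1 - tf,
          tff3=lambda he, tf: _ones(he))
_register("H&E and (TFF3 or Pathologist)",
          final=lambda he, tf, pa: he & (tf | pa),
          review=lambda he, tf: he & (1 - tf),
          tff3=lambda he, tf: he)
_register("H&E and TFF3 and Pathologist",
          final=lambda he, tf, pa: he & tf & pa,
          review=lambda he, tf: he & tf,
          tff3=lambda he, tf: he)
_register("(H&E or TFF3) and Pathologist",  # "Pathologist reviews any positives"
          final=lambda he, tf, pa: (he | tf) & pa,
          review=lambda he, tf: he | tf,
          tff3=lambda he, tf: _ones(he))
_register("(H&E and TFF3) or Pathologist",
          final=lambda he, tf, pa: (he & tf) | pa,
          review=lambda he, tf: 1 - (he & tf),
          tff3=lambda he, tf: _ones(he))
_register("Consensus or Pathologist",
          final=lambda he, tf, pa: np.where(he == tf, he, pa),
          review=lambda he, tf: (he != tf).astype(int),
          tff3=lambda he, tf: _ones(he))

WORKFLOW_NAMES = list(WORKFLOWS.keys())


# ---------------------------------------------------------------------------
# re-weighting
# ---------------------------------------------------------------------------

def reweight(decisions: pd.DataFrame,
             target_prevalence: float = TARGET_PREVALENCE) -> pd.DataFrame:
    """Importance weights that shift the effective prevalence to the target.

    Positives get pi_t / pi_s and negatives (1 - pi_t) / (1 - pi_s), where
    pi_s is the sample prevalence; the weighted prevalence then equals the
    target exactly, and per-class metrics (sensitivity, specificity) are
    unchanged because weights are constant within class.
    """
    labels = decisions["label"].to_numpy().astype(int)
    pi_s = labels.mean()
    if pi_s in (0.0, 1.0):
        raise ValueError("both classes must be present for re-weighting")
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")
    out = decisions.copy()
    out["weight"] = np.where(labels == 1, target_prevalence / pi_s,
                             (1.0 - target_prevalence) / (1.0 - pi_s))
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class WorkflowMetrics:
    name: str
    sensitivity: float
    specificity: float
    review_fraction: float
    tff3_fraction: float
    observed_prevalence: float
    workload_reduction: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _weighted_metrics(he, tff3, path, label, weight,
                      spec: WorkflowSpec) -> dict[str, float]:
    final = np.asarray(spec.final(he, tff3, path)).astype(int)
    review = np.asarray(spec.review(he, tff3)).astype(int)
    stain = np.asarray(spec.tff3(he, tff3)).astype(int)
    w = weight
    w_pos = (w * (label == 1)).sum()
    w_neg = (w * (label == 0)).sum()
    w_total = w.sum()
    w_review = (w * review).sum()
    return {
        "sensitivity": ((w * final * (label == 1)).sum() / w_pos
                        if w_pos > 0 else np.nan),
        "specificity": ((w * (1 - final) * (label == 0)).sum() / w_neg
                        if w_neg > 0 else np.nan),
        "review_fraction": w_review / w_total,
        "tff3_fraction": (w * stain).sum() / w_total,
        "observed_prevalence": ((w * review * (label == 1)).sum() / w_review
                                if w_review > 0 else np.nan),
    }


def workload_reduction(review_fraction: float) -> float:
    """Reciprocal of the manual-review fraction, reported to one decimal."""
    if not 0.0 < review_fraction <= 1.0:
        raise ValueError("review fraction must lie in (0, 1]")
    return round(1.0 / review_fraction, 1)


def evaluate_workflow(spec: WorkflowSpec | str, decisions: pd.DataFrame,
                      n_boot: int = 1000, seed: int = 0) -> WorkflowMetrics:
    """Weighted workflow metrics with percentile-bootstrap CIs.

    ``decisions`` must carry columns (label, he_pred, tff3_pred, path_pred)
    and a ``weight`` column (see :func:`reweight`); rows are resampled
    jointly for the CIs.
    """
    if isinstance(spec, str):
        if spec not in WORKFLOWS:
            raise ValueError(f"unknown workflow {spec!r}; known workflows: "
                             f"{WORKFLOW_NAMES}")
        spec = WORKFLOWS[spec]
    if "weight" not in decisions.columns:
        raise ValueError("decisions need a 'weight' column; call reweight()")
    cols = ["he_pred", "tff3_pred", "path_pred", "label", "weight"]
    he, tff3, path, label, weight = (decisions[c].to_numpy() for c in cols)
    he, tff3, path, label = (v.astype(int) for v in (he, tff3, path, label))
    weight = weight.astype(float)
    if np.any(weight <= 0):
        raise ValueError("weights must be positive")

    point = _weighted_metrics(he, tff3, path, label, weight, spec)
    rf = point["review_fraction"]
    metrics = WorkflowMetrics(
        name=spec.name,
        workload_reduction=(1.0 / rf if rf > 0 else np.inf),
        **point)

    rng = np.random.default_rng(seed)
    n = len(decisions)
    samples: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = _weighted_metrics(he[idx], tff3[idx], path[idx], label[idx],
                                 weight[idx], spec)
        for k, v in boot.items():
            if not np.isnan(v):
                samples[k].append(v)
    for k, vals in samples.items():
        if vals:
            lo, hi = np.percentile(vals, (2.5, 97.5))
            metrics.ci[k] = (float(lo), float(hi))
    return metrics


def run_all(decisions: pd.DataFrame,
            target_prevalence: float = TARGET_PREVALENCE,
            n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Evaluate all 14 workflows; one row each, sorted by review fraction."""
    weighted = reweight(decisions, target_prevalence)
    rows = []
    for name in WORKFLOW_NAMES:
        m = evaluate_workflow(name, weighted, n_boot=n_boot, seed=seed)
        row = {
            "workflow": name,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "review_fraction": m.review_fraction,
            "tff3_fraction": m.tff3_fraction,
            "observed_prevalence": m.observed_prevalence,
            "workload_reduction": (round(m.workload_reduction, 1)
                                   if np.isfinite(m.workload_reduction)
                                   else np.inf),
        }
        for key, (lo, hi) in m.ci.items():
            row[f"{key}_lo"] = lo
            row[f"{key}_hi"] = hi
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values("review_fraction", kind="stable").reset_index(
        drop=True)
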