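"""MaxAF positivity scoring and diagnostic accuracy statistics.

A sample's MaxAF is the maximum mutant allele fraction over its filtered
SNV/Indel calls (fusions, copy-number events and large genomic
rearrangements are excluded), expressed as percent. A sample is cfDNA
positive when MaxAF strictly exceeds the positivity cutoff; the cutoff is
selected on a training cohort as the ROC operating point maximizing
Youden's J = sensitivity + specificity - 1.

AUC is computed by the trapezoidal rule over the empirical curve, which
for this construction equals the tie-corrected probability that a random
PM sample scores above a random non-PM sample.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .models import (MAXAF_ELIGIBLE_CLASSES, ContingencyTable, MaxAfResult,
                     RocCurve, RocPoint, VariantCall)
from .study import POSITIVITY_THRESHOLD_PCT
from .utils import percent


def compute_maxaf(variants: Sequence[VariantCall],
                  sample_id: str | None = None,
                  threshold_pct: float = POSITIVITY_THRESHOLD_PCT,
                  ) -> MaxAfResult:
    """MaxAF (percent) of one sample's filtered variants.

    ``variants`` must all belong to one sample; pass ``sample_id``
    explicitly when the list may be empty. MaxAF is 0 when no SNV/Indel
    variant remains.
    """
    ids = {v.sample_id for v in variants}
    if len(ids) > 1:
        raise ValidationError(
            f"variants: mixed sample_ids {sorted(ids)}; one sample at a time")
    if sample_id is None:
        if not ids:
            raise ValidationError(
                "sample_id: required when the variant list is empty")
        sample_id = next(iter(ids))
    eligible = [v.allele_fraction for v in variants
                if v.variant_class in MAXAF_ELIGIBLE_CLASSES]
    maxaf_pct = 100.0 * max(eligible) if eligible else 0.0
    return MaxAfResult(
        sample_id=sample_id,
        maxaf_pct=maxaf_pct,
        n_eligible_variants=len(eligible),
        positive=classify_positivity(maxaf_pct, threshold_pct),
    )


def classify_positivity(maxaf_pct: float,
                        threshold_pct: float = POSITIVITY_THRESHOLD_PCT,
                        ) -> bool:
    """True (positive) iff MaxAF strictly exceeds the cutoff; a score exactly
    at the cutoff is negative."""
    if threshold_pct < 0:
        raise ValidationError(
            f"threshold_pct: must be >= 0, got {threshold_pct}")
    if maxaf_pct < 0:
        raise ValidationError(f"maxaf_pct: must be >= 0, got {maxaf_pct}")
    return maxaf_pct > threshold_pct


def roc_curve(scores: Sequence[tuple[float, bool]]) -> RocCurve:
    """Empirical ROC of MaxAF scores against PM status.

    ``scores`` is a sequence of (maxaf_pct, is_pm). Operating points are
    computed at every distinct observed score under the strict
    ``score > threshold`` rule. Both classes must be present.
    """
    values = np.asarray([s for s, _ in scores], dtype=float)
    labels = np.asarray([bool(t) for _, t in scores], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError(
            "roc_curve requires both PM and non-PM samples")
    thresholds = np.unique(values)
    points = []
    for t in thresholds:
        sens = float((values[labels] > t).mean())
        spec = float((values[~labels] <= t).mean())
        points.append(RocPoint(threshold_pct=float(t), sensitivity=sens,
                               specificity=spec))
    # trapezoid over (FPR, TPR); the virtual all-positive endpoint (1, 1)
    # completes the curve, and the highest threshold contributes (0, 0)
    fpr = np.array([1.0] + [1.0 - p.specificity for p in points])
    tpr = np.array([1.0] + [p.sensitivity for p in points])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    curve = RocCurve(points=tuple(points), auc=auc,
                     best_cutoff_pct=points[0].threshold_pct)
    return RocCurve(points=curve.points, auc=curve.auc,
                    best_cutoff_pct=best_cutoff(curve))


def best_cutoff(roc: RocCurve) -> float:
    """Threshold maximizing Youden's J; ties broken toward higher
    specificity, then higher threshold (a rule-in test)."""
    best = max(roc.points,
               key=lambda p: (p.sensitivity + p.specificity - 1.0,
                              p.specificity, p.threshold_pct))
    return best.threshold_pct


def build_contingency(predictions: Mapping[str, bool],
                      truth: Mapping[str, bool]) -> ContingencyTable:
    """Count tp/fp/fn/tn with positive = cfDNA positive, condition = PM.

    ``predictions`` maps sample -> positivity, ``truth`` maps sample -> PM
    status; the sample sets must coincide.
    """
    diff = set(predictions) ^ set(truth)
    if diff:
        raise ValidationError(
            f"predictions/truth sample sets differ: {sorted(diff)}")
    if not predictions:
        raise ValidationError("predictions: empty input")
    tp = fp = fn = tn = 0
    for sample, predicted in predictions.items():
        is_pm = truth[sample]
        if predicted and is_pm:
            tp += 1
        elif predicted and not is_pm:
            fp += 1
        elif not predicted and is_pm:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def diagnostic_metrics(table: ContingencyTable) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, PPV and NPV as percents rounded
    half-up to one decimal; a metric with zero denominator is None
    (undefined), never 0."""
    if table.total == 0:
        raise ValidationError("table: total must be > 0")
    return {
        "sensitivity": percent(table.tp, table.tp + table.fn),
        "specificity": percent(table.tn, table.tn + table.fp),
        "accuracy": percent(table.tp + table.tn, table.total),
        "ppv": percent(table.tp, table.tp + table.fp),
        "npv": percent(table.tn, table.tn + table.fn),
    }


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact test (fixed margins, probability ordering).

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's. Computed with exact integer arithmetic, so ties are handled
    without floating-point slack.
    """
    a, b, c, d = table.tp, table.fp, table.fn, table.tn
    if a + b + c + d == 0:
        raise ValidationError("table: total must be > 0")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # numerator of P(k) with the common denominator C(n, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k)
               for k in range(lo, hi + 1)]
    observed = math.comb(r1, a) * math.comb(r2, c)
    tail = sum(w for w in weights if w <= observed)
    return tail / math.comb(n, c1)
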