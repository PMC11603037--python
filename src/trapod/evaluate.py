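"""Metrics, bootstrap confidence intervals, the train/test-size-corrected
paired t-test, decision-threshold scenarios, and confusion-matrix scaling.

The corrected t-test compares per-resample performance vectors P0, P1 of two
models evaluated on the same bootstrapped test sets.  Because resamples
overlap, the naive paired t-test underestimates the variance; the corrected
variance scales Var(D) of the absolute differences D = |P0 - P1| by
``1/n + n_train/n_test`` and the statistic is ``t = mean(D)/sqrt(var_mod)``
with n-1 degrees of freedom.  The ratio orientation (the correction
literature uses n_test/n_train) and the absolute value on D are
configurable; defaults follow the printed form of the method this package
reimplements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "MetricSet",
    "PairedComparison",
    "ScenarioResult",
    "aggregate_attention_report",
    "bootstrap_metrics",
    "compute_metrics",
    "corrected_t_test",
    "scale_confusion",
    "threshold_scenarios",
]


@dataclass
class MetricSet:
    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    precision_at_recall: float
    threshold: float
    recall_level: float

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision_at_recall": self.precision_at_recall,
        }


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")


def compute_metrics(
    scores, labels, threshold: float = 0.5, recall_level: float = 0.8
) -> MetricSet:
    """AUROC (rank concordance, ties half), AUPRC (precision-recall step
    integration), sensitivity/specificity at ``threshold``, and the maximum
    precision among operating points with recall >= ``recall_level``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    sens = float((pred & pos).sum() / pos.sum())
    spec = float((~pred & neg).sum() / neg.sum())
    precision, recall, _ = precision_recall_curve(labels, scores)
    feasible = recall >= recall_level
    prec_at = float(precision[feasible].max()) if feasible.any() else float("nan")
    return MetricSet(auroc, auprc, sens, spec, prec_at, threshold, recall_level)


@dataclass
class BootstrapResult:
    values: np.ndarray  # per-resample metric, length B
    mean: float
    ci_low: float
    ci_high: float
    seed: int
    n_redrawn: int = 0


def bootstrap_metrics(
    scores,
    labels,
    B: int = 1000,
    seed: int = 0,
    metric: str = "auroc",
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Metric distribution over B bootstrap resamples of the test set.

    Resamples are drawn with replacement at the test-set size; a resample
    containing a single class is redrawn (and counted)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    values = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a two-class resample")
        s, y = scores[idx], labels[idx]
        if metric == "auroc":
            values[b] = roc_auc_score(y, s)
        elif metric == "auprc":
            values[b] = average_precision_score(y, s)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    if n_redrawn:
        logger.info("redrew %d single-class bootstrap resamples", n_redrawn)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return BootstrapResult(values, float(values.mean()), float(lo), float(hi),
                           seed, n_redrawn)


@dataclass
class PairedComparison:
    d: np.ndarray
    d_bar: float
    sigma2_mod: float
    n: int
    n_train: int
    n_test: int
    t: float
    p: float


def corrected_t_test(
    P0,
    P1,
    n_train: int,
    n_test: int,
    absolute: bool = True,
    ratio: str = "train_over_test",
) -> PairedComparison:
    """Train/test-size-corrected paired t-test on resampled metric vectors.

    ``sigma2_mod = Var(D) * (1/n + r)`` with ``r = n_train/n_test`` (default)
    or ``n_test/n_train``; ``t = mean(D)/sqrt(sigma2_mod)``; two-sided p from
    the t distribution with n-1 df.  With ``absolute=True`` (default) D is
    |P0 - P1|, making the statistic one-sided by construction.
    """
    P0 = np.asarray(P0, dtype=float)
    P1 = np.asarray(P1, dtype=float)
    if P0.shape != P1.shape or P0.ndim != 1:
        raise ValueError("P0 and P1 must be equal-length vectors")
    n = len(P0)
    if n < 2:
        raise ValueError("need at least 2 resamples")
    d = np.abs(P0 - P1) if absolute else P0 - P1
    d_bar = float(d.mean())
    var = float(d.var(ddof=1))
    if ratio == "train_over_test":
        r = n_train / n_test
    elif ratio == "test_over_train":
        r = n_test / n_train
    else:
        raise ValueError(f"unknown ratio orientation {ratio!r}")
    sigma2 = var * (1.0 / n + r)
    if sigma2 == 0:
        if d_bar == 0:
            t, p = 0.0, 1.0
        else:
            logger.warning("zero variance with nonzero mean difference; t=+inf")
            t, p = float("inf"), 0.0
    else:
        t = d_bar / np.sqrt(sigma2)
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedComparison(d, d_bar, sigma2, n, n_train, n_test, float(t), p)


@dataclass
class ScenarioResult:
    scenario: str
    threshold: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float


def threshold_scenarios(scores, labels, recall_target: float = 0.8) -> dict:
    """Three clinical operating points:

    A — threshold maximizing sensitivity + specificity;
    B — threshold maximizing precision + recall;
    C — smallest threshold achieving recall >= ``recall_target``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)

    fpr, tpr, roc_thr = roc_curve(labels, scores)
    j = np.argmax(tpr - fpr)
    thr_a = float(roc_thr[j])

    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    # precision_recall_curve appends a (1, 0) endpoint with no threshold
    pr_prec, pr_rec = precision[:-1], recall[:-1]
    b = np.argmax(pr_prec + pr_rec)
    thr_b = float(pr_thr[b])

    feas = pr_rec >= recall_target
    if not feas.any():
        raise ValueError(f"recall {recall_target} unreachable")
    thr_c = float(pr_thr[feas].max())

    out = {}
    for name, thr in (("A", thr_a), ("B", thr_b), ("C", thr_c)):
        pred = scores >= thr
        pos, neg = labels == 1, labels == 0
        tp = int((pred & pos).sum())
        fp = int((pred & neg).sum())
        sens = tp / pos.sum()
        spec = int((~pred & neg).sum()) / neg.sum()
        prec = tp / max(tp + fp, 1)
        out[name] = ScenarioResult(name, thr, float(sens), float(spec),
                                   float(prec), float(sens))
    return out


def scale_confusion(
    recall: float, precision: float, caseload: int = 100, prevalence: float = 0.09
) -> tuple[int, int, int, int]:
    """Project an operating point onto a daily caseload.

    With P = round(caseload * prevalence) positives and N = caseload - P
    negatives: TP = floor(recall * P); predicted positives
    PP = round(TP / precision); FP = PP - TP; TN = N - FP; FN = P - TP.
    Returns (TP, FP, TN, FN).
    """
    if not (0 < recall <= 1 and 0 < precision <= 1):
        raise ValueError("recall and precision must be in (0, 1]")
    P = int(round(caseload * prevalence))
    if P < 1:
        raise ValueError("caseload * prevalence must be >= 1")
    N = caseload - P
    TP = int(np.floor(recall * P))
    PP = int(round(TP / precision))
    FP = PP - TP
    if FP < 0:
        raise ValueError("inconsistent recall/precision inputs (FP < 0)")
    TN = N - FP
    FN = P - TP
    return TP, FP, TN, FN


def aggregate_attention_report(att, B: int = 200, seed: int = 0) -> dict:
    """Summaries of an :class:`~trapod.models.AttentionMatrix`.

    Returns per-feature saliency sums over time, the per-time mean profile
    across features, and (when per-surgery received attention is present)
    bootstrap percentile CIs of the time profile over surgeries.
    """
    feature_sums = att.saliency.sum(axis=1)
    time_profile = att.saliency.mean(axis=0)
    report = {
        "feature_names": list(att.channel_names),
        "feature_sums": feature_sums.tolist(),
        "time_profile": time_profile.tolist(),
        "per_time_mean_attention": att.per_time_mean.tolist(),
    }
    if att.per_surgery_received is not None and B > 0:
        rng = np.random.default_rng(seed)
        m = att.per_surgery_received.shape[0]
        boots = np.empty((B, att.per_surgery_received.shape[1]))
        for b in range(B):
            idx = rng.integers(0, m, size=m)
            boots[b] = att.per_surgery_received[idx].mean(axis=0)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        report["per_time_ci_low"] = lo.tolist()
        report["per_time_ci_high"] = hi.tolist()
    return report
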