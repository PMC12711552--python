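"""Clinical evaluation stack: metric panel, DeLong AUROC comparison,
calibration and decision-curve analysis.

All routines take AC (adenocarcinoma, the minority subtype) as the
positive class.  AUROC is computed as the Mann-Whitney statistic — the
probability that a random positive outscores a random negative, ties
counted half — via midranks, which coincides with trapezoidal
integration of the empirical ROC curve.  Confidence intervals are
case-level percentile bootstraps (resampling cases, not patches,
respects the clustering of patches within slides and slides within
patients).  The DeLong test compares two correlated AUROCs through their
structural components.  Decision-curve analysis reports the net benefit
``NB(t) = TP/n − FP/n · t/(1−t)`` against treat-all / treat-none
references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport", "CalibrationCurve", "DecisionCurve", "confusion_metrics",
    "auroc", "bootstrap_ci", "delong_test", "calibration", "decision_curve",
    "evaluate_calls",
]

POSITIVE = "AC"


def _binarize(y: Sequence) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "iufb":
        return arr.astype(int)
    return (arr == POSITIVE).astype(int)


@dataclass
class EvalReport:
    """Point estimates (and optional 95% CIs) of the standard metric panel."""

    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None
    auroc: Optional[float] = None
    ci: dict = field(default_factory=dict)  # metric -> (lo, hi)
    n_pos: int = 0
    n_neg: int = 0

    def as_dict(self) -> dict:
        out = {}
        for m in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auroc"):
            out[m] = {"value": getattr(self, m)}
            if m in self.ci:
                out[m]["ci95"] = list(self.ci[m])
        out["n_pos"], out["n_neg"] = self.n_pos, self.n_neg
        return out


@dataclass
class CalibrationCurve:
    bin_mid: np.ndarray
    mean_predicted: np.ndarray
    observed_fraction: np.ndarray
    bin_count: np.ndarray


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def confusion_metrics(y_true: Sequence, y_pred: Sequence) -> EvalReport:
    """Accuracy/sensitivity/specificity/PPV/NPV from hard SCC/AC calls.

    Ratios with a zero denominator are reported as absent (None), never
    as zero.
    """
    yt, yp = _binarize(y_true), _binarize(y_pred)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred lengths differ")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))

    def ratio(a, b):
        return a / b if b > 0 else None

    return EvalReport(
        accuracy=ratio(tp + tn, len(yt)),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        n_pos=tp + fn, n_neg=tn + fp)


def auroc(scores: Sequence[float], y_true: Sequence) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + ½ P(equal)."""
    y = _binarize(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(s)  # midranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_ci(metric_fn: Callable[[dict], float], data: dict,
                 B: int = 2000, seed: int = 0,
                 case_ids: Optional[Sequence] = None,
                 max_redraws: int = 10000) -> tuple[float, float]:
    """Percentile 95% bootstrap of a metric over case-level resamples.

    ``data`` is a dict of parallel arrays handed to ``metric_fn`` after
    resampling.  When ``case_ids`` is given, whole cases are resampled
    with replacement (all rows of a drawn case enter together).
    Resamples that degenerate to a single class in ``y_true`` are
    redrawn and counted.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    keys = list(data)
    arrays = {k: np.asarray(v) for k, v in data.items()}
    n = len(arrays[keys[0]])
    rng = np.random.default_rng(seed)
    if case_ids is not None:
        case_ids = np.asarray(case_ids)
        uniq = np.unique(case_ids)
        members = {c: np.flatnonzero(case_ids == c) for c in uniq}
    stats = []
    redraws = 0
    while len(stats) < B:
        if case_ids is not None:
            drawn = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([members[c] for c in drawn])
        else:
            idx = rng.integers(0, n, size=n)
        sample = {k: v[idx] for k, v in arrays.items()}
        if "y_true" in sample and len(np.unique(_binarize(sample["y_true"]))) < 2:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        stats.append(metric_fn(sample))
    if redraws:
        logger.info("bootstrap: %d degenerate resamples redrawn", redraws)
    return (float(np.nanpercentile(stats, 2.5)), float(np.nanpercentile(stats, 97.5)))


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong V10 (per positive) and V01 (per negative) components via midranks."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = rankdata(pos), rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                y_true: Sequence) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUROCs on the same cases.

    Returns ``(auroc_a, auroc_b, z, p)`` with a two-sided normal p-value.
    Identical score vectors give z = 0, p = 1.
    """
    y = _binarize(y_true)
    sa, sb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if len(sa) != len(sb) or len(sa) != len(y):
        raise ValueError("scores_a, scores_b and y_true must be paired")
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _structural_components(sa, y)
    auc_b, v10_b, v01_b = _structural_components(sb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


def delong_variance(scores: Sequence[float], y_true: Sequence) -> float:
    """Variance of a single AUROC from its structural components."""
    y = _binarize(y_true)
    _, v10, v01 = _structural_components(np.asarray(scores, float), y)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def calibration(probs: Sequence[float], y_true: Sequence,
                n_bins: int = 10) -> CalibrationCurve:
    """Reliability curve over equal-width probability bins (empty bins omitted)."""
    p = np.asarray(probs, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = _binarize(y_true)
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)
    mids, meanp, obs, counts = [], [], [], []
    for b in range(n_bins):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        mids.append((b + 0.5) / n_bins)
        meanp.append(float(p[mask].mean()))
        obs.append(float(y[mask].mean()))
        counts.append(cnt)
    return CalibrationCurve(bin_mid=np.array(mids), mean_predicted=np.array(meanp),
                            observed_fraction=np.array(obs),
                            bin_count=np.array(counts))


def decision_curve(probs: Sequence[float], y_true: Sequence,
                   thresholds: Optional[Sequence[float]] = None) -> DecisionCurve:
    """Net benefit across decision thresholds, with treat-all/none references.

    A case is called positive at threshold t iff its probability >= t;
    ``NB(t) = TP/n − FP/n · t/(1−t)``.  Treat-all reduces to
    ``prev − (1−prev)·t/(1−t)``; treat-none is identically zero.
    """
    t = np.arange(0.01, 1.0, 0.01) if thresholds is None else np.asarray(thresholds, float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    p = np.asarray(probs, float)
    y = _binarize(y_true)
    n = len(y)
    prev = y.mean()
    nb = np.empty_like(t)
    for i, ti in enumerate(t):
        pred = p >= ti
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        nb[i] = tp - fp * ti / (1.0 - ti)
    treat_all = prev - (1.0 - prev) * t / (1.0 - t)
    return DecisionCurve(thresholds=t, net_benefit=nb, treat_all=treat_all,
                         treat_none=np.zeros_like(t))


def evaluate_calls(y_true: Sequence, y_pred: Sequence,
                   scores: Optional[Sequence[float]] = None,
                   case_ids: Optional[Sequence] = None,
                   B: int = 2000, seed: int = 0) -> EvalReport:
    """Full metric panel with case-level bootstrap 95% CIs."""
    report = confusion_metrics(y_true, y_pred)
    data = {"y_true": np.asarray(y_true), "y_pred": np.asarray(y_pred)}
    if scores is not None:
        report.auroc = auroc(scores, y_true)
        data["scores"] = np.asarray(scores, float)

    def metric(name):
        def fn(d):
            if name == "auroc":
                return auroc(d["scores"], d["y_true"])
            val = getattr(confusion_metrics(d["y_true"], d["y_pred"]), name)
            return np.nan if val is None else val
        return fn

    metrics = ["accuracy", "sensitivity", "specificity", "ppv", "npv"]
    if scores is not None:
        metrics.append("auroc")
    for i, name in enumerate(metrics):
        if getattr(report, name) is None:
            continue
        report.ci[name] = bootstrap_ci(metric(name), data, B=B, seed=seed + i,
                                       case_ids=case_ids)
    return report
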