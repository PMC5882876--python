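"""Prediction-accuracy metrics: AUC with DeLong CI, sensitivity/specificity,
Youden threshold, Nagelkerke pseudo-R^2.

The AUC is the Mann-Whitney probability that a randomly chosen remitter
outranks a randomly chosen non-remitter (ties count 1/2); its variance and
the test against AUC = 0.5 follow DeLong's placement-value method. The
classification threshold is chosen on training data by maximizing Youden's
J = sensitivity + specificity - 1 and frozen before validation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm, rankdata


@dataclasses.dataclass
class EvaluationReport:
    """One cell of the study design (drug x train/validation x same/cross)."""

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    sensitivity: float
    specificity: float
    pseudo_r2: float
    threshold: float
    n: int
    n_remitters: int
    context: str = ""
    degenerate_auc_variance: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _split_classes(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC (rank formula; ties contribute 1/2)."""
    pos, neg = _split_classes(scores, labels)
    all_scores = np.concatenate([pos, neg])
    ranks = rankdata(all_scores)
    r1 = ranks[: pos.size].sum()
    return float((r1 - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def delong_ci(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> tuple[float, float, float, bool]:
    """DeLong variance-based CI for the AUC and two-sided p vs AUC = 0.5.

    Returns (ci_low, ci_high, p_value, degenerate) where ``degenerate`` flags
    zero placement-value variance (e.g. perfect separation), in which case
    the CI collapses to a point and p is reported at the smallest positive
    float.
    """
    pos, neg = _split_classes(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("DeLong CI needs at least 2 members per class")
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)  # placement value of each positive
    v01 = cmp.mean(axis=0)  # placement value of each negative
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    if var <= 0:
        return auc, auc, float(np.finfo(float).tiny), True
    se = float(np.sqrt(var))
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    lo, hi = max(auc - z * se, 0.0), min(auc + z * se, 1.0)
    p = float(2.0 * norm.sf(abs(auc - 0.5) / se))
    return lo, hi, p, False


def sensitivity_specificity(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """Sensitivity and specificity classifying p >= threshold as remitter."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec


def choose_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J on the supplied (training) data.

    Candidates are the midpoints between consecutive distinct probabilities;
    ties in J are broken toward the candidate nearest 0.5 (then the smaller).
    A constant score vector yields 0.5.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    uniq = np.unique(p)
    if uniq.size < 2:
        return 0.5
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_key = None, None
    for t in candidates:
        sens, spec = sensitivity_specificity(p, y, t)
        j = sens + spec - 1.0
        key = (round(j, 12), -abs(t - 0.5), -t)
        if best_key is None or key > best_key:
            best_key, best_t = key, float(t)
    return best_t


def nagelkerke_r2(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Nagelkerke pseudo-R^2 of supplied probabilities against the labels.

    The null is the intercept-only model refitted on the evaluated labels;
    the Cox-Snell ratio is rescaled by its maximum and clamped to [0, 1].
    """
    p = np.clip(np.asarray(probabilities, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n = len(y)
    l1 = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    ybar = float(y.mean())
    l0 = n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    r2_cs = 1.0 - np.exp(2.0 * (l0 - l1) / n)
    denom = 1.0 - np.exp(2.0 * l0 / n)
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC as an array of (fpr, tpr) pairs, for plotting/export."""
    pos, neg = _split_classes(scores, labels)
    thresholds = np.unique(np.concatenate([scores, [np.inf]]))[::-1]
    pts = [
        (float(np.mean(neg >= t)), float(np.mean(pos >= t))) for t in thresholds
    ]
    return np.asarray(pts)


def evaluate_predictions(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    context: str = "",
    level: float = 0.95,
) -> EvaluationReport:
    """Full accuracy report for one set of predictions."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    auc = roc_auc(probabilities, labels)
    lo, hi, p, degenerate = delong_ci(probabilities, labels, level=level)
    sens, spec = sensitivity_specificity(probabilities, labels, threshold)
    r2 = nagelkerke_r2(probabilities, labels)
    return EvaluationReport(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        sensitivity=sens,
        specificity=spec,
        pseudo_r2=r2,
        threshold=float(threshold),
        n=int(len(labels)),
        n_remitters=int(np.sum(labels == 1)),
        context=context,
        degenerate_auc_variance=degenerate,
    )
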