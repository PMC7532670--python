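"""ROC analysis: AUC, DeLong confidence intervals, Wald AUC-difference test,
and the Youden-index cutoff.

The AUC is the Mann-Whitney two-sample statistic: the probability that a
positive's score exceeds a negative's, counting ties as 1/2.  Variances and
covariances of (possibly paired) AUCs come from the DeLong placement-value
estimator, which underlies the confidence intervals and the Wald z test for
the difference of two correlated AUCs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def _placements(scores, labels):
    """DeLong placement values.

    V10[i] = fraction of negatives scored below positive i (ties 1/2);
    V01[j] = fraction of positives scored above negative j (ties 1/2).
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    mid = stats.rankdata(np.concatenate([pos, neg]))  # pooled midranks
    m, n = len(pos), len(neg)
    v10 = (mid[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (mid[m:] - stats.rankdata(neg)) / m
    return v10, v01


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: mean over (pos, neg) pairs of [s_p > s_n] + 1/2[s_p == s_n]."""
    scores, labels = _validate(scores, labels)
    v10, _ = _placements(scores, labels)
    return float(v10.mean())


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC estimate."""
    scores, labels = _validate(scores, labels)
    v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for the AUC with DeLong variance, clipped to [0,1].

    A degenerate (zero-variance) AUC returns the point estimate twice, with a
    warning: the normal approximation carries no information there.
    """
    scores, labels = _validate(scores, labels)
    auc = roc_auc(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0:
        warnings.warn("zero DeLong variance; returning degenerate CI", stacklevel=2)
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def wald_auc_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Wald z test for the difference of two correlated AUCs on the same slides.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov), with DeLong paired
    covariance; two-sided normal p.  Identical scores give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    _, labels = _validate(scores_a, labels)
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    m, n = len(va10), len(va01)
    auc_a, auc_b = va10.mean(), vb10.mean()
    var_a = np.var(va10, ddof=1) / m + np.var(va01, ddof=1) / n
    var_b = np.var(vb10, ddof=1) / m + np.var(vb01, ddof=1) / n
    cov = (
        np.cov(va10, vb10, ddof=1)[0, 1] / m + np.cov(va01, vb01, ddof=1)[0, 1] / n
    )
    denom = var_a + var_b - 2 * cov
    if denom <= 0:
        return 0.0, 1.0
    z = float((auc_a - auc_b) / np.sqrt(denom))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct scores plus one cutoff
    below all scores; a score >= cutoff is called positive.  Ties in J are
    broken toward the smallest cutoff.
    """
    scores, labels = _validate(scores, labels)
    distinct = np.unique(scores)
    cands = [distinct[0] - 1.0]
    cands += list((distinct[:-1] + distinct[1:]) / 2)
    cands.append(distinct[-1] + 1.0)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None
    for c in cands:
        calls = scores >= c
        sens = (calls & (labels == 1)).sum() / n_pos
        spec = (~calls & (labels == 0)).sum() / n_neg
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, cutoff, sens, spec = best
    return float(cutoff), float(sens), float(spec)


def roc_curve_points(scores, labels) -> np.ndarray:
    """(fpr, tpr, threshold) rows over all distinct thresholds, descending."""
    scores, labels = _validate(scores, labels)
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    rows = [(0.0, 0.0, np.inf)]
    for t in thresholds:
        calls = scores >= t
        rows.append(
            (
                (calls & (labels == 0)).sum() / n_neg,
                (calls & (labels == 1)).sum() / n_pos,
                float(t),
            )
        )
    return np.array(rows)


@dataclass
class RocResult:
    """Full ROC report for one score vector."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int

    def to_json(self, path: str | Path | None = None) -> dict:
        d = dataclasses.asdict(self)
        d["ci"] = [d.pop("ci_low"), d.pop("ci_high")]
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2))
        return d


def evaluate_scores(scores, labels, level: float = 0.95) -> RocResult:
    """AUC with DeLong CI plus the Youden operating point."""
    scores, labels = _validate(scores, labels)
    auc = roc_auc(scores, labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        low, high = delong_ci(scores, labels, level)
    cutoff, sens, spec = youden_cutoff(scores, labels)
    return RocResult(
        auc=auc,
        ci_low=low,
        ci_high=high,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
    )
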