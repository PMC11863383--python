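"""Reporting surfaces per split: volcano statistics and cv-score tables.

For any two pooled groups a volcano table gives, per variable, the fold
change on the original measurement scale (as log2) and a two-sided Welch
t-test p-value; a variable is flagged significant when both p < alpha and
the fold change exceeds the fold threshold (defaults 0.01 and 2-fold).  The
cv-score table exposes each sample's cross-validated predictive score (and
first orthogonal cv-score when one exists) together with per-class 95%
Hotelling's T² confidence-ellipse parameters for score plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Dataset, InsufficientSamplesError
from .hda import HdaNode

#: smallest reportable p-value; keeps p in (0, 1] even for infinite t
_P_FLOOR = 1e-300


def volcano_stats(data: Dataset, group0, group1, alpha: float = 0.01,
                  fold_threshold: float = 2.0) -> pd.DataFrame:
    """Per-variable fold change and Welch-test significance for two groups.

    Fold change is ``mean(group1) / mean(group0)`` on the original unscaled
    data, reported as log2; ``direction`` says which side of the split the
    variable is high in (group1 = right).  Variables with a nonpositive
    group mean cannot carry a ratio fold change: they are flagged, their
    log2 fold change is NaN, and they are excluded from the significance
    gate.  ``q_value`` adds a Benjamini-Hochberg FDR column; the
    ``significant`` gate itself uses the raw p-value, conjunction with the
    fold threshold.
    """
    group0 = set(group0)
    group1 = set(group1)
    labels = np.asarray(data.labels)
    m0 = np.isin(labels, sorted(group0))
    m1 = np.isin(labels, sorted(group1))
    if m0.sum() < 2 or m1.sum() < 2:
        raise InsufficientSamplesError(
            "each group needs >= 2 samples for volcano statistics")
    X0 = data.values[m0]
    X1 = data.values[m1]
    mean0 = X0.mean(axis=0)
    mean1 = X1.mean(axis=0)

    t_stat, p = stats.ttest_ind(X1, X0, equal_var=False, axis=0)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: p is NaN; equal means are a non-effect
    both_const = (X0.std(axis=0) == 0) & (X1.std(axis=0) == 0)
    p[both_const & (mean0 == mean1)] = 1.0
    p[both_const & (mean0 != mean1)] = _P_FLOOR
    p = np.clip(p, _P_FLOOR, 1.0)

    flagged = (mean0 <= 0) | (mean1 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(flagged, np.nan, np.log2(mean1 / mean0))

    significant = (~flagged) & (p < alpha) & (np.abs(log2fc) > np.log2(fold_threshold))
    q = _benjamini_hochberg(p)
    direction = np.where(np.isnan(log2fc), "n/a",
                         np.where(log2fc >= 0, "high_in_right",
                                  "high_in_left"))
    return pd.DataFrame({
        "variable_name": data.variable_names,
        "log2_fold_change": log2fc,
        "p_value": p,
        "q_value": q,
        "significant": significant,
        "flagged_nonpositive_mean": flagged,
        "direction": direction,
    })


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(ranked, 1.0)
    return q


@dataclass
class Ellipse:
    """95% Hotelling's T² confidence ellipse of a 2-D score cloud."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float
    confidence: float = 0.95


@dataclass
class Interval:
    """1-D fallback when a node has no orthogonal score dimension."""

    center: float
    half_width: float
    confidence: float = 0.95


def hotelling_limit(n: int, p: int, confidence: float = 0.95) -> float:
    """Critical Mahalanobis radius² for an n-point, p-dimensional cloud.

    ``c = p (n-1) / (n-p) * F_{p, n-p}(confidence)``; a point lies inside
    the ellipse when its squared Mahalanobis distance to the mean is <= c.
    """
    if n <= p:
        raise InsufficientSamplesError(
            f"need more than {p} samples for a {p}-D ellipse (got {n})")
    return p * (n - 1) / (n - p) * float(stats.f.ppf(confidence, p, n - p))


def score_ellipse(scores: np.ndarray, confidence: float = 0.95
                  ) -> Ellipse | Interval:
    """Hotelling's T² confidence region of a score cloud (2-D or 1-D)."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1 or scores.shape[1] == 1:
        s = scores.ravel()
        c = hotelling_limit(s.size, 1, confidence)
        return Interval(center=float(s.mean()),
                        half_width=float(s.std(ddof=1) * np.sqrt(c)),
                        confidence=confidence)
    n = scores.shape[0]
    c = hotelling_limit(n, 2, confidence)
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    eigval = np.maximum(eigval, 0.0)
    # largest axis first
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return Ellipse(center=(float(center[0]), float(center[1])),
                   semi_axes=(float(np.sqrt(eigval[0] * c)),
                              float(np.sqrt(eigval[1] * c))),
                   angle_rad=angle, confidence=confidence)


def cv_score_table(node: HdaNode, confidence: float = 0.95
                   ) -> tuple[pd.DataFrame, dict[str, Ellipse | Interval]]:
    """Cross-validated score table for one split, with per-class ellipses.

    Rows carry ``sample_id, class, t_cv`` and, when the node kept at least
    one orthogonal component, ``t_orth_1``.  Ellipses are per original
    class (not pooled side), matching how score plots are drawn.
    """
    cv = node.cv
    table = pd.DataFrame({"sample_id": cv.sample_ids,
                          "class": cv.labels,
                          "t_cv": cv.t_cv})
    two_d = cv.t_orth1_cv is not None
    if two_d:
        table["t_orth_1"] = cv.t_orth1_cv
    ellipses: dict[str, Ellipse | Interval] = {}
    for cls in sorted(set(cv.labels)):
        mask = np.asarray(cv.labels) == cls
        if two_d:
            pts = np.column_stack([cv.t_cv[mask], cv.t_orth1_cv[mask]])
        else:
            pts = cv.t_cv[mask]
        ellipses[cls] = score_ellipse(pts, confidence)
    return table, ellipses
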