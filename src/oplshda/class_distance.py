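"""Cohen's d separability between classes from pairwise OPLS-DA models.

Every unordered pair of classes gets its own one-vs-one OPLS-DA model,
fit only on that pair's samples with its own component selection; the
standardized mean difference of the cross-validated predictions,

    d = |m1 - m0| / s_p,    s_p = sqrt((ss0 + ss1) / (n0 + n1 - 2)),

with ``ss`` the within-group sums of squared deviations, is the distance
between the two classes.  A model that separates the pair cleanly pushes the
predictions toward their 0/1 targets with little spread (large d); a weak
model's predictions collapse around the response mean with a large spread
(small d).  For N classes this yields N(N-1)/2 models and a symmetric NxN
distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Dataset, InsufficientSamplesError, encode_dummy
from .model_selection import CvResult, select_n_orth

logger = logging.getLogger(__name__)

#: Cap applied when the pooled SD of the cv-predictions is exactly zero
#: (perfect noiseless separation); any cap above realistic d values produces
#: the same dendrogram.
D_CAP = 1e6


def cohens_d(yhat0, yhat1, cap: float = D_CAP) -> float:
    """Standardized mean difference between two groups of cv-predictions.

    Uses the pooled standard deviation ``s_p = sqrt((ss0+ss1)/(n0+n1-2))``;
    the absolute difference makes the result a nonnegative dissimilarity.
    ``s_p = 0`` with distinct means returns ``cap``; with equal means, 0.
    """
    yhat0 = np.asarray(yhat0, dtype=float)
    yhat1 = np.asarray(yhat1, dtype=float)
    if yhat0.size < 2 or yhat1.size < 2:
        raise InsufficientSamplesError(
            "each group needs >= 2 values for a pooled SD "
            f"(got {yhat0.size} and {yhat1.size})")
    m0 = yhat0.mean()
    m1 = yhat1.mean()
    ss0 = float(np.sum((yhat0 - m0) ** 2))
    ss1 = float(np.sum((yhat1 - m1) ** 2))
    s_p = np.sqrt((ss0 + ss1) / (yhat0.size + yhat1.size - 2))
    diff = abs(m1 - m0)
    if s_p == 0.0:
        return 0.0 if diff == 0.0 else float(cap)
    return float(min(diff / s_p, cap))


@dataclass
class PairModelRecord:
    """Summary of one one-vs-one OPLS-DA model."""

    class_a: str
    class_b: str
    cv_result: CvResult
    cohens_d: float
    chosen_A: int

    def summary(self) -> dict:
        return {"class_a": self.class_a, "class_b": self.class_b,
                "chosen_A": self.chosen_A, "q2": self.cv_result.q2,
                "cohens_d": self.cohens_d}


@dataclass
class ClassDistanceMatrix:
    """Symmetric Cohen's d matrix over classes, lexicographic order."""

    class_names: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.class_names)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} for {n} classes")

    def value(self, a: str, b: str) -> float:
        i = self.class_names.index(a)
        j = self.class_names.index(b)
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.class_names,
                            columns=self.class_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(class_names=[str(c) for c in df.columns],
                   d=df.to_numpy(dtype=float))


def pairwise_distance_matrix(data: Dataset, config=None
                             ) -> tuple[ClassDistanceMatrix,
                                        list[PairModelRecord]]:
    """All one-vs-one OPLS-DA models and the resulting distance matrix.

    Pairs are visited in lexicographic order; for each pair the dataset is
    subset to the two classes, the orthogonal-component count is selected by
    cross-validated Q² gain, and Cohen's d is computed from the chosen
    model's ``y_cv`` split by class.  Returns the symmetric matrix plus one
    :class:`PairModelRecord` per pair (N(N-1)/2 records).
    """
    from .config import RunConfig

    if config is None:
        config = RunConfig()
    names = data.class_names
    if len(names) < 2:
        raise InsufficientSamplesError("need at least 2 classes")
    n = len(names)
    d = np.zeros((n, n))
    records: list[PairModelRecord] = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        sub = data.subset_classes([a, b])
        dummy = encode_dummy(sub.labels, {a}, {b})
        cv = select_n_orth(sub, dummy, k=config.cv_folds, seed=config.cv_seed,
                           max_orth=config.max_orth,
                           q2_gain_threshold=config.q2_gain_threshold,
                           mode=config.scaling)
        lab = np.asarray(sub.labels)
        dist = cohens_d(cv.y_cv[lab == a], cv.y_cv[lab == b],
                        cap=config.cohens_d_cap)
        d[i, j] = d[j, i] = dist
        records.append(PairModelRecord(class_a=a, class_b=b, cv_result=cv,
                                       cohens_d=dist, chosen_A=cv.chosen_A))
        logger.info("pair %s vs %s: A_orth=%d Q2=%.3f cohens_d=%.3f",
                    a, b, cv.chosen_A, cv.q2, dist)
    return ClassDistanceMatrix(class_names=names, d=d), records


def pair_summary_frame(records: list[PairModelRecord]) -> pd.DataFrame:
    """Per-pair summary table (class_a, class_b, chosen_A, Q², Cohen's d)."""
    return pd.DataFrame([r.summary() for r in records])
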