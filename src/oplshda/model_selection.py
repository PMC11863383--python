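"""k-fold cross-validation and orthogonal-component selection.

Each sample's cross-validated prediction ``y_cv`` comes from the fold model
that excluded it; preprocessing is refit inside every fold so nothing about a
held-out sample leaks into the model that predicts it.  PRESS (the sum of
squared cross-validated errors) and Q² = 1 − PRESS/SS_y drive the choice of
how many orthogonal components to keep: an extra component is retained only
while it improves Q² by more than a small configurable gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    ConfigurationError,
    Dataset,
    DummyResponse,
    RankError,
    fit_preprocessor,
)
from .opls import fit_opls, predict_opls


@dataclass
class CvResult:
    """Cross-validation output for one two-group OPLS-DA model.

    ``y_cv``/``t_cv`` belong to the *chosen* component count ``chosen_A``;
    ``press_by_A``/``q2_by_A`` trace every count evaluated.  ``t_orth1_cv``
    holds the first orthogonal cv-score when ``chosen_A >= 1`` (used by
    cv-score plots), else ``None``.
    """

    y_cv: np.ndarray
    t_cv: np.ndarray
    t_orth1_cv: np.ndarray | None
    press_by_A: dict[int, float]
    q2_by_A: dict[int, float]
    chosen_A: int
    fold_assignment: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    @property
    def press(self) -> float:
        return self.press_by_A[self.chosen_A]

    @property
    def q2(self) -> float:
        return self.q2_by_A[self.chosen_A]

    def to_frame(self) -> pd.DataFrame:
        """Per-sample dump: sample_id, fold, y_cv, t_cv."""
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "fold": self.fold_assignment,
            "y_cv": self.y_cv,
            "t_cv": self.t_cv,
        })

    def to_dict(self) -> dict:
        return {
            "y_cv": self.y_cv.tolist(),
            "t_cv": self.t_cv.tolist(),
            "t_orth1_cv": None if self.t_orth1_cv is None
            else self.t_orth1_cv.tolist(),
            "press_by_A": {str(k): v for k, v in self.press_by_A.items()},
            "q2_by_A": {str(k): v for k, v in self.q2_by_A.items()},
            "chosen_A": self.chosen_A,
            "fold_assignment": self.fold_assignment.tolist(),
            "sample_ids": list(self.sample_ids),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CvResult":
        return cls(
            y_cv=np.array(d["y_cv"], dtype=float),
            t_cv=np.array(d["t_cv"], dtype=float),
            t_orth1_cv=None if d["t_orth1_cv"] is None
            else np.array(d["t_orth1_cv"], dtype=float),
            press_by_A={int(k): float(v) for k, v in d["press_by_A"].items()},
            q2_by_A={int(k): float(v) for k, v in d["q2_by_A"].items()},
            chosen_A=int(d["chosen_A"]),
            fold_assignment=np.array(d["fold_assignment"], dtype=int),
            sample_ids=list(d["sample_ids"]),
            labels=list(d["labels"]),
        )


def assign_folds(labels, k: int, seed: int) -> np.ndarray:
    """Stratified, seeded fold assignment.

    Within each class the sample indices are shuffled with the seeded
    generator and dealt round-robin from a seeded starting fold, so fold
    sizes within a class differ by at most one and a class with fewer
    samples than folds still lands in distinct folds.  Deterministic given
    ``(labels, k, seed)``.
    """
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        start = int(rng.integers(k))
        folds[idx] = (start + np.arange(len(idx))) % k
    return folds


def _cv_arrays(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
               n_orth: int, mode: str
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """One CV pass at a fixed component count, on raw arrays."""
    n = X.shape[0]
    y_cv = np.full(n, np.nan)
    t_cv = np.full(n, np.nan)
    t_o1 = np.full(n, np.nan) if n_orth >= 1 else None
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        pre = fit_preprocessor(X[train], mode=mode)
        y_tr = y[train]
        y_mean = float(y_tr.mean())
        model = fit_opls(pre.transform(X[train]), y_tr - y_mean, n_orth,
                         preprocessor=pre, y_mean=y_mean)
        y_hat, t_hat, T_orth = predict_opls(model, X[test])
        y_cv[test] = y_hat
        t_cv[test] = t_hat
        if t_o1 is not None:
            t_o1[test] = T_orth[:, 0]
    return y_cv, t_cv, t_o1


def cross_validate(data: Dataset, dummy: DummyResponse, n_orth: int,
                   k: int = 7, seed: int = 0, mode: str = "uv",
                   folds: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Cross-validated predictions for a fixed orthogonal-component count.

    Returns ``(y_cv, t_cv, PRESS)`` in the dataset's sample order, with
    ``PRESS = sum((y - y_cv)**2)``.
    """
    if folds is None:
        folds = assign_folds(data.labels, k, seed)
    y_cv, t_cv, _ = _cv_arrays(data.values, dummy.y, folds, n_orth, mode)
    press = float(np.sum((dummy.y - y_cv) ** 2))
    return y_cv, t_cv, press


def select_n_orth(data: Dataset, dummy: DummyResponse, k: int = 7,
                  seed: int = 0, max_orth: int = 5,
                  q2_gain_threshold: float = 0.01,
                  mode: str = "uv") -> CvResult:
    """Choose the orthogonal-component count by sequential Q² gain.

    Counts ``A = 0, 1, 2, ...`` are evaluated in order; ``A+1`` replaces
    ``A`` only if ``Q²(A+1) − Q²(A) > q2_gain_threshold``.  The search stops
    at the first failing gain, at ``max_orth``, or when the data cannot
    support another component.  The returned :class:`CvResult` carries the
    chosen model's per-sample ``y_cv``/cv-scores and the full PRESS/Q² trace
    of every count evaluated.
    """
    if max_orth < 0:
        raise ConfigurationError(f"max_orth must be >= 0, got {max_orth}")
    folds = assign_folds(data.labels, k, seed)
    y = dummy.y
    ss_y = float(np.sum((y - y.mean()) ** 2))

    press_by_A: dict[int, float] = {}
    q2_by_A: dict[int, float] = {}

    def evaluate(A: int):
        y_cv, t_cv, t_o1 = _cv_arrays(data.values, y, folds, A, mode)
        press = float(np.sum((y - y_cv) ** 2))
        press_by_A[A] = press
        q2_by_A[A] = 1.0 - press / ss_y
        return y_cv, t_cv, t_o1

    best = evaluate(0)
    chosen = 0
    for A in range(1, max_orth + 1):
        try:
            candidate = evaluate(A)
        except RankError:
            break
        if q2_by_A[A] - q2_by_A[chosen] > q2_gain_threshold:
            chosen = A
            best = candidate
        else:
            break

    y_cv, t_cv, t_o1 = best
    return CvResult(
        y_cv=y_cv, t_cv=t_cv, t_orth1_cv=t_o1,
        press_by_A=press_by_A, q2_by_A=q2_by_A, chosen_A=chosen,
        fold_assignment=folds,
        sample_ids=list(data.sample_ids),
        labels=list(data.labels) if data.labels is not None else [],
    )
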