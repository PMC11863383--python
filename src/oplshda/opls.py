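"""Two-class OPLS(-DA): one predictive latent component plus orthogonal ones.

The model decomposes a preprocessed predictor matrix X into a predictive part
``t_pred p_pred'`` that carries the variation correlated with the 0/1 dummy
response, orthogonal parts ``T_orth P_orth'`` that carry systematic variation
uncorrelated with the response (within-class variation in the discriminant
setting), and a residual E:

    X = t_pred p_pred' + T_orth P_orth' + E
    y = q t_pred + f

With a single response vector the PLS weight has the closed form
``w = X'y / ||X'y||``, so fitting is fully deterministic: each orthogonal
component is the response-orthogonal part of the current loading, its
variation is deflated from X, and the single predictive component is
extracted last.  Predictions from a model with ``a`` orthogonal components
are identical to those of an ``(a+1)``-component PLS regression on the same
data — the orthogonal split changes interpretation, not predictive power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import (
    DegenerateResponseError,
    DummyResponse,
    Preprocessor,
    RankError,
    ShapeError,
)

_TOL = 1e-12


@dataclass
class OplsModel:
    """A fitted two-class OPLS(-DA) model.

    All weight vectors have unit norm; ``w_pred`` is orthogonal to every
    column of ``W_orth`` and ``t_pred`` to every column of ``T_orth``.
    ``y_mean`` is the training response mean, added back so predictions land
    on the original 0/1 dummy scale (0.5-centered for balanced groups).
    """

    w_pred: np.ndarray          # (p,)
    p_pred: np.ndarray          # (p,)
    t_pred: np.ndarray          # (n_train,)
    q: float
    W_orth: np.ndarray          # (p, A_orth)
    P_orth: np.ndarray          # (p, A_orth)
    T_orth: np.ndarray          # (n_train, A_orth)
    n_orth: int
    preprocessor: Preprocessor | None
    dummy: DummyResponse | None
    y_mean: float
    residual_X: np.ndarray      # E, (n_train, p)
    residual_y: np.ndarray      # f, (n_train,)

    @property
    def n_variables(self) -> int:
        return self.w_pred.shape[0]

    @property
    def fitted_y(self) -> np.ndarray:
        """Fitted responses of the training samples, on the dummy scale."""
        return self.q * self.t_pred + self.y_mean

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "w_pred": self.w_pred.tolist(),
            "p_pred": self.p_pred.tolist(),
            "t_pred": self.t_pred.tolist(),
            "q": self.q,
            "W_orth": self.W_orth.tolist(),
            "P_orth": self.P_orth.tolist(),
            "T_orth": self.T_orth.tolist(),
            "n_orth": self.n_orth,
            "preprocessor": None if self.preprocessor is None
            else self.preprocessor.to_dict(),
            "dummy": None if self.dummy is None else self.dummy.to_dict(),
            "y_mean": self.y_mean,
            "residual_X": self.residual_X.tolist(),
            "residual_y": self.residual_y.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OplsModel":
        p = len(d["w_pred"])
        n = len(d["t_pred"])
        a = int(d["n_orth"])
        return cls(
            w_pred=np.array(d["w_pred"], dtype=float),
            p_pred=np.array(d["p_pred"], dtype=float),
            t_pred=np.array(d["t_pred"], dtype=float),
            q=float(d["q"]),
            W_orth=np.array(d["W_orth"], dtype=float).reshape(p, a),
            P_orth=np.array(d["P_orth"], dtype=float).reshape(p, a),
            T_orth=np.array(d["T_orth"], dtype=float).reshape(n, a),
            n_orth=a,
            preprocessor=None if d["preprocessor"] is None
            else Preprocessor.from_dict(d["preprocessor"]),
            dummy=None if d["dummy"] is None
            else DummyResponse.from_dict(d["dummy"]),
            y_mean=float(d["y_mean"]),
            residual_X=np.array(d["residual_X"], dtype=float).reshape(n, p),
            residual_y=np.array(d["residual_y"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "OplsModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def max_orthogonal_components(n_samples: int, n_variables: int) -> int:
    """Upper bound on extractable orthogonal components.

    One direction is consumed by the predictive component; centering removes
    one degree of freedom from the sample space.
    """
    return max(0, min(n_samples - 2, n_variables - 1))


def fit_opls(X: np.ndarray, y: np.ndarray, n_orth: int, *,
             preprocessor: Preprocessor | None = None,
             y_mean: float = 0.0,
             dummy: DummyResponse | None = None) -> OplsModel:
    """Fit an OPLS model on an already-preprocessed X and centered y.

    Parameters
    ----------
    X
        Preprocessed (centered, optionally scaled) matrix, ``(n, p)``.
    y
        Centered response vector, ``(n,)``; must have nonzero variance.
    n_orth
        Number of orthogonal components to extract before the single
        predictive component.
    preprocessor, y_mean, dummy
        Training-state bookkeeping stored on the model so that
        :func:`predict_opls` can consume raw matrices and return predictions
        on the original dummy scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ShapeError("X must be 2-D with >= 2 rows and >= 1 column")
    if y.shape != (X.shape[0],):
        raise ShapeError(
            f"y has length {y.shape}, expected ({X.shape[0]},)")
    if np.ptp(y) < _TOL:
        raise DegenerateResponseError("response is constant")
    if n_orth < 0:
        raise RankError("n_orth must be >= 0")
    bound = max_orthogonal_components(*X.shape)
    if n_orth > bound:
        raise RankError(
            f"n_orth={n_orth} exceeds the extractable bound {bound} for "
            f"a {X.shape[0]}x{X.shape[1]} matrix")

    n, p = X.shape
    # Single-y PLS weight: closed form, no iteration needed.
    w = X.T @ y
    w_norm = np.linalg.norm(w)
    if w_norm < _TOL:
        raise DegenerateResponseError("X carries no covariance with y")
    w = w / w_norm

    Xd = X.copy()
    W_orth = np.zeros((p, n_orth))
    P_orth = np.zeros((p, n_orth))
    T_orth = np.zeros((n, n_orth))
    for a in range(n_orth):
        t = Xd @ w
        tt = t @ t
        if tt < _TOL:
            raise RankError(
                f"orthogonal component {a + 1}: predictive score collapsed "
                f"(extractable bound reached)")
        p_load = Xd.T @ t / tt
        w_o = p_load - (w @ p_load) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-10 * max(1.0, np.linalg.norm(p_load)):
            raise RankError(
                f"no orthogonal variation left for component {a + 1} "
                f"(extractable bound is {a})")
        w_o = w_o / norm_o
        t_o = Xd @ w_o
        tto = t_o @ t_o
        if tto < _TOL:
            raise RankError(
                f"orthogonal component {a + 1} has zero score variance")
        p_o = Xd.T @ t_o / tto
        Xd = Xd - np.outer(t_o, p_o)
        W_orth[:, a] = w_o
        P_orth[:, a] = p_o
        T_orth[:, a] = t_o

    # Deflating by y-orthogonal components leaves X'y — and hence w — intact,
    # so the predictive weight is extracted from the deflated matrix directly.
    t_pred = Xd @ w
    tt = t_pred @ t_pred
    if tt < _TOL:
        raise RankError("predictive component has zero score variance")
    p_pred = Xd.T @ t_pred / tt
    q = float(y @ t_pred / tt)
    residual_X = Xd - np.outer(t_pred, p_pred)
    residual_y = y - q * t_pred

    return OplsModel(
        w_pred=w, p_pred=p_pred, t_pred=t_pred, q=q,
        W_orth=W_orth, P_orth=P_orth, T_orth=T_orth, n_orth=n_orth,
        preprocessor=preprocessor, dummy=dummy, y_mean=float(y_mean),
        residual_X=residual_X, residual_y=residual_y,
    )


def fit_opls_da(X_raw: np.ndarray, dummy: DummyResponse, n_orth: int,
                mode: str = "uv") -> OplsModel:
    """Preprocess raw X, center the dummy response, and fit OPLS-DA."""
    from .data_model import fit_preprocessor

    pre = fit_preprocessor(X_raw, mode=mode)
    Xp = pre.transform(X_raw)
    y_mean = float(dummy.y.mean())
    return fit_opls(Xp, dummy.y - y_mean, n_orth,
                    preprocessor=pre, y_mean=y_mean, dummy=dummy)


def predict_opls(model: OplsModel, X_new: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply a fitted model to raw samples.

    The stored preprocessor is applied, orthogonal variation is removed
    component by component, and the remainder is projected onto the
    predictive weight.  Returns ``(y_hat, t_pred_new, T_orth_new)`` with
    ``y_hat`` on the original dummy scale.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_variables:
        raise ShapeError(
            f"X_new has {X_new.shape[1]} columns, model expects "
            f"{model.n_variables}")
    if model.preprocessor is not None:
        Xp = model.preprocessor.transform(X_new)
    else:
        Xp = X_new.copy()
    T_orth_new = np.zeros((Xp.shape[0], model.n_orth))
    for a in range(model.n_orth):
        t_o = Xp @ model.W_orth[:, a]
        Xp = Xp - np.outer(t_o, model.P_orth[:, a])
        T_orth_new[:, a] = t_o
    t_pred_new = Xp @ model.w_pred
    y_hat = model.q * t_pred_new + model.y_mean
    return y_hat, t_pred_new, T_orth_new
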