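import json

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from oplshda import (
    DegenerateResponseError,
    RankError,
    encode_dummy,
    fit_opls,
    fit_opls_da,
    predict_opls,
)
from oplshda.data_model import fit_preprocessor
from oplshda.opls import OplsModel, max_orthogonal_components


def _centered_fit(X, y, n_orth):
    pre = fit_preprocessor(X, mode="center")
    return fit_opls(pre.transform(X), y - y.mean(), n_orth,
                    preprocessor=pre, y_mean=float(y.mean()))


def test_single_column_equal_to_y_is_perfect(rng):
    y = rng.normal(size=10)
    X = y[:, None].copy()
    model = _centered_fit(X, y, 0)
    yc = y - y.mean()
    # predictive score proportional to the (centered) column
    corr = np.corrcoef(model.t_pred, yc)[0, 1]
    assert abs(corr) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(model.residual_y, 0.0, atol=1e-12)


@pytest.mark.parametrize("n_orth", [0, 1, 2, 3])
def test_decomposition_invariants(rng, n_orth):
    """X reconstructs from predictive + orthogonal parts + residual, and
    scores/weights are mutually orthogonal."""
    X = rng.normal(size=(15, 8))
    y = rng.normal(size=15)
    pre = fit_preprocessor(X, mode="uv")
    Xp = pre.transform(X)
    model = fit_opls(Xp, y - y.mean(), n_orth)
    recon = (np.outer(model.t_pred, model.p_pred)
             + model.T_orth @ model.P_orth.T + model.residual_X)
    err = np.linalg.norm(recon - Xp) / np.linalg.norm(Xp)
    assert err < 1e-8
    fitted = model.q * model.t_pred + model.residual_y
    np.testing.assert_allclose(fitted, y - y.mean(), atol=1e-8)
    for a in range(n_orth):
        t_o = model.T_orth[:, a]
        cos = abs(model.t_pred @ t_o) / (
            np.linalg.norm(model.t_pred) * np.linalg.norm(t_o))
        assert cos < 1e-8
        assert abs(model.w_pred @ model.W_orth[:, a]) < 1e-8


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("n_orth", [0, 1, 2])
def test_opls_matches_pls_predictions(seed, n_orth):
    """One predictive + a orthogonal components predict identically to an
    (a+1)-component PLS regression — the orthogonal split moves variation
    between parts without changing the fit."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 41))
    p = int(rng.integers(3, 61))
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    model = _centered_fit(X, y, n_orth)
    X_test = rng.normal(size=(7, p))
    y_opls, _, _ = predict_opls(model, X_test)
    pls = PLSRegression(n_components=n_orth + 1, scale=False).fit(X, y)
    y_pls = pls.predict(X_test).ravel()
    np.testing.assert_allclose(y_opls, y_pls, atol=1e-8)


def test_recovers_constructed_orthogonal_component(rng):
    """X built as y*p' + t_o*p_o' with t_o orthogonal to y: the fitted
    orthogonal score spans t_o.  p_o overlaps p so the orthogonal
    variation actually disturbs the predictive loading (fully decoupled
    variation leaves predictions untouched and is never extracted)."""
    n = 6
    y = rng.normal(size=n)
    y -= y.mean()
    t_o = rng.normal(size=n)
    t_o -= t_o.mean()
    t_o -= (t_o @ y) / (y @ y) * y          # exact orthogonality
    p_vec = np.array([1.0, 0.0, 0.0])
    p_o = np.array([0.6, 1.0, 0.5])
    X = np.outer(y, p_vec) + np.outer(t_o, p_o)
    model = fit_opls(X, y, 1)
    fit_to = model.T_orth[:, 0]
    cos = abs(fit_to @ t_o) / (np.linalg.norm(fit_to) * np.linalg.norm(t_o))
    angle = np.arccos(min(cos, 1.0))
    assert angle < 1e-6


def test_predict_training_matches_fitted(rng):
    X = rng.normal(size=(12, 5))
    y = rng.normal(size=12)
    model = _centered_fit(X, y, 2)
    y_hat, t_hat, _ = predict_opls(model, X)
    np.testing.assert_allclose(y_hat, model.fitted_y, atol=1e-10)
    np.testing.assert_allclose(t_hat, model.t_pred, atol=1e-10)


def test_duplicated_row_gives_identical_predictions(rng):
    X = rng.normal(size=(10, 4))
    y = rng.normal(size=10)
    model = _centered_fit(X, y, 1)
    row = np.tile(X[3], (3, 1))
    y_hat, _, _ = predict_opls(model, row)
    assert y_hat[0] == y_hat[1] == y_hat[2]


def test_mean_shift_absorbed_by_centering(rng):
    """Predicting X_new and X_new refit after a global column-mean shift
    of the training data gives the same y_hat: centering removes it."""
    X = rng.normal(size=(12, 4))
    y = rng.normal(size=12)
    shift = rng.normal(size=4) * 10
    m1 = _centered_fit(X, y, 1)
    m2 = _centered_fit(X + shift, y, 1)
    X_new = rng.normal(size=(5, 4))
    y1, _, _ = predict_opls(m1, X_new)
    y2, _, _ = predict_opls(m2, X_new + shift)
    np.testing.assert_allclose(y1, y2, atol=1e-8)


def test_deterministic_refit_bitwise(rng):
    X = rng.normal(size=(14, 6))
    y = rng.normal(size=14)
    m1 = _centered_fit(X, y, 2)
    m2 = _centered_fit(X.copy(), y.copy(), 2)
    assert np.array_equal(m1.w_pred, m2.w_pred)
    assert np.array_equal(m1.T_orth, m2.T_orth)
    assert m1.q == m2.q


def test_constant_y_raises():
    X = np.eye(4)
    with pytest.raises(DegenerateResponseError):
        fit_opls(X, np.zeros(4), 0)


def test_rank_bound_error_names_bound(rng):
    X = rng.normal(size=(5, 3))
    y = rng.normal(size=5)
    bound = max_orthogonal_components(5, 3)
    with pytest.raises(RankError, match=str(bound)):
        fit_opls(X - X.mean(0), y - y.mean(), bound + 1)


def test_json_roundtrip_preserves_predictions_bitwise(tmp_path, rng):
    X = rng.normal(size=(16, 6))
    labels = ["a"] * 8 + ["b"] * 8
    dummy = encode_dummy(labels, {"a"}, {"b"})
    model = fit_opls_da(X, dummy, 2, mode="uv")
    path = tmp_path / "model.json"
    model.to_json(path)
    back = OplsModel.from_json(path)
    X_new = rng.normal(size=(6, 6))
    y1, t1, o1 = predict_opls(model, X_new)
    y2, t2, o2 = predict_opls(back, X_new)
    assert np.array_equal(y1, y2)
    assert np.array_equal(t1, t2)
    assert np.array_equal(o1, o2)
    assert back.dummy.class0 == frozenset({"a"})
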