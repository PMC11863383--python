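import numpy as np
import pytest

from oplshda import (
    ConfigurationError,
    assign_folds,
    cross_validate,
    encode_dummy,
    select_n_orth,
)
from conftest import make_dataset


# ---------------------------------------------------------------------------
# assign_folds
# ---------------------------------------------------------------------------

def test_folds_balanced_single_class():
    folds = assign_folds(["a"] * 14, k=7, seed=0)
    counts = np.bincount(folds, minlength=7)
    assert (counts == 2).all()


def test_folds_stratified_two_classes():
    labels = ["a"] * 7 + ["b"] * 7
    folds = assign_folds(labels, k=7, seed=3)
    for f in range(7):
        members = [labels[i] for i in np.flatnonzero(folds == f)]
        assert sorted(members) == ["a", "b"]


def test_folds_deterministic():
    labels = ["a"] * 9 + ["b"] * 5
    f1 = assign_folds(labels, k=4, seed=11)
    f2 = assign_folds(labels, k=4, seed=11)
    np.testing.assert_array_equal(f1, f2)


def test_small_class_spread_over_distinct_folds():
    labels = ["a"] * 10 + ["b"] * 3
    folds = assign_folds(labels, k=7, seed=5)
    b_folds = folds[10:]
    assert len(set(b_folds.tolist())) == 3


def test_folds_within_class_sizes_differ_by_at_most_one():
    labels = ["a"] * 11 + ["b"] * 6
    folds = assign_folds(labels, k=4, seed=2)
    for cls, sl in (("a", slice(0, 11)), ("b", slice(11, 17))):
        counts = np.bincount(folds[sl], minlength=4)
        assert counts.max() - counts.min() <= 1


def test_k_below_two_rejected():
    with pytest.raises(ConfigurationError):
        assign_folds(["a", "a", "b", "b"], k=1, seed=0)


# ---------------------------------------------------------------------------
# cross_validate
# ---------------------------------------------------------------------------

def test_separable_classes_predict_near_targets(rng):
    """Two perfectly separated point clouds on one informative variable:
    every cross-validated prediction lands near its 0/1 target."""
    n = 14
    x = np.r_[rng.normal(0.0, 0.05, n), rng.normal(6.0, 0.05, n)]
    d = make_dataset(x[:, None], ["low"] * n + ["high"] * n)
    dummy = encode_dummy(d.labels, {"low"}, {"high"})
    y_cv, t_cv, press = cross_validate(d, dummy, n_orth=0, k=7, seed=0)
    assert np.all(np.abs(y_cv - dummy.y) < 0.1)
    assert press < 0.1 * len(y_cv)


def test_leave_one_out_structure(rng):
    X = rng.normal(size=(6, 3))
    X[3:, 0] += 5.0
    d = make_dataset(X, ["a"] * 3 + ["b"] * 3)
    dummy = encode_dummy(d.labels, {"a"}, {"b"})
    y_cv, _, _ = cross_validate(d, dummy, n_orth=0, k=6, seed=0)
    assert y_cv.shape == (6,)
    assert np.all(np.isfinite(y_cv))


def test_y_cv_permutes_with_rows(rng):
    X = rng.normal(size=(20, 6))
    X[10:, 0] += 3.0
    d = make_dataset(X, ["a"] * 10 + ["b"] * 10)
    dummy = encode_dummy(d.labels, {"a"}, {"b"})
    folds = assign_folds(d.labels, 5, seed=1)
    y_cv, _, _ = cross_validate(d, dummy, 1, folds=folds)
    perm = rng.permutation(20)
    dp = d.subset_rows(perm)
    dummyp = encode_dummy(dp.labels, {"a"}, {"b"})
    y_cvp, _, _ = cross_validate(dp, dummyp, 1, folds=folds[perm])
    np.testing.assert_allclose(y_cvp, y_cv[perm], atol=1e-12)


# ---------------------------------------------------------------------------
# select_n_orth
# ---------------------------------------------------------------------------

def test_no_orthogonal_structure_chooses_zero(rng):
    """y depends on one X direction; remaining columns are tiny noise."""
    n = 24
    y_dir = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    X = rng.normal(size=(n, 5)) * 0.05
    X[:, 0] += y_dir * 4.0
    d = make_dataset(X, ["a"] * (n // 2) + ["b"] * (n // 2))
    dummy = encode_dummy(d.labels, {"a"}, {"b"})
    res = select_n_orth(d, dummy, k=7, seed=0, mode="center")
    assert res.chosen_A == 0


def test_masking_orthogonal_variance_selected(rng):
    """A dominant y-orthogonal variance component contaminates the raw
    predictive direction; removing it as an orthogonal component must
    improve cross-validated prediction."""
    n = 30
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    yc = y - y.mean()
    t_o = rng.normal(size=n)
    t_o -= t_o.mean()
    t_o -= (t_o @ yc) / (yc @ yc) * yc
    v1 = np.zeros(8); v1[0] = 1.0
    v2 = np.zeros(8); v2[1] = 1.0
    X = (np.outer(yc, v1) + 10.0 * np.outer(t_o, v2)
         + rng.normal(size=(n, 8)) * 0.05)
    d = make_dataset(X, ["a"] * (n // 2) + ["b"] * (n // 2))
    dummy = encode_dummy(d.labels, {"a"}, {"b"})
    res = select_n_orth(d, dummy, k=7, seed=0, mode="center")
    assert res.chosen_A >= 1
    assert res.q2_by_A[1] > res.q2_by_A[0]


def test_max_orth_zero_forces_zero(two_blob_dataset):
    d = two_blob_dataset
    dummy = encode_dummy(d.labels, {"low"}, {"high"})
    res = select_n_orth(d, dummy, max_orth=0)
    assert res.chosen_A == 0
    assert list(res.press_by_A) == [0]


def test_chosen_press_not_worse_than_zero_component(rng):
    for seed in range(5):
        local = np.random.default_rng(seed)
        X = local.normal(size=(26, 10))
        X[13:, :2] += 1.5
        d = make_dataset(X, ["a"] * 13 + ["b"] * 13)
        dummy = encode_dummy(d.labels, {"a"}, {"b"})
        res = select_n_orth(d, dummy, seed=seed)
        if res.chosen_A > 0:
            assert res.press <= res.press_by_A[0]


def test_permuted_labels_no_signal(rng):
    """Label permutation destroys class information: Q² stays near or
    below zero — guards against train/test leakage in the CV loop."""
    X = rng.normal(size=(30, 20))
    base = ["a"] * 15 + ["b"] * 15
    q2s = []
    for i in range(20):
        labels = list(rng.permutation(base))
        d = make_dataset(X, labels)
        dummy = encode_dummy(d.labels, {"a"}, {"b"})
        res = select_n_orth(d, dummy, k=5, seed=i)
        q2s.append(res.q2)
    assert np.median(q2s) <= 0.05


def test_cvresult_frame_columns(two_blob_dataset):
    d = two_blob_dataset
    dummy = encode_dummy(d.labels, {"low"}, {"high"})
    res = select_n_orth(d, dummy)
    frame = res.to_frame()
    assert list(frame.columns) == ["sample_id", "fold", "y_cv", "t_cv"]
    assert len(frame) == d.n_samples
    assert res.q2 <= 1.0
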