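import numpy as np
import pytest

from oplshda import (
    BuildError,
    RunConfig,
    ValidationError,
    accuracy,
    build_hda,
    confusion_matrix,
    encode_dummy,
    fit_opls_da,
    make_iris_like,
    predict_hda,
    predict_opls,
    route_direction,
    select_n_orth,
    whitefish_like_spec,
    make_hierarchical,
)
from oplshda.synthetic import iris_class_means
from conftest import make_dataset


@pytest.fixture(scope="module")
def iris_model():
    data = make_iris_like(7, 40)
    return data, build_hda(data)


def test_iris_structure(iris_model):
    """Two splits; the top split isolates the compact outlying class."""
    data, model = iris_model
    assert len(model.nodes) == 2
    top = model.nodes[0]
    sides = (top.left_classes, top.right_classes)
    assert frozenset({"setosa"}) in sides
    assert frozenset({"versicolor", "virginica"}) in sides


def test_iris_grid_matches_nearest_mean_in_clear_regions(iris_model):
    """On grid points that clearly belong to one class's territory the
    tree agrees with the nearest-class-mean rule >= 95% of the time."""
    data, model = iris_model
    means = iris_class_means()
    names = sorted(means)
    centers = np.array([means[c] for c in names])
    sds = {"setosa": 0.15, "versicolor": 0.35, "virginica": 0.40}
    radii = np.array([2 * sds[c] for c in names])

    g1, g2 = np.meshgrid(np.linspace(0.5, 6.5, 60),
                         np.linspace(-0.5, 3.0, 60))
    grid = np.column_stack([g1.ravel(), g2.ravel()])
    dist = np.linalg.norm(grid[:, None, :] - centers[None], axis=2)
    inside = dist <= radii[None, :]
    clear = inside.sum(axis=1) == 1
    grid = grid[clear]
    nearest = [names[i] for i in dist[clear].argmin(axis=1)]
    pred, _ = predict_hda(model, grid)
    agreement = np.mean([a == b for a, b in zip(pred, nearest)])
    assert agreement >= 0.95


def test_two_class_tree_reduces_to_plain_opls(rng):
    X = rng.normal(size=(24, 6))
    X[12:, 0] += 4.0
    data = make_dataset(X, ["a"] * 12 + ["b"] * 12)
    model = build_hda(data)
    assert len(model.nodes) == 1
    node = model.nodes[0]
    X_new = rng.normal(size=(10, 6))
    X_new[5:, 0] += 4.0
    labels, paths = predict_hda(model, X_new)
    y_hat, _, _ = predict_opls(node.model, X_new)
    left_name = next(iter(node.left_classes))
    right_name = next(iter(node.right_classes))
    expected = [right_name if yh >= node.threshold else left_name
                for yh in y_hat]
    assert labels == expected


def test_twelve_classes_eleven_nodes_66_records():
    data, _ = make_hierarchical(whitefish_like_spec(seed=5, n_per_class=8))
    model = build_hda(data, RunConfig(cv_folds=4))
    assert len(model.nodes) == 11
    assert len(model.pair_records) == 66
    # every class reachable by exactly one root-to-leaf path
    leaves = {next(iter(n.member_classes))
              for n in model.dendrogram.nodes if n.is_leaf}
    assert leaves == set(model.class_names)


def test_training_samples_routed_home(two_blob_dataset):
    model = build_hda(two_blob_dataset)
    labels, paths = predict_hda(model, two_blob_dataset.values)
    correct = np.mean([a == b for a, b in
                       zip(labels, two_blob_dataset.labels)])
    assert correct >= 0.99
    assert all(len(p) <= len(model.class_names) - 1 for p in paths)


def test_tie_routes_right():
    assert route_direction(0.5, 0.5) == "right"
    assert route_direction(0.4999999, 0.5) == "left"
    assert route_direction(0.6, 0.5) == "right"


def test_node_threshold_between_group_means(iris_model):
    data, model = iris_model
    for node in model.nodes:
        fitted = node.model.fitted_y
        y = node.model.dummy.y
        m0 = fitted[y == 0].mean()
        m1 = fitted[y == 1].mean()
        lo, hi = min(m0, m1), max(m0, m1)
        assert lo < node.threshold < hi
        assert node.model.dummy.class0 == node.left_classes
        assert node.model.dummy.class1 == node.right_classes


def test_split_numbering_by_decreasing_height(iris_model):
    _, model = iris_model
    heights = [model.dendrogram.node(n.dendro_id).height
               for n in model.nodes]
    assert heights == sorted(heights, reverse=True)
    assert [n.split_id for n in model.nodes] == [1, 2]


def test_build_deterministic_serialization(two_blob_dataset):
    m1 = build_hda(two_blob_dataset)
    m2 = build_hda(two_blob_dataset)
    import json
    assert json.dumps(m1.to_dict()) == json.dumps(m2.to_dict())


def test_model_json_roundtrip_predictions(tmp_path, iris_model):
    from oplshda import HdaModel

    data, model = iris_model
    path = tmp_path / "hda.json"
    model.to_json(path)
    back = HdaModel.from_json(path)
    X = make_iris_like(99, 10).values
    l1, p1 = predict_hda(model, X)
    l2, p2 = predict_hda(back, X)
    assert l1 == l2
    assert p1 == p2


def test_build_error_on_tiny_side(rng):
    # one class with only 2 samples is legal, but forcing its side below 2
    # is impossible through the public API; instead check the degenerate
    # guard directly via a 2-sample class dataset with k small enough
    X = rng.normal(size=(10, 3))
    X[:2, 0] += 10
    X[2:6, 1] += 10
    data = make_dataset(X, ["a"] * 2 + ["b"] * 4 + ["c"] * 4)
    model = build_hda(data, RunConfig(cv_folds=2))
    assert len(model.nodes) == 2


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

def test_confusion_perfect_diagonal():
    conf = confusion_matrix(["a", "b", "b"], ["a", "b", "b"], ["a", "b"])
    np.testing.assert_array_equal(conf, [[1, 0], [0, 2]])
    assert accuracy(conf) == 1.0


def test_confusion_single_predicted_column():
    conf = confusion_matrix(["a", "b", "c"], ["b", "b", "b"],
                            ["a", "b", "c"])
    assert conf[:, 1].sum() == 3
    assert conf.sum() == 3


def test_confusion_one_swap_counts():
    true = ["a"] * 3 + ["b"] * 3
    pred = ["a", "a", "b", "b", "b", "b"]  # one a predicted as b
    conf = confusion_matrix(true, pred, ["a", "b"])
    assert conf[0, 1] == 1
    assert accuracy(conf) == pytest.approx(5 / 6)


def test_confusion_rows_are_actual():
    conf = confusion_matrix(["a", "a", "b"], ["b", "b", "b"], ["a", "b"])
    # actual a row has the misclassifications
    np.testing.assert_array_equal(conf, [[0, 2], [0, 1]])


def test_confusion_unknown_label_raises():
    with pytest.raises(ValidationError):
        confusion_matrix(["a"], ["z"], ["a", "b"])
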