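"""Seeded synthetic datasets with known class geometry and known hierarchy.

Two generators cover the geometries the method is built for:

* :func:`make_iris_like` — three Gaussian classes in two dimensions with
  collinear means and unequal spacing (one compact outlying class, two
  adjacent overlapping ones).  This is the layout where a flat one-vs-rest
  discriminant fails — its boundaries share a common center while the middle
  class needs two separate cuts — and where a hierarchical model places both
  cuts correctly.
* :func:`make_hierarchical` — multiclass Gaussian data whose class means are
  generated by walking a declared binary grouping tree, adding opposed
  offsets (+v / −v along a seeded random direction) at each split with a
  per-level decay.  The generative topology is returned so dendrogram
  recovery can be scored exactly.  Appended pure-noise variables exercise
  scaling and orthogonal-component selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ConfigurationError, Dataset, ValidationError

# Class means mimic petal length/width centroids: a compact outlying class
# and two adjacent classes, all three centers exactly collinear.
_IRIS_BASE = np.array([1.46, 0.25])
_IRIS_FAR = np.array([5.55, 2.03])
_IRIS_MID_FRAC = 0.68
_IRIS_SDS = {"setosa": 0.15, "versicolor": 0.35, "virginica": 0.40}


def make_iris_like(seed: int, n_per_class: int = 50) -> Dataset:
    """Three collinear Gaussian classes in 2-D (petal-like layout).

    ``setosa`` is compact and outlying; ``versicolor`` sits between
    ``setosa`` and ``virginica`` on the segment joining their means, so the
    three classes are separated along the same direction at different
    scales.
    """
    if n_per_class < 4:
        raise ConfigurationError("n_per_class must be >= 4")
    rng = np.random.default_rng(seed)
    means = {
        "setosa": _IRIS_BASE,
        "versicolor": _IRIS_BASE + _IRIS_MID_FRAC * (_IRIS_FAR - _IRIS_BASE),
        "virginica": _IRIS_FAR,
    }
    rows, labels, ids = [], [], []
    for cls in sorted(means):
        pts = means[cls] + rng.normal(0.0, _IRIS_SDS[cls], (n_per_class, 2))
        rows.append(pts)
        labels += [cls] * n_per_class
        ids += [f"{cls}_{i}" for i in range(n_per_class)]
    return Dataset(values=np.vstack(rows), sample_ids=ids,
                   variable_names=["petal_length", "petal_width"],
                   labels=labels)


def iris_class_means() -> dict[str, np.ndarray]:
    """The generative class means of :func:`make_iris_like`."""
    return {
        "setosa": _IRIS_BASE.copy(),
        "versicolor": _IRIS_BASE + _IRIS_MID_FRAC * (_IRIS_FAR - _IRIS_BASE),
        "virginica": _IRIS_FAR.copy(),
    }


@dataclass
class HierarchySpec:
    """Recipe for hierarchically structured multiclass Gaussian data.

    ``tree`` is a nested binary grouping of class names, e.g.
    ``(("a", "b"), ("c", ("d", "e")))``.  Each split displaces its two
    subtrees in opposite directions by ``between_scale * level_decay**depth``
    along a seeded random unit vector; successive split directions are
    orthogonalized against all earlier ones (while dimensions remain), so
    each level of class variation occupies its own subspace and sibling
    separation at depth ``k`` is exactly ``2 * between_scale * level_decay**k``
    in units of ``within_sd``.  Samples add isotropic Gaussian noise of SD
    ``within_sd``; ``n_noise_variables`` pure standard-normal columns are
    appended.
    """

    tree: tuple
    class_sizes: dict[str, int]
    n_variables: int
    between_scale: float
    within_sd: float
    n_noise_variables: int = 0
    seed: int = 0
    level_decay: float = 0.5

    def __post_init__(self) -> None:
        if self.between_scale < 0:
            raise ConfigurationError("between_scale must be >= 0")
        if self.within_sd <= 0:
            raise ConfigurationError("within_sd must be > 0")
        if self.level_decay <= 0:
            raise ConfigurationError("level_decay must be > 0")
        leaves = _tree_leaves(self.tree)
        if len(leaves) != len(set(leaves)):
            raise ValidationError("duplicate class name in tree")
        missing = set(leaves) - set(self.class_sizes)
        if missing:
            raise ValidationError(
                f"no class size given for {sorted(missing)[0]!r}")
        small = [c for c in leaves if self.class_sizes[c] < 4]
        if small:
            raise ValidationError(
                f"class {small[0]!r} has size < 4")


def _tree_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out: list[str] = []
    for child in tree:
        out.extend(_tree_leaves(child))
    return out


def _walk_means(tree, depth: int, mean: np.ndarray, spec: HierarchySpec,
                rng: np.random.Generator, used: list[np.ndarray],
                out: dict[str, np.ndarray]) -> None:
    if isinstance(tree, str):
        out[tree] = mean
        return
    if len(tree) != 2:
        raise ValidationError("tree must be strictly binary")
    v = rng.normal(size=spec.n_variables)
    # each split direction orthogonal to all earlier ones, while the
    # dimensionality allows: levels of variation occupy disjoint subspaces
    for u in used:
        v = v - (v @ u) * u
    norm = np.linalg.norm(v)
    if norm < 1e-8:  # directions exhausted; fall back to a fresh random one
        v = rng.normal(size=spec.n_variables)
        norm = np.linalg.norm(v)
    v = v / norm
    if len(used) < spec.n_variables:
        used.append(v)
    offset = spec.between_scale * spec.level_decay ** depth
    _walk_means(tree[0], depth + 1, mean + offset * v, spec, rng, used, out)
    _walk_means(tree[1], depth + 1, mean - offset * v, spec, rng, used, out)


def make_hierarchical(spec: HierarchySpec) -> tuple[Dataset, tuple]:
    """Generate a dataset from a :class:`HierarchySpec`.

    Returns the dataset and the generative topology (the recipe's tree),
    for recovery scoring against the fitted dendrogram's clades.
    """
    rng = np.random.default_rng(spec.seed)
    means: dict[str, np.ndarray] = {}
    _walk_means(spec.tree, 0, np.zeros(spec.n_variables), spec, rng, [],
                means)

    rows, labels, ids = [], [], []
    for cls in sorted(means):
        n_c = spec.class_sizes[cls]
        pts = means[cls] + rng.normal(0.0, spec.within_sd,
                                      (n_c, spec.n_variables))
        if spec.n_noise_variables:
            noise = rng.normal(size=(n_c, spec.n_noise_variables))
            pts = np.hstack([pts, noise])
        rows.append(pts)
        labels += [cls] * n_c
        ids += [f"{cls}_{i}" for i in range(n_c)]
    names = [f"var_{j}" for j in range(spec.n_variables)]
    names += [f"noise_{j}" for j in range(spec.n_noise_variables)]
    data = Dataset(values=np.vstack(rows), sample_ids=ids,
                   variable_names=names, labels=labels)
    return data, spec.tree


def generative_means(spec: HierarchySpec) -> dict[str, np.ndarray]:
    """Class mean vectors the recipe generates (noise columns excluded)."""
    rng = np.random.default_rng(spec.seed)
    means: dict[str, np.ndarray] = {}
    _walk_means(spec.tree, 0, np.zeros(spec.n_variables), spec, rng, [],
                means)
    return means


def tree_clades(tree) -> set[frozenset[str]]:
    """Member sets of every internal node of a nested grouping tree."""
    clades: set[frozenset[str]] = set()

    def walk(node) -> frozenset[str]:
        if isinstance(node, str):
            return frozenset([node])
        members = frozenset().union(*(walk(c) for c in node))
        clades.add(members)
        return members

    walk(tree)
    return clades


def whitefish_like_spec(seed: int = 0, n_per_class: int = 28,
                        n_variables: int = 12, n_noise_variables: int = 4,
                        between_scale: float = 5.0, within_sd: float = 1.0
                        ) -> HierarchySpec:
    """A 12-class, two-level design: 4 groups x 3 subclasses.

    Mirrors a class structure with two nested sources of variation (e.g.
    sample state dominating species): the top splits separate the 4 groups,
    the deepest splits the 3 subclasses within each group.
    """
    def group(g: str) -> tuple:
        return (f"{g}1", (f"{g}2", f"{g}3"))

    tree = ((group("A"), group("B")), (group("C"), group("D")))
    sizes = {f"{g}{i}": n_per_class for g in "ABCD" for i in (1, 2, 3)}
    return HierarchySpec(tree=tree, class_sizes=sizes,
                         n_variables=n_variables,
                         between_scale=between_scale, within_sd=within_sd,
                         n_noise_variables=n_noise_variables, seed=seed)
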