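"""The hierarchical discriminant model: an OPLS-DA-populated decision tree.

The dendrogram from the class-distance stage fixes the tree topology; each
internal node then gets its own two-group OPLS-DA model that discriminates
the pooled classes of its left subtree (dummy 0) from those of its right
subtree (dummy 1), with orthogonal components selected by cross-validation
at that node.  A new sample starts at the root and moves left or right at
each node according to the node model's prediction against a threshold
placed midway between the two training-group mean fitted responses, until it
reaches a leaf — its predicted class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    BuildError,
    Dataset,
    ValidationError,
    encode_dummy,
)
from .opls import OplsModel, fit_opls_da, predict_opls
from .model_selection import CvResult, select_n_orth
from .class_distance import (
    ClassDistanceMatrix,
    PairModelRecord,
    pairwise_distance_matrix,
)
from .hierarchy import Dendrogram, agglomerate

logger = logging.getLogger(__name__)


def route_direction(y_hat: float, threshold: float) -> str:
    """Routing rule at a node: left if ``y_hat < threshold``, else right.

    A prediction exactly at the threshold goes right (the dummy-1 side) —
    a fixed, documented tie rule for determinism.
    """
    return "left" if y_hat < threshold else "right"


@dataclass
class HdaNode:
    """One decision split: a two-group OPLS-DA model over pooled classes."""

    split_id: int
    left_classes: frozenset[str]
    right_classes: frozenset[str]
    model: OplsModel
    cv: CvResult
    threshold: float
    dendro_id: int = -1

    def to_dict(self) -> dict:
        return {"split_id": self.split_id,
                "left_classes": sorted(self.left_classes),
                "right_classes": sorted(self.right_classes),
                "model": self.model.to_dict(),
                "cv": self.cv.to_dict(),
                "threshold": self.threshold,
                "dendro_id": self.dendro_id}

    @classmethod
    def from_dict(cls, d: dict) -> "HdaNode":
        return cls(split_id=int(d["split_id"]),
                   left_classes=frozenset(d["left_classes"]),
                   right_classes=frozenset(d["right_classes"]),
                   model=OplsModel.from_dict(d["model"]),
                   cv=CvResult.from_dict(d["cv"]),
                   threshold=float(d["threshold"]),
                   dendro_id=int(d["dendro_id"]))


@dataclass
class HdaModel:
    """The full hierarchical discriminant model.

    ``nodes`` holds one :class:`HdaNode` per internal dendrogram node,
    numbered 1..N-1 by decreasing merge height (split #1 = top split).
    ``pair_records`` is the build log of the N(N-1)/2 one-vs-one models that
    produced the distance matrix.
    """

    dendrogram: Dendrogram
    nodes: list[HdaNode]
    class_names: list[str]
    config: dict
    pair_records: list[PairModelRecord] = field(default_factory=list)
    variable_names: list[str] = field(default_factory=list)

    def node_for_dendro(self, dendro_id: int) -> HdaNode:
        return self._by_dendro[dendro_id]

    @property
    def _by_dendro(self) -> dict[int, HdaNode]:
        return {n.dendro_id: n for n in self.nodes}

    def to_dict(self) -> dict:
        return {"dendrogram": self.dendrogram.to_dict(),
                "nodes": [n.to_dict() for n in self.nodes],
                "class_names": list(self.class_names),
                "config": self.config,
                "variable_names": list(self.variable_names)}

    @classmethod
    def from_dict(cls, d: dict) -> "HdaModel":
        return cls(dendrogram=Dendrogram.from_dict(d["dendrogram"]),
                   nodes=[HdaNode.from_dict(nd) for nd in d["nodes"]],
                   class_names=list(d["class_names"]),
                   config=dict(d["config"]),
                   variable_names=list(d.get("variable_names", [])))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "HdaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_hda(data: Dataset, config=None, *,
              dist: ClassDistanceMatrix | None = None,
              records: list[PairModelRecord] | None = None) -> HdaModel:
    """Build the full model: distances -> dendrogram -> split models.

    A precomputed distance matrix (with its pair records) may be passed to
    skip the pairwise stage, e.g. when re-linking with a different linkage.
    """
    from .config import RunConfig

    if config is None:
        config = RunConfig()
    if dist is None:
        dist, records = pairwise_distance_matrix(data, config)
    dend = agglomerate(dist, linkage=config.linkage)

    nodes: list[HdaNode] = []
    for split_id, dnode in enumerate(dend.internal_by_height_desc(), start=1):
        left = dend.node(dnode.left).member_classes
        right = dend.node(dnode.right).member_classes
        sub = data.subset_classes(left | right)
        labels = np.asarray(sub.labels)
        n_left = int(np.isin(labels, sorted(left)).sum())
        n_right = len(labels) - n_left
        if n_left < 2 or n_right < 2:
            raise BuildError(
                f"split {split_id} ({sorted(left)} vs {sorted(right)}): "
                f"a side has fewer than 2 samples")
        dummy = encode_dummy(sub.labels, left, right)
        cv = select_n_orth(sub, dummy, k=config.cv_folds, seed=config.cv_seed,
                           max_orth=config.max_orth,
                           q2_gain_threshold=config.q2_gain_threshold,
                           mode=config.scaling)
        model = fit_opls_da(sub.values, dummy, cv.chosen_A,
                            mode=config.scaling)
        fitted = model.fitted_y
        mean0 = float(fitted[dummy.y == 0].mean())
        mean1 = float(fitted[dummy.y == 1].mean())
        threshold = 0.5 * (mean0 + mean1)
        logger.info("split %d: %s vs %s A_orth=%d Q2=%.3f threshold=%.3f",
                    split_id, sorted(left), sorted(right), cv.chosen_A,
                    cv.q2, threshold)
        nodes.append(HdaNode(split_id=split_id,
                             left_classes=frozenset(left),
                             right_classes=frozenset(right),
                             model=model, cv=cv, threshold=threshold,
                             dendro_id=dnode.id))

    return HdaModel(dendrogram=dend, nodes=nodes,
                    class_names=list(data.class_names),
                    config=config.to_dict(),
                    pair_records=list(records) if records else [],
                    variable_names=list(data.variable_names))


def predict_hda(model: HdaModel, X_new: np.ndarray
                ) -> tuple[list[str], list[list[tuple[int, float, str]]]]:
    """Classify samples by top-down traversal of the decision tree.

    Returns predicted class names and, per sample, the audit path: a list of
    ``(split_id, y_hat, direction)`` for every node visited.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    by_dendro = model._by_dendro
    dend = model.dendrogram
    n = X_new.shape[0]
    labels: list[str | None] = [None] * n
    paths: list[list[tuple[int, float, str]]] = [[] for _ in range(n)]

    # vectorized traversal: process all samples currently at each node
    frontier: dict[int, np.ndarray] = {dend.root_id: np.arange(n)}
    while frontier:
        dendro_id, idx = frontier.popitem()
        node = by_dendro[dendro_id]
        y_hat, _, _ = predict_opls(node.model, X_new[idx])
        go_right = y_hat >= node.threshold
        for i, yh, right in zip(idx, y_hat, go_right):
            paths[i].append((node.split_id, float(yh),
                             "right" if right else "left"))
        dnode = dend.node(dendro_id)
        for child_id, mask in ((dnode.left, ~go_right),
                               (dnode.right, go_right)):
            sel = idx[mask]
            if sel.size == 0:
                continue
            child = dend.node(child_id)
            if child.is_leaf:
                cls = next(iter(child.member_classes))
                for i in sel:
                    labels[i] = cls
            else:
                frontier[child_id] = sel
    return list(labels), paths


def confusion_matrix(true_labels, predicted, class_order
                     ) -> np.ndarray:
    """Count matrix with actual classes on rows and predicted on columns."""
    if len(true_labels) != len(predicted):
        raise ValidationError("label lists differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    mat = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted):
        if t not in index:
            raise ValidationError(f"unknown true label {t!r}")
        if p not in index:
            raise ValidationError(f"unknown predicted label {p!r}")
        mat[index[t], index[p]] += 1
    return mat


def accuracy(conf: np.ndarray) -> float:
    """Trace over total of a confusion matrix."""
    total = conf.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(conf) / total)


# ---------------------------------------------------------------------------
# One-vs-rest reference classifier
# ---------------------------------------------------------------------------

def fit_one_vs_rest(data: Dataset, config=None) -> dict[str, OplsModel]:
    """Flat one-vs-rest OPLS-DA baseline: one class-vs-rest model per class.

    All models share the full training set, so every decision boundary
    passes through a common center — the geometry that fails when one class
    lies between two others along the same direction.  Component counts are
    selected per model by the same cross-validated rule as the tree's nodes.
    """
    from .config import RunConfig

    if config is None:
        config = RunConfig()
    models: dict[str, OplsModel] = {}
    for cls in data.class_names:
        rest = set(data.class_names) - {cls}
        dummy = encode_dummy(data.labels, rest, {cls})
        cv = select_n_orth(data, dummy, k=config.cv_folds, seed=config.cv_seed,
                           max_orth=config.max_orth,
                           q2_gain_threshold=config.q2_gain_threshold,
                           mode=config.scaling)
        models[cls] = fit_opls_da(data.values, dummy, cv.chosen_A,
                                  mode=config.scaling)
    return models


def predict_one_vs_rest(models: dict[str, OplsModel], X_new: np.ndarray
                        ) -> list[str]:
    """Assign each sample to the class whose own-vs-rest response is largest."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    names = sorted(models)
    scores = np.column_stack([predict_opls(models[c], X_new)[0]
                              for c in names])
    return [names[i] for i in scores.argmax(axis=1)]
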