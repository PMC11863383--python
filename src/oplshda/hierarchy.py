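"""Agglomerative clustering of the class-distance matrix into a dendrogram.

Classes start as singleton clusters and the two closest clusters under the
chosen linkage are merged repeatedly; merge heights are Cohen's d values, so
the dendrogram's vertical axis reads directly as class separability.
Cluster-cluster distances are maintained with the Lance-Williams update
formulas.  Ties are broken lexicographically (the pair whose smallest member
class name sorts first) so the tree is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ConfigurationError
from .class_distance import ClassDistanceMatrix

LINKAGES = ("single", "complete", "average", "ward")

_NEWICK_SPECIAL = set("(),:;'\"[] \t\n")


@dataclass
class DendroNode:
    """One dendrogram node; leaves have ``left == right == None``."""

    id: int
    left: int | None
    right: int | None
    height: float
    member_classes: frozenset[str]

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class Dendrogram:
    """Binary merge tree over classes: N leaves at height 0, N-1 merges."""

    nodes: list[DendroNode]
    root_id: int
    class_names: list[str] = field(default_factory=list)

    def node(self, node_id: int) -> DendroNode:
        return self.nodes[node_id]

    @property
    def root(self) -> DendroNode:
        return self.nodes[self.root_id]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if n.is_leaf)

    @property
    def internal_nodes(self) -> list[DendroNode]:
        return [n for n in self.nodes if not n.is_leaf]

    def internal_by_height_desc(self) -> list[DendroNode]:
        """Internal nodes sorted by decreasing merge height (root first).

        Height ties are resolved by the smallest member-class name, matching
        the construction's own tie rule.
        """
        return sorted(self.internal_nodes,
                      key=lambda n: (-n.height, min(n.member_classes)))

    def clades(self) -> set[frozenset[str]]:
        """Member-class sets of all internal nodes (topology signature)."""
        return {n.member_classes for n in self.internal_nodes}

    def to_dict(self) -> dict:
        return {
            "root_id": self.root_id,
            "class_names": list(self.class_names),
            "nodes": [
                {"id": n.id, "left": n.left, "right": n.right,
                 "height": n.height,
                 "member_classes": sorted(n.member_classes)}
                for n in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Dendrogram":
        nodes = [DendroNode(id=nd["id"], left=nd["left"], right=nd["right"],
                            height=float(nd["height"]),
                            member_classes=frozenset(nd["member_classes"]))
                 for nd in d["nodes"]]
        return cls(nodes=nodes, root_id=int(d["root_id"]),
                   class_names=list(d["class_names"]))

    def linkage_frame(self) -> pd.DataFrame:
        """Merges in the conventional 4-column format.

        Columns: left child id, right child id, merge height, cluster size —
        internal nodes in merge (height-construction) order.
        """
        rows = [(n.left, n.right, n.height, len(n.member_classes))
                for n in self.nodes if not n.is_leaf]
        return pd.DataFrame(rows, columns=["left", "right", "height", "size"])


def _lance_williams(linkage: str, d_ki: float, d_kj: float, d_ij: float,
                    n_i: int, n_j: int, n_k: int) -> float:
    """Distance from cluster k to the merger of clusters i and j."""
    if linkage == "single":
        return min(d_ki, d_kj)
    if linkage == "complete":
        return max(d_ki, d_kj)
    if linkage == "average":
        return (n_i * d_ki + n_j * d_kj) / (n_i + n_j)
    if linkage == "ward":
        tot = n_i + n_j + n_k
        return np.sqrt(((n_k + n_i) * d_ki ** 2 + (n_k + n_j) * d_kj ** 2
                        - n_k * d_ij ** 2) / tot)
    raise ConfigurationError(
        f"unknown linkage {linkage!r}; choose from {LINKAGES}")


def agglomerate(dist: ClassDistanceMatrix, linkage: str = "average"
                ) -> Dendrogram:
    """Cluster the class-distance matrix bottom-up into a dendrogram.

    At every step the two active clusters at minimal linkage distance merge;
    the merge height is that distance.  The child whose lexicographically
    smallest member class sorts first becomes the left child.
    """
    if linkage not in LINKAGES:
        raise ConfigurationError(
            f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    names = dist.class_names
    n = len(names)
    if n < 2:
        raise ConfigurationError("need at least 2 classes to cluster")

    nodes = [DendroNode(id=i, left=None, right=None, height=0.0,
                        member_classes=frozenset([names[i]]))
             for i in range(n)]
    active: list[int] = list(range(n))
    # distances between active clusters, keyed by sorted id pair
    dmat: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = float(dist.d[i, j])

    while len(active) > 1:
        # minimal distance, ties broken by sorted smallest-member names
        def key(pair: tuple[int, int]):
            a, b = pair
            na = min(nodes[a].member_classes)
            nb = min(nodes[b].member_classes)
            return (dmat[pair], *sorted((na, nb)))

        best = min(((a, b) for ai, a in enumerate(active)
                    for b in active[ai + 1:]),
                   key=lambda p: key((min(p), max(p))))
        i, j = min(best), max(best)
        height = dmat[(i, j)]

        # left child = lexicographically smaller smallest member
        if min(nodes[i].member_classes) <= min(nodes[j].member_classes):
            left, right = i, j
        else:
            left, right = j, i
        new_id = len(nodes)
        members = nodes[i].member_classes | nodes[j].member_classes
        nodes.append(DendroNode(id=new_id, left=left, right=right,
                                height=height, member_classes=members))
        active.remove(i)
        active.remove(j)
        n_i = len(nodes[i].member_classes)
        n_j = len(nodes[j].member_classes)
        for k in active:
            d_ki = dmat.pop((min(k, i), max(k, i)))
            d_kj = dmat.pop((min(k, j), max(k, j)))
            n_k = len(nodes[k].member_classes)
            dmat[(k, new_id)] = _lance_williams(
                linkage, d_ki, d_kj, height, n_i, n_j, n_k)
        del dmat[(i, j)]
        active.append(new_id)

    return Dendrogram(nodes=nodes, root_id=active[0],
                      class_names=list(names))


def _newick_name(name: str) -> str:
    if set(name) & _NEWICK_SPECIAL:
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(dend: Dendrogram) -> str:
    """Serialize a dendrogram as a Newick string.

    Branch lengths are parent height minus child height; child order follows
    the dendrogram's deterministic left/right assignment (lexicographically
    smallest member class first).
    """

    def render(node_id: int, parent_height: float) -> str:
        node = dend.node(node_id)
        branch = parent_height - node.height
        if node.is_leaf:
            name = _newick_name(next(iter(node.member_classes)))
            return f"{name}:{branch:g}"
        inner = (f"({render(node.left, node.height)},"
                 f"{render(node.right, node.height)})")
        return f"{inner}:{branch:g}"

    root = dend.root
    body = (f"({render(root.left, root.height)},"
            f"{render(root.right, root.height)})")
    return body + ";"


def write_newick(dend: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(to_newick(dend) + "\n")
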