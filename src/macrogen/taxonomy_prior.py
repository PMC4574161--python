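"""Taxonomic tree, Grafen branch lengths and the Brownian species correlation.

Without a dated phylogeny, relatedness among the sampled species is
approximated from their Linnaean classification: a rooted tree whose
internal nodes are shared Class/Order/Family/Genus groups.  Grafen's method
assigns each node a height proportional to (number of descendant tips - 1),
normalised so the root sits at height 1 and tips at 0; under a Brownian
motion model of trait evolution the correlation between two tips is then the
depth of their most recent common ancestor measured from the root, i.e.
``1 - height(MRCA)``.  The resulting matrix is the correlation of the
multivariate-normal prior on species effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import ValidationError

SpeciesPath = tuple[str, str, str, str, str]


@dataclass
class Node:
    label: str
    children: list["Node"] = field(default_factory=list)
    height: float = 0.0  # 1 at the root, 0 at tips after Grafen scaling

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["Node"]:
        if self.is_tip:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out


@dataclass
class TaxonomyTree:
    """Rooted ultrametric tree over species, with per-node heights in [0, 1]."""

    root: Node
    tip_labels: list[str]

    def n_tips(self) -> int:
        return len(self.tip_labels)

    def edges(self) -> list[tuple[str, str, float]]:
        """(parent label, child label, branch length) with length = height drop."""
        out = []

        def walk(node: Node):
            for c in node.children:
                out.append((node.label, c.label, node.height - c.height))
                walk(c)

        walk(self.root)
        return out

    def mrca_height(self, a: str, b: str) -> float:
        """Height of the most recent common ancestor of two tips."""
        pa = self._path_to(a)
        pb = self._path_to(b)
        shared = None
        sb = {id(n) for n in pb}
        for n in pa:
            if id(n) in sb:
                shared = n  # paths are root->tip; last shared is the MRCA
        assert shared is not None
        return shared.height

    def _path_to(self, tip_label: str) -> list[Node]:
        path: list[Node] = []

        def walk(node: Node) -> bool:
            path.append(node)
            if node.is_tip and node.label == tip_label:
                return True
            for c in node.children:
                if walk(c):
                    return True
            path.pop()
            return False

        if not walk(self.root):
            raise KeyError(f"tip {tip_label!r} not in tree")
        return path

    def to_newick(self) -> str:
        def fmt(node: Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_tip:
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}){node.label}:{bl:.6g}"

        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        if not self.root.children:
            return f"({self.root.label}:0);"
        return f"({inner}){self.root.label};"


def build_taxonomy(species_paths: Sequence[SpeciesPath]) -> TaxonomyTree:
    """Build the ranked tree from (class, order, family, genus, species) paths.

    Unary internal nodes (a rank level that does not split) are collapsed:
    they change no MRCA, hence no correlation.  Rank inconsistency (the same
    genus appearing under two families, etc.) raises ``ValidationError``.
    """
    if not species_paths:
        raise ValidationError("need at least one species")
    paths = [tuple(p) for p in species_paths]
    seen: dict[str, SpeciesPath] = {}
    for p in paths:
        if len(p) != 5 or any(not x for x in p):
            raise ValidationError(f"species path {p!r} must have five non-empty ranks")
        if p[-1] in seen and seen[p[-1]] != p:
            raise ValidationError(f"species {p[-1]!r} has two different classifications")
        seen[p[-1]] = p
    # rank consistency: a label at rank k determines all shallower ranks
    for k in range(1, 5):
        parent_of: dict[str, tuple] = {}
        for p in paths:
            lbl, par = p[k], p[:k]
            if lbl in parent_of and parent_of[lbl] != par:
                raise ValidationError(
                    f"rank inconsistency: {lbl!r} appears under both "
                    f"{parent_of[lbl]} and {par}"
                )
            parent_of[lbl] = par
    uniq = sorted(set(paths), key=lambda p: p[-1])

    def make(level: int, group: list[SpeciesPath], label: str) -> Node:
        if level == 5:
            assert len(group) == 1
            return Node(label=group[0][-1])
        buckets: dict[str, list[SpeciesPath]] = {}
        for p in group:
            buckets.setdefault(p[level], []).append(p)
        if len(buckets) == 1:  # unary node: collapse
            (lbl, sub), = buckets.items()
            return make(level + 1, sub, lbl)
        children = [make(level + 1, sub, lbl) for lbl, sub in sorted(buckets.items())]
        return Node(label=label, children=children)

    if len(uniq) == 1:
        root = Node(label=uniq[0][-1])
    else:
        buckets: dict[str, list[SpeciesPath]] = {}
        for p in uniq:
            buckets.setdefault(p[0], []).append(p)
        children = [make(1, sub, lbl) for lbl, sub in sorted(buckets.items())]
        root = Node(label="root", children=children) if len(children) > 1 else children[0]
        if len(children) == 1:
            root.label = "root"
    tree = TaxonomyTree(root=root, tip_labels=[t.label for t in root.tips()])
    return grafen_heights(tree)


def grafen_heights(tree: TaxonomyTree, rho: float = 1.0) -> TaxonomyTree:
    """Assign Grafen heights: node height = (descendant tips - 1)/(T - 1).

    Tips get height 0 and the root height 1; heights are then raised to the
    power ``rho`` (the default 1 leaves them untouched).  Branch lengths are
    implied as parent height minus child height.
    """
    T = tree.n_tips()

    def walk(node: Node) -> int:
        if node.is_tip:
            node.height = 0.0
            return 1
        ntips = sum(walk(c) for c in node.children)
        node.height = ((ntips - 1) / (T - 1)) ** rho if T > 1 else 0.0
        return ntips

    walk(tree.root)
    return tree


def brownian_correlation(tree: TaxonomyTree) -> tuple[np.ndarray, list[str]]:
    """Species correlation under Brownian motion on the Grafen-scaled tree.

    ``corr(i, j) = 1 - height(MRCA(i, j))`` (shared root-to-MRCA depth on a
    depth-1 tree); diagonal 1.  Returns ``(matrix, tip_labels)`` with rows
    ordered as ``tip_labels``.  Raises if the matrix is not positive
    semi-definite beyond numerical tolerance.
    """
    tips = tree.tip_labels
    T = len(tips)
    C = np.eye(T)
    # single tree walk: depth of each internal node covers all tip pairs below it
    def walk(node: Node) -> list[int]:
        if node.is_tip:
            return [tips.index(node.label)]
        groups = [walk(c) for c in node.children]
        depth = 1.0 - node.height
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        C[i, j] = C[j, i] = depth
        return [i for g in groups for i in g]

    walk(tree.root)
    eigmin = np.linalg.eigvalsh(C).min()
    if eigmin < -1e-10:
        raise ValidationError(f"correlation matrix not PSD (min eigenvalue {eigmin})")
    return C, list(tips)
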