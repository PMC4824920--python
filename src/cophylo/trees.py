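"""Phylogenetic tree container and topology utilities.

Trees are read and written as Newick (via dendropy) and held in a light
parent/child node structure that the reconciliation, rooting and simulation
code manipulates directly.  A tree is *rooted* when its basal node has exactly
two children; a basal multifurcation marks an unrooted tree stored with a
trifurcating "seed" node, following the usual Newick convention.

Branch lengths are optional nonnegative reals.  Internal node labels
(including numeric support values) are parsed and preserved on round-trip but
ignored by every downstream computation.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import TreeFormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "PhyloTree",
    "DistanceMatrix",
    "RootPlacement",
    "read_newick",
    "write_newick",
]


class Node:
    """A tree node with an optional label and branch length to its parent."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length})"


@dataclass(frozen=True)
class RootPlacement:
    """A candidate root position on an edge of an unrooted tree.

    The edge is identified by the set of leaf labels on its child side, which
    is stable across tree copies (an unordered node pair would not be).
    ``split`` is the fraction of the edge length between the new root and the
    child-side node; the default 0.5 puts the root at the edge midpoint.
    """

    bipartition: frozenset
    split: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.split <= 1.0:
            raise ValidationError(f"split position must lie in [0, 1], got {self.split}")


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of nonnegative distances between labelled taxa."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValidationError("distance matrix must have a zero diagonal")
        if np.any(self.values < -1e-9):
            raise ValidationError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index), df.to_numpy(dtype=float))


class PhyloTree:
    """Rooted or unrooted phylogeny with unique leaf labels."""

    def __init__(self, root: Node, rooted: Optional[bool] = None):
        self.root = root
        if rooted is None:
            rooted = len(root.children) <= 2
        self.rooted = rooted
        self._validate()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        """Parse a Newick string or file path into a :class:`PhyloTree`.

        The rooted flag is inferred from the basal degree: a degree-2 basal
        node means rooted, a basal multifurcation means unrooted.
        """
        text = _slurp(source)
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate leaf labels in Newick source: {exc}") from exc
            col = getattr(exc, "col_num", None) or getattr(exc, "column", None)
            line = getattr(exc, "line_num", None)
            where = ""
            if line is not None or col is not None:
                where = f" (line {line}, column {col})"
            raise TreeFormatError(f"invalid Newick{where}: {exc}") from exc
        root = _from_dendropy(dtree.seed_node)
        return cls(root)

    def to_newick(self) -> str:
        """Serialise to a Newick string (preserving labels and lengths)."""
        dtree = self._to_dendropy()
        s = dtree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
        return s.strip()

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def _to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def build(node: Node, dnode):
            if node.is_leaf:
                dnode.taxon = taxa.new_taxon(node.label)
            else:
                dnode.label = node.label
            dnode.edge.length = node.length
            for child in node.children:
                build(child, dnode.new_child())

        build(self.root, dtree.seed_node)
        return dtree

    # ------------------------------------------------------------ traversal

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def total_length(self) -> float:
        return float(
            sum(n.length for n in self.preorder() if n is not self.root and n.length is not None)
        )

    def is_binary(self) -> bool:
        for node in self.preorder():
            if node.is_leaf:
                continue
            expected = (3,) if (node is self.root and not self.rooted) else (2,)
            if len(node.children) not in expected:
                return False
        return True

    def copy(self) -> "PhyloTree":
        return PhyloTree(_clone(self.root), rooted=self.rooted)

    def _validate(self) -> None:
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate leaf labels: {', '.join(map(str, dupes))}")
        if any(l is None or l == "" for l in labels):
            raise ValidationError("every leaf must carry a non-empty label")
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} on node {node.label!r}"
                )

    # ------------------------------------------------------------ topology

    def resolve_polytomies(self) -> "PhyloTree":
        """Return a copy with every multifurcation resolved into a binary
        left-to-right caterpillar of zero-length edges.

        The (arbitrary) resolution is deterministic; a warning is logged when
        any node actually needed resolving.
        """
        tree = self.copy()
        resolved = 0
        for node in list(tree.preorder()):
            limit = 3 if (node is tree.root and not tree.rooted) else 2
            while len(node.children) > limit:
                resolved += 1
                right = node.children.pop()
                left = node.children.pop()
                joint = Node(label=None, length=0.0)
                joint.add_child(left)
                joint.add_child(right)
                node.add_child(joint)
        if resolved:
            logger.warning(
                "resolved %d multifurcation(s) arbitrarily with zero-length edges", resolved
            )
        return tree

    def bipartition_of(self, node: Node) -> frozenset:
        """Leaf labels on the child side of the edge above ``node``."""
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.label)
            stack.extend(n.children)
        return frozenset(out)

    def patristic_distances(self) -> DistanceMatrix:
        """Pairwise sums of branch lengths along leaf-to-leaf paths.

        Computed by post-order merging of leaf-depth lists, so entry (i, j) is
        the exact path sum on the tree.  All branch lengths below the basal
        node must be present.
        """
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise ValidationError(
                    f"missing branch length on node {node.label!r}; patristic distances need all lengths"
                )
        labels = self.leaf_labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))
        # depths[node] = list of (leaf index, distance from node)
        depths: dict = {}
        for node in self.postorder():
            if node.is_leaf:
                depths[id(node)] = [(index[node.label], 0.0)]
                continue
            lists = []
            for child in node.children:
                lists.append([(i, d + child.length) for i, d in depths.pop(id(child))])
            for a in range(len(lists)):
                for b in range(a + 1, len(lists)):
                    for i, di in lists[a]:
                        for j, dj in lists[b]:
                            dist[i, j] = dist[j, i] = di + dj
            depths[id(node)] = [pair for lst in lists for pair in lst]
        return DistanceMatrix(tuple(labels), dist)

    # ------------------------------------------------------------- rooting

    def unroot(self) -> "PhyloTree":
        """Collapse a degree-2 root, yielding the unrooted topology."""
        if not self.rooted:
            return self.copy()
        tree = self.copy()
        root = tree.root
        if len(root.children) != 2:
            return PhyloTree(tree.root, rooted=False)
        a, b = root.children
        keep, move = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            raise ValidationError("cannot unroot a two-leaf tree")
        if keep.length is not None and move.length is not None:
            move.length = keep.length + move.length
        keep.parent = None
        keep.add_child(move)
        keep.length = None
        return PhyloTree(keep, rooted=False)

    def enumerate_rootings(self) -> list:
        """One :class:`RootPlacement` per edge of an unrooted tree.

        For a fully binary unrooted tree with n leaves this yields exactly
        2n-3 placements (n pendant edges plus n-3 internal ones).
        """
        if self.rooted:
            raise ValidationError("enumerate_rootings requires an unrooted tree")
        if self.n_leaves < 3:
            raise ValidationError("enumerate_rootings requires at least 3 leaves")
        placements = []
        for node in self.preorder():
            if node is self.root:
                continue
            placements.append(RootPlacement(self.bipartition_of(node)))
        return placements

    def find_edge(self, bipartition: frozenset) -> Node:
        """Return the node under the edge whose child-side leaf set equals
        ``bipartition`` (or its complement)."""
        all_leaves = frozenset(self.leaf_labels)
        target = frozenset(bipartition)
        complement = all_leaves - target
        for node in self.preorder():
            if node is self.root:
                continue
            bp = self.bipartition_of(node)
            if bp == target or bp == complement:
                return node
        raise ValidationError(
            f"no edge separates leaves {{{', '.join(sorted(map(str, target)))}}} from the rest"
        )

    def reroot_at(self, placement: RootPlacement) -> "PhyloTree":
        """Insert a degree-2 root on the edge named by ``placement``.

        The leaf set, total tree length and all leaf-to-leaf patristic
        distances are preserved; only the direction of edges changes.
        """
        if self.rooted:
            raise ValidationError("reroot_at expects an unrooted tree")
        tree = self.copy()
        child = tree.find_edge(placement.bipartition)
        old_parent = child.parent
        edge_len = child.length
        new_root = Node(label=None, length=None)
        if edge_len is None:
            child_len = parent_len = None
        else:
            child_len = edge_len * placement.split
            parent_len = edge_len * (1.0 - placement.split)
        old_parent.children.remove(child)
        new_root.add_child(child)
        child.length = child_len
        rehung = _rehang(old_parent)
        new_root.add_child(rehung)
        rehung.length = parent_len
        return PhyloTree(new_root, rooted=True)


def _rehang(node: Node) -> Node:
    """Reverse parent pointers from ``node`` up to the old basal node.

    After the call ``node`` is parentless and its former ancestors hang below
    it, each keeping the length of the edge that previously connected it to
    its child on the path.  Degree-2 leftovers of the old basal node are
    suppressed.
    """
    parent = node.parent
    node.parent = None
    prev = node
    prev_edge_len = node.length
    node.length = None
    while parent is not None:
        grand = parent.parent
        parent.children.remove(prev)
        next_edge_len = parent.length
        parent.parent = prev
        parent.length = prev_edge_len
        prev.children.append(parent)
        prev, parent, prev_edge_len = parent, grand, next_edge_len
    # prev is now the old basal node; suppress it if it became degree-2
    _suppress_unary(prev)
    return node


def _suppress_unary(node: Node) -> None:
    if len(node.children) == 1 and node.parent is not None:
        child = node.children[0]
        parent = node.parent
        idx = parent.children.index(node)
        if child.length is not None and node.length is not None:
            child.length = child.length + node.length
        child.parent = parent
        parent.children[idx] = child


def _clone(node: Node) -> Node:
    new = Node(node.label, node.length)
    for child in node.children:
        new.add_child(_clone(child))
    return new


def _from_dendropy(dnode) -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for dchild in dnode.child_nodes():
        node.add_child(_from_dendropy(dchild))
    return node


def _slurp(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        stripped = source.strip()
        if "(" in stripped or stripped.endswith(";"):
            return source
        if os.path.exists(source):
            return Path(source).read_text()
        raise TreeFormatError(f"not a Newick string and no such file: {source!r}")
    raise TreeFormatError(f"unsupported Newick source type: {type(source).__name__}")


def read_newick(source) -> PhyloTree:
    """Read a tree from a Newick string or file path."""
    return PhyloTree.from_newick(source)


def write_newick(tree: PhyloTree, path=None) -> str:
    """Serialise ``tree``; write to ``path`` when given, return the string."""
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
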