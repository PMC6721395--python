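"""Rooted phylogenies: Newick I/O, pruning, and phylogenetic covariance.

Trees are stored as a light-weight adjacency structure (integer node ids,
parent/child maps, branch lengths on non-root nodes).  Newick parsing and
writing are delegated to :mod:`dendropy`; all downstream likelihood code
consumes either the :class:`Phylogeny` itself or the flat array view
produced by :func:`linearize`.

Conventions
-----------
* Branch lengths are required on every non-root edge and must be finite
  and non-negative.
* Tip labels must be unique; internal labels are optional, ignored by the
  numerics, and preserved on write.
* Polytomies are accepted on input and can be resolved deterministically
  into binary nodes joined by zero-length branches
  (:meth:`Phylogeny.resolve_polytomies`); every likelihood in this package
  is invariant to zero-length resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeArrays",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "phylo_covariance",
    "linearize",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural invariant."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths.

    Attributes
    ----------
    parent : dict
        Maps each non-root node id to its parent id.
    children : dict
        Maps each node id to the (ordered) list of its children.
    branch_length : dict
        Maps each non-root node id to the length of the edge above it.
    labels : dict
        Maps node ids to labels.  Every tip has a label; internal labels
        are optional.
    root : int
        Id of the unique root node.
    """

    parent: dict[int, int]
    children: dict[int, list[int]]
    branch_length: dict[int, float]
    labels: dict[int, str]
    root: int = 0

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def nodes(self) -> list[int]:
        return list(self.children.keys())

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    @property
    def tips(self) -> list[int]:
        return [n for n in self.postorder() if self.is_tip(n)]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[t] for t in self.tips]

    def postorder(self) -> Iterator[int]:
        """Children-before-parent traversal covering every node once."""
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(self.children[node]):
                    stack.append((child, False))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(self.children[node]):
                stack.append(child)

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths (root depth 0)."""
        out = {self.root: 0.0}
        for node in self.preorder():
            if node != self.root:
                out[node] = out[self.parent[node]] + self.branch_length[node]
        return out

    def total_length(self) -> float:
        return float(sum(self.branch_length.values()))

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            parent=dict(self.parent),
            children={k: list(v) for k, v in self.children.items()},
            branch_length=dict(self.branch_length),
            labels=dict(self.labels),
            root=self.root,
        )

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.root in self.parent:
            raise TreeValidationError("root must not have a parent")
        for node in self.children:
            if node != self.root and node not in self.parent:
                raise TreeValidationError(f"node {node} has no parent")
            if node != self.root:
                bl = self.branch_length.get(node)
                if bl is None or not np.isfinite(bl) or bl < 0:
                    raise TreeValidationError(
                        f"node {node} has invalid branch length {bl!r}"
                    )
        seen = list(self.postorder())
        if len(seen) != len(set(seen)) or set(seen) != set(self.children):
            raise TreeValidationError("traversal does not cover nodes exactly once")
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")

    # ------------------------------------------------------------------
    # manipulation
    # ------------------------------------------------------------------
    def resolve_polytomies(self) -> "Phylogeny":
        """Return a binary tree; multifurcations split with zero branches.

        Resolution is deterministic: at each polytomy the children are
        sorted by the label of their smallest descendant tip and combined
        left-to-right through fresh zero-length internal nodes.
        """
        tree = self.copy()
        min_tip: dict[int, str] = {}
        for node in tree.postorder():
            if tree.is_tip(node):
                min_tip[node] = tree.labels[node]
            else:
                min_tip[node] = min(min_tip[c] for c in tree.children[node])
        next_id = max(tree.children) + 1
        for node in list(tree.postorder()):
            kids = tree.children[node]
            while len(kids) > 2:
                kids.sort(key=lambda c: min_tip[c])
                a, b = kids[0], kids[1]
                new = next_id
                next_id += 1
                tree.children[new] = [a, b]
                tree.parent[a] = new
                tree.parent[b] = new
                tree.parent[new] = node
                tree.branch_length[new] = 0.0
                min_tip[new] = min(min_tip[a], min_tip[b])
                kids[:] = [new] + kids[2:]
        return tree

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        return write_newick(self)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)


# ----------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ----------------------------------------------------------------------

def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on non-root edges; internal labels are
    kept.  Malformed input raises :class:`NewickParseError` carrying
    dendropy's description of the offending position; duplicate tip
    labels raise :class:`TreeValidationError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    branch_length: dict[int, float] = {}
    labels: dict[int, str] = {}
    ids: dict[dendropy.Node, int] = {}

    for i, dnode in enumerate(dtree.preorder_node_iter()):
        ids[dnode] = i
        children[i] = []
        if dnode.parent_node is not None:
            p = ids[dnode.parent_node]
            parent[i] = p
            children[p].append(i)
            if dnode.edge.length is None:
                raise NewickParseError(
                    "missing branch length on a non-root edge"
                )
            branch_length[i] = float(dnode.edge.length)
        if dnode.taxon is not None:
            labels[i] = dnode.taxon.label
        elif dnode.label is not None:
            labels[i] = dnode.label

    tree = Phylogeny(parent, children, branch_length, labels, root=0)
    for tip in tree.tips:
        if tip not in tree.labels:
            raise NewickParseError("unlabeled tip in Newick string")
    tree.validate()
    return tree


def write_newick(tree: Phylogeny, digits: int = 10) -> str:
    """Serialize to single-line Newick with ``digits`` significant digits."""

    def fmt(x: float) -> str:
        return f"{x:.{digits}g}"

    def rec(node: int) -> str:
        if tree.is_tip(node):
            s = tree.labels[node]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[node]) + ")"
            s += tree.labels.get(node, "")
        if node != tree.root:
            s += ":" + fmt(tree.branch_length[node])
        return s

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * tree.n_nodes + 100))
    try:
        return rec(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict a tree to a subset of tips.

    Unary internal nodes created by tip removal are suppressed with their
    branch lengths summed, so root-to-tip depths of retained tips (and
    all pairwise shared path lengths) are unchanged.
    """
    keep = set(keep)
    tip_set = set(tree.tip_labels)
    unknown = keep - tip_set
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeValidationError("need at least 2 tips to keep")

    out = tree.copy()
    # drop unwanted tips, then repeatedly clean empty/unary nodes bottom-up
    retained: dict[int, bool] = {}
    for node in out.postorder():
        if out.is_tip(node):
            retained[node] = out.labels[node] in keep
        else:
            out.children[node] = [c for c in out.children[node] if retained[c]]
            retained[node] = bool(out.children[node])

    def drop(node: int) -> None:
        del out.children[node]
        out.parent.pop(node, None)
        out.branch_length.pop(node, None)
        out.labels.pop(node, None)

    for node in list(out.children):
        if node in out.children and not retained.get(node, False):
            drop(node)

    # suppress unary nodes (root handled last)
    changed = True
    while changed:
        changed = False
        for node in list(out.children):
            kids = out.children.get(node)
            if kids is None or len(kids) != 1:
                continue
            (child,) = kids
            if node == out.root:
                # new root is the single child; its pendant edge is dropped
                out.parent.pop(child, None)
                out.branch_length.pop(child, None)
                out.root = child
                drop(node)
            else:
                p = out.parent[node]
                out.branch_length[child] = (
                    out.branch_length[child] + out.branch_length[node]
                )
                out.parent[child] = p
                out.children[p][out.children[p].index(node)] = child
                drop(node)
            changed = True

    out.validate()
    return out


# ----------------------------------------------------------------------
# covariance
# ----------------------------------------------------------------------

def phylo_covariance(
    tree: Phylogeny, order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of the tips.

    Entry ``(i, j)`` is the root-to-tip path length shared by tips *i*
    and *j*, i.e. the depth of their most recent common ancestor; the
    diagonal holds each tip's depth.  Returns the matrix and the tip
    label order of its rows.
    """
    tree.validate()
    if order is None:
        order = tree.tip_labels
    idx = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    depth = tree.depths()
    cov = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            i = idx[tree.labels[node]]
            cov[i, i] = depth[node]
            below[node] = [i]
        else:
            kids = tree.children[node]
            sets = [below.pop(c) for c in kids]
            d = depth[node]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            cov[i, j] = d
                            cov[j, i] = d
            merged: list[int] = []
            for s in sets:
                merged.extend(s)
            below[node] = merged
    return cov, list(order)


# ----------------------------------------------------------------------
# flat array view for likelihood code
# ----------------------------------------------------------------------

@dataclass
class TreeArrays:
    """Postorder array view of a phylogeny for vectorized likelihoods.

    ``order`` lists node ids in postorder (root last); ``parent_index``
    and ``branch_lengths`` are aligned to that order (root entries are
    ``-1`` / ``nan``).  ``tip_rows`` maps tip label to its position in
    ``order``; ``desc_mask`` is an (n_nodes, n_tips) boolean incidence
    of tips below each node (used to assemble regime covariances).
    """

    tree: Phylogeny
    order: list[int] = field(init=False)
    index: dict[int, int] = field(init=False)
    parent_index: np.ndarray = field(init=False)
    branch_lengths: np.ndarray = field(init=False)
    children_index: list[list[int]] = field(init=False)
    tip_labels: list[str] = field(init=False)
    tip_rows: dict[str, int] = field(init=False)
    desc_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = self.tree
        self.order = list(t.postorder())
        self.index = {nid: i for i, nid in enumerate(self.order)}
        n = len(self.order)
        self.parent_index = np.full(n, -1, dtype=int)
        self.branch_lengths = np.full(n, np.nan)
        self.children_index = [[] for _ in range(n)]
        self.tip_labels = []
        self.tip_rows = {}
        for i, nid in enumerate(self.order):
            if nid != t.root:
                self.parent_index[i] = self.index[t.parent[nid]]
                self.branch_lengths[i] = t.branch_length[nid]
            self.children_index[i] = [self.index[c] for c in t.children[nid]]
            if t.is_tip(nid):
                self.tip_rows[t.labels[nid]] = i
                self.tip_labels.append(t.labels[nid])
        n_tips = len(self.tip_labels)
        tip_col = {self.tip_rows[lab]: j for j, lab in enumerate(self.tip_labels)}
        self.desc_mask = np.zeros((n, n_tips), dtype=bool)
        for i in range(n):
            if not self.children_index[i]:
                self.desc_mask[i, tip_col[i]] = True
            else:
                for c in self.children_index[i]:
                    self.desc_mask[i] |= self.desc_mask[c]

    @property
    def n_nodes(self) -> int:
        return len(self.order)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def levels(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Internal nodes grouped by height above the tips.

        Each entry is ``(nodes, child_concat, starts)``: all nodes of
        one level, their children concatenated node-by-node, and the
        segment starts into that concatenation — the layout consumed by
        the batched pruning pass (children always live in lower levels).
        """
        if not hasattr(self, "_levels"):
            n = self.n_nodes
            height = np.zeros(n, dtype=int)
            for i in range(n):
                kids = self.children_index[i]
                if kids:
                    height[i] = max(height[c] for c in kids) + 1
            out = []
            for h in range(1, height.max() + 1):
                nodes = np.nonzero(height == h)[0]
                childs = []
                starts = []
                pos = 0
                for i in nodes:
                    starts.append(pos)
                    kids = self.children_index[i]
                    childs.extend(kids)
                    pos += len(kids)
                out.append(
                    (nodes, np.asarray(childs, dtype=int), np.asarray(starts, dtype=int))
                )
            self._levels = out
        return self._levels

    @property
    def root_index(self) -> int:
        return self.n_nodes - 1

    def nonroot(self) -> np.ndarray:
        """Indices of all non-root nodes (each owns the branch above it)."""
        return np.arange(self.n_nodes - 1)


def linearize(tree: Phylogeny) -> TreeArrays:
    """Build the postorder array view used by the likelihood modules."""
    return TreeArrays(tree)
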