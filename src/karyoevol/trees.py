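"""Rooted phylogenies: Newick I/O, pruning, heights and Brownian covariance.

The container is a light node/edge structure tailored to the comparative
methods in this package (GLS covariances, pruning likelihoods). Newick
parsing and writing are delegated to :mod:`dendropy`; trees round-trip
through it so bracketed comments and label dialects are tolerated.

Branch lengths are in the time units of the input tree (Myr for dated
trees). Trees are rooted; polytomies are resolved deterministically with
zero-length branches before any likelihood computation.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeError",
    "read_newick",
    "prune_to_taxa",
    "vcv",
    "normalize_label",
]

#: relative tolerance used when checking that all root-to-tip depths agree
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Malformed tree or invalid tree operation."""


def normalize_label(label: str) -> str:
    """Canonical taxon label: trimmed, underscores read as spaces."""
    return " ".join(label.replace("_", " ").split())


class Node:
    __slots__ = ("name", "length", "parent", "children", "label")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 label: str | None = None):
        self.name = name
        self.length = float(length)
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.label = label  # free-form internal-node annotation

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """A rooted tree with named tips and non-negative branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, strict_lengths: bool = False) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"could not parse Newick: {exc}") from exc

        def convert(dnode) -> Node:
            name = None
            if dnode.taxon is not None:
                name = normalize_label(dnode.taxon.label)
            elif dnode.is_leaf() and dnode.label:
                name = normalize_label(dnode.label)
            length = dnode.edge.length
            if length is None:
                if strict_lengths and dnode.parent_node is not None:
                    raise TreeError(f"missing branch length at node {name or dnode.label!r}")
                length = 0.0
            if length < 0:
                raise TreeError(f"negative branch length {length} at {name or dnode.label!r}")
            node = Node(name=name, length=length,
                        label=None if dnode.is_leaf() else dnode.label)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    def _validate(self) -> None:
        names = [t.name for t in self.tips()]
        if any(n is None for n in names):
            raise TreeError("unnamed tip in tree")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeError(f"duplicate tip names: {sorted(dupes)}")

    # -- traversal ----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    @property
    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    # -- geometry -----------------------------------------------------

    def depths(self) -> dict[Node, float]:
        """Distance of every node from the root."""
        depth = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + node.length
        return depth

    def height(self) -> float:
        depth = self.depths()
        return max(depth[t] for t in self.tips())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depth = self.depths()
        d = np.array([depth[t] for t in self.tips()])
        scale = max(d.max(), 1e-300)
        return bool((d.max() - d.min()) <= rtol * scale)

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    # -- editing ------------------------------------------------------

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.label)
            for c in node.children:
                new.add_child(clone(c))
            return new
        return Phylogeny(clone(self.root))

    def resolve_polytomies(self) -> "Phylogeny":
        """Binary copy of the tree; multifurcations are split with
        zero-length branches, grouping children in alphabetical order of
        their smallest descendant tip so the resolution is deterministic."""
        def min_tip(node: Node) -> str:
            while node.children:
                node = min(node.children, key=min_tip_key)
            return node.name
        def min_tip_key(node: Node) -> str:
            return min_tip(node)

        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.label)
            kids = sorted((clone(c) for c in node.children), key=min_tip_key)
            while len(kids) > 2:
                joiner = Node(length=0.0)
                for c in kids[:2]:
                    joiner.add_child(c)
                kids = [joiner] + kids[2:]
            for c in kids:
                new.add_child(c)
            return new

        return Phylogeny(clone(self.root))

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # -- output -------------------------------------------------------

    def to_newick(self, node_labels: dict[Node, str] | None = None,
                  precision: int = 10) -> str:
        labels = node_labels or {}

        def fmt(node: Node) -> str:
            if node.is_leaf:
                name = node.name.replace(" ", "_")
                body = name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                tag = labels.get(node, node.label) or ""
                body = f"({inner}){tag}"
            if node is self.root:
                return body
            return f"{body}:{node.length:.{precision}g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, height {self.height():.4g}>"


def read_newick(text: str, strict_lengths: bool = False) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Tip labels are normalized (whitespace trimmed, underscores read as
    spaces). Bracketed comments are ignored. Duplicate tip names raise
    :class:`TreeError`.
    """
    return Phylogeny.from_newick(text, strict_lengths=strict_lengths)


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``keep``; suppressed degree-2 nodes have their
    branch lengths summed, so patristic distances among kept taxa — and
    ultrametricity — are preserved."""
    keep = {normalize_label(k) for k in keep}
    tips = set(tree.tip_labels)
    unknown = keep - tips
    if unknown:
        raise TreeError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least two taxa to keep")

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in keep:
                return Node(node.name, node.length)
            return None
        kept = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress this degree-2 node: fold its length into the child
            child = kept[0]
            child.length += node.length
            return child
        new = Node(node.name, node.length, node.label)
        for c in kept:
            new.add_child(c)
        return new

    new_root = build(tree.root)
    new_root.length = 0.0
    return Phylogeny(new_root)


def vcv(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance structure of the tips.

    ``C[i, j]`` is the root-to-MRCA path length shared by tips *i* and
    *j*; the diagonal holds root-to-tip depths. Returns the tip-label
    order alongside the matrix.
    """
    tips = tree.tips()
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    depth = tree.depths()
    C = np.zeros((n, n))
    for t in tips:
        C[index[t], index[t]] = depth[t]

    # descendant tip indices per node, filled postorder
    below: dict[Node, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = [index[node]]
            continue
        kids = [below[c] for c in node.children]
        d = depth[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    for j in kids[b]:
                        C[i, j] = C[j, i] = d
        below[node] = [i for k in kids for i in k]
    return [t.name for t in tips], C


def warn_if_not_ultrametric(tree: Phylogeny, context: str = "") -> None:
    if not tree.is_ultrametric():
        warnings.warn(
            f"tree is not ultrametric within {ULTRAMETRIC_RTOL:g} relative "
            f"tolerance{(' (' + context + ')') if context else ''}",
            stacklevel=2,
        )
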