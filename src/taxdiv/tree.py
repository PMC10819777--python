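"""Rooted phylogenetic trees with branch lengths.

A thin wrapper over :class:`skbio.TreeNode` adding the invariants this
package relies on (single root with zero-length stem, unique leaf labels,
non-negative branch lengths) and a canonical node numbering that is
independent of child order, so tie-breaks during grafting are
reproducible for any serialization of the same tree.
"""

from __future__ import annotations

import warnings
from io import StringIO
from typing import IO, Iterator, Union

from skbio import TreeNode
from skbio.io import NewickFormatError

from .errors import ParseError, ValidationError


class PhyloTree:
    """A rooted tree whose leaves are labeled (typically with taxIDs)."""

    def __init__(self, root: TreeNode):
        self.root = root
        # the root has no parent edge: any stem length in the input is
        # meaningless for distances and is dropped
        root.length = 0.0
        fixed = 0
        for node in root.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                fixed += 1
            if node.length < 0:
                raise ValidationError(f"negative branch length on {node.name!r}")
        if fixed:
            warnings.warn(
                f"{fixed} branch length(s) missing; defaulted to 0", stacklevel=2
            )
        labels = [tip.name for tip in root.tips()]
        if root.is_tip():  # single-node tree
            labels = [root.name]
        if any(lbl is None for lbl in labels):
            raise ValidationError("unlabeled leaf")
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate leaf labels: {', '.join(dupes)}")
        self._reindex()

    # -- canonical numbering -------------------------------------------------

    def _reindex(self) -> None:
        """Number nodes by a preorder in which children are visited in
        order of their smallest descendant leaf label. Invariant under
        permutation of children in the input."""
        mins: dict[int, str] = {}
        for node in self.root.postorder(include_self=True):
            if node.is_tip():
                mins[id(node)] = node.name
            else:
                mins[id(node)] = min(mins[id(c)] for c in node.children)
        counter = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            node.node_id = counter
            counter += 1
            stack.extend(
                sorted(node.children, key=lambda c: mins[id(c)], reverse=True)
            )
        self._n_nodes = counter

    # -- queries -------------------------------------------------------------

    def __len__(self) -> int:
        return self._n_nodes

    def nodes(self) -> Iterator[TreeNode]:
        return self.root.traverse(include_self=True)

    def leaves(self) -> list[TreeNode]:
        if self.root.is_tip():
            return [self.root]
        return list(self.root.tips())

    def leaf_labels(self) -> list[str]:
        return [tip.name for tip in self.leaves()]

    def find_leaf(self, label: str) -> TreeNode:
        for tip in self.leaves():
            if tip.name == label:
                return tip
        raise ValidationError(f"no leaf labeled {label!r}")

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Descendant leaf-label set per node, keyed by node_id."""
        sets: dict[int, frozenset[str]] = {}
        by_id: dict[int, frozenset[str]] = {}
        for node in self.root.postorder(include_self=True):
            if node.is_tip():
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(by_id[id(c)] for c in node.children))
            by_id[id(node)] = s
            sets[node.node_id] = s
        return sets

    def total_length(self) -> float:
        return sum(
            node.length for node in self.root.traverse(include_self=False)
        )

    def distance(self, a: str, b: str) -> float:
        return self.find_leaf(a).distance(self.find_leaf(b))

    def depth_of(self, node: TreeNode) -> float:
        """Path length from ``node`` up to the root."""
        total = 0.0
        while node.parent is not None:
            total += node.length
            node = node.parent
        return total

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    # -- io ------------------------------------------------------------------

    @classmethod
    def from_newick(cls, source: Union[str, IO[str]]) -> "PhyloTree":
        if isinstance(source, str):
            source = StringIO(source)
        try:
            root = TreeNode.read(source, format="newick")
        except NewickFormatError as exc:
            raise ParseError(f"invalid Newick: {exc}") from exc
        return cls(root)

    def to_newick(self) -> str:
        buf = StringIO()
        self.root.write(buf, format="newick")
        return buf.getvalue()


def read_newick(source: Union[str, IO[str]]) -> PhyloTree:
    """Parse Newick text (or a stream) into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(source)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()
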