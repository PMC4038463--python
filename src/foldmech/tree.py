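"""Minimal rooted-tree container shared by the parsimony and age machinery.

Newick parsing and serialisation to disk live in :mod:`foldmech.io`; this
module only provides the in-memory node structure and canonicalisation used
for deterministic tie-breaking among equally parsimonious trees.
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeNode:
    """A node of a rooted tree; leaves carry a label, internal nodes do not."""

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list["TreeNode"]] = None):
        self.label = label
        self.children: list[TreeNode] = list(children) if children else []

    # -- basic structure -------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        # iterative to cope with deep caterpillar trees
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "TreeNode":
        if self.is_leaf:
            return TreeNode(self.label)
        return TreeNode(self.label, [c.copy() for c in self.children])

    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    # -- canonical form --------------------------------------------------
    def _canonical_key(self) -> str:
        if self.is_leaf:
            return self.label
        keys = sorted(c._canonical_key() for c in self.children)
        return "(" + ",".join(keys) + ")"

    def canonicalise(self) -> "TreeNode":
        """Sort children recursively by their canonical key (in place)."""
        for node in self.postorder():
            if not node.is_leaf:
                node.children.sort(key=TreeNode._canonical_key)
        return self

    def canonical_newick(self) -> str:
        """Newick string with children in canonical order; used as a total
        order on topologies when breaking ties among co-optimal trees."""
        return self.copy().canonicalise().newick()

    def newick(self) -> str:
        if self.is_leaf:
            return _quote_label(self.label)
        return "(" + ",".join(c.newick() for c in self.children) + ")"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode<{self.newick()}>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def collapse_unifurcations(root: TreeNode) -> TreeNode:
    """Remove internal nodes with a single child (artifacts of some Newick
    writers); returns the possibly new root."""
    while not root.is_leaf and len(root.children) == 1:
        root = root.children[0]
    for node in list(root.postorder()):
        new_children = []
        for child in node.children:
            while not child.is_leaf and len(child.children) == 1:
                child = child.children[0]
            new_children.append(child)
        node.children = new_children
    return root
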