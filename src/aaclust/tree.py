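"""Labelled trees: dendrogram conversion, Newick serialization, subtree extraction.

A dendrogram becomes a rooted binary tree with leaves at height 0 and each
branch length equal to the parent's merge height minus the child's own
height.  Centroid/median inversions therefore surface as negative branch
lengths, which are preserved (and warned about) rather than hidden.

Newick output always carries branch lengths and is terminated by ";"; labels
outside the safe character class [A-Za-z0-9_.-] are single-quoted with the
standard ''-escape.  Branch lengths are printed with 12 significant digits so
that a write/parse round trip preserves them to well below 1e-9.
"""

from __future__ import annotations

import warnings
from fnmatch import fnmatchcase
from typing import Callable, Iterable, Iterator

from .cluster import Dendrogram

__all__ = [
    "TreeNode",
    "NewickParseError",
    "dendrogram_to_tree",
    "to_newick",
    "parse_newick",
    "extract_subtree",
    "trees_equal",
]

_SAFE_LABEL_CHARS = frozenset(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.-"
)


class NewickParseError(ValueError):
    """Malformed Newick input; carries the 0-based character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class TreeNode:
    """Node of a rooted tree; a leaf iff ``children`` is empty.

    ``length`` is the branch length to the parent (None at the root);
    ``height`` is the node's merge height when built from a dendrogram.
    """

    __slots__ = ("label", "length", "children", "height")

    def __init__(self, label=None, length=None, children=None, height=None):
        self.label: str | None = label
        self.length: float | None = length
        self.children: list[TreeNode] = children if children is not None else []
        self.height: float | None = height

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """All nodes, depth-first pre-order, without recursion."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [node for node in self.walk() if node.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.label, self.length, height=self.height)
        clone.children = [c.copy() for c in self.children]
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({to_newick(self)!r})"


def dendrogram_to_tree(dendrogram: Dendrogram, labels: list[str]) -> TreeNode:
    """Convert a merge history into a labelled binary tree.

    ``labels[i]`` names leaf i; labels must be unique.  Branch length of each
    node is its parent's merge height minus its own height (leaves sit at 0).
    """
    n = dendrogram.n_leaves
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} leaves")
    if len(set(labels)) != n:
        raise ValueError("leaf labels must be unique")
    nodes: list[TreeNode] = [TreeNode(label=lbl, height=0.0) for lbl in labels]
    sizes: list[int] = [1] * n
    for left, right, height, _size in dendrogram.merges:
        i, j = int(left), int(right)
        # display convention: larger subtree first, ties by cluster id
        if (-sizes[i], i) > (-sizes[j], j):
            i, j = j, i
        a, b = nodes[i], nodes[j]
        parent = TreeNode(height=float(height), children=[a, b])
        a.length = parent.height - a.height
        b.length = parent.height - b.height
        nodes.append(parent)
        sizes.append(sizes[i] + sizes[j])
    root = nodes[-1]
    if any(node.length is not None and node.length < 0 for node in root.walk()):
        warnings.warn(
            "dendrogram contains inversions: some branch lengths are negative",
            stacklevel=2,
        )
    return root


# -- Newick ------------------------------------------------------------------


def _format_label(label: str) -> str:
    if label and set(label) <= _SAFE_LABEL_CHARS:
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(x: float) -> str:
    return format(float(x), ".12g")


def to_newick(root: TreeNode) -> str:
    """Serialize a tree as Newick with branch lengths, ';'-terminated."""
    # iterative post-order: (node, visited) pairs
    stack: list[tuple[TreeNode, bool]] = [(root, False)]
    out: dict[int, str] = {}
    while stack:
        node, visited = stack.pop()
        if not visited and node.children:
            stack.append((node, True))
            stack.extend((c, False) for c in reversed(node.children))
            continue
        if node.children:
            inner = ",".join(out.pop(id(c)) for c in node.children)
            text = f"({inner})"
        else:
            text = _format_label(node.label if node.label is not None else "")
        if node.length is not None:
            text += ":" + _format_length(node.length)
        out[id(node)] = text
    return out[id(root)] + ";"


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode` tree.

    Accepts branch lengths, quoted labels and (ignored) internal-node labels.
    Raises :class:`NewickParseError` with the offending position for
    unbalanced parentheses, a missing ';' terminator, or duplicate leaf
    labels.
    """
    pos = 0
    n_chars = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n_chars and text[pos].isspace():
            pos += 1

    def parse_label() -> str:
        nonlocal pos
        if pos < n_chars and text[pos] == "'":
            pos += 1
            chunks: list[str] = []
            while True:
                if pos >= n_chars:
                    raise NewickParseError("unterminated quoted label", pos)
                ch = text[pos]
                if ch == "'":
                    if pos + 1 < n_chars and text[pos + 1] == "'":
                        chunks.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(chunks)
                chunks.append(ch)
                pos += 1
        start = pos
        while pos < n_chars and text[pos] not in "(),:;[]'":
            pos += 1
        return text[start:pos].strip()

    def parse_length() -> float | None:
        nonlocal pos
        skip_ws()
        if pos < n_chars and text[pos] == ":":
            pos += 1
            start = pos
            while pos < n_chars and (text[pos] in "+-.eE" or text[pos].isdigit()):
                pos += 1
            try:
                return float(text[start:pos])
            except ValueError:
                raise NewickParseError("malformed branch length", start) from None
        return None

    def parse_subtree() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos < n_chars and text[pos] == "(":
            open_pos = pos
            pos += 1
            children = [parse_subtree()]
            skip_ws()
            while pos < n_chars and text[pos] == ",":
                pos += 1
                children.append(parse_subtree())
                skip_ws()
            if pos >= n_chars or text[pos] != ")":
                raise NewickParseError("unbalanced parentheses", open_pos)
            pos += 1
            parse_label()  # internal label, discarded
            node = TreeNode(children=children)
            node.length = parse_length()
            return node
        label = parse_label()
        if not label:
            raise NewickParseError("empty leaf label", pos)
        node = TreeNode(label=label)
        node.length = parse_length()
        return node

    root = parse_subtree()
    skip_ws()
    if pos >= n_chars or text[pos] != ";":
        raise NewickParseError("missing ';' terminator", pos)
    pos += 1
    skip_ws()
    if pos != n_chars:
        raise NewickParseError("trailing characters after ';'", pos)
    labels = root.leaf_labels()
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf labels {dupes!r}", 0)
    return root


def trees_equal(a: TreeNode, b: TreeNode, tol: float = 1e-9) -> bool:
    """Same topology, labels and branch lengths (within ``tol``), child order included."""
    la = a.length if a.length is not None else 0.0
    lb = b.length if b.length is not None else 0.0
    if abs(la - lb) > tol or a.label != b.label:
        return False
    if len(a.children) != len(b.children):
        return False
    return all(trees_equal(ca, cb, tol) for ca, cb in zip(a.children, b.children))


# -- subtree extraction ------------------------------------------------------


def _match_leaves(root: TreeNode, selector) -> set[str]:
    labels = root.leaf_labels()
    if callable(selector):
        matched = {l for l in labels if selector(l)}
    else:
        patterns: Iterable[str] = (
            [selector] if isinstance(selector, str) else list(selector)
        )
        matched = {l for l in labels if any(fnmatchcase(l, p) for p in patterns)}
    return matched


def extract_subtree(
    root: TreeNode,
    selector: str | Iterable[str] | Callable[[str], bool],
    prune: bool = False,
) -> TreeNode:
    """Minimal clade whose leaves contain every leaf matched by ``selector``.

    ``selector`` is a glob pattern, an iterable of glob patterns / labels, or
    a predicate over leaf labels.  The returned clade keeps *all* its leaves,
    including unselected bystanders — the clustering neighbourhood of a
    family is usually the interesting part.  With ``prune=True`` the clade is
    instead reduced to the selected leaves only (unary nodes collapsed,
    branch lengths summed).
    """
    matched = _match_leaves(root, selector)
    if not matched:
        raise ValueError(f"selector {selector!r} matches no leaf")

    def leafset(node: TreeNode) -> frozenset[str]:
        return frozenset(node.leaf_labels())

    # minimal containing clade = deepest node whose leaf set covers the match
    best = root
    node = root
    while True:
        covering = [c for c in node.children if matched <= leafset(c)]
        if not covering:
            break
        node = covering[0]
        best = node
    clade = best.copy()
    clade.length = None
    if not prune:
        return clade

    def prune_node(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return node if node.label in matched else None
        kept = [p for p in (prune_node(c) for c in node.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None:
                child.length = (child.length or 0.0) + node.length
            return child
        node.children = kept
        return node

    pruned = prune_node(clade)
    assert pruned is not None
    pruned.length = None
    return pruned
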