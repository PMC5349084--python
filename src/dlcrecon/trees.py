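"""Rooted binary trees and the order/path/separation predicates.

Trees are rooted and (on input) strictly binary: every node has exactly 0 or
2 children.  Children are ordered so that constructions and tie-breaking are
deterministic; the order carries no semantic weight for any cost.  Edges are
identified throughout by their child node -- the edge ``e(v)`` is the pair
``(p(v), v)`` -- so an edge set is simply a set of non-root node ids.

Reconciliation augments a gene tree with *implied speciation* nodes that
subdivide edges; augmented trees therefore may contain nodes with a single
child.  :meth:`RootedBinaryTree.validate` checks strict binarity and is
applied on parse; the in-memory structure tolerates unary nodes.

The newick dialect is labels-only: no branch lengths, no quoting, internal
labels written on output and auto-generated (``n0``, ``n1``, ... in preorder)
when absent on input.  The ``n<digits>`` namespace is reserved for generated
ids; user labels of that shape trigger a warning.
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, Iterator, List, Optional, Sequence

from .errors import ArityError, ConstraintError, NewickParseError, UnknownNodeError

_RESERVED_ID = re.compile(r"^n\d+$")
_LABEL_END = set("(),;:\t\n\r ")


class TreeNode:
    """A tree node with an id, a parent pointer, and ordered children."""

    __slots__ = ("id", "parent", "children")

    def __init__(self, id: str, children: Sequence["TreeNode"] = ()):
        self.id = id
        self.parent: Optional[TreeNode] = None
        self.children: List[TreeNode] = list(children)
        for child in self.children:
            child.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id!r}, {len(self.children)} children)"


def node(id: str, *children: TreeNode) -> TreeNode:
    """Functional builder used by the gadget constructions."""
    return TreeNode(id, children)


class RootedBinaryTree:
    """A rooted tree indexed by node id.

    The constructor walks the structure hanging off ``root``, checks id
    uniqueness and parent/child consistency, and builds the id index.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: Dict[str, TreeNode] = {}
        self._reindex()

    def _reindex(self) -> None:
        self.nodes = {}
        for v in self.preorder():
            if v.id in self.nodes:
                raise ConstraintError(f"duplicate node id {v.id!r}")
            self.nodes[v.id] = v
            for child in v.children:
                if child.parent is not v:
                    raise ConstraintError(
                        f"inconsistent parent pointer at node {child.id!r}"
                    )
        if self.root.parent is not None:
            raise ConstraintError("root has a parent")

    # -- traversal -------------------------------------------------------

    def preorder(self, start: Optional[TreeNode] = None) -> Iterator[TreeNode]:
        stack = [start or self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(v.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: List[TreeNode] = []
        for v in self.preorder():
            out.append(v)
        return reversed(out)

    def node(self, node_id: str) -> TreeNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise UnknownNodeError(f"unknown node id {node_id!r}") from None

    def leaves(self) -> List[str]:
        return [v.id for v in self.preorder() if v.is_leaf]

    def internal_nodes(self) -> List[str]:
        return [v.id for v in self.preorder() if not v.is_leaf]

    def edges(self) -> List[str]:
        """All edges, each named by its child node, in preorder."""
        return [v.id for v in self.preorder() if not v.is_root]

    def terminal_edges(self) -> List[str]:
        return [v.id for v in self.preorder() if v.is_leaf and not v.is_root]

    def parent_id(self, node_id: str) -> Optional[str]:
        v = self.node(node_id)
        return v.parent.id if v.parent is not None else None

    def children_ids(self, node_id: str) -> List[str]:
        return [c.id for c in self.node(node_id).children]

    def __len__(self) -> int:
        return len(self.nodes)

    # -- order predicates ------------------------------------------------

    def depth(self, node_id: str) -> int:
        d = 0
        v = self.node(node_id)
        while v.parent is not None:
            v = v.parent
            d += 1
        return d

    def root_path(self, node_id: str) -> List[str]:
        """Node ids from the root down to ``node_id`` (inclusive)."""
        path = []
        v = self.node(node_id)
        while v is not None:
            path.append(v.id)
            v = v.parent
        path.reverse()
        return path

    def is_ancestor(self, u: str, v: str) -> bool:
        """True iff ``u`` lies on the root-to-``v`` path (reflexive)."""
        un = self.node(u)
        w: Optional[TreeNode] = self.node(v)
        while w is not None:
            if w is un:
                return True
            w = w.parent
        return False

    def lca(self, u: str, v: str) -> str:
        """Deepest common ancestor of ``u`` and ``v``."""
        a, b = self.node(u), self.node(v)
        da, db = self.depth(u), self.depth(v)
        while da > db:
            a = a.parent
            da -= 1
        while db > da:
            b = b.parent
            db -= 1
        while a is not b:
            a, b = a.parent, b.parent
        return a.id

    def path_edges(self, u: str, v: str) -> List[str]:
        """Edges (child ids) on the u--v path, i.e. on the two lca-to-endpoint
        legs.  Empty iff ``u == v``."""
        w = self.lca(u, v)
        edges: List[str] = []
        for end in (u, v):
            x = self.node(end)
            while x.id != w:
                edges.append(x.id)
                x = x.parent
        return edges

    def separates(self, edge_child: str, u: str, v: str) -> bool:
        """True iff edge ``e(edge_child)`` lies on the path from lca(u, v) to
        ``u`` or from lca(u, v) to ``v``."""
        self.node(edge_child)
        return edge_child in set(self.path_edges(u, v))

    # -- structure checks and mutation -----------------------------------

    def is_binary(self) -> bool:
        return all(len(v.children) in (0, 2) for v in self.preorder())

    def validate(self) -> None:
        for v in self.preorder():
            if len(v.children) not in (0, 2):
                raise ArityError(
                    f"node {v.id!r} has {len(v.children)} children; "
                    "a binary tree node has exactly 0 or 2"
                )

    def copy(self) -> "RootedBinaryTree":
        def clone(v: TreeNode) -> TreeNode:
            return TreeNode(v.id, [clone(c) for c in v.children])

        return RootedBinaryTree(clone(self.root))

    def subdivide_edge(self, child_id: str, new_id: str) -> TreeNode:
        """Insert a new (unary) node on edge ``e(child_id)`` and return it."""
        if new_id in self.nodes:
            raise ConstraintError(f"node id {new_id!r} already present")
        v = self.node(child_id)
        p = v.parent
        if p is None:
            raise UnknownNodeError(f"{child_id!r} is the root; it has no edge")
        h = TreeNode(new_id)
        p.children[p.children.index(v)] = h
        h.parent = p
        h.children = [v]
        v.parent = h
        self.nodes[new_id] = h
        return h

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedBinaryTree):
            return NotImplemented

        def same(a: TreeNode, b: TreeNode) -> bool:
            return (
                a.id == b.id
                and len(a.children) == len(b.children)
                and all(same(x, y) for x, y in zip(a.children, b.children))
            )

        return same(self.root, other.root)

    def __hash__(self):  # structural trees are mutable; identity hash
        return id(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedBinaryTree({len(self.nodes)} nodes, root={self.root.id!r})"


# -- newick I/O ----------------------------------------------------------


def _parse_label(text: str, i: int) -> tuple[Optional[str], int]:
    j = i
    while j < len(text) and text[j] not in _LABEL_END:
        j += 1
    if j < len(text) and text[j] == ":":
        raise NewickParseError("branch lengths are not supported", j)
    label = text[i:j]
    return (label or None), j


def _parse_subtree(text: str, i: int) -> tuple[TreeNode, int]:
    while i < len(text) and text[i].isspace():
        i += 1
    if i >= len(text):
        raise NewickParseError("unexpected end of input", i)
    if text[i] == "(":
        i += 1
        children = []
        while True:
            child, i = _parse_subtree(text, i)
            children.append(child)
            while i < len(text) and text[i].isspace():
                i += 1
            if i >= len(text):
                raise NewickParseError("unclosed '('", i)
            if text[i] == ",":
                i += 1
                continue
            if text[i] == ")":
                i += 1
                break
            raise NewickParseError(f"expected ',' or ')', got {text[i]!r}", i)
        label, i = _parse_label(text, i)
        v = TreeNode(label or "")
        v.children = children
        for c in children:
            c.parent = v
        return v, i
    label, i = _parse_label(text, i)
    if label is None:
        raise NewickParseError(f"expected a subtree or label, got {text[i]!r}", i)
    return TreeNode(label), i


def parse_newick(text: str) -> RootedBinaryTree:
    """Parse a labels-only newick string into a strictly binary tree.

    Unlabeled nodes receive deterministic preorder ids ``n0``, ``n1``, ...
    Raises :class:`NewickParseError` on malformed input (with the offending
    position) and :class:`ArityError` when any node is non-binary.
    """
    root, i = _parse_subtree(text, 0)
    while i < len(text) and text[i].isspace():
        i += 1
    if i >= len(text) or text[i] != ";":
        raise NewickParseError("expected trailing ';'", i)
    i += 1
    if text[i:].strip():
        raise NewickParseError("trailing characters after ';'", i)

    # deterministic auto-labels, then index and validate
    used = set()
    order: List[TreeNode] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(v.children))
        if v.id:
            used.add(v.id)
    reserved = sorted(x for x in used if _RESERVED_ID.match(x))
    if reserved:
        warnings.warn(
            f"labels {reserved} use the reserved generated-id shape 'n<digits>'",
            stacklevel=2,
        )
    counter = 0
    for v in order:
        if not v.id:
            while f"n{counter}" in used:
                counter += 1
            v.id = f"n{counter}"
            used.add(v.id)
    tree = RootedBinaryTree(root)
    tree.validate()
    return tree


def write_newick(tree: RootedBinaryTree) -> str:
    """Serialize with internal labels and a trailing semicolon."""

    def emit(v: TreeNode) -> str:
        if v.is_leaf:
            return v.id
        inner = ",".join(emit(c) for c in v.children)
        return f"({inner}){v.id}"

    return emit(tree.root) + ";"
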