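"""Reading, writing, pruning and rooting of phylogenetic trees in Newick format.

Trees are held in a minimal in-memory structure (:class:`Node` / :class:`Tree`)
carrying only what the divergence math needs: topology, leaf labels and branch
lengths in substitutions/site.  Parsing is delegated to dendropy; the strict
validation layer (unique leaf labels, finite non-negative branch lengths,
collapsed unary chains) is ours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "prune_to_leaves",
    "root_by_outgroup",
]


class TreeError(ValueError):
    """Base class for tree-related errors."""


class NewickParseError(TreeError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(TreeError):
    """Raised when a parsed tree violates a structural invariant."""


# Characters that force quoting of a label on output.  Underscore is NOT in
# this set: unquoted labels are read and written with underscores preserved
# (the common "Hs_CCT8"-style convention), so they round-trip unquoted.
_NEWICK_META = set("()[]{}:;,='\" \t\n")


@dataclass
class Node:
    """A tree node.

    ``branch_length`` is the length of the edge to the parent, in
    substitutions/site; it is ``None`` exactly at the root.  ``label`` is
    required and unique for leaves, optional for internal nodes (internal
    labels are retained but ignored by all divergence math).
    """

    label: str | None = None
    branch_length: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            label=self.label,
            branch_length=self.branch_length,
            children=[c.copy() for c in self.children],
        )


class Tree:
    """A rooted (or basally multifurcating) phylogenetic tree."""

    __slots__ = ("root",)

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        """Sum of all branch lengths (the tree length L)."""
        return sum(n.branch_length for n in self.preorder() if n.branch_length is not None)

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({write_newick(self)!r})"


# ---------------------------------------------------------------------------
# parsing


def _scan_brackets(text: str) -> None:
    """Cheap pre-scan reporting the offset of the first bracket imbalance."""
    depth = 0
    in_quote = False
    in_comment = False
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if in_quote:
            if ch == "'":
                if i + 1 < n and text[i + 1] == "'":
                    i += 1  # escaped quote
                else:
                    in_quote = False
        elif in_comment:
            if ch == "]":
                in_comment = False
        elif ch == "'":
            in_quote = True
        elif ch == "[":
            in_comment = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at character offset {i}")
        i += 1
    if depth > 0:
        raise NewickParseError(
            f"unbalanced '(' — {depth} unclosed at character offset {n}"
        )


def parse_newick(
    text: str,
    *,
    allow_missing_lengths: bool = False,
    clamp_negative: bool = False,
) -> Tree:
    """Parse a single Newick statement into a validated, normalized Tree.

    Parameters
    ----------
    text:
        One Newick statement terminated by ``;``.  Bracket comments are
        stripped, single-quoted labels are unescaped, and underscores in
        unquoted labels are preserved verbatim.
    allow_missing_lengths:
        If true, edges without a branch length are assigned 0.0 instead of
        raising a validation error.
    clamp_negative:
        If true, negative branch lengths (as emitted by some inference tools)
        are clamped to 0.0 instead of raising.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty input (no Newick statement)")
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"Newick statement not terminated by ';' (character offset {len(text)})"
        )
    _scan_brackets(stripped)
    try:
        # labels are kept as plain node labels (not taxa) so that duplicate
        # leaf labels reach our own validator instead of failing inside dendropy
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        return Node(
            label=label,
            branch_length=dnode.edge.length,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dtree.seed_node)
    root.branch_length = None  # a length on the root edge has no meaning here
    tree = Tree(_collapse_unary(root))
    _validate(tree, allow_missing_lengths=allow_missing_lengths, clamp_negative=clamp_negative)
    return tree


def _collapse_unary(root: Node) -> Node:
    """Collapse unary chains, summing branch lengths along the chain."""

    def rec(node: Node) -> Node:
        node.children = [rec(c) for c in node.children]
        if len(node.children) == 1:
            child = node.children[0]
            if node.branch_length is None:
                child.branch_length = None  # node was the root
            else:
                child.branch_length = node.branch_length + (child.branch_length or 0.0)
            return child
        return node

    return rec(root)


def _validate(tree: Tree, *, allow_missing_lengths: bool, clamp_negative: bool) -> None:
    seen: set[str] = set()
    for node in tree.preorder():
        if node.is_leaf:
            if not node.label:
                raise TreeValidationError("leaf with empty or missing label")
            if node.label in seen:
                raise TreeValidationError(f"duplicate leaf label: {node.label!r}")
            seen.add(node.label)
        if node is tree.root:
            continue
        if node.branch_length is None:
            if allow_missing_lengths:
                node.branch_length = 0.0
            else:
                where = node.label or "an internal node"
                raise TreeValidationError(
                    f"missing branch length on the edge to {where} "
                    "(pass allow_missing_lengths=True to assign 0)"
                )
        if not math.isfinite(node.branch_length):
            raise TreeValidationError(f"non-finite branch length on {node.label or 'internal node'}")
        if node.branch_length < 0:
            if clamp_negative:
                node.branch_length = 0.0
            else:
                raise TreeValidationError(
                    f"negative branch length {node.branch_length} on "
                    f"{node.label or 'an internal node'} (pass clamp_negative=True to clamp to 0)"
                )


# ---------------------------------------------------------------------------
# writing


def _format_label(label: str) -> str:
    if label == "" or any(ch in _NEWICK_META for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize a tree to a Newick string with fixed-precision branch lengths."""

    def rec(node: Node) -> str:
        if node.is_leaf:
            s = _format_label(node.label or "")
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.label:
                s += _format_label(node.label)
        if node.branch_length is not None:
            s += f":{node.branch_length:.{precision}f}"
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# pruning


def prune_to_leaves(tree: Tree, keep: Iterable[str]) -> Tree:
    """Induced subtree on a leaf subset, rooted at the subset's MRCA.

    Unary nodes created by the pruning are collapsed with branch lengths
    summed, so all pairwise patristic distances among kept leaves are
    preserved exactly.
    """
    keep_set = set(keep)
    labels = set(tree.leaf_labels())
    unknown = keep_set - labels
    if unknown:
        raise TreeError(f"unknown leaf labels: {sorted(unknown)}")
    if len(keep_set) < 2:
        raise TreeError("need at least 2 leaves to prune to")

    def induce(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep_set:
                return Node(label=node.label, branch_length=node.branch_length)
            return None
        kids = [k for k in (induce(c) for c in node.children) if k is not None]
        if not kids:
            return None
        return Node(label=node.label, branch_length=node.branch_length, children=kids)

    root = induce(tree.root)
    assert root is not None
    # descend to the MRCA of the kept set, dropping the stem above it
    while len(root.children) == 1:
        root = root.children[0]
    root.branch_length = None
    return Tree(_collapse_unary(root))


# ---------------------------------------------------------------------------
# outgroup rooting


def root_by_outgroup(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Extract the ingroup clade, rooted at its MRCA, given an outgroup.

    The outgroup must be monophyletic in the unrooted sense (its leaves sit
    together on one side of some edge of the input).  The returned tree
    contains only the ingroup leaves; the edge separating outgroup from
    ingroup and all outgroup branches are excluded, so divergence is measured
    from the ingroup's most recent common ancestor.
    """
    og = set(outgroup)
    labels = set(tree.leaf_labels())
    if not og:
        raise TreeError("outgroup must be non-empty")
    unknown = og - labels
    if unknown:
        raise TreeError(f"outgroup labels not in tree: {sorted(unknown)}")
    if og == labels:
        raise TreeError("outgroup cannot contain all leaves")
    ingroup = labels - og

    # leaf set under each node, keyed by id (nodes are not hashable by value)
    leafsets: dict[int, frozenset[str]] = {}
    parents: dict[int, Node | None] = {id(tree.root): None}

    def collect(node: Node) -> frozenset[str]:
        if node.is_leaf:
            ls = frozenset([node.label])  # type: ignore[list-item]
        else:
            parts = []
            for c in node.children:
                parents[id(c)] = node
                parts.append(collect(c))
            ls = frozenset().union(*parts)
        leafsets[id(node)] = ls
        return ls

    collect(tree.root)

    # Case A: the ingroup is a clade of the input as rooted — take it directly.
    for node in tree.preorder():
        if node is not tree.root and leafsets[id(node)] == ingroup:
            root = node.copy()
            root.branch_length = None
            return Tree(_collapse_unary(root))

    # Case B: the outgroup is a clade; re-root at its parent (the ingroup-side
    # endpoint of the separating edge) after cutting that edge.
    og_node = None
    for node in tree.preorder():
        if node is not tree.root and leafsets[id(node)] == og:
            og_node = node
            break
    if og_node is None:
        # not monophyletic — report the leaves that break it
        mrca = tree.root
        for node in tree.preorder():
            if og <= leafsets[id(node)] and len(leafsets[id(node)]) < len(leafsets[id(mrca)]):
                mrca = node
        violating = sorted(leafsets[id(mrca)] - og)
        raise TreeError(
            "outgroup is not monophyletic: its smallest containing clade also "
            f"holds {violating}"
        )

    attach = parents[id(og_node)]
    assert attach is not None

    # undirected adjacency with the separating edge removed
    adjacency: dict[int, list[tuple[Node, float]]] = {id(n): [] for n in tree.preorder()}
    for node in tree.preorder():
        for child in node.children:
            if child is og_node and node is attach:
                continue
            length = child.branch_length or 0.0
            adjacency[id(node)].append((child, length))
            adjacency[id(child)].append((node, length))

    def build(node: Node, prev: Node | None) -> Node:
        new = Node(label=node.label)
        for neighbour, length in adjacency[id(node)]:
            if neighbour is prev:
                continue
            child = build(neighbour, node)
            child.branch_length = length
            new.children.append(child)
        return new

    root = build(attach, None)
    root.branch_length = None
    return Tree(_collapse_unary(root))


def patristic_distance_matrix(tree: Tree) -> dict[frozenset[str], float]:
    """All pairwise leaf-to-leaf path lengths, keyed by label pair."""
    out: dict[frozenset[str], float] = {}

    def rec(node: Node) -> list[tuple[str, float]]:
        if node.is_leaf:
            return [(node.label, 0.0)]  # type: ignore[list-item]
        groups = []
        for c in node.children:
            depths = rec(c)
            groups.append([(lab, d + (c.branch_length or 0.0)) for lab, d in depths])
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for lab_a, da in groups[i]:
                    for lab_b, db in groups[j]:
                        out[frozenset((lab_a, lab_b))] = da + db
        return [pair for g in groups for pair in g]

    rec(tree.root)
    return out
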