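"""The B-index: tree-aware average divergence of a sequence family from its root.

The estimator reduces a rooted tree bottom-up.  A terminal branch of length
``d_i`` is a cluster of size ``w_i = 1``.  Clusters hanging from a common node
with stem branch ``d_s`` merge into a single cluster with

    d = (sum_i w_i d_i) / (sum_i w_i) + d_s
    w = (sum_i w_i d_i + d_s) / d          (w = sum_i w_i when d = 0)

At the root (``d_s = 0``) the final cluster gives the B-index ``D`` and the
effective size ``W``.  The product ``D * W`` equals the tree length ``L`` (the
sum of all branch lengths), which makes ``D`` an unbiased estimate of the
family's average divergence from its last common ancestor: on a clock-like
(ultrametric) tree of depth ``T``, ``D = T`` exactly, for any topology and any
subsample of the leaves.  ``2 * D`` is an unbiased analogue of the pairwise
distance, and the relative differentiation rate of two families sampled from
the same species is the ratio of their ``D`` (equivalently, of their tree
lengths when sizes match).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .treeio import Tree

__all__ = [
    "Cluster",
    "BIndexResult",
    "FamilyDivergence",
    "ComparisonReport",
    "DivergenceError",
    "SpeciesMismatchWarning",
    "merge_clusters",
    "compute_bindex",
    "mean_pairwise_distance",
    "family_divergence",
    "compare_families",
    "family_report",
    "comparison_report",
]


class DivergenceError(ValueError):
    """Raised on invalid inputs to the divergence computations."""


class SpeciesMismatchWarning(UserWarning):
    """Two compared families were not sampled from the same species set.

    The invariance argument behind the ratio comparison assumes identical
    species sampling; the ratios are still reported, with this warning.
    """


@dataclass(frozen=True)
class Cluster:
    """A (length, size) summary of a subtree during the reduction.

    ``d`` is the average divergence (substitutions/site) of the subtree's
    leaves from the top of the cluster's stem; ``w`` is the effective number
    of independent lineages the cluster represents.  The product ``d * w``
    equals the total branch length of the summarized subtree.
    """

    d: float
    w: float


def merge_clusters(children: Sequence[Cluster], stem_length: float = 0.0) -> Cluster:
    """Merge sibling clusters through their common stem branch.

    Generalizes the bifurcating merge to k >= 2 children; successive pairwise
    merges with zero-length stems give the same result in any order.  When the
    merged average length is 0 (all children and stem of length 0), the size
    is the sum of child sizes, the continuity limit of the general formula.
    """
    if len(children) < 2:
        raise DivergenceError("merge requires at least 2 child clusters")
    if stem_length < 0:
        raise DivergenceError(f"negative stem length: {stem_length}")
    sw = 0.0
    swd = 0.0
    for c in children:
        sw += c.w
        swd += c.w * c.d
    d = swd / sw + stem_length
    if d == 0.0:
        return Cluster(0.0, sw)
    return Cluster(d, (swd + stem_length) / d)


@dataclass(frozen=True)
class BIndexResult:
    """Outcome of the reduction on one tree.

    D is the B-index (substitutions/site), W the effective size, L = D*W the
    tree length, ``unbiased_pairwise`` is 2*D.
    """

    D: float
    W: float
    L: float
    unbiased_pairwise: float
    n_leaves: int


def compute_bindex(tree: Tree, *, allow_unrooted: bool = False) -> BIndexResult:
    """Reduce a rooted tree to its B-index.

    A basal multifurcation usually means the tree is unrooted; by default this
    raises with instructions to root (see ``treeio.root_by_outgroup``).  Pass
    ``allow_unrooted=True`` to treat the basal polytomy as a genuine
    multifurcating root and apply the k-ary merge there.
    """
    root = tree.root
    if root.is_leaf or tree.n_leaves < 2:
        raise DivergenceError("the B-index needs a tree with at least 2 leaves")
    if len(root.children) > 2 and not allow_unrooted:
        raise DivergenceError(
            "the root is a multifurcation, which usually means the tree is "
            "unrooted; root it with root_by_outgroup() first, or pass "
            "allow_unrooted=True to treat it as a true multifurcating root"
        )

    def reduce(node) -> Cluster:
        if node.is_leaf:
            return Cluster(node.branch_length, 1.0)
        kids = [reduce(c) for c in node.children]
        stem = 0.0 if node is root else node.branch_length
        if len(kids) == 1:  # defensive; normalized trees have no unary nodes
            return Cluster(kids[0].d + stem, kids[0].w)
        return merge_clusters(kids, stem)

    top = reduce(root)
    return BIndexResult(
        D=top.d,
        W=top.w,
        L=top.d * top.w,
        unbiased_pairwise=2.0 * top.d,
        n_leaves=tree.n_leaves,
    )


def mean_pairwise_distance(tree: Tree) -> float:
    """Arithmetic mean patristic distance over all unordered leaf pairs."""
    n = tree.n_leaves
    if n < 2:
        raise DivergenceError("mean pairwise distance needs at least 2 leaves")
    total = 0.0

    def rec(node) -> tuple[int, float]:
        """Return (#leaves, sum of leaf depths) below node; accumulate cross terms."""
        nonlocal total
        if node.is_leaf:
            return 1, 0.0
        groups = []
        for c in node.children:
            cnt, sm = rec(c)
            groups.append((cnt, sm + cnt * (c.branch_length or 0.0)))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ni, si = groups[i]
                nj, sj = groups[j]
                total += si * nj + sj * ni
        return sum(g[0] for g in groups), sum(g[1] for g in groups)

    rec(tree.root)
    return total / (n * (n - 1) / 2)


@dataclass(frozen=True)
class FamilyDivergence:
    """Divergence summary of one sequence family."""

    family: str
    species: frozenset[str]
    result: BIndexResult
    mean_pairwise: float

    @property
    def b_index(self) -> float:
        return self.result.D

    @property
    def size(self) -> float:
        return self.result.W

    @property
    def tree_length(self) -> float:
        return self.result.L

    @classmethod
    def from_summary(
        cls,
        family: str,
        b_index: float,
        size: float,
        tree_length: float | None = None,
        mean_pairwise: float = math.nan,
        n_leaves: int = 0,
        species: frozenset[str] = frozenset(),
    ) -> "FamilyDivergence":
        """Build a record from published summary numbers instead of a tree.

        Useful for re-deriving ratio blocks from a printed table.  When the
        printed ``tree_length`` is given it is kept verbatim (published
        roundings can make it differ from b_index*size in the last decimal);
        otherwise the product is used.
        """
        L = b_index * size if tree_length is None else tree_length
        res = BIndexResult(
            D=b_index,
            W=size,
            L=L,
            unbiased_pairwise=2.0 * b_index,
            n_leaves=n_leaves,
        )
        return cls(family=family, species=species, result=res, mean_pairwise=mean_pairwise)


def family_divergence(
    tree: Tree,
    family_name: str,
    species_delimiter: str = "_",
    *,
    allow_unrooted: bool = False,
) -> FamilyDivergence:
    """Bundle the B-index and mean pairwise distance for one family tree.

    Species codes are the leaf-label prefixes before ``species_delimiter``
    (a label without the delimiter counts whole as its species code).
    """
    result = compute_bindex(tree, allow_unrooted=allow_unrooted)
    species = frozenset(lab.split(species_delimiter, 1)[0] for lab in tree.leaf_labels())
    return FamilyDivergence(
        family=family_name,
        species=species,
        result=result,
        mean_pairwise=mean_pairwise_distance(tree),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Ratio block comparing a focal family B against a reference family C."""

    focal: str
    reference: str
    b_ratio: float
    l_ratio: float
    d_ratio: float
    w_ratio: float
    species_matched: bool


def compare_families(focal: FamilyDivergence, reference: FamilyDivergence) -> ComparisonReport:
    """Relative differentiation of a focal family against a reference.

    Reports B_B/B_C, L_B/L_C, D_B/D_C (mean pairwise) and W_B/W_C.  When the
    two species sets differ a :class:`SpeciesMismatchWarning` is issued — the
    ratios remain meaningful but the strict invariance argument assumes both
    families were sampled from the same species.
    """
    for name, value in (
        ("B-index", reference.b_index),
        ("tree length", reference.tree_length),
        ("mean pairwise distance", reference.mean_pairwise),
        ("size", reference.size),
    ):
        if value == 0:
            raise DivergenceError(f"reference family {reference.family!r} has zero {name}")
    matched = focal.species == reference.species
    if not matched and focal.species and reference.species:
        warnings.warn(
            f"families {focal.family!r} and {reference.family!r} were sampled "
            "from different species sets; rate ratios assume matched sampling",
            SpeciesMismatchWarning,
            stacklevel=2,
        )
    return ComparisonReport(
        focal=focal.family,
        reference=reference.family,
        b_ratio=focal.b_index / reference.b_index,
        l_ratio=focal.tree_length / reference.tree_length,
        d_ratio=focal.mean_pairwise / reference.mean_pairwise,
        w_ratio=focal.size / reference.size,
        species_matched=matched,
    )


# ---------------------------------------------------------------------------
# report writers (TSV)

_FAMILY_ROWS = (
    ("Size (W)", lambda fd: fd.size),
    ("B-index (B)", lambda fd: fd.b_index),
    ("Unbiased pair-wise distance (B x 2)", lambda fd: fd.result.unbiased_pairwise),
    ("L (B x W)", lambda fd: fd.tree_length),
    ("Average D_ij", lambda fd: fd.mean_pairwise),
)

_RATIO_ROWS = (
    ("B_B/B_C", lambda r: r.b_ratio),
    ("L_B/L_C", lambda r: r.l_ratio),
    ("D_B/D_C", lambda r: r.d_ratio),
    ("W_B/W_C", lambda r: r.w_ratio),
)


def _fmt(x: float, precision: int) -> str:
    return "nan" if math.isnan(x) else f"{x:.{precision}f}"


def family_report(fd: FamilyDivergence, precision: int = 4) -> str:
    """Single-family TSV report (Size, B-index, 2B, L, Average D_ij)."""
    lines = [f"Family\t{fd.family}", f"No. leaves\t{fd.result.n_leaves}"]
    lines += [f"{name}\t{_fmt(fn(fd), precision)}" for name, fn in _FAMILY_ROWS]
    return "\n".join(lines) + "\n"


def comparison_report(
    pairs: Sequence[tuple[FamilyDivergence, FamilyDivergence]],
    precision: int = 4,
) -> str:
    """Multi-column TSV comparison block, one (focal, reference) pair per column.

    Layout: focal rows (Size, B-index, 2B, L, Average D_ij), the same rows for
    each pair's reference family, then the four ratio rows.
    """
    if not pairs:
        raise DivergenceError("no family pairs to report")
    reports = [compare_families(f, r) for f, r in pairs]
    header = "\t" + "\t".join(f.family for f, _ in pairs)
    lines = [header]
    for name, fn in _FAMILY_ROWS:
        lines.append(name + "\t" + "\t".join(_fmt(fn(f), precision) for f, _ in pairs))
    lines.append("Reference\t" + "\t".join(r.family for _, r in pairs))
    for name, fn in _FAMILY_ROWS:
        lines.append(name + "\t" + "\t".join(_fmt(fn(r), precision) for _, r in pairs))
    for name, fn in _RATIO_ROWS:
        lines.append(name + "\t" + "\t".join(_fmt(fn(rep), precision) for rep in reports))
    return "\n".join(lines) + "\n"
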