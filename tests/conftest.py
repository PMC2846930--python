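"""Shared fixtures: random tree generators and an independent patristic oracle."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from bindex.simulate import SimulationConfig, apply_rate_heterogeneity, simulate_clock_tree
from bindex.treeio import Tree, parse_newick, write_newick

BALANCED_4LEAF = "((A:0.6,B:0.6):0.4,(C:0.6,D:0.6):0.4);"


@pytest.fixture
def balanced_tree() -> Tree:
    return parse_newick(BALANCED_4LEAF)


def random_tree(n_leaves: int, seed: int, sigma: float = 0.5, contract: float = 0.0) -> Tree:
    """Random non-ultrametric test tree.

    Built as a clock tree perturbed by lognormal branch-rate noise; with
    ``contract > 0`` each internal non-root edge is contracted with that
    probability (children re-attached to the grandparent with the contracted
    edge's length folded into theirs), producing multifurcations.
    """
    base = simulate_clock_tree(SimulationConfig(n_leaves=n_leaves, depth=1.0, seed=seed))
    tree = apply_rate_heterogeneity(base, sigma, seed + 1)
    if contract > 0:
        rng = np.random.default_rng(seed + 2)
        changed = True
        while changed:
            changed = False
            for node in tree.preorder():
                for child in list(node.children):
                    if child.is_leaf:
                        continue
                    if rng.random() < contract:
                        node.children.remove(child)
                        for g in child.children:
                            g.branch_length = (g.branch_length or 0.0) + (
                                child.branch_length or 0.0
                            )
                            node.children.append(g)
                        changed = True
    return tree


def subset_spanning_root(tree: Tree, k: int, rng: np.random.Generator) -> set[str]:
    """Random leaf subset of size k whose MRCA is the tree's root.

    Ensured by drawing at least one leaf from each of two different root
    children; the divergence estimate is defined from the common ancestor, so
    subsampling invariance applies to subsets sharing that ancestor.
    """
    clades = [Tree(c).leaf_labels() if not c.is_leaf else [c.label]
              for c in tree.root.children]
    first = [str(rng.choice(clades[0])), str(rng.choice(clades[1]))]
    rest = [lab for lab in tree.leaf_labels() if lab not in first]
    extra = [str(x) for x in rng.choice(rest, size=k - 2, replace=False)] if k > 2 else []
    return set(first + extra)


def dendropy_patristic(tree: Tree) -> dict[frozenset, float]:
    """Independent all-pairs patristic distances via dendropy."""
    dtree = dendropy.Tree.get(data=write_newick(tree, precision=12), schema="newick",
                              preserve_underscores=True)
    pdm = dtree.phylogenetic_distance_matrix()
    out: dict[frozenset, float] = {}
    taxa = list(dtree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out
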