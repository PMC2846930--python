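"""B-index reduction, pairwise statistics and the family comparison report."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindex.divergence import (
    Cluster,
    DivergenceError,
    SpeciesMismatchWarning,
    compare_families,
    comparison_report,
    compute_bindex,
    family_divergence,
    family_report,
    mean_pairwise_distance,
    merge_clusters,
)
from bindex.simulate import SimulationConfig, simulate_clock_tree
from bindex.treeio import parse_newick, prune_to_leaves

from conftest import random_tree


class TestMergeClusters:
    def test_two_leaf_average(self):
        c = merge_clusters([Cluster(0.3, 1), Cluster(0.5, 1)], 0.0)
        assert math.isclose(c.d, 0.4) and math.isclose(c.w, 2.0)

    def test_fork_with_stem(self):
        # d = (0.6+0.6)/2 + 0.4 = 1.0 ; w = (0.6+0.6+0.4)/1.0 = 1.6
        c = merge_clusters([Cluster(0.6, 1), Cluster(0.6, 1)], 0.4)
        assert math.isclose(c.d, 1.0) and math.isclose(c.w, 1.6)

    def test_zero_length_continuity_limit(self):
        c = merge_clusters([Cluster(0.0, 1), Cluster(0.0, 1)], 0.0)
        assert c.d == 0.0 and c.w == 2.0

    def test_invalid_inputs(self):
        with pytest.raises(DivergenceError):
            merge_clusters([Cluster(0.3, 1)], 0.0)
        with pytest.raises(DivergenceError):
            merge_clusters([Cluster(0.3, 1), Cluster(0.5, 1)], -0.1)

    def test_product_dw_is_subtree_branch_sum(self):
        # d*w after a merge = sum of child d_i*w_i plus the stem
        children = [Cluster(0.7, 1.3), Cluster(0.2, 2.5), Cluster(0.9, 1.0)]
        stem = 0.35
        c = merge_clusters(children, stem)
        assert math.isclose(c.d * c.w, sum(k.d * k.w for k in children) + stem, rel_tol=1e-12)

    @given(ds=st.lists(st.floats(0, 10, allow_nan=False), min_size=3, max_size=6))
    @settings(max_examples=50, derandomize=True)
    def test_merge_order_invariance(self, ds):
        """Resolving a k-furcation by pairwise zero-stem merges is order-independent."""
        leaves = [Cluster(d, 1.0) for d in ds]
        direct = merge_clusters(leaves, 0.0)
        for order in itertools.permutations(range(len(leaves))):
            acc = [leaves[i] for i in order]
            while len(acc) > 2:
                acc = [merge_clusters(acc[:2], 0.0)] + acc[2:]
            stepwise = merge_clusters(acc, 0.0)
            assert math.isclose(stepwise.d, direct.d, rel_tol=1e-9, abs_tol=1e-12)
            assert math.isclose(stepwise.w, direct.w, rel_tol=1e-9, abs_tol=1e-12)


class TestComputeBIndex:
    def test_two_leaf_tree(self):
        r = compute_bindex(parse_newick("(A:0.3,B:0.5);"))
        assert math.isclose(r.D, 0.4)
        assert math.isclose(r.W, 2.0)
        assert math.isclose(r.L, 0.8)
        assert r.unbiased_pairwise == 2 * r.D
        assert r.n_leaves == 2

    def test_balanced_ultrametric_hand_reduction(self, balanced_tree):
        r = compute_bindex(balanced_tree)
        assert math.isclose(r.D, 1.0)
        assert math.isclose(r.W, 3.2)
        assert math.isclose(r.L, 4 * 0.6 + 2 * 0.4)

    def test_single_leaf_rejected(self):
        with pytest.raises(DivergenceError):
            compute_bindex(parse_newick("A:1.0;"))

    def test_multifurcating_root_needs_explicit_consent(self):
        tree = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(DivergenceError, match="root"):
            compute_bindex(tree)
        r = compute_bindex(tree, allow_unrooted=True)
        assert math.isclose(r.D, 1.0) and math.isclose(r.W, 3.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_dw_equals_branch_sum(self, seed):
        """D*W = L against the brute-force branch sum, binary and multifurcating."""
        tree = random_tree(
            n_leaves=4 + 4 * (seed % 5), seed=seed, contract=0.4 if seed % 3 else 0.0
        )
        r = compute_bindex(tree, allow_unrooted=True)
        L = tree.total_length()
        assert math.isclose(r.L, L, rel_tol=1e-9)
        assert 2.0 <= r.W <= tree.n_leaves + 1e-9

    @pytest.mark.parametrize("n", [2, 3, 8, 33])
    def test_ultrametric_exactness(self, n):
        """On a clock tree of depth T, the estimator returns exactly T."""
        for seed in range(5):
            tree = simulate_clock_tree(SimulationConfig(n_leaves=n, depth=0.73, seed=seed))
            assert abs(compute_bindex(tree).D - 0.73) < 1e-12

    def test_subsampling_invariance(self):
        """Pruning an ultrametric tree to any subset with the same common
        ancestor (MRCA = root) never changes the estimate."""
        from conftest import subset_spanning_root

        tree = simulate_clock_tree(SimulationConfig(n_leaves=20, depth=1.5, seed=11))
        rng = np.random.default_rng(0)
        for k in (2, 3, 7, 15):
            keep = subset_spanning_root(tree, k, rng)
            sub = prune_to_leaves(tree, keep)
            assert abs(compute_bindex(sub).D - 1.5) < 1e-12

    def test_prune_to_nested_clade_measures_from_new_ancestor(self):
        """A subset nested inside one clade is re-rooted at its own MRCA, so
        the estimate becomes the (shallower) depth below that ancestor."""
        tree = parse_newick("((A:0.6,B:0.6):0.4,(C:0.6,D:0.6):0.4);")
        sub = prune_to_leaves(tree, {"A", "B"})
        assert abs(compute_bindex(sub).D - 0.6) < 1e-12

    def test_scaling_equivariance(self):
        tree = random_tree(n_leaves=10, seed=5)
        scaled = tree.copy()
        for node in scaled.preorder():
            if node.branch_length is not None:
                node.branch_length *= 3.0
        r1, r3 = compute_bindex(tree), compute_bindex(scaled)
        assert math.isclose(r3.D, 3 * r1.D, rel_tol=1e-9)
        assert math.isclose(r3.L, 3 * r1.L, rel_tol=1e-9)
        assert math.isclose(r3.W, r1.W, rel_tol=1e-9)
        assert math.isclose(mean_pairwise_distance(scaled), 3 * mean_pairwise_distance(tree),
                            rel_tol=1e-9)


class TestMeanPairwise:
    def test_single_pair(self):
        assert math.isclose(mean_pairwise_distance(parse_newick("(A:0.3,B:0.5);")), 0.8)

    def test_balanced_hand_enumeration(self, balanced_tree):
        # pairs: AB=1.2, CD=1.2, and 4 cross pairs of 2.0
        assert math.isclose(mean_pairwise_distance(balanced_tree), (1.2 + 1.2 + 4 * 2.0) / 6)

    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_oracle(self, seed):
        from conftest import dendropy_patristic

        tree = random_tree(n_leaves=9, seed=200 + seed, contract=0.3)
        dists = dendropy_patristic(tree)
        expected = sum(dists.values()) / len(dists)
        assert math.isclose(mean_pairwise_distance(tree), expected, rel_tol=1e-6)

    def test_pairwise_bound_on_ultrametric_trees(self):
        """mean D_ij <= 2D on clock trees, equality only for stars."""
        for seed in range(10):
            tree = simulate_clock_tree(SimulationConfig(n_leaves=12, depth=1.0, seed=seed))
            r = compute_bindex(tree)
            assert mean_pairwise_distance(tree) <= 2 * r.D + 1e-12
        star = parse_newick("(" + ",".join(f"L{i}:1.0" for i in range(6)) + ");")
        r = compute_bindex(star, allow_unrooted=True)
        assert math.isclose(mean_pairwise_distance(star), 2 * r.D, rel_tol=1e-12)


class TestFamilyComparison:
    def test_species_parsing(self, balanced_tree):
        tree = parse_newick("(Hs_X:0.3,Mm_X:0.5);")
        fd = family_divergence(tree, "X")
        assert fd.species == frozenset({"Hs", "Mm"})

    def test_family_bundle(self, balanced_tree):
        fd = family_divergence(balanced_tree, "toy")
        assert math.isclose(fd.size, 3.2)
        assert math.isclose(fd.b_index, 1.0)
        assert math.isclose(fd.tree_length, 3.2)
        assert math.isclose(fd.mean_pairwise, 26 / 15)

    def test_self_comparison_is_unity(self, balanced_tree):
        fd = family_divergence(balanced_tree, "toy")
        rep = compare_families(fd, fd)
        assert rep.b_ratio == rep.l_ratio == rep.d_ratio == rep.w_ratio == 1.0
        assert rep.species_matched

    def test_published_ratio_from_printed_summaries(self):
        """Published chaperonin family summaries reproduce the printed B ratio."""
        from bindex.divergence import FamilyDivergence

        mkks = FamilyDivergence.from_summary("MKKS", b_index=0.6976, size=5.7770)
        cct8 = FamilyDivergence.from_summary("CCT8", b_index=0.1146, size=5.5202)
        rep = compare_families(mkks, cct8)
        assert round(rep.b_ratio, 4) == 6.0873

    def test_scaled_tree_ratios(self):
        tree = random_tree(n_leaves=10, seed=77)
        scaled = tree.copy()
        for node in scaled.preorder():
            if node.branch_length is not None:
                node.branch_length *= 3.0
        # same leaf labels -> same species set, no warning expected
        rep = compare_families(
            family_divergence(scaled, "focal"), family_divergence(tree, "ref")
        )
        assert math.isclose(rep.b_ratio, 3.0, rel_tol=1e-9)
        assert math.isclose(rep.l_ratio, 3.0, rel_tol=1e-9)
        assert math.isclose(rep.d_ratio, 3.0, rel_tol=1e-9)
        assert math.isclose(rep.w_ratio, 1.0, rel_tol=1e-9)

    def test_species_mismatch_warns(self):
        fa = family_divergence(parse_newick("(Hs_X:0.3,Mm_X:0.5);"), "A")
        fb = family_divergence(parse_newick("(Hs_Y:0.3,Gg_Y:0.5);"), "B")
        with pytest.warns(SpeciesMismatchWarning):
            rep = compare_families(fa, fb)
        assert not rep.species_matched

    def test_zero_reference_rejected(self):
        from bindex.divergence import FamilyDivergence

        focal = FamilyDivergence.from_summary("F", b_index=1.0, size=2.0)
        zero = FamilyDivergence.from_summary("Z", b_index=0.0, size=2.0)
        with pytest.raises(DivergenceError, match="zero"):
            compare_families(focal, zero)


class TestReports:
    def test_family_report_layout(self, balanced_tree):
        text = family_report(family_divergence(balanced_tree, "toy"))
        assert "Size (W)\t3.2000" in text
        assert "B-index (B)\t1.0000" in text
        assert "L (B x W)\t3.2000" in text
        assert "Average D_ij\t1.7333" in text

    def test_comparison_report_ratio_rows(self, balanced_tree):
        fd = family_divergence(balanced_tree, "toy")
        text = comparison_report([(fd, fd)])
        assert "B_B/B_C\t1.0000" in text
        assert "L_B/L_C\t1.0000" in text
        assert "D_B/D_C\t1.0000" in text
        assert "W_B/W_C\t1.0000" in text
        assert text.splitlines()[0] == "\ttoy"
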