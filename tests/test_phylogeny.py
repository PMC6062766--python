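"""Distances, neighbor joining, bootstrap supports, consensus, Newick I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obpkit.phylogeny import (
    AlignedBlock,
    DistanceMatrix,
    InvalidMatrixError,
    NewickParseError,
    SaturationError,
    UndefinedDistanceError,
    bootstrap_supports,
    consensus_collapse,
    distance_matrix,
    neighbor_joining,
    p_distance,
    patristic_matrix,
    poisson_distance,
    read_newick,
    tree_bipartitions,
    write_newick,
)
from obpkit.synthetic_data import AlignmentSpec, gen_alignment

from _oracles import ls_best_topology, random_additive_matrix


def nj_splits_as_ints(tree):
    return {frozenset(int(l[1:]) for l in bip) for bip in tree_bipartitions(tree)}


class TestPDistance:
    def test_identical_rows_are_zero(self):
        assert p_distance("ACDE", "ACDE") == 0.0

    def test_one_in_four_differs(self):
        assert p_distance("ACDE", "ACDF") == 0.25

    def test_pairwise_deletion_skips_gapped_columns(self):
        assert p_distance("A-CD", "AACD", deletion="pairwise") == 0.0

    def test_all_gapped_pair_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("--AA", "AA--", deletion="pairwise")

    def test_complete_deletion_uses_block_columns(self):
        block = AlignedBlock(("a", "b", "c"), ("AACD", "AACD", "-ACD"))
        dm = distance_matrix(block, deletion="complete", correction="p")
        # column 0 is gapped in one row, so only 3 columns are compared
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 0.0


class TestPoissonDistance:
    def test_closed_form_values(self):
        assert poisson_distance(0.0) == 0.0
        assert math.isclose(poisson_distance(0.5), math.log(2), rel_tol=1e-12)
        assert poisson_distance(0.999999) > 13.0

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            poisson_distance(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=0.9999))
    def test_correction_dominates_p_everywhere(self, p):
        d = poisson_distance(p)
        assert d >= p
        # strict dominance (d = p + p^2/2 + ...) is representable only once
        # the quadratic term survives rounding
        if p > 1e-7:
            assert d > p

    def test_correction_dominates_p_and_is_monotone(self):
        grid = np.linspace(0.0, 0.99, 250)
        d = np.array([poisson_distance(p) for p in grid])
        assert np.all(d >= grid)
        assert d[0] == 0.0 and np.all(np.diff(d) > 0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), D))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:2):5,(C:3,D:4)) -> additive distances
        D = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float
        )
        labels = ("L00", "L01", "L02", "L03")
        tree = neighbor_joining(DistanceMatrix(labels, D))
        assert nj_splits_as_ints(tree) == {frozenset({2, 3})}
        assert np.allclose(patristic_matrix(tree, labels), D, atol=1e-9)

    def test_equidistant_taxa_deterministic_under_tie_rule(self):
        D = np.ones((4, 4)) - np.eye(4)
        labels = ("A", "B", "C", "D")
        newicks = {
            write_newick(neighbor_joining(DistanceMatrix(labels, D)))
            for _ in range(3)
        }
        assert len(newicks) == 1

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InvalidMatrixError):
            DistanceMatrix(("A", "B"), np.array([[0, 1], [2, 0]], float))
        with pytest.raises(InvalidMatrixError):
            DistanceMatrix(("A", "B"), np.array([[0, -1], [-1, 0]], float))

    @pytest.mark.parametrize("seed", range(12))
    def test_random_additive_matrices_match_exhaustive_search(self, seed):
        """NJ equals exhaustive least-squares topology search on additive input."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        D, true_splits = random_additive_matrix(n, rng)
        labels = tuple(f"L{i:02d}" for i in range(n))
        tree = neighbor_joining(DistanceMatrix(labels, D))
        assert np.allclose(patristic_matrix(tree, labels), D, atol=1e-9)
        ls_splits, resid = ls_best_topology(D)
        assert resid < 1e-12
        assert nj_splits_as_ints(tree) == set(ls_splits) == set(true_splits)


class TestBootstrap:
    def test_zero_replicates_gives_empty_supports(self):
        block, _ = gen_alignment(AlignmentSpec(), seed=1)
        result = bootstrap_supports(block, n_reps=0, seed=2)
        assert result.supports == {}

    def test_separated_clusters_get_high_central_support(self):
        block, truth = gen_alignment(AlignmentSpec(), seed=3)
        result = bootstrap_supports(block, n_reps=100, seed=4)
        central = truth["left"] if truth["left"] in result.supports else truth["right"]
        assert result.supports[central] >= 0.95
        assert all(0.0 <= s <= 1.0 for s in result.supports.values())

    def test_fixed_seed_reproduces_supports_exactly(self):
        block, _ = gen_alignment(AlignmentSpec(), seed=5)
        a = bootstrap_supports(block, n_reps=30, seed=6)
        b = bootstrap_supports(block, n_reps=30, seed=6)
        assert a.supports == b.supports


class TestConsensusCollapse:
    def _tree_and_supports(self, values):
        block, _ = gen_alignment(
            AlignmentSpec(
                clusters={
                    "x": ("A1", "A2"),
                    "y": ("B1", "B2"),
                    "z": ("C1", "C2"),
                }
            ),
            seed=7,
        )
        tree = neighbor_joining(distance_matrix(block))
        bips = list(tree_bipartitions(tree))
        supports = {bip: v for bip, v in zip(sorted(bips, key=sorted), values)}
        return tree, supports

    def test_full_support_leaves_tree_unchanged(self):
        tree, supports = self._tree_and_supports([1.0, 1.0, 1.0])
        out = consensus_collapse(tree, supports)
        assert tree_bipartitions(out).keys() == supports.keys()

    def test_zero_support_collapses_to_star(self):
        tree, supports = self._tree_and_supports([0.0, 0.0, 0.0])
        out = consensus_collapse(tree, supports)
        assert tree_bipartitions(out) == {}
        assert len(list(out.leaf_node_iter())) == 6

    def test_only_subthreshold_edge_collapses(self):
        tree, supports = self._tree_and_supports([0.49, 0.8, 0.9])
        collapsed_bip = min(supports, key=supports.get)
        out = consensus_collapse(tree, supports, cutoff=0.5)
        remaining = tree_bipartitions(out)
        assert collapsed_bip not in remaining
        assert len(remaining) == len(supports) - 1

    def test_missing_support_rejected(self):
        tree, supports = self._tree_and_supports([1.0, 1.0, 1.0])
        supports.pop(next(iter(supports)))
        with pytest.raises(ValueError):
            consensus_collapse(tree, supports)


class TestNewick:
    def test_round_trip_is_byte_stable(self):
        s = "(A:1,B:2,(C:3,D:4):5);"
        tree = read_newick(s)
        once = write_newick(tree)
        again = write_newick(read_newick(once))
        assert once == again
        assert len(list(tree.leaf_node_iter())) == 4

    def test_malformed_newick_rejected(self):
        with pytest.raises(NewickParseError):
            read_newick("(A:1,B:2,(C:3,D:4):5;")

    def test_nj_newick_preserves_patristic_distances(self):
        D = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float
        )
        labels = ("L00", "L01", "L02", "L03")
        tree = neighbor_joining(DistanceMatrix(labels, D))
        back = read_newick(write_newick(tree))
        assert np.allclose(patristic_matrix(back, labels), D, atol=1e-6)

    def test_cross_check_against_independent_nj(self):
        """Topology agrees with scikit-bio's NJ on a random additive matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        D, true_splits = random_additive_matrix(7, rng)
        labels = tuple(f"L{i:02d}" for i in range(7))
        ours = neighbor_joining(DistanceMatrix(labels, D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        ref_splits = set()
        n = len(labels)
        all_leaves = frozenset(range(n))
        for node in theirs.non_tips(include_self=False):
            side = frozenset(int(t.name[1:]) for t in node.tips())
            if 2 <= len(side) <= n - 2:
                ref_splits.add(side if 0 not in side else all_leaves - side)
        assert nj_splits_as_ints(ours) == ref_splits
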