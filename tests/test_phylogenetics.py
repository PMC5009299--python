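"""Alignment, distances, Neighbor-Joining and bootstrap supports."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from hsp_atlas import phylogenetics as ph
from hsp_atlas.formats_io import read_newick, write_newick

BLOSUM = ph._BLOSUM


def brute_force_global_score(a: str, b: str, gap_open=-10.0, gap_extend=-0.5) -> float:
    """Enumerate every global alignment (tiny inputs) and return the best
    affine-gap score; a gap of length k costs open + (k-1) * extend."""

    best = -np.inf

    def go(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, "M", score + BLOSUM[a[i], b[j]])
        if i < len(a):
            go(i + 1, j, "X", score + (gap_extend if prev == "X" else gap_open))
        if j < len(b):
            go(i, j + 1, "Y", score + (gap_extend if prev == "Y" else gap_open))

    go(0, 0, "", 0.0)
    return best


class TestPairwiseAlignment:
    def test_identical_sequences(self):
        (ra, rb, _), identity = ph.align_pair_global("ACDE", "ACDE")
        assert identity == 1.0 and "-" not in ra + rb

    def test_single_gap_identity(self):
        (ra, rb, _), identity = ph.align_pair_global("ACDE", "ACE")
        assert identity == 0.75
        assert sorted((ra, rb)) == ["AC-E", "ACDE"]

    @pytest.mark.parametrize(
        "a,b",
        [("AC", "A"), ("ACD", "AD"), ("MKVL", "MKL"), ("WWGC", "WGC"), ("ACDE", "CDE")],
    )
    def test_score_equals_exhaustive_enumeration(self, a, b):
        (_, _, score), _ = ph.align_pair_global(a, b)
        assert score == pytest.approx(brute_force_global_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ph.align_pair_global("", "ACD")


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self):
        msa = ph.progressive_msa([("a", "MKVLI")] * 1 + [("b", "MKVLI"), ("c", "MKVLI")])
        assert all("-" not in r for r in msa.rows)

    def test_planted_insertion_confined_to_block(self):
        msa = ph.progressive_msa(
            [("a", "MKVAAALI"), ("b", "MKVLI"), ("c", "MKVLI")]
        )
        by_id = dict(zip(msa.ids, msa.rows))
        assert by_id["b"] == by_id["c"]
        gap_run = by_id["b"].count("-")
        assert gap_run == 3 and "-" * 3 in by_id["b"]

    def test_column_count_at_least_max_input_length(self):
        seqs = [("a", "MKV"), ("b", "MKVLITPW"), ("c", "MKVLI")]
        msa = ph.progressive_msa(seqs)
        assert msa.length >= 8

    def test_single_sequence_returned_as_is(self):
        msa = ph.progressive_msa([("only", "MKVLI")])
        assert msa.rows == ["MKVLI"]


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = ph.Msa(["a", "b"], ["MKVL", "MKVL"])
        assert ph.distance_matrix(msa)[0, 1] == 0.0

    def test_poisson_closed_form(self):
        msa = ph.Msa(["a", "b"], ["A" * 9 + "C", "A" * 9 + "G"])  # p = 0.1
        d = ph.distance_matrix(msa, model="poisson")
        assert d[0, 1] == pytest.approx(0.10536, abs=1e-5)

    def test_symmetric_zero_diagonal(self):
        msa = ph.Msa(["a", "b", "c"], ["MKVL", "MKIL", "MQVL"])
        D = ph.distance_matrix(msa)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_gap_columns_pairwise_deleted(self):
        msa = ph.Msa(["a", "b"], ["MK-L", "MKVL"])
        assert ph.distance_matrix(msa)[0, 1] == 0.0

    def test_saturated_poisson_errors(self):
        msa = ph.Msa(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="undefined"):
            ph.distance_matrix(msa, model="poisson")


def random_additive_tree(rng, n_leaves):
    """A random binary tree with branch lengths and its additive matrix."""
    ids = [f"L{i}" for i in range(n_leaves)]
    nodes = {i: [i] for i in range(n_leaves)}
    dist = np.zeros((n_leaves, n_leaves))
    height = {i: 0.0 for i in range(n_leaves)}
    # agglomerate randomly, adding random positive branch lengths
    active = list(range(n_leaves))
    paths = {i: {i: 0.0} for i in range(n_leaves)}  # leaf -> dist to current root

    class Node:
        def __init__(self, leaves, dists):
            self.leaves = leaves
            self.dists = dists  # leaf -> distance to this node

    items = [Node([i], {i: 0.0}) for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        for x in a.leaves:
            for y in b.leaves:
                dist[x, y] = dist[y, x] = a.dists[x] + la + b.dists[y] + lb
        merged = Node(
            a.leaves + b.leaves,
            {**{x: d + la for x, d in a.dists.items()},
             **{y: d + lb for y, d in b.dists.items()}},
        )
        items.append(merged)
    return ids, dist


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits, each written as the side holding a fixed leaf."""
    out = set()
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if min(len(side), len(leaves) - len(side)) < 2:
            continue
        out.add(side if ref in side else frozenset(leaves - side))
    return out


def patristic_matrix(tree: dendropy.Tree, ids: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    ns = tree.taxon_namespace
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                ns.get_taxon(ids[i]), ns.get_taxon(ids[j])
            )
    return D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = ph.nj_tree(D, ["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_recovers_known_quartet(self):
        # ((A:1,B:2):1,(C:3,D:4))
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = ph.nj_tree(D, list("ABCD"))
        assert frozenset("AB") in tree_bipartitions(tree) or frozenset("CD") in tree_bipartitions(tree)
        assert np.allclose(patristic_matrix(tree, list("ABCD")), D)

    def test_exact_on_random_additive_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            ids, D = random_additive_tree(rng, n)
            tree = ph.nj_tree(D, ids)
            assert np.allclose(patristic_matrix(tree, ids), D, atol=1e-9)

    def test_agrees_with_dendropy_nj_on_ultrametric(self):
        """Independent oracle: dendropy's NJ yields the same topology."""
        rng = np.random.default_rng(3)
        ids, D = random_additive_tree(rng, 8)
        mine = ph.nj_tree(D, ids)
        csv_rows = ["," + ",".join(ids)]
        for i, row in enumerate(D):
            csv_rows.append(ids[i] + "," + ",".join(f"{x:.10f}" for x in row))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO("\n".join(csv_rows)),
            taxon_namespace=dendropy.TaxonNamespace(ids),
        )
        theirs = pdm.nj_tree()
        assert tree_bipartitions(mine) == tree_bipartitions(theirs)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ph.nj_tree(D, list("abc"))


def perfect_alignment():
    """Zero-homoplasy 5-taxon alignment, 20 columns.

    Both internal splits (AB|CDE and ABC|DE) are supported by 10
    columns each and nothing conflicts, so every bootstrap replicate
    that retains at least one column of each type (probability
    1 - 2*(1/2)^20 per replicate) contains both reference bipartitions.
    """
    taxa = list("ABCDE")
    rows = {
        "A": "W" * 10 + "W" * 10,
        "B": "W" * 10 + "W" * 10,
        "C": "G" * 10 + "W" * 10,
        "D": "G" * 10 + "G" * 10,
        "E": "G" * 10 + "G" * 10,
    }
    return ph.Msa(taxa, [rows[t] for t in taxa])


class TestBootstrap:
    def test_perfect_signal_gives_full_support(self):
        tree = ph.bootstrap_support(perfect_alignment(), n_replicates=200, seed=5)
        supports = [n.support for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n is not tree.seed_node and hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_seed_fixed_identical_supports(self):
        msa = perfect_alignment()
        t1 = ph.bootstrap_support(msa, n_replicates=50, seed=9)
        t2 = ph.bootstrap_support(msa, n_replicates=50, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_invariant_under_leaf_relabeling(self):
        msa = perfect_alignment()
        t1 = ph.bootstrap_support(msa, n_replicates=100, seed=2)
        # relabel by reversing the id order (same data, new names)
        mapping = dict(zip(msa.ids, reversed(msa.ids)))
        msa2 = ph.Msa([mapping[i] for i in msa.ids], msa.rows)
        t2 = ph.bootstrap_support(msa2, n_replicates=100, seed=2)
        sup1 = sorted(
            n.support for n in t1.preorder_node_iter() if hasattr(n, "support")
        )
        sup2 = sorted(
            n.support for n in t2.preorder_node_iter() if hasattr(n, "support")
        )
        assert sup1 == sup2

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            ph.bootstrap_support(perfect_alignment(), n_replicates=0)

    def test_supports_roundtrip_through_newick(self):
        tree = ph.bootstrap_support(perfect_alignment(), n_replicates=20, seed=1)
        text = write_newick(tree)
        back = read_newick(text)
        labels = [n.label for n in back.preorder_node_iter() if n.label]
        assert labels and all(0 <= float(x) <= 100 for x in labels)
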