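"""Neighbor-joining, bootstrap support and bipartition comparison."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from evorate import seqio
from evorate.distance import DistanceMatrix, distance_matrix
from evorate.errors import EvorateError, IncompleteMatrixError
from evorate.treebuild import (
    additive_matrix,
    bootstrap_support,
    compare_bipartitions,
    nj_tree,
)

from oracles import (
    additive_matrix_from,
    adjacency_bipartitions,
    least_squares_topology,
    random_additive_tree,
)


def _dm(taxa, values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(
        taxa=list(taxa),
        values=values,
        model="p_distance",
        deletion="pairwise",
        sites_used=np.zeros_like(values, dtype=int),
    )


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = _dm("ABC", [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(dm)
        # v_A = (d_AB + d_AC - d_BC)/2 etc.
        paths = tree.path_lengths()
        assert paths[0, 1] == pytest.approx(0.3)
        assert paths[0, 2] == pytest.approx(0.5)
        assert paths[1, 2] == pytest.approx(0.6)
        assert tree.n_branches == 3

    def test_additive_five_taxon_round_trip(self, rng):
        adj, lengths = random_additive_tree(rng, 5)
        matrix = additive_matrix_from(adj, lengths, 5)
        dm = _dm([f"t{i}" for i in range(5)], matrix)
        tree = nj_tree(dm)
        np.testing.assert_allclose(tree.path_lengths(), matrix, atol=1e-10)
        assert tree.n_branches == 2 * 5 - 3

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_topology_matches_exhaustive_least_squares(self, n, rng):
        for _ in range(8):
            adj, lengths = random_additive_tree(rng, n)
            matrix = additive_matrix_from(adj, lengths, n)
            dm = _dm([f"t{i}" for i in range(n)], matrix)
            tree = nj_tree(dm)
            best, ssq = least_squares_topology(matrix)
            assert ssq < 1e-18
            want = adjacency_bipartitions(best, n)
            got = {
                frozenset(int(t[1:]) for t in bp) for bp in tree.bipartitions()
            }
            assert got == want

    def test_agrees_with_skbio_on_additive_matrix(self, rng):
        """Independent NJ implementation recovers the same topology."""
        n = 7
        adj, lengths = random_additive_tree(rng, n)
        matrix = additive_matrix_from(adj, lengths, n)
        taxa = [f"t{i}" for i in range(n)]
        import io

        ours = nj_tree(_dm(taxa, matrix)).newick()
        buf = io.StringIO()
        skbio_nj(SkbioDM(matrix, ids=taxa)).write(buf, format="newick")
        theirs = buf.getvalue()
        ns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=ns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=ns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert treecompare.symmetric_difference(t1, t2) == 0

    def test_branch_lengths_never_negative(self, rng):
        for _ in range(20):
            n = 6
            noise = rng.normal(0, 0.05, size=(n, n))
            noise = np.abs(noise + noise.T)
            np.fill_diagonal(noise, 0)
            adj, lengths = random_additive_tree(rng, n)
            matrix = additive_matrix_from(adj, lengths, n) + noise
            tree = nj_tree(_dm([f"t{i}" for i in range(n)], matrix))
            for _, nbrs in tree.adjacency.items():
                for _, length in nbrs:
                    assert length >= 0.0

    def test_missing_entries_refused(self):
        values = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(IncompleteMatrixError):
            nj_tree(_dm("ABC", values))

    def test_too_few_taxa(self):
        with pytest.raises(EvorateError):
            nj_tree(_dm("AB", [[0, 0.1], [0.1, 0]]))

    def test_additive_matrix_helper_round_trip(self, rng):
        adj, lengths = random_additive_tree(rng, 6)
        matrix = additive_matrix_from(adj, lengths, 6)
        tree = nj_tree(_dm([f"t{i}" for i in range(6)], matrix))
        np.testing.assert_allclose(
            additive_matrix(tree).values, matrix, atol=1e-10
        )


def _two_group_alignment(n_cols=60):
    """Two clearly distinct sequence groups; every column supports the split."""
    left = "A" * n_cols
    right = "C" * n_cols
    return seqio.LocusAlignment(
        locus="x",
        members={"a1": left, "a2": left, "b1": right, "b2": right},
    )


class TestBootstrap:
    def test_uniform_signal_full_support(self):
        tree = bootstrap_support(_two_group_alignment(), b_replicates=100, seed=3)
        bps = tree.bipartitions()
        assert len(bps) == 1
        assert tree.support[next(iter(bps))] == 100.0

    def test_single_replicate_supports_binary(self, study_dataset):
        concat = seqio.concatenate(
            list(study_dataset.loci.values()), study_dataset.locus_order
        )
        tree = bootstrap_support(concat, b_replicates=1, seed=5)
        assert set(tree.support.values()) <= {0.0, 100.0}

    def test_replicates_reproducible(self):
        aln = _two_group_alignment()
        t1 = bootstrap_support(aln, b_replicates=20, seed=9)
        t2 = bootstrap_support(aln, b_replicates=20, seed=9)
        assert t1.support == t2.support
        assert t1.newick(with_support=True) == t2.newick(with_support=True)

    def test_stratified_resampling_runs(self, study_dataset):
        concat = seqio.concatenate(
            list(study_dataset.loci.values()), study_dataset.locus_order
        )
        tree = bootstrap_support(
            concat, b_replicates=10, seed=2, stratified=True
        )
        assert all(0.0 <= s <= 100.0 for s in tree.support.values())


class TestCompareBipartitions:
    def test_identical_trees(self, rng):
        adj, lengths = random_additive_tree(rng, 6)
        matrix = additive_matrix_from(adj, lengths, 6)
        dm = _dm([f"t{i}" for i in range(6)], matrix)
        a, b = nj_tree(dm), nj_tree(dm)
        cmp = compare_bipartitions(a, b)
        assert cmp.unique_a == cmp.unique_b == 0
        assert cmp.shared == 3  # n - 3 internal bipartitions

    def test_four_taxon_alternative_resolutions(self):
        # additive matrices supporting (AB|CD) vs (AC|BD)
        ab_cd = _dm("ABCD", [[0, 0.2, 1, 1], [0.2, 0, 1, 1], [1, 1, 0, 0.2], [1, 1, 0.2, 0]])
        ac_bd = _dm("ABCD", [[0, 1, 0.2, 1], [1, 0, 1, 0.2], [0.2, 1, 0, 1], [1, 0.2, 1, 0]])
        cmp = compare_bipartitions(nj_tree(ab_cd), nj_tree(ac_bd))
        assert cmp.shared == 0
        assert cmp.unique_a == 1
        assert cmp.unique_b == 1
        assert cmp.rf_distance == 2

    def test_leaf_set_mismatch(self, rng):
        adj, lengths = random_additive_tree(rng, 5)
        matrix = additive_matrix_from(adj, lengths, 5)
        a = nj_tree(_dm([f"t{i}" for i in range(5)], matrix))
        b = nj_tree(_dm([f"u{i}" for i in range(5)], matrix))
        with pytest.raises(EvorateError):
            compare_bipartitions(a, b)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 8))
            taxa = [f"t{i}" for i in range(n)]
            trees = []
            for _ in range(2):
                adj, lengths = random_additive_tree(rng, n)
                matrix = additive_matrix_from(adj, lengths, n)
                trees.append(nj_tree(_dm(taxa, matrix)))
            cmp = compare_bipartitions(*trees)
            sets = []
            for t in trees:
                ref = set(trees[0].taxa)
                bps = {
                    frozenset(ref - bp) if taxa[0] in bp else bp
                    for bp in t.bipartitions()
                }
                sets.append(bps)
            assert cmp.shared == len(sets[0] & sets[1])
            assert cmp.rf_distance == len(sets[0] ^ sets[1])


class TestNewick:
    def test_newick_parses_and_preserves_paths(self, rng):
        adj, lengths = random_additive_tree(rng, 6)
        matrix = additive_matrix_from(adj, lengths, 6)
        taxa = [f"t{i}" for i in range(6)]
        tree = nj_tree(_dm(taxa, matrix))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        ns = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                got = pdm.distance(ns[a], ns[b])
                assert got == pytest.approx(
                    matrix[taxa.index(a), taxa.index(b)], abs=1e-9
                )

    def test_support_labels_in_newick(self):
        tree = bootstrap_support(_two_group_alignment(), b_replicates=10, seed=1)
        assert "100" in tree.newick(with_support=True)
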