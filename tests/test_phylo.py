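"""Distances, neighbor joining, bootstrap and subfamily assignment."""

import numpy as np
import pytest

from burpfam.phylo import (
    DistanceMatrix,
    ProteinAlignment,
    assign_subfamilies,
    bootstrap_support,
    nj_tree,
    path_length_matrix,
    protein_distance,
    tree_bipartitions,
)


class TestDistances:
    def test_identical_rows_zero(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["MKLV", "MKLV"])
        assert protein_distance(aln, "p").d[0, 1] == 0.0

    def test_p_distance_quarter(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["AAAA", "AAAT"])
        assert protein_distance(aln, "p").d[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_of_gaps(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["AA-C", "AAGA"])
        # only 3 comparable columns, one mismatch
        assert protein_distance(aln, "p").d[0, 1] == pytest.approx(1 / 3)

    def test_matches_counting_oracle(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY-")
        rows = ["".join(rng.choice(alphabet, size=100)) for _ in range(4)]
        aln = ProteinAlignment(ids=list("abcd"), rows=rows)
        dm = protein_distance(aln, "p")
        for i in range(4):
            for j in range(i + 1, 4):
                mism = comp = 0
                for x, y in zip(rows[i], rows[j]):
                    if x in "-.X" or y in "-.X":
                        continue
                    comp += 1
                    mism += x != y
                assert dm.d[i, j] == pytest.approx(mism / comp)

    def test_poisson_is_log_corrected(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["AAAA", "AAAT"])
        assert protein_distance(aln, "poisson").d[0, 1] == pytest.approx(
            -np.log(0.75)
        )

    def test_saturated_pair_flagged(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["AAAA", "TTTT"])
        dm = protein_distance(aln, "poisson")
        assert ("a", "b") in dm.saturated and np.isfinite(dm.d[0, 1])

    def test_no_comparable_columns_is_error(self):
        aln = ProteinAlignment(ids=["a", "b"], rows=["A--", "-AA"])
        with pytest.raises(ValueError, match="a.*b"):
            protein_distance(aln)


class TestNeighborJoining:
    def test_three_taxa_solves_point_formulas(self):
        # d(ab)=5, d(ac)=7, d(bc)=8 -> a:2, b:3, c:5
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 5, 7], [5, 0, 8], [7, 8, 0]], float))
        labels, P = path_length_matrix(nj_tree(dm))
        d = dict()
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                d[li + lj] = P[i, j]
        assert d["ab"] == pytest.approx(5)
        assert d["ac"] == pytest.approx(7)
        assert d["bc"] == pytest.approx(8)

    def test_additive_matrix_reproduced_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): additive distances
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(list("ABCD"), d)
        labels, P = path_length_matrix(nj_tree(dm))
        order = [labels.index(x) for x in "ABCD"]
        assert np.abs(P[np.ix_(order, order)] - d).max() < 1e-9

    def test_recovers_topology_against_least_squares_enumeration(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(list("ABCD"), d)
        t = nj_tree(dm)
        # the best of the three unrooted 4-taxon topologies pairs (A,B)|(C,D):
        # check by four-point condition (smallest sum identifies the split)
        sums = {
            "AB|CD": d[0, 1] + d[2, 3],
            "AC|BD": d[0, 2] + d[1, 3],
            "AD|BC": d[0, 3] + d[1, 2],
        }
        assert min(sums, key=sums.get) == "AB|CD"
        assert frozenset("AB") in tree_bipartitions(t.tree) or frozenset(
            "CD"
        ) in tree_bipartitions(t.tree)

    def test_ultrametric_matrix_matches_upgma_oracle(self):
        # ultrametric: ((A,B):2,(C,D):1) with heights 1,3
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        from scipy.cluster.hierarchy import average, fcluster
        from scipy.spatial.distance import squareform

        Z = average(squareform(d))
        upgma_groups = fcluster(Z, t=2, criterion="maxclust")
        t = nj_tree(DistanceMatrix(list("ABCD"), d))
        bp = tree_bipartitions(t.tree)
        assert frozenset("AB") in bp or frozenset("CD") in bp
        assert upgma_groups[0] == upgma_groups[1] != upgma_groups[2]

    def test_topology_agrees_with_scikit_bio(self, rng):
        """Independent NJ implementation (scikit-bio) yields the same
        unrooted topology on random noisy distance matrices."""
        skbio = pytest.importorskip("skbio")
        import dendropy

        for _ in range(5):
            n = 6
            coords = rng.random((n, 3)) * 5
            d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
            ids = [f"t{k}" for k in range(n)]
            ours = nj_tree(DistanceMatrix(ids, d))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
            their_tree = dendropy.Tree.get(
                data=str(theirs), schema="newick"
            )
            assert tree_bipartitions(ours.tree) == tree_bipartitions(their_tree)

    def test_fewer_than_three_taxa_is_error(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_negative_branch_clamped_and_logged(self):
        d = np.array(
            [[0, 1, 1, 1.9], [1, 0, 1.9, 1], [1, 1.9, 0, 1], [1.9, 1, 1, 0]]
        )
        t = nj_tree(DistanceMatrix(list("ABCD"), d))
        lengths = [
            nd.edge.length
            for nd in t.tree.preorder_node_iter()
            if nd.edge.length is not None
        ]
        assert all(l >= 0 for l in lengths)


class TestBootstrap:
    def _aln(self):
        # two clearly separated clades
        rows = [
            "AAAAAAAAAACCCCCCCCCC",
            "AAAAAAAAAACCCCCCCCCA",
            "TTTTTTTTTTGGGGGGGGGG",
            "TTTTTTTTTTGGGGGGGGGA",
        ]
        return ProteinAlignment(ids=list("abcd"), rows=rows)

    def test_strong_signal_high_support(self):
        t = bootstrap_support(self._aln(), n_reps=100, seed=0)
        supports = [
            int(nd.label)
            for nd in t.tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None and nd.label
        ]
        assert supports and min(supports) >= 95

    def test_single_replicate_supports_are_binary(self):
        t = bootstrap_support(self._aln(), n_reps=1, seed=3)
        for nd in t.tree.preorder_node_iter():
            if not nd.is_leaf() and nd.parent_node is not None and nd.label:
                assert int(nd.label) in (0, 100)

    def test_same_seed_same_supports(self):
        t1 = bootstrap_support(self._aln(), n_reps=25, seed=7)
        t2 = bootstrap_support(self._aln(), n_reps=25, seed=7)
        assert t1.newick() == t2.newick()

    def test_row_order_permutation_invariance(self):
        aln = self._aln()
        perm = ProteinAlignment(
            ids=[aln.ids[i] for i in (2, 0, 3, 1)],
            rows=[aln.rows[i] for i in (2, 0, 3, 1)],
        )
        t1 = bootstrap_support(aln, n_reps=50, seed=5)
        t2 = bootstrap_support(perm, n_reps=50, seed=5)

        def support_map(t):
            out = {}
            all_ids = frozenset(aln.ids)
            for nd in t.tree.preorder_node_iter():
                if nd.is_leaf() or nd.parent_node is None or not nd.label:
                    continue
                side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                canon = min(side, all_ids - side, key=lambda s: (len(s), sorted(s)))
                out[canon] = int(nd.label)
            return out

        assert support_map(t1) == support_map(t2)


class TestSubfamilies:
    def test_seeded_clades(self):
        import dendropy

        t = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        got = assign_subfamilies(t, {"X": ["a"], "Y": ["c"]})
        assert got == {"a": "X", "b": "X", "c": "Y", "d": "Y"}

    def test_leaf_outside_seeded_clades_unassigned(self):
        import dendropy

        t = dendropy.Tree.get(data="((a,b),(c,d),e);", schema="newick")
        got = assign_subfamilies(t, {"X": ["a"], "Y": ["c"]})
        assert got["e"] == "unassigned"

    def test_missing_seed_is_error(self):
        import dendropy

        t = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        with pytest.raises(ValueError, match="zzz"):
            assign_subfamilies(t, {"X": ["zzz"]})

    def test_simulated_family_recovery(self, family):
        t = nj_tree(protein_distance(family.alignment))
        got = assign_subfamilies(t, family.subfamily_seeds)
        truth = dict(zip(family.truth_members.id, family.truth_members.subfamily))
        acc = np.mean([got[g] == truth[g] for g in got])
        assert acc >= 0.95
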