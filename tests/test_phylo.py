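"""MSA, identity matrices, neighbor joining, bootstrap, RF distance,
subgroup classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micromine import phylo
from micromine.errors import MicromineError
from micromine.io import SequenceRecord

from conftest import random_additive_tree

AA = "ACDEFGHIKLMNPQRSTVWY"


def _recs(seqs):
    return [SequenceRecord(id=f"s{i}", residues=s) for i, s in enumerate(seqs)]


class TestProgressiveMsa:
    def test_identical_sequences_align_without_gaps(self):
        aln = phylo.progressive_msa(_recs(["MKVLA" * 10] * 4))
        assert all(row == "MKVLA" * 10 for row in aln.rows)

    def test_two_sequences_equal_pairwise_global_optimum(self, rng):
        from Bio.Align import PairwiseAligner, substitution_matrices

        B = substitution_matrices.load("BLOSUM62")
        pa = PairwiseAligner()
        pa.mode = "global"
        pa.substitution_matrix = B
        pa.open_gap_score = -10.5
        pa.extend_gap_score = -0.5

        def row_score(r1, r2):
            s, gap = 0.0, None
            for x, y in zip(r1, r2):
                if x == "-" or y == "-":
                    which = 0 if x == "-" else 1
                    s -= 10.5 if gap != which else 0.5
                    gap = which
                else:
                    s += B[x][y]
                    gap = None
            return s

        for _ in range(15):
            a = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(15, 60)))
            b = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(15, 60)))
            aln = phylo.progressive_msa(_recs([a, b]))
            assert row_score(*aln.rows) == pytest.approx(pa.score(a, b))

    def test_column_count_at_least_longest_input(self, rng):
        seqs = ["".join(AA[i] for i in rng.integers(0, 20, n)) for n in (30, 45, 60)]
        aln = phylo.progressive_msa(_recs(seqs))
        assert aln.n_columns >= 60
        for rec, i in zip(seqs, range(3)):
            assert aln.degapped(i) == rec  # removing gaps restores inputs

    def test_single_sequence_rejected(self):
        with pytest.raises(MicromineError):
            phylo.progressive_msa(_recs(["MKVL"]))


class TestIdentityMatrix:
    def test_hand_counted_toy_values(self):
        aln = phylo.ProteinAlignment(ids=["a", "b"], rows=["AC-GT", "ACAGT"])
        m = phylo.percent_identity_matrix(aln)
        assert m.values[0, 1] == 100.0  # 4 co-aligned, 4 matches
        aln2 = phylo.ProteinAlignment(ids=["a", "b"], rows=["ACAGT", "ACCGT"])
        m2 = phylo.percent_identity_matrix(aln2)
        assert m2.values[0, 1] == 80.0  # 4/5

    def test_include_gaps_denominator(self):
        aln = phylo.ProteinAlignment(ids=["a", "b"], rows=["AC-GT", "ACAGT"])
        m = phylo.percent_identity_matrix(aln, include_gaps=True)
        assert m.values[0, 1] == 80.0  # 4 matches over 5 occupied columns

    def test_symmetric_with_diagonal_100(self, rng):
        seqs = ["".join(AA[i] for i in rng.integers(0, 20, 40)) for _ in range(5)]
        m = phylo.percent_identity_matrix(phylo.progressive_msa(_recs(seqs)))
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 100.0)

    def test_disjoint_pair_warns_and_scores_zero(self):
        aln = phylo.ProteinAlignment(ids=["a", "b"], rows=["AAAA----", "----CCCC"])
        with pytest.warns(UserWarning, match="no co-aligned"):
            m = phylo.percent_identity_matrix(aln)
        assert m.values[0, 1] == 0.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = phylo.nj_tree(["A", "B", "C"], D)
        lens = {n.name: n.length for n in tree.root.children}
        assert lens["A"] == pytest.approx(0.05, abs=1e-12)
        assert lens["B"] == pytest.approx(0.15, abs=1e-12)
        assert lens["C"] == pytest.approx(0.25, abs=1e-12)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:0.1,B:0.2):0.15,C:0.3,D:0.4)
        D = np.array(
            [
                [0.0, 0.3, 0.55, 0.65],
                [0.3, 0.0, 0.65, 0.75],
                [0.55, 0.65, 0.0, 0.7],
                [0.65, 0.75, 0.7, 0.0],
            ]
        )
        tree = phylo.nj_tree(list("ABCD"), D)
        assert tree.splits() == {
            frozenset((frozenset("AB"), frozenset("CD")))
        }
        lens = {}
        for n in tree.root.traverse(include_self=False):
            key = "".join(sorted(t.name for t in n.tips())) or n.name
            lens[key] = n.length
        assert lens["A"] == pytest.approx(0.1, abs=1e-12)
        assert lens["B"] == pytest.approx(0.2, abs=1e-12)
        assert lens["AB"] == pytest.approx(0.15, abs=1e-12)

    def test_additive_consistency_on_random_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 11))
            D, true_splits, _lens = random_additive_tree(n, rng)
            tree = phylo.nj_tree([f"L{i}" for i in range(n)], D)
            assert tree.splits() == true_splits

    def test_agreement_with_independent_nj_implementation(self, rng):
        """Cross-check against scikit-bio's neighbor joining on a noisy
        (non-additive) matrix: same topology."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        n = 8
        D, _s, _l = random_additive_tree(n, rng)
        D = D + rng.uniform(0, 0.01, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = [f"L{i}" for i in range(n)]
        mine = phylo.nj_tree(ids, D)
        theirs = phylo.PhyloTree(skbio_nj(DistanceMatrix(D, ids)))
        assert phylo.rf_distance(mine, theirs) == 0

    def test_equal_distances_are_deterministic(self):
        D = np.ones((5, 5)) - np.eye(5)
        t1 = phylo.nj_tree(list("ABCDE"), D)
        t2 = phylo.nj_tree(list("ABCDE"), D)
        assert t1.to_newick() == t2.to_newick()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(MicromineError):
            phylo.nj_tree(["A", "B", "C"], np.array([[0, 1, 2], [1, 0, 3], [2.5, 3, 0]]))
        bad_diag = np.array([[-0.1, 1, 2], [1, 0, 3], [2, 3, 0]])
        with pytest.raises(MicromineError):
            phylo.nj_tree(["A", "B", "C"], (bad_diag + bad_diag.T) / 2)


class TestBootstrap:
    def _paired_alignment(self):
        # two identical-sequence pairs: every column supports the split
        rows = ["MKLV" * 15, "MKLV" * 15, "WDEF" * 15, "WDEF" * 15]
        return phylo.ProteinAlignment(ids=["a1", "a2", "b1", "b2"], rows=rows)

    def test_fully_supported_split_scores_100(self):
        tree = phylo.bootstrap_support(self._paired_alignment(), n_reps=50, seed=1)
        assert list(tree.split_supports().values()) == [100.0]

    def test_supports_within_range_and_deterministic(self, cohort):
        vp1s = []
        for truth in cohort.truths[:6]:
            vp1 = next(o for o in truth.orfs if o.role == "VP1")
            vp1s.append(SequenceRecord(id=truth.genome_id, residues=vp1.protein))
        aln = phylo.progressive_msa(vp1s)
        t1 = phylo.bootstrap_support(aln, n_reps=30, seed=5)
        t2 = phylo.bootstrap_support(aln, n_reps=30, seed=5)
        s1, s2 = t1.split_supports(), t2.split_supports()
        assert s1 == s2
        assert all(0 <= v <= 100 for v in s1.values())


class TestRfDistance:
    def test_identical_trees_zero(self):
        t = phylo.PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        assert phylo.rf_distance(t, t) == 0

    def test_two_quartet_topologies_distance_two(self):
        t1 = phylo.PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = phylo.PhyloTree.from_newick("((A:1,C:1):1,B:1,D:1);")
        assert phylo.rf_distance(t1, t2) == 2
        assert phylo.rf_distance(t2, t1) == 2

    def test_differing_leaf_sets_rejected(self):
        t1 = phylo.PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = phylo.PhyloTree.from_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(MicromineError):
            phylo.rf_distance(t1, t2)

    def test_agreement_with_dendropy(self, rng):
        import dendropy

        for _ in range(10):
            n = int(rng.integers(5, 9))
            D1, _s1, _l1 = random_additive_tree(n, rng)
            D2, _s2, _l2 = random_additive_tree(n, rng)
            ids = [f"L{i}" for i in range(n)]
            t1, t2 = phylo.nj_tree(ids, D1), phylo.nj_tree(ids, D2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert phylo.rf_distance(t1, t2) == expected


class TestClassification:
    def test_query_identical_to_reference_joins_its_subgroup(self, cohort):
        name = "Microvirus"
        refs = [
            (SequenceRecord(id=f"ref_{n}", residues=p["VP1"]), n)
            for n, p in sorted(cohort.subgroup_proteins.items())
        ]
        q = SequenceRecord(id="q0", residues=cohort.subgroup_proteins[name]["VP1"])
        calls = phylo.classify_subgroup([q], refs, n_reps=30, seed=0)
        assert calls["q0"].subgroup == name

    def test_no_references_rejected(self):
        with pytest.raises(MicromineError):
            phylo.classify_subgroup([SequenceRecord(id="q", residues="MKVL")], [])
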