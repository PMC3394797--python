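"""Accessory-gene detection, locus naming, antisense flags, HGT congruence."""

import numpy as np
import pytest
from Bio.Seq import Seq

from micromine import accessory, annotate, assembly, phylo, simulate
from micromine.errors import MicromineError
from micromine.io import SequenceRecord


@pytest.fixture(scope="module")
def annotated_with_accessory(cohort):
    """Annotations (canonicalized) for every cohort genome carrying a
    planted accessory gene, keyed by genome id."""
    core_refs = [r for r in cohort.refs if r.id.startswith("VP")]
    out = {}
    for truth in cohort.truths:
        if not truth.accessory:
            continue
        orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
        anns = annotate.assign_core_genes(orfs, core_refs)
        out[truth.genome_id] = (truth, anns)
    return out


class TestDetectAccessory:
    def test_planted_peptidase_detected_with_truth_locus(self, cohort, annotated_with_accessory):
        acc_refs = [r for r in cohort.refs if r.id == "peptidase"]
        for gid, (truth, anns) in annotated_with_accessory.items():
            reports = accessory.detect_accessory(anns, acc_refs, genome_length=truth.length)
            want = [a for a in truth.accessory if a.orf.role == "peptidase"]
            assert len(reports) == len(want)
            for rep, acc in zip(sorted(reports, key=lambda r: r.orf.start),
                                sorted(want, key=lambda a: a.orf.start)):
                assert rep.role == "peptidase"
                assert rep.locus == acc.locus
                assert rep.bit_score >= 50

    def test_genome_without_accessory_is_clean(self, cohort):
        core_refs = [r for r in cohort.refs if r.id.startswith("VP")]
        acc_refs = [r for r in cohort.refs if r.id == "peptidase"]
        truth = next(t for t in cohort.truths if not t.accessory)
        orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
        anns = annotate.assign_core_genes(orfs, core_refs)
        assert accessory.detect_accessory(anns, acc_refs, genome_length=truth.length) == []

    def test_raising_threshold_empties_reports(self, cohort, annotated_with_accessory):
        acc_refs = [r for r in cohort.refs if r.id == "peptidase"]
        gid, (truth, anns) = next(iter(annotated_with_accessory.items()))
        reports = accessory.detect_accessory(anns, acc_refs, genome_length=truth.length)
        top = max(r.bit_score for r in reports)
        assert accessory.detect_accessory(
            anns, acc_refs, bit_threshold=top + 1, genome_length=truth.length
        ) == []

    def test_core_roles_never_reassigned(self, cohort, annotated_with_accessory):
        acc_refs = [r for r in cohort.refs if r.id == "peptidase"]
        for gid, (truth, anns) in annotated_with_accessory.items():
            reports = accessory.detect_accessory(anns, acc_refs, genome_length=truth.length)
            core_starts = {a.orf.start for a in anns if a.role in annotate.CORE_ROLES}
            assert all(r.orf.start not in core_starts for r in reports)


class TestLocusClassification:
    def test_both_alpavirinae_loci_represented(self, annotated_with_accessory):
        loci = set()
        for gid, (truth, _anns) in annotated_with_accessory.items():
            if truth.subgroup == "Alpavirinae":
                loci |= {a.locus for a in truth.accessory}
        assert loci == {"VP2-VP4", "VP4-VP1"}

    def test_label_invariant_under_rotation_and_reverse_complement(self, cohort):
        core_refs = [r for r in cohort.refs if r.id.startswith("VP")]
        acc_refs = [r for r in cohort.refs if r.id == "peptidase"]
        truth = next(t for t in cohort.truths if t.accessory)
        expected = truth.accessory[0].locus

        def locus_of(seq):
            circ = assembly.CircularGenome(id="g", residues=seq, overlap_len=0)
            orfs = annotate.find_orfs_circular(seq, genome_id="g")
            anns = annotate.assign_core_genes(orfs, core_refs)
            circ2, anns = assembly.canonical_rotation(circ, anns)
            reports = accessory.detect_accessory(
                anns, acc_refs, genome_length=len(circ2.residues)
            )
            return {r.locus for r in reports}

        rotated = truth.sequence[1500:] + truth.sequence[:1500]
        flipped = str(Seq(truth.sequence).reverse_complement())
        assert expected in locus_of(truth.sequence)
        assert locus_of(rotated) == locus_of(truth.sequence)
        assert locus_of(flipped) == locus_of(truth.sequence)

    def test_accessory_overlapping_core_gene_is_within(self, cohort):
        core_refs = [r for r in cohort.refs if r.id.startswith("VP")]
        truth = next(t for t in cohort.truths if not t.accessory)
        orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
        anns = annotate.assign_core_genes(orfs, core_refs)
        vp1 = next(a for a in anns if a.role == "VP1")
        fake = annotate.Orf(
            genome_id=truth.genome_id, start=vp1.orf.start + 30, end=vp1.orf.end - 30,
            strand="+", frame=1, protein="M" * 100,
        )
        label = accessory.locus_classification(anns, fake, genome_length=truth.length)
        assert label == "within-VP1"


class TestAntisense:
    def test_planted_antisense_orf_listed(self, cohort, annotated_with_accessory):
        gid = next(
            t.genome_id for t in cohort.truths
            if any(a.orf.strand == "-" for a in t.accessory)
        )
        truth, anns = annotated_with_accessory[gid]
        minus = accessory.antisense_orfs(anns)
        want = next(a.orf for a in truth.accessory if a.orf.strand == "-")
        assert any(a.orf.start == want.start and a.orf.end == want.end for a in minus)

    def test_all_forward_genome_has_none(self, cohort):
        core_refs = [r for r in cohort.refs if r.id.startswith("VP")]
        truth = next(t for t in cohort.truths if not t.accessory)
        orfs = [o for o in annotate.find_orfs_circular(truth.sequence) if o.strand == "+"]
        anns = annotate.assign_core_genes(orfs, core_refs)
        assert accessory.antisense_orfs(anns) == []


class TestHgtCongruence:
    def test_same_tree_is_consistent_with_rf_zero(self):
        t = phylo.PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        res = accessory.hgt_congruence(t, t)
        assert res == {
            "shared_taxa": 5, "rf": 0, "normalized_rf": 0.0, "verdict": "consistent"
        }

    def test_accessory_evolving_on_vp1_tree_is_consistent(self, cohort):
        """Peptidases diverged along the same subgroup structure as VP1
        give congruent trees."""
        pep, vp1 = [], []
        for truth in cohort.truths:
            if not any(a.orf.role == "peptidase" for a in truth.accessory):
                continue
            pep.append(SequenceRecord(
                id=truth.genome_id,
                residues=next(a.orf.protein for a in truth.accessory if a.orf.role == "peptidase"),
            ))
            vp1.append(SequenceRecord(
                id=truth.genome_id,
                residues=next(o.protein for o in truth.orfs if o.role == "VP1"),
            ))

        def tree_of(seqs):
            aln = phylo.progressive_msa(seqs)
            idm = phylo.percent_identity_matrix(aln)
            return phylo.nj_tree(idm.ids, phylo.identity_to_distance(idm))

        res = accessory.hgt_congruence(tree_of(pep), tree_of(vp1))
        assert res["shared_taxa"] >= 4
        assert res["verdict"] == "consistent"

    def test_label_shuffled_accessory_tree_is_inconsistent(self, rng):
        n = 8
        ids = [f"g{i}" for i in range(n)]
        # caterpillar vs a tree whose leaves are cyclically permuted
        nwk = "((((((g0:1,g1:1):1,g2:1):1,g3:1):1,g4:1):1,g5:1):1,g6:1,g7:1);"
        t1 = phylo.PhyloTree.from_newick(nwk)
        perm = {f"g{i}": f"g{(i + 3) % n}" for i in range(n)}
        shuffled = nwk
        for a, b in [(k, v.upper()) for k, v in perm.items()]:
            shuffled = shuffled.replace(a + ":", b + ":")
        t2 = phylo.PhyloTree.from_newick(shuffled.lower())
        res = accessory.hgt_congruence(t1, t2)
        assert res["verdict"] == "inconsistent"

    def test_fewer_than_four_shared_taxa_rejected(self):
        t1 = phylo.PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = phylo.PhyloTree.from_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(MicromineError):
            accessory.hgt_congruence(t1, t2)
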