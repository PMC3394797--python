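"""Circular ORF prediction, role assignment, VP2 features/rescue,
gene-order signatures."""

import dataclasses

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from micromine import annotate, simulate
from micromine.annotate import CORE_GENE_ORDERS
from micromine.io import SequenceRecord
from micromine.search import local_align_protein

from conftest import random_dna


def oracle_orfs(seq, min_len=60, code=11):
    """Independent exhaustive six-frame scan of the doubled sequence:
    for every stop codon, the earliest in-frame start after the previous
    stop; wrap-equivalents deduplicated; spans above one circle dropped."""
    L = len(seq)
    stops = {"TAA", "TAG", "TGA"} if code == 11 else {"TAA", "TAG"}
    starts = {"ATG", "GTG", "TTG"}
    out = set()
    for strand in "+-":
        work = seq + seq if strand == "+" else str(Seq(seq + seq).reverse_complement())
        for off in range(3):
            codons = [work[i : i + 3] for i in range(off, len(work) - 2, 3)]
            last_stop = -1
            for ci, codon in enumerate(codons):
                if codon not in stops:
                    continue
                for si in range(last_stop + 1, ci):
                    if codons[si] in starts:
                        nt_start, nt_end = off + 3 * si, off + 3 * (ci + 1)
                        span = nt_end - nt_start
                        if nt_start < L and span <= L and span // 3 >= min_len:
                            fs = nt_start % L if strand == "+" else (2 * L - nt_end) % L
                            out.add((fs, fs + span, strand))
                        break
                last_stop = ci
    return out


class TestFindOrfsCircular:
    def test_all_truth_orfs_recovered_exactly(self, cohort):
        for truth in cohort.truths:
            orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
            predicted = {(o.start, o.end, o.strand): o.protein for o in orfs}
            for t in truth.all_orfs:
                assert (t.start, t.end, t.strand) in predicted
                assert predicted[(t.start, t.end, t.strand)] == t.protein

    def test_origin_spanning_orf_reported_with_wraps_and_correct_protein(self, cohort):
        truth = cohort.truths[0]
        target = truth.orfs[1]
        cut = target.start + (target.end - target.start) // 2  # cut inside the gene
        rotated = truth.sequence[cut:] + truth.sequence[:cut]
        orfs = annotate.find_orfs_circular(rotated, genome_id="rot")
        L = truth.length
        new_start = (target.start - cut) % L
        hit = next(o for o in orfs if o.start == new_start and o.strand == "+")
        assert hit.wraps and hit.end > L
        assert hit.protein == target.protein

    def test_rotation_invariance_of_orf_set(self, cohort):
        truth = cohort.truths[3]
        L = truth.length
        base = {((o.start) % L, o.end - o.start, o.strand)
                for o in annotate.find_orfs_circular(truth.sequence)}
        cut = 1234 % L
        rot = truth.sequence[cut:] + truth.sequence[:cut]
        shifted = {((o.start + cut) % L, o.end - o.start, o.strand)
                   for o in annotate.find_orfs_circular(rot)}
        assert base == shifted

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_oracle_on_random_circles(self, trial, rng):
        seq = random_dna(2000, rng)
        got = {(o.start, o.end, o.strand)
               for o in annotate.find_orfs_circular(seq, min_len=25)}
        assert got == oracle_orfs(seq, min_len=25)


class TestAssignCoreGenes:
    def test_roles_match_truth_on_default_divergence(self, cohort, core_refs):
        for truth in cohort.truths:
            orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
            anns = annotate.assign_core_genes(orfs, core_refs)
            pred = {a.orf.start: a.role for a in anns if a.role != "unknown"}
            want = {o.start: o.role for o in truth.orfs if o.role.startswith("VP")}
            assert pred == want

    def test_hit_below_threshold_is_unknown(self, cohort, core_refs):
        truth = cohort.truths[0]
        orfs = annotate.find_orfs_circular(truth.sequence)
        anns = annotate.assign_core_genes(orfs, core_refs)
        vp1 = next(a for a in anns if a.role == "VP1")
        # exact boundary: same score assigned at its own bit, unknown just above
        at = annotate.assign_core_genes([vp1.orf], core_refs, bit_threshold=vp1.bit_score)
        above = annotate.assign_core_genes([vp1.orf], core_refs, bit_threshold=vp1.bit_score + 0.1)
        assert at[0].role == "VP1"
        assert above[0].role == "unknown"

    def test_duplicate_role_resolved_by_score_then_length_then_start(self, cohort, core_refs):
        truth = cohort.truths[0]
        orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
        anns = annotate.assign_core_genes(orfs, core_refs)
        vp1 = next(a for a in anns if a.role == "VP1").orf
        paralog = dataclasses.replace(vp1, start=vp1.start + 3, end=vp1.end + 3,
                                      protein=vp1.protein[:-10])
        result = annotate.assign_core_genes([vp1, paralog], core_refs)
        roles = [a.role for a in result]
        assert roles.count("VP1") == 1
        assert result[0].role == "VP1"  # longer, higher-scoring copy wins


class TestVp2Features:
    def test_poly_leucine_n_terminus_is_tm(self):
        protein = "L" * 25 + "D" * 60
        rep = annotate.detect_vp2_features(protein)
        assert rep["n_terminal_tm"]  # Leu hydropathy 3.8 >= 1.6

    def test_poly_aspartate_has_no_features(self):
        rep = annotate.detect_vp2_features("D" * 100)
        assert rep == {"n_terminal_tm": False, "coiled_coil": False, "verdict": False}

    def test_designed_tm_plus_heptads_verdict_true(self):
        protein = "M" + "L" * 21 + "LAALEQK" * 4 + "D" * 60
        rep = annotate.detect_vp2_features(protein)
        assert rep["verdict"]
        # a/d positions of LAALEQK are L,L -> 100% hydrophobic under phase 0
        assert rep["coiled_coil"]


@pytest.fixture(scope="module")
def cryptic(cohort):
    template = simulate.DEFAULT_TEMPLATES["Alpavirinae"]
    truth = simulate.generate_genome(
        template, seed=[21, 0], refs=cohort.refs,
        subgroup_proteins=cohort.subgroup_proteins["Alpavirinae"],
        vp2_cryptic=True,
    )
    core_refs = [r for r in cohort.refs if r.id.startswith("VP")]
    orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
    anns = annotate.assign_core_genes(orfs, core_refs)
    return truth, anns


class TestVp2Rescue:

    def test_cryptic_vp2_escapes_similarity_but_is_rescued(self, cryptic):
        truth, anns = cryptic
        assert "VP2" not in {a.role for a in anns}
        rescued = annotate.positional_vp2_rescue(anns, truth.length, 270)
        want = next(o for o in truth.orfs if o.role == "VP2")
        assert rescued is not None
        assert rescued.evidence == "feature-based"
        assert (rescued.orf.start, rescued.orf.end) == (want.start, want.end)

    def test_no_rescue_on_core_complete_genome(self, cohort, core_refs):
        truth = cohort.truths[6]  # Alpavirinae with intact VP2
        orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
        anns = annotate.assign_core_genes(orfs, core_refs)
        assert annotate.positional_vp2_rescue(anns, truth.length, 270) is None

    def test_candidate_failing_feature_tests_is_not_rescued(self, cryptic):
        truth, anns = cryptic
        want = next(o for o in truth.orfs if o.role == "VP2")
        # strip the candidate of its biophysical features
        crippled = [
            dataclasses.replace(a, orf=dataclasses.replace(a.orf, protein="D" * len(a.orf.protein)))
            if a.role == "unknown" and a.orf.start == want.start
            else a
            for a in anns
        ]
        assert annotate.positional_vp2_rescue(crippled, truth.length, 270) is None


class TestGeneOrderSignature:
    EXPECTED = {
        "Microvirus": ("VP4", "VP1", "VP2"),
        "Gokushovirinae_aquatic": ("VP4", "VP5", "VP1", "VP2", "VP3"),
        "Gokushovirinae_gut": ("VP4", "VP5", "VP3", "VP1", "VP2"),
        "Alpavirinae": ("VP4", "VP1", "VP2"),
        "Pichovirinae": ("VP4", "VP2", "VP1"),
    }

    def test_template_signatures(self, cohort, core_refs):
        for truth in cohort.truths:
            orfs = annotate.find_orfs_circular(truth.sequence, genome_id=truth.genome_id)
            anns = annotate.assign_core_genes(orfs, core_refs)
            assert annotate.gene_order_signature(anns) == self.EXPECTED[truth.subgroup]

    def test_signature_invariant_under_rotation(self, cohort, core_refs):
        truth = cohort.truths[8]  # a pichovirus
        base = None
        for cut in (0, 500, 2222):
            rot = truth.sequence[cut:] + truth.sequence[:cut]
            orfs = annotate.find_orfs_circular(rot, genome_id="r")
            sig = annotate.gene_order_signature(annotate.assign_core_genes(orfs, core_refs))
            base = base or sig
            assert sig == base

    def test_pichovirinae_signature_cyclically_distinct_from_all_others(self):
        picho = self.EXPECTED["Pichovirinae"]
        for name, sig in self.EXPECTED.items():
            if name == "Pichovirinae":
                continue
            reduced = tuple(r for r in sig if r in ("VP4", "VP1", "VP2"))
            assert not annotate._cyclic_equal(picho, reduced)
            assert annotate._cyclic_equal(reduced, ("VP4", "VP1", "VP2"))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rotation=st.integers(0, 10_000))
def test_normalize_cyclic_is_rotation_invariant(rotation):
    order = ("VP4", "VP5", "VP3", "VP1", "VP2")
    k = rotation % len(order)
    assert annotate.normalize_cyclic(order[k:] + order[:k]) == order
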