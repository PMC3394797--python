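"""Translated local similarity search.

Functional stand-in for tBLASTx/BLASTx/BLASTp at desk scale: exact
Smith-Waterman affine-gap local alignment (via Bio.Align.PairwiseAligner)
between six-frame translations of DNA queries and a curated protein
reference set, with BLAST-comparable bit scores

    bit = (lambda * raw - ln K) / ln 2

using the published gapped BLOSUM62 constants lambda = 0.267, K = 0.041, so
the screening threshold of 50 bits is directly comparable to BLAST output.
Frames are split at stop codons and each stop-free segment of >= 20 aa is
aligned independently; no E-values are computed because the pipeline filters
on bit score only.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import MicromineError
from .io import SequenceRecord

BLAST_LAMBDA = 0.267
BLAST_K = 0.041
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
HYDROPHOBIC = set("LIVMFA")

#: stop codons per genetic code (4 = TGA read-through as Trp)
STOP_CODONS = {11: {"TAA", "TAG", "TGA"}, 4: {"TAA", "TAG"}}


@dataclasses.dataclass
class AlignmentHit:
    """A local alignment between a (translated) query and a reference protein."""

    query_id: str
    subject_id: str
    query_start: int  # nt (translated search) or aa (protein search), 0-based
    query_end: int  # half-open
    subject_start: int  # aa
    subject_end: int
    raw_score: float
    bit_score: float
    percent_identity: float
    strand: str = "+"
    frame: int | None = None  # +1..+3 / -1..-3 for translated queries
    query_unit: str = "aa"


def bit_from_raw(raw: float, lam: float = BLAST_LAMBDA, k: float = BLAST_K) -> float:
    return (lam * raw - math.log(k)) / math.log(2)


def raw_from_bit(bit: float, lam: float = BLAST_LAMBDA, k: float = BLAST_K) -> float:
    return (bit * math.log(2) + math.log(k)) / lam


@lru_cache(maxsize=8)
def _aligner(mode: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    """Affine-gap aligner; a gap of length g costs gap_open + g * gap_extend
    (BLAST convention, so gap_open=11 / gap_extend=1 mirrors BLAST defaults)."""
    aln = Align.PairwiseAligner()
    aln.mode = mode
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    return aln


def _check_protein(seq: str, label: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in PROTEIN_ALPHABET:
            raise MicromineError(f"illegal residue {ch!r} at position {i} of {label}")


def _identity_from_alignment(alignment) -> float:
    counts = alignment.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / total if total else 0.0


def local_align_protein(
    query: str | SequenceRecord,
    subject: str | SequenceRecord,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentHit | None:
    """Optimal Smith-Waterman local alignment of two proteins.

    Returns None when no positive-scoring local alignment exists.
    """
    qid, q = (query.id, query.residues) if isinstance(query, SequenceRecord) else ("query", query)
    sid, s = (
        (subject.id, subject.residues) if isinstance(subject, SequenceRecord) else ("subject", subject)
    )
    if not q or not s:
        raise MicromineError("sequences must be non-empty")
    _check_protein(q, qid)
    _check_protein(s, sid)
    aligner = _aligner("local", gap_open, gap_extend)
    score = aligner.score(q, s)
    if score <= 0:
        return None
    alignment = aligner.align(q, s)[0]
    blocks_q, blocks_s = alignment.aligned
    return AlignmentHit(
        query_id=qid,
        subject_id=sid,
        query_start=int(blocks_q[0][0]),
        query_end=int(blocks_q[-1][1]),
        subject_start=int(blocks_s[0][0]),
        subject_end=int(blocks_s[-1][1]),
        raw_score=float(score),
        bit_score=bit_from_raw(score),
        percent_identity=_identity_from_alignment(alignment),
        strand="+",
        frame=None,
        query_unit="aa",
    )


# -- six-frame machinery --------------------------------------------------

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def six_frame_segments(seq: str, code: int = 11, min_segment_aa: int = 20):
    """Yield (frame, aa_offset, protein_segment) for all six reading frames.

    Frames +1..+3 read the forward strand, -1..-3 the reverse complement
    (offsets are aa positions within the frame's own translation).  Each
    frame is split at stop codons; only stop-free segments of at least
    ``min_segment_aa`` residues are yielded.
    """
    stops = STOP_CODONS[code]
    for strand, work in (("+", seq.upper()), ("-", _revcomp(seq.upper()))):
        for off in range(3):
            frame = (off + 1) if strand == "+" else -(off + 1)
            n_codons = (len(work) - off) // 3
            seg_start = 0
            aa = []
            for ci in range(n_codons):
                codon = work[off + 3 * ci : off + 3 * ci + 3]
                if codon in stops:
                    if len(aa) >= min_segment_aa:
                        yield frame, seg_start, "".join(aa)
                    seg_start = ci + 1
                    aa = []
                else:
                    aa.append(_translate_codon(codon, code))
            if len(aa) >= min_segment_aa:
                yield frame, seg_start, "".join(aa)


@lru_cache(maxsize=4)
def _codon_map(code: int) -> dict:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[code]
    mapping = dict(table.forward_table)
    return mapping


def _translate_codon(codon: str, code: int) -> str:
    return _codon_map(code).get(codon, "X")


def _segment_nt_interval(frame: int, aa_start: int, aa_end: int, seq_len: int):
    """Project an aa interval within a frame's translation to forward-strand
    nt coordinates (0-based, half-open)."""
    off = abs(frame) - 1
    s = off + 3 * aa_start
    e = off + 3 * aa_end
    if frame > 0:
        return s, e
    return seq_len - e, seq_len - s


def translated_search(
    query: str | SequenceRecord,
    refs: Sequence[SequenceRecord],
    code: int = 11,
    bit_threshold: float = 50.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    min_segment_aa: int = 20,
) -> list[AlignmentHit]:
    """Align all six reading frames of a DNA query to every reference protein.

    Returns hits with bit score >= ``bit_threshold``, sorted by bit score
    descending; query coordinates are nt on the forward strand, with the
    frame and strand recorded.
    """
    if not refs:
        raise MicromineError("reference set must be non-empty")
    qid, q = (query.id, query.residues) if isinstance(query, SequenceRecord) else ("query", query)
    aligner = _aligner("local", gap_open, gap_extend)
    hits: list[AlignmentHit] = []
    for frame, aa_off, segment in six_frame_segments(q, code=code, min_segment_aa=min_segment_aa):
        for ref in refs:
            score = aligner.score(segment, ref.residues)
            if score <= 0:
                continue
            bit = bit_from_raw(score)
            if bit < bit_threshold:
                continue
            alignment = aligner.align(segment, ref.residues)[0]
            blocks_q, blocks_s = alignment.aligned
            a0, a1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
            nt_s, nt_e = _segment_nt_interval(frame, aa_off + a0, aa_off + a1, len(q))
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=ref.id,
                    query_start=nt_s,
                    query_end=nt_e,
                    subject_start=int(blocks_s[0][0]),
                    subject_end=int(blocks_s[-1][1]),
                    raw_score=float(score),
                    bit_score=bit,
                    percent_identity=_identity_from_alignment(alignment),
                    strand="+" if frame > 0 else "-",
                    frame=frame,
                    query_unit="nt",
                )
            )
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id, h.query_start, h.frame))
    return hits


def has_hit(
    query: str | SequenceRecord,
    refs: Sequence[SequenceRecord],
    code: int = 11,
    bit_threshold: float = 50.0,
    min_segment_aa: int = 20,
) -> bool:
    """Cheap screening predicate: does any frame segment reach the threshold?

    Scores only (no alignment retrieval), stopping at the first hit.
    """
    if not refs:
        return False
    qid, q = (query.id, query.residues) if isinstance(query, SequenceRecord) else ("query", query)
    aligner = _aligner("local", 11.0, 1.0)
    min_raw = raw_from_bit(bit_threshold)
    for _frame, _off, segment in six_frame_segments(q, code=code, min_segment_aa=min_segment_aa):
        for ref in refs:
            if aligner.score(segment, ref.residues) >= min_raw:
                return True
    return False


def contig_orf_proteins(
    contig: SequenceRecord, code: int = 11, min_orf_codons: int = 60
) -> list[SequenceRecord]:
    """Stop-free translated segments of >= min_orf_codons from all six frames,
    used as additional queries when recruiting distant homologues."""
    out = []
    for i, (_f, _o, seg) in enumerate(
        six_frame_segments(contig.residues, code=code, min_segment_aa=min_orf_codons)
    ):
        out.append(SequenceRecord(id=f"{contig.id}|orf{i}", residues=seg))
    return out


def iterative_recruit(
    contigs: Sequence[SequenceRecord],
    refs: Sequence[SequenceRecord],
    max_iter: int = 2,
    code: int = 11,
    bit_threshold: float = 50.0,
    min_orf_codons: int = 60,
) -> list[set[str]]:
    """Iterative homology recruitment of contigs against a reference set.

    Iteration 1 recruits every contig with at least one hit against ``refs``;
    each later iteration additionally uses the translated ORFs (>= 60 codons)
    of all previously recruited contigs as queries, so more distant
    homologues are pulled in transitively.  Returns the cumulative recruited
    id set after each iteration (monotonically non-decreasing); stops early
    at a fixed point.
    """
    if max_iter < 1:
        raise MicromineError("max_iter must be >= 1")
    per_iteration: list[set[str]] = []
    recruited: set[str] = set()
    extra_refs: list[SequenceRecord] = []
    for _it in range(max_iter):
        if not refs:
            per_iteration.append(set(recruited))
            continue
        pool = list(refs) + extra_refs
        newly = {
            c.id
            for c in contigs
            if c.id not in recruited
            and has_hit(c, pool, code=code, bit_threshold=bit_threshold)
        }
        recruited |= newly
        per_iteration.append(set(recruited))
        if not newly:
            break
        for c in contigs:
            if c.id in newly:
                extra_refs.extend(contig_orf_proteins(c, code=code, min_orf_codons=min_orf_codons))
    while len(per_iteration) < max_iter:
        per_iteration.append(set(recruited))
    return per_iteration


def scan_prophage(
    chromosome: str | SequenceRecord,
    refs: Sequence[SequenceRecord],
    bit_threshold: float = 50.0,
    merge_gap: int = 2000,
    code: int = 11,
) -> list[dict]:
    """Scan a bacterial chromosome for integrated phage-like regions.

    Translated hits against the core-protein references on either strand are
    projected to chromosome coordinates and merged when closer than
    ``merge_gap`` nt; each candidate interval reports which roles were hit.
    """
    cid, seq = (
        (chromosome.id, chromosome.residues)
        if isinstance(chromosome, SequenceRecord)
        else ("chromosome", chromosome)
    )
    if not seq:
        raise MicromineError("chromosome must be non-empty")
    hits = translated_search(
        SequenceRecord(id=cid, residues=seq), refs, code=code, bit_threshold=bit_threshold
    )
    if not hits:
        return []
    intervals = sorted((h.query_start, h.query_end, h.subject_id) for h in hits)
    merged: list[dict] = []
    cur_s, cur_e, roles = intervals[0][0], intervals[0][1], {intervals[0][2]}
    n = 1
    for s, e, role in intervals[1:]:
        if s - cur_e <= merge_gap:
            cur_e = max(cur_e, e)
            roles.add(role)
            n += 1
        else:
            merged.append({"start": cur_s, "end": cur_e, "roles": sorted(roles), "n_hits": n})
            cur_s, cur_e, roles, n = s, e, {role}, 1
    merged.append({"start": cur_s, "end": cur_e, "roles": sorted(roles), "n_hits": n})
    return merged
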