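"""Read assembly and circular-genome recovery.

A greedy overlap-layout-consensus assembler working at the stringency used
for virome assembly here (minimum overlap 35 nt at >= 98% ungapped
identity, i.e. the -ml/-mi parameter pair of the cited 454 assembler),
followed by terminal-redundancy circularity detection: a contig whose end
realigns to its start at the same stringency is a circular genome, and the
redundant terminal copy is trimmed away.

The greedy merge order is longest overlap first, then higher identity, then
lexicographically smaller contig-id pair; consensus is per-column majority
over the supporting reads (ties broken toward the alphabetically smaller
base).  Candidate overlaps are discovered by probing contig-end k-mers
(k = min(20, min_overlap)) against contig interiors, which is exact for
error-free reads; a final sweep re-checks all surviving contigs so that no
mergeable pair remains.
"""

from __future__ import annotations

import dataclasses
import heapq
from typing import Iterable, Sequence

import numpy as np

from .errors import MicromineError
from .io import SequenceRecord

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise MicromineError(f"assembly input contains non-ACGT character {bad!r}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed codes of all k-mers (empty if the sequence is shorter)."""
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    a = arr.astype(np.int64)
    code = np.zeros(len(arr) - k + 1, dtype=np.int64)
    for j in range(k):
        code = (code << 2) | a[j : j + len(code)]
    return code


@dataclasses.dataclass
class Contig:
    id: str
    residues: str
    support: int  # number of reads merged into the contig


@dataclasses.dataclass
class CircularGenome:
    """A recovered circular sequence with the terminal redundancy trimmed."""

    id: str
    residues: str
    overlap_len: int  # detected terminal self-overlap (nt)
    rotation_offset: int = 0
    flipped: bool = False
    warning: str | None = None

    @property
    def length(self) -> int:
        return len(self.residues)


class _Contig:
    __slots__ = ("id", "seq", "counts", "support")

    def __init__(self, cid: str, seq: np.ndarray, counts: np.ndarray, support: int):
        self.id = cid
        self.seq = seq
        self.counts = counts
        self.support = support


def _max_mismatches(length: int, min_identity: float) -> int:
    return int(np.floor(length * (1.0 - min_identity) + 1e-9))


def _best_overlap(a: np.ndarray, b: np.ndarray, offsets: Iterable[int], min_overlap: int, min_identity: float):
    """Best valid ungapped overlap of b placed at each candidate offset in a's
    coordinates.  Returns (ovl_len, identity, offset) or None."""
    best = None
    for d in set(offsets):
        s = max(0, d)
        e = min(len(a), d + len(b))
        ovl = e - s
        if ovl < min_overlap:
            continue
        mism = int(np.count_nonzero(a[s:e] != b[s - d : e - d]))
        if mism > _max_mismatches(ovl, min_identity):
            continue
        ident = 1.0 - mism / ovl
        key = (ovl, ident)
        if best is None or key > (best[0], best[1]):
            best = (ovl, ident, d)
    return best


def assemble_greedy(
    reads: Sequence[SequenceRecord],
    min_overlap: int = 35,
    min_identity: float = 0.98,
) -> list[Contig]:
    """Greedy overlap-layout-consensus assembly of reads into contigs.

    Repeatedly merges the contig pair with the longest overlap of at least
    ``min_overlap`` nt at >= ``min_identity`` ungapped identity, both
    orientations considered, until no mergeable pair remains.
    """
    if not reads:
        return []
    k = min(20, min_overlap)
    contigs: dict[str, _Contig] = {}
    for rec in reads:
        arr = encode(rec.residues)
        counts = np.zeros((len(arr), 4), dtype=np.int32)
        counts[np.arange(len(arr)), arr] = 1
        contigs[rec.id] = _Contig(rec.id, arr, counts, 1)

    # end-index: k-mer code -> list of (contig id, end 'L'|'R', strand)
    end_index: dict[int, list] = {}

    def index_ends(c: _Contig):
        if len(c.seq) < k:
            return
        rc = revcomp_arr(c.seq)
        for arr, strand in ((c.seq, "+"), (rc, "-")):
            first = int(_kmer_codes(arr[:k], k)[0])
            last = int(_kmer_codes(arr[-k:], k)[0])
            end_index.setdefault(first, []).append((c.id, "L", strand))
            end_index.setdefault(last, []).append((c.id, "R", strand))

    def candidates_for(c: _Contig):
        """Scan c's k-mers against the end index; yield merge candidates."""
        codes = _kmer_codes(c.seq, k)
        raw: dict[tuple, list[int]] = {}
        for pos in range(len(codes)):
            entries = end_index.get(int(codes[pos]))
            if not entries:
                continue
            for oid, end, strand in entries:
                if oid == c.id or oid not in contigs:
                    continue
                other = contigs[oid]
                if end == "L":
                    d = pos  # other (oriented) starts at pos in c's coords
                else:
                    d = pos + k - len(other.seq)
                raw.setdefault((oid, strand), []).append(d)
        out = []
        for (oid, strand), offsets in raw.items():
            other = contigs.get(oid)
            if other is None:
                continue
            b = other.seq if strand == "+" else revcomp_arr(other.seq)
            best = _best_overlap(c.seq, b, offsets, min_overlap, min_identity)
            if best:
                ovl, ident, d = best
                out.append((ovl, ident, c.id, oid, strand, d))
        return out

    heap: list[tuple] = []

    def push(cands):
        for ovl, ident, ida, idb, strand, d in cands:
            lo, hi = sorted((ida, idb))
            heapq.heappush(heap, (-ovl, -ident, lo, hi, ida, idb, strand, d))

    for c in contigs.values():
        index_ends(c)
    for c in list(contigs.values()):
        push(candidates_for(c))

    merge_counter = 0

    def merge(a: _Contig, b: _Contig, strand: str, d: int) -> _Contig:
        nonlocal merge_counter
        if strand == "-":
            b_seq = revcomp_arr(b.seq)
            b_counts = b.counts[::-1, ::-1]
        else:
            b_seq, b_counts = b.seq, b.counts
        start = min(0, d)
        end = max(len(a.seq), d + len(b_seq))
        counts = np.zeros((end - start, 4), dtype=np.int32)
        counts[-start : -start + len(a.seq)] += a.counts
        counts[d - start : d - start + len(b_seq)] += b_counts
        seq = np.argmax(counts, axis=1).astype(np.uint8)  # ties -> smaller base
        merge_counter += 1
        return _Contig(f"m{merge_counter:07d}", seq, counts, a.support + b.support)

    while True:
        while heap:
            neg_ovl, _neg_ident, _lo, _hi, ida, idb, strand, d = heapq.heappop(heap)
            a = contigs.get(ida)
            b = contigs.get(idb)
            if a is None or b is None:
                continue
            # re-verify (sequences are immutable, but thresholds guard anyway)
            bseq = b.seq if strand == "+" else revcomp_arr(b.seq)
            best = _best_overlap(a.seq, bseq, [d], min_overlap, min_identity)
            if best is None:
                continue
            merged = merge(a, b, strand, d)
            del contigs[ida], contigs[idb]
            contigs[merged.id] = merged
            index_ends(merged)
            push(candidates_for(merged))
        # final sweep: no mergeable pair may remain
        end_index.clear()
        for c in contigs.values():
            index_ends(c)
        leftovers = []
        for c in list(contigs.values()):
            leftovers.extend(candidates_for(c))
        if not leftovers:
            break
        push(leftovers)

    out = [
        Contig(id=c.id, residues=decode(c.seq), support=c.support)
        for c in contigs.values()
    ]
    out.sort(key=lambda c: (-len(c.residues), c.id))
    return [
        Contig(id=f"contig{i + 1:04d}", residues=c.residues, support=c.support)
        for i, c in enumerate(out)
    ]


def detect_circular(
    contig: Contig | SequenceRecord,
    min_overlap: int = 35,
    min_identity: float = 0.98,
) -> CircularGenome | None:
    """Detect a circular genome from a contig's terminal self-overlap.

    Searches for the longest ungapped suffix-prefix alignment of length
    >= ``min_overlap`` at >= ``min_identity``; when found, the redundant
    suffix copy is trimmed so the returned length is the true circle length.
    """
    seq = contig.residues
    if len(seq) <= 2 * min_overlap:
        raise MicromineError("contig too short for circularity detection")
    arr = encode(seq)
    support = getattr(contig, "support", 1)
    for ell in range(len(arr) // 2, min_overlap - 1, -1):
        mism = int(np.count_nonzero(arr[:ell] != arr[-ell:]))
        if mism <= _max_mismatches(ell, min_identity):
            return CircularGenome(
                id=contig.id,
                residues=seq[: len(seq) - ell],
                overlap_len=ell,
            )
    return None


def rotate_sequence(seq: str, offset: int) -> str:
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def canonical_rotation(circ: CircularGenome, annotations: Sequence) -> tuple[CircularGenome, list]:
    """Rotate/flip a circular genome to canonical form.

    Canonical form places VP1 on the forward strand and the VP4 start codon
    at position 0, so gene orders are directly comparable across genomes.
    Annotation coordinates are re-mapped accordingly.  Without both VP1 and
    VP4 annotations the genome is returned unchanged with a warning flag.
    """
    length = len(circ.residues)
    by_role = {}
    for ann in annotations:
        role = getattr(ann, "role", None)
        if role in ("VP1", "VP4") and role not in by_role:
            by_role[role] = ann
    if "VP1" not in by_role or "VP4" not in by_role:
        return (
            dataclasses.replace(circ, warning="missing VP1 or VP4; not canonicalized"),
            list(annotations),
        )
    flip = by_role["VP1"].orf.strand == "-"
    seq = circ.residues
    anns = list(annotations)
    if flip:
        from Bio.Seq import Seq

        seq = str(Seq(seq).reverse_complement())
        anns = [_flip_annotation(a, length) for a in anns]
        by_role = {r: _flip_annotation(a, length) for r, a in by_role.items()}
    offset = by_role["VP4"].orf.start % length
    seq = rotate_sequence(seq, offset)
    anns = [_rotate_annotation(a, length, offset) for a in anns]
    return (
        CircularGenome(
            id=circ.id,
            residues=seq,
            overlap_len=circ.overlap_len,
            rotation_offset=(circ.rotation_offset + offset) % length,
            flipped=circ.flipped ^ flip,
        ),
        anns,
    )


def _flip_orf(orf, length: int):
    span = orf.end - orf.start
    new_start = (length - orf.end) % length
    return dataclasses.replace(
        orf,
        start=new_start,
        end=new_start + span,
        strand="-" if orf.strand == "+" else "+",
        wraps=new_start + span > length,
    )


def _rotate_orf(orf, length: int, offset: int):
    span = orf.end - orf.start
    new_start = (orf.start - offset) % length
    return dataclasses.replace(orf, start=new_start, end=new_start + span, wraps=new_start + span > length)


def _flip_annotation(ann, length: int):
    return dataclasses.replace(ann, orf=_flip_orf(ann.orf, length))


def _rotate_annotation(ann, length: int, offset: int):
    return dataclasses.replace(ann, orf=_rotate_orf(ann.orf, length, offset))
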