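"""Circular-aware ORF prediction and core-gene annotation.

Small ssDNA phage genomes are circular, so ORFs may span the sequence
origin; prediction works on the doubled sequence of both strands and
deduplicates wrap-equivalent calls.  Predicted ORFs are assigned the core
roles of the family (VP1 major capsid protein, VP2 DNA pilot protein, VP3
internal scaffolding protein, VP4 replication initiation protein, VP5 DNA
binding protein) by best local-alignment hit against a reference protein
set; highly divergent VP2 genes that escape similarity search can still be
rescued from their conserved positional and biophysical features
(N-terminal transmembrane segment plus a coiled-coil region).

Coordinates are 0-based half-open on the forward strand of the canonically
rotated genome; a feature whose end exceeds the genome length wraps across
the origin.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import MicromineError
from .io import SequenceRecord
from .search import STOP_CODONS, _translate_codon, local_align_protein

CORE_ROLES = ("VP1", "VP2", "VP3", "VP4", "VP5")

#: subgroup-specific cyclic core-gene orders (forward strand, from VP4)
CORE_GENE_ORDERS: dict[str, tuple[str, ...]] = {
    "Microvirus": ("VP4", "VP1", "VP2"),
    "Gokushovirinae_aquatic": ("VP4", "VP5", "VP1", "VP2", "VP3"),
    "Gokushovirinae_gut": ("VP4", "VP5", "VP3", "VP1", "VP2"),
    "Alpavirinae": ("VP4", "VP1", "VP2"),
    "Pichovirinae": ("VP4", "VP2", "VP1"),
}

DEFAULT_STARTS = frozenset({"ATG", "GTG", "TTG"})

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}
HYDROPHOBIC = set("LIVMFA")


@dataclasses.dataclass(frozen=True)
class Orf:
    """A predicted open reading frame on a circular genome.

    ``start``/``end`` are 0-based half-open forward-strand coordinates of
    the full CDS (stop codon included); ``end > genome length`` marks an
    origin-spanning ORF (``wraps``).  ``length`` counts codons including
    the stop; the protein's initiator residue is always reported as Met.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    wraps: bool = False

    @property
    def length(self) -> int:
        return (self.end - self.start) // 3


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    orf: Orf
    role: str  # VP1..VP5 | peptidase | unknown
    subject_id: str | None = None
    bit_score: float = 0.0
    evidence: str = "similarity"  # similarity | feature-based

    @property
    def start(self) -> int:
        return self.orf.start

    @property
    def end(self) -> int:
        return self.orf.end


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_orfs_circular(
    genome: str | SequenceRecord,
    min_len: int = 60,
    starts: frozenset = DEFAULT_STARTS,
    code: int = 11,
    genome_id: str | None = None,
) -> list[Orf]:
    """Predict maximal ORFs on both strands of a circular genome.

    Scans the doubled sequence so ORFs may span the origin; for each stop
    codon the maximal ORF (earliest in-frame start after the previous stop)
    is reported; wrap-equivalent duplicates are removed keyed on
    (start mod L, strand, length).  ``min_len`` is in codons (stop
    included).
    """
    if isinstance(genome, SequenceRecord):
        gid, seq = genome.id, genome.residues
    else:
        gid, seq = genome_id or "genome", genome
    seq = seq.upper()
    L = len(seq)
    if L < 3 * min_len:
        raise MicromineError("genome shorter than 3 x min_len")
    stops = STOP_CODONS[code]
    found: dict[tuple, Orf] = {}
    for strand in ("+", "-"):
        work = (seq + seq) if strand == "+" else _revcomp(seq + seq)
        for off in range(3):
            n_codons = (len(work) - off) // 3
            codons = [work[off + 3 * i : off + 3 * i + 3] for i in range(n_codons)]
            prev_stop = -1  # codon index of previous stop
            pending_start = None  # earliest start since previous stop
            for ci in range(n_codons):
                if codons[ci] in stops:
                    if pending_start is not None:
                        orf = _make_orf(
                            gid, seq, L, strand, off, pending_start, ci, codons, code
                        )
                        if orf is not None and orf.length >= min_len:
                            key = (orf.start % L, orf.strand, orf.length)
                            found.setdefault(key, orf)
                    prev_stop = ci
                    pending_start = None
                elif pending_start is None and codons[ci] in starts:
                    pending_start = ci
    out = sorted(found.values(), key=lambda o: (o.start, o.strand, o.end))
    return out


def _make_orf(gid, seq, L, strand, off, start_ci, stop_ci, codons, code):
    """Build an Orf from codon indices on the doubled (possibly revcomp'd)
    sequence; returns None for duplicates beyond the first genome copy or
    full-circle artifacts."""
    nt_start = off + 3 * start_ci
    nt_end = off + 3 * (stop_ci + 1)  # stop codon included
    if nt_start >= L:  # wrap-equivalent of an ORF already seen
        return None
    if nt_end - nt_start > L:  # would wrap the full circle
        return None
    protein = "M" + "".join(
        _translate_codon(c, code) for c in codons[start_ci + 1 : stop_ci]
    )
    span = nt_end - nt_start
    if strand == "+":
        f_start = nt_start % L
        frame = nt_start % 3 + 1
    else:
        # coordinates were on revcomp(doubled); map back to forward strand
        f_start = (2 * L - nt_end) % L
        frame = -(nt_start % 3 + 1)
    end_mod = f_start + span
    return Orf(
        genome_id=gid,
        start=f_start,
        end=end_mod,
        strand=strand,
        frame=frame,
        protein=protein,
        wraps=end_mod > L,
    )


def orf_cds(orf: Orf, genome: str) -> str:
    """Forward-strand-extracted CDS of an ORF (reverse-complemented for '-')."""
    L = len(genome)
    doubled = genome + genome
    cds = doubled[orf.start : orf.end]
    return cds if orf.strand == "+" else _revcomp(cds)


def assign_core_genes(
    orfs: Sequence[Orf],
    refs: Sequence[SequenceRecord],
    bit_threshold: float = 50.0,
    roles: dict[str, str] | None = None,
) -> list[GeneAnnotation]:
    """Assign each ORF the role of its best-scoring reference hit.

    Hits below ``bit_threshold`` leave the ORF ``unknown``.  When two ORFs
    claim the same role the higher bit score wins (ties: longer ORF, then
    smaller start); the loser reverts to unknown.
    """
    if roles is None:
        roles = {r.id: r.id for r in refs}
    anns: list[GeneAnnotation] = []
    for orf in orfs:
        best = None
        for ref in refs:
            hit = local_align_protein(orf.protein, ref.residues)
            if hit is None:
                continue
            if best is None or hit.bit_score > best[0].bit_score:
                best = (hit, ref.id)
        if best and best[0].bit_score >= bit_threshold:
            anns.append(
                GeneAnnotation(
                    orf=orf,
                    role=roles.get(best[1], best[1]),
                    subject_id=best[1],
                    bit_score=best[0].bit_score,
                )
            )
        else:
            anns.append(
                GeneAnnotation(
                    orf=orf,
                    role="unknown",
                    subject_id=best[1] if best else None,
                    bit_score=best[0].bit_score if best else 0.0,
                )
            )
    return _resolve_role_conflicts(anns)


def _resolve_role_conflicts(anns: list[GeneAnnotation]) -> list[GeneAnnotation]:
    by_role: dict[str, list[int]] = {}
    for i, ann in enumerate(anns):
        if ann.role != "unknown":
            by_role.setdefault(ann.role, []).append(i)
    out = list(anns)
    for role, idxs in by_role.items():
        if len(idxs) <= 1:
            continue
        ranked = sorted(
            idxs,
            key=lambda i: (-out[i].bit_score, -out[i].orf.length, out[i].orf.start),
        )
        for i in ranked[1:]:
            out[i] = dataclasses.replace(out[i], role="unknown")
    return out


def detect_vp2_features(
    protein: str,
    tm_window: int = 19,
    tm_cutoff: float = 1.6,
    tm_search_span: int = 60,
    cc_window: int = 28,
    cc_fraction: float = 0.6,
) -> dict:
    """Biophysical features characteristic of DNA pilot (VP2-like) proteins.

    ``n_terminal_tm``: some 19-aa window starting within the first 60
    residues has mean Kyte-Doolittle hydropathy >= 1.6.  ``coiled_coil``:
    some 28-aa window has, under its best heptad phase, >= 60% hydrophobic
    residues (L, I, V, M, F, A) at the a/d positions.  ``verdict`` requires
    both.
    """
    if len(protein) < 60:
        raise MicromineError("protein too short for VP2 feature detection")
    scores = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in protein]
    n_terminal_tm = False
    for s in range(0, min(tm_search_span, len(protein) - tm_window) + 1):
        window = scores[s : s + tm_window]
        if len(window) == tm_window and sum(window) / tm_window >= tm_cutoff:
            n_terminal_tm = True
            break
    coiled_coil = False
    for s in range(0, len(protein) - cc_window + 1):
        window = protein[s : s + cc_window]
        for phase in range(7):
            ad = [window[i] for i in range(cc_window) if (i + phase) % 7 in (0, 3)]
            if ad and sum(ch in HYDROPHOBIC for ch in ad) / len(ad) >= cc_fraction:
                coiled_coil = True
                break
        if coiled_coil:
            break
    return {
        "n_terminal_tm": n_terminal_tm,
        "coiled_coil": coiled_coil,
        "verdict": n_terminal_tm and coiled_coil,
    }


def cyclic_segments(start: int, end: int, length: int) -> list[tuple[int, int]]:
    """Linear segments covered by a (possibly wrapping) circular interval."""
    start %= length
    span = end - start if end >= start else (end % length) + length - start
    if start + span <= length:
        return [(start, start + span)]
    return [(start, length), (0, (start + span) % length)]


def cyclic_overlap(s1: int, e1: int, s2: int, e2: int, length: int) -> bool:
    """Do two (possibly wrapping) intervals on the circle intersect?"""
    return any(
        a < d and c < b
        for a, b in cyclic_segments(s1, e1, length)
        for c, d in cyclic_segments(s2, e2, length)
    )


def _cyclic_arc_contains(start: int, end: int, pos: int, length: int) -> bool:
    """Is pos within the cyclic arc [start, end) on a circle of given length?"""
    start %= length
    end %= length
    pos %= length
    if start <= end:
        return start <= pos < end
    return pos >= start or pos < end


def positional_vp2_rescue(
    annotations: Sequence[GeneAnnotation],
    genome_length: int,
    reference_vp2_len: int,
    gene_orders: dict[str, tuple[str, ...]] | None = None,
) -> GeneAnnotation | None:
    """Rescue a highly divergent VP2 from position and features.

    Applies when a genome carries VP1 and VP4 but no VP2: an unknown ORF
    sitting in the cyclic slot VP2 occupies in a compatible subgroup gene
    order, sized within +/-50% of the reference VP2, and passing the VP2
    feature tests, is annotated as VP2 with feature-based evidence.
    """
    if gene_orders is None:
        gene_orders = CORE_GENE_ORDERS
    by_role = {a.role: a for a in annotations if a.role != "unknown"}
    if "VP2" in by_role or "VP1" not in by_role or "VP4" not in by_role:
        return None
    observed = gene_order_signature(annotations)
    candidates: list[GeneAnnotation] = []
    for order in gene_orders.values():
        if "VP2" not in order:
            continue
        reduced = tuple(r for r in order if r != "VP2" and r in observed)
        obs_reduced = tuple(r for r in observed if r in reduced)
        if not _cyclic_equal(reduced, obs_reduced):
            continue
        i = order.index("VP2")
        before = next(
            (order[(i - j) % len(order)] for j in range(1, len(order)) if order[(i - j) % len(order)] in by_role),
            None,
        )
        after = next(
            (order[(i + j) % len(order)] for j in range(1, len(order)) if order[(i + j) % len(order)] in by_role),
            None,
        )
        if before is None or after is None:
            continue
        arc_start = by_role[before].orf.end
        arc_end = by_role[after].orf.start
        core_spans = [(a.orf.start, a.orf.end) for a in annotations if a.role in CORE_ROLES]
        for ann in annotations:
            if ann.role != "unknown" or ann.orf.strand != "+":
                continue  # VP2 sits on the forward strand of the canonical genome
            if not _cyclic_arc_contains(arc_start, arc_end, ann.orf.start, genome_length):
                continue
            if any(
                cyclic_overlap(ann.orf.start, ann.orf.end, s, e, genome_length)
                for s, e in core_spans
            ):
                continue
            plen = len(ann.orf.protein)
            if not (0.5 * reference_vp2_len <= plen <= 1.5 * reference_vp2_len):
                continue
            if plen < 60 or not detect_vp2_features(ann.orf.protein)["verdict"]:
                continue
            candidates.append(ann)
    if not candidates:
        return None
    best = sorted(candidates, key=lambda a: (-len(a.orf.protein), a.orf.start))[0]
    return dataclasses.replace(best, role="VP2", evidence="feature-based", bit_score=0.0)


def gene_order_signature(annotations: Sequence[GeneAnnotation]) -> tuple[str, ...]:
    """Cyclic core-gene order signature, normalized to start at VP4.

    Roles are read by start coordinate on the canonical forward strand;
    without VP4 the lexicographically smallest rotation is used so equality
    remains rotation-independent.
    """
    core = [a for a in annotations if a.role in CORE_ROLES]
    if len(core) < 2:
        raise MicromineError("need at least 2 core annotations for a signature")
    ordered = [a.role for a in sorted(core, key=lambda a: a.orf.start)]
    return normalize_cyclic(tuple(ordered))


def normalize_cyclic(order: tuple[str, ...]) -> tuple[str, ...]:
    if "VP4" in order:
        i = order.index("VP4")
        return order[i:] + order[:i]
    rotations = [order[i:] + order[:i] for i in range(len(order))]
    return min(rotations)


def _cyclic_equal(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    return any(b[i:] + b[:i] == a for i in range(len(b)))
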