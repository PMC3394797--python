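"""Horizontally acquired accessory genes.

Unknown ORFs are re-scored against accessory references (the M15-family
peptidase analogue); detected genes are located on the canonical circle by
their flanking core genes (e.g. "VP2-VP4" vs "VP4-VP1"), antisense ORFs are
flagged, and the accessory-gene tree is tested for congruence against the
VP1 phylogeny via the Robinson-Foulds distance on shared taxa.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .annotate import CORE_ROLES, GeneAnnotation, Orf, cyclic_overlap
from .errors import MicromineError
from .phylo import PhyloTree, rf_distance
from .search import local_align_protein
from .io import SequenceRecord


@dataclasses.dataclass
class AccessoryReport:
    genome_id: str
    role: str
    orf: Orf
    subject_id: str
    bit_score: float
    locus: str
    antisense: bool


def detect_accessory(
    annotations: Sequence[GeneAnnotation],
    accessory_refs: Sequence[SequenceRecord],
    bit_threshold: float = 50.0,
    roles: dict[str, str] | None = None,
    genome_length: int | None = None,
) -> list[AccessoryReport]:
    """Re-score unknown ORFs against accessory references.

    ORFs already holding a core role are never reassigned.  Each hit at or
    above the bit threshold yields a report including the cyclic locus
    label and the antisense flag.
    """
    if not accessory_refs:
        raise MicromineError("accessory reference set must be non-empty")
    if roles is None:
        roles = {r.id: r.id for r in accessory_refs}
    out = []
    for ann in annotations:
        if ann.role != "unknown":
            continue
        best = None
        for ref in accessory_refs:
            hit = local_align_protein(ann.orf.protein, ref.residues)
            if hit and (best is None or hit.bit_score > best[0].bit_score):
                best = (hit, ref.id)
        if best and best[0].bit_score >= bit_threshold:
            out.append(
                AccessoryReport(
                    genome_id=ann.orf.genome_id,
                    role=roles.get(best[1], best[1]),
                    orf=ann.orf,
                    subject_id=best[1],
                    bit_score=best[0].bit_score,
                    locus=locus_classification(annotations, ann.orf, genome_length=genome_length),
                    antisense=ann.orf.strand == "-",
                )
            )
    return out


def locus_classification(
    annotations: Sequence[GeneAnnotation],
    accessory_orf: Orf,
    genome_length: int | None = None,
) -> str:
    """Cyclic locus label "X-Y" of an accessory ORF on the canonical circle.

    X is the core gene whose end most closely precedes the accessory start,
    Y the core gene whose start most closely follows its end.  An accessory
    overlapping a core gene is labelled "within-X".
    """
    core = [a for a in annotations if a.role in CORE_ROLES]
    if len(core) < 2:
        raise MicromineError("need >= 2 core annotations to name a locus")
    L = genome_length or max([a.orf.end for a in core] + [accessory_orf.end])
    s, e = accessory_orf.start, accessory_orf.end
    for a in core:
        if cyclic_overlap(a.orf.start, a.orf.end, s, e, L):
            return f"within-{a.role}"
    before = min(core, key=lambda a: _cyclic_gap(a.orf.end, s, L))
    after = min(core, key=lambda a: _cyclic_gap(e, a.orf.start, L))
    return f"{before.role}-{after.role}"


def _cyclic_gap(from_pos: int, to_pos: int, L: int) -> int:
    return (to_pos - from_pos) % L


def antisense_orfs(annotations: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    """All annotated ORFs on the complementary strand of the canonical genome."""
    return [a for a in annotations if a.orf.strand == "-"]


def hgt_congruence(
    accessory_tree: PhyloTree,
    vp1_tree: PhyloTree,
    max_normalized_rf: float = 0.5,
) -> dict:
    """Topological congruence between accessory-gene and VP1 trees.

    Both trees are restricted to their shared taxa (>= 4 required); the
    Robinson-Foulds distance is normalized by the maximum 2(n-3); the
    verdict is "consistent" when normalized RF <= 0.5 (configurable).
    """
    shared = set(accessory_tree.leaf_names()) & set(vp1_tree.leaf_names())
    if len(shared) < 4:
        raise MicromineError(f"need >= 4 shared taxa, got {len(shared)}")
    t1 = accessory_tree.restrict(shared)
    t2 = vp1_tree.restrict(shared)
    rf = rf_distance(t1, t2)
    max_rf = 2 * (len(shared) - 3)
    norm = rf / max_rf if max_rf else 0.0
    return {
        "shared_taxa": len(shared),
        "rf": rf,
        "normalized_rf": norm,
        "verdict": "consistent" if norm <= max_normalized_rf else "inconsistent",
    }
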