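"""Reference-anchored analysis of major capsid protein (VP1) insertions.

Insertions are read off alignments against a reference capsid (the
PhiX174-F analogue of the family): maximal runs where the reference is
gapped and the query has residues.  The mushroom-protrusion insertion is
the block anchored inside a configured reference interval (it decorates the
3-fold axes of all subgroups except the Microvirus-type phages); hot-spots
are single-linkage clusters of large (>= 15 aa) insertion anchors; size
statistics per subgroup/ecosystem come with a one-way ANOVA.

Pairwise query-vs-reference alignments are the default basis (an MSA can be
supplied instead) to avoid gap-column compression artifacts.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MicromineError
from .phylo import ProteinAlignment, progressive_msa
from .io import SequenceRecord


@dataclasses.dataclass(frozen=True)
class InsertionBlock:
    """An insertion in a query relative to the ungapped reference.

    ``anchor`` is the count of reference residues preceding the insertion
    (0..reference length)."""

    sequence_id: str
    anchor: int
    length: int
    residues: str


@dataclasses.dataclass
class HotSpot:
    interval: tuple[int, int]  # reference-coordinate anchor range
    members: list[tuple[str, int]]  # (sequence id, insertion length)

    @property
    def max_length(self) -> int:
        return max(l for _, l in self.members)


def extract_insertions(
    aln: ProteinAlignment, reference_id: str, min_len: int = 10
) -> list[InsertionBlock]:
    """Insertion blocks of every non-reference row relative to the reference.

    Within each maximal stretch of reference-gap columns, the residues a row
    carries form one block if they number >= ``min_len``; the anchor is the
    number of non-gap reference positions before the stretch.
    """
    if reference_id not in aln.ids:
        raise MicromineError(f"reference {reference_id!r} not in alignment")
    ref_row = aln.rows[aln.ids.index(reference_id)]
    blocks: list[InsertionBlock] = []
    # reference-gap stretches with their anchors
    stretches = []  # (col_start, col_end, anchor)
    anchor = 0
    c = 0
    C = len(ref_row)
    while c < C:
        if ref_row[c] == "-":
            start = c
            while c < C and ref_row[c] == "-":
                c += 1
            stretches.append((start, c, anchor))
        else:
            anchor += 1
            c += 1
    for rid, row in zip(aln.ids, aln.rows):
        if rid == reference_id:
            continue
        for start, end, anch in stretches:
            residues = row[start:end].replace("-", "")
            if len(residues) >= min_len:
                blocks.append(
                    InsertionBlock(sequence_id=rid, anchor=anch, length=len(residues), residues=residues)
                )
    return blocks


def pairwise_insertions(
    query: SequenceRecord,
    reference: SequenceRecord,
    min_len: int = 10,
    gap_open: float = 100.0,
    gap_extend: float = 0.01,
) -> list[InsertionBlock]:
    """Insertions from a query-vs-reference global pairwise alignment.

    The default gap penalties give a near length-independent gap cost:
    domain-scale insertions are expected to be few and long, and a second
    gap opening can only pay off if an island of chance matches outscores
    a full extra opening, so each insertion stays in a single gap run --
    the regime insertion-length bookkeeping needs.  (The residual
    ambiguity is the anchor position, which can slip by roughly +/-15
    residues in diverged flanks; protrusion intervals should allow for
    that.)"""
    aln = progressive_msa([reference, query], gap_open=gap_open, gap_extend=gap_extend)
    return extract_insertions(aln, reference.id, min_len=min_len)


def mushroom_insertion(
    blocks: Sequence[InsertionBlock], protrusion_interval: tuple[int, int]
) -> InsertionBlock | None:
    """The protrusion-forming insertion: the block anchored inside the
    configured reference interval (largest wins if several; None if absent)."""
    lo, hi = protrusion_interval
    inside = [b for b in blocks if lo <= b.anchor <= hi]
    if not inside:
        return None
    return sorted(inside, key=lambda b: (-b.length, b.anchor))[0]


def insertion_hotspots(
    blocks: Sequence[InsertionBlock], min_len: int = 15, merge_tol: int = 10
) -> list[HotSpot]:
    """Single-linkage clustering of large-insertion anchors.

    Blocks shorter than ``min_len`` are discarded; anchors whose gaps are
    <= ``merge_tol`` reference positions chain into one hot-spot.
    """
    big = sorted((b for b in blocks if b.length >= min_len), key=lambda b: (b.anchor, b.sequence_id))
    if not big:
        return []
    spots: list[HotSpot] = []
    cur = [big[0]]
    for b in big[1:]:
        if b.anchor - cur[-1].anchor <= merge_tol:
            cur.append(b)
        else:
            spots.append(_make_spot(cur))
            cur = [b]
    spots.append(_make_spot(cur))
    return spots


def _make_spot(blocks: list[InsertionBlock]) -> HotSpot:
    return HotSpot(
        interval=(blocks[0].anchor, blocks[-1].anchor),
        members=[(b.sequence_id, b.length) for b in blocks],
    )


def size_stats(groups: dict[str, Sequence[float]]):
    """Per-group summaries plus a one-way ANOVA across groups.

    Returns (DataFrame with group/n/mean/min/max, F, p); F and p are None
    (with a warning) when fewer than two groups have >= 2 members.
    """
    rows = []
    for name in sorted(groups):
        vals = list(groups[name])
        if not vals:
            continue
        rows.append(
            {
                "group": name,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
            }
        )
    table = pd.DataFrame(rows, columns=["group", "n", "mean", "min", "max"])
    eligible = [list(groups[name]) for name in sorted(groups) if len(groups[name]) >= 2]
    if len(eligible) < 2:
        warnings.warn("ANOVA omitted: need >= 2 groups with >= 2 members")
        return table, None, None
    F, p = stats.f_oneway(*eligible)
    return table, float(F), float(p)
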