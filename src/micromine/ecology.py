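"""Environmental affiliation of unassembled reads.

Reads are affiliated to Microviridae subgroups by best translated hit
against a labeled database of major capsid proteins (VP1), at the same
50-bit screening threshold used elsewhere; reads shorter than 60 nt are
skipped (the translated segment would be < 20 aa, where 50 bits is nearly
unreachable).  Per-sample counts and presence flags roll up into a
per-biome matrix.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .errors import MicromineError
from .io import SequenceRecord
from .search import _aligner, raw_from_bit, six_frame_segments


def affiliate_reads(
    reads: Sequence[SequenceRecord],
    vp1_db: Sequence[tuple[SequenceRecord, str]],
    bit_threshold: float = 50.0,
    code: int = 11,
    min_read_len: int = 60,
) -> dict[str, str | None]:
    """Best-hit subgroup per read (None below threshold or too short).

    Ties on the best bit score are broken toward the first-listed
    reference.
    """
    if not vp1_db:
        raise MicromineError("VP1 database must be non-empty and labeled")
    aligner = _aligner("local", 11.0, 1.0)
    out: dict[str, str | None] = {}
    for read in reads:
        if len(read.residues) < min_read_len:
            out[read.id] = None
            continue
        best_label, best_raw = None, raw_from_bit(bit_threshold)
        for _frame, _off, segment in six_frame_segments(read.residues, code=code, min_segment_aa=20):
            for ref, label in vp1_db:
                raw = aligner.score(segment, ref.residues)
                if raw > best_raw:  # strict: first-listed reference wins ties
                    best_label, best_raw = label, raw
        out[read.id] = best_label
    return out


def presence_matrix(
    affiliations_by_sample: dict[str, dict[str, str | None]],
    sample_to_ecosystem: dict[str, str],
    subgroups: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample read counts / presence and a per-biome roll-up.

    The roll-up counts, per ecosystem and subgroup, the number of samples
    in which the subgroup is present (>= 1 affiliated read).
    """
    for sample in affiliations_by_sample:
        if sample not in sample_to_ecosystem:
            raise MicromineError(f"sample {sample!r} has no ecosystem mapping")
    if subgroups is None:
        labels = set()
        for aff in affiliations_by_sample.values():
            labels |= {v for v in aff.values() if v}
        subgroups = sorted(labels)
    rows = []
    for sample in sorted(affiliations_by_sample):
        aff = affiliations_by_sample[sample]
        row = {"sample": sample, "ecosystem": sample_to_ecosystem[sample]}
        for sg in subgroups:
            row[f"count_{sg}"] = sum(1 for v in aff.values() if v == sg)
        rows.append(row)
    table = pd.DataFrame(rows)
    for sg in subgroups:
        table[f"present_{sg}"] = (table[f"count_{sg}"] >= 1).astype(int) if len(table) else 0
    rollup_rows = []
    if len(table):
        for eco, sub in table.groupby("ecosystem"):
            row = {"ecosystem": eco, "n_samples": len(sub)}
            for sg in subgroups:
                row[f"samples_with_{sg}"] = int(sub[f"present_{sg}"].sum())
            rollup_rows.append(row)
    rollup = pd.DataFrame(rollup_rows)
    return table, rollup
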