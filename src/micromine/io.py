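"""Readers and writers for the external formats the pipeline touches.

FASTA (plain and aligned), Newick trees with internal-node bootstrap labels,
and TSV report tables.  Every writer stamps a comment header carrying the RNG
seed and the active thresholds so any output file identifies the run that
produced it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FastaParseError, MicromineError

DNA_LETTERS = set("ACGTN")
PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX*")
GAP = "-"


@dataclasses.dataclass
class SequenceRecord:
    """A named DNA or protein sequence (uppercase, IUPAC letters)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise MicromineError("sequence record id must be non-empty")
        if not self.residues:
            raise MicromineError(f"sequence record {self.id!r} has empty residues")


def _legal_letters(moltype: str, allow_gaps: bool) -> set:
    base = DNA_LETTERS if moltype == "dna" else PROTEIN_LETTERS
    return base | {GAP} if allow_gaps else set(base)


def read_fasta(path, moltype: str = "dna", allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving file order.

    Residues are uppercase-normalized and validated against the declared
    molecule type (``dna`` or ``protein``); ``allow_gaps`` additionally
    permits ``-`` for aligned FASTA.  Malformed headers or illegal residues
    raise :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    legal = _legal_letters(moltype, allow_gaps)
    # Validation pass over raw lines so errors can carry line numbers;
    # the actual record parsing is delegated to Bio.SeqIO below.
    with open(path) as fh:
        in_any_record = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(";"):  # old-style FASTA comment (run headers)
                continue
            if line.startswith(">"):
                in_any_record = True
                if not line[1:].strip():
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if not in_any_record:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                for ch in line.strip().upper():
                    if ch not in legal:
                        raise FastaParseError(
                            f"{path}:{lineno}: illegal {moltype} character {ch!r}"
                        )
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as FASTA (fixed line width, file order preserved)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_tsv(df: pd.DataFrame, path, header_comments: Sequence[str] = ()) -> None:
    """Write a DataFrame as TSV preceded by '#'-prefixed comment lines."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- Newick ---------------------------------------------------------------

def write_newick(tree, path) -> None:
    """Write a :class:`micromine.phylo.PhyloTree` as Newick.

    Branch lengths are written at full precision (a round trip preserves
    them well past 6 decimals); bootstrap supports appear as internal node
    labels.  Duplicate leaf labels are rejected.
    """
    from .phylo import PhyloTree  # local import to avoid a cycle

    if not isinstance(tree, PhyloTree):
        raise MicromineError("write_newick expects a PhyloTree")
    leaves = tree.leaf_names()
    if len(leaves) != len(set(leaves)):
        raise MicromineError("duplicate leaf labels in tree")
    if len(leaves) < 2:
        raise MicromineError("tree must have at least 2 leaves")
    Path(path).write_text(tree.to_newick())


def read_newick(path):
    from .phylo import PhyloTree

    return PhyloTree.from_newick(Path(path).read_text())


def config_header(config, extra: Sequence[str] = ()) -> list[str]:
    """Comment-header lines naming the seed and thresholds of a run."""
    lines = [
        f"seed={config.seed}",
        f"assembly_min_identity={config.assembly_min_identity}",
        f"assembly_min_overlap={config.assembly_min_overlap}",
        f"bit_threshold={config.bit_threshold}",
        f"reference_bit_threshold={config.reference_bit_threshold}",
        f"insertion_min_len={config.insertion_min_len}",
        f"hotspot_min_len={config.hotspot_min_len}",
        f"genetic_code={config.genetic_code}",
    ]
    lines.extend(extra)
    return lines
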