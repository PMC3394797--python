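"""Structured run configuration.

One YAML file (nested key/value sections) drives a whole run; CLI flags
override individual entries.  The defaults wire in the procedure parameters
used throughout: 98% identity on 35 bp for assembly and circularity, a bit
score of 50 for homology screening, 90 for accessory reference gathering,
10 aa for reporting capsid insertions and 15 aa for hot-spot inclusion.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclasses.dataclass
class PipelineConfig:
    # Assembly / circularity stringency (fraction identity, nt overlap)
    assembly_min_identity: float = 0.98
    assembly_min_overlap: int = 35
    # Homology screening thresholds (bit scores)
    bit_threshold: float = 50.0
    reference_bit_threshold: float = 90.0
    # Capsid insertion cutoffs (aa)
    insertion_min_len: int = 10
    hotspot_min_len: int = 15
    hotspot_merge_tol: int = 10
    # Subgroup classification support cutoff (bootstrap %)
    clade_support: float = 75.0
    bootstrap_reps: int = 100
    # Candidate genome size screen (nt)
    min_genome_len: int = 3000
    max_genome_len: int = 10000
    # ORF prediction
    orf_min_codons: int = 60
    genetic_code: int = 11
    # Mushroom-protrusion anchor interval on the reference capsid (aa);
    # +/-30 around the canonical protrusion loop to absorb alignment slip
    protrusion_start: int = 230
    protrusion_end: int = 290
    # Synthetic-study conditions (used when no reads/contigs are supplied)
    n_per_template: int = 4
    coverage: float = 20.0
    read_len: int = 250
    error_rate: float = 0.0
    # Reproducibility
    seed: int = 0
    # File paths (optional; used by the CLI `all` run)
    reads: str | None = None
    contigs: str | None = None
    references: str | None = None
    outdir: str = "micromine_out"

    def validate(self) -> "PipelineConfig":
        if not (0 < self.assembly_min_identity <= 1):
            raise ConfigError(
                f"assembly_min_identity must be in (0, 1], got {self.assembly_min_identity}"
            )
        positive = [
            ("assembly_min_overlap", self.assembly_min_overlap),
            ("bit_threshold", self.bit_threshold),
            ("reference_bit_threshold", self.reference_bit_threshold),
            ("insertion_min_len", self.insertion_min_len),
            ("hotspot_min_len", self.hotspot_min_len),
            ("orf_min_codons", self.orf_min_codons),
            ("bootstrap_reps", self.bootstrap_reps),
            ("min_genome_len", self.min_genome_len),
            ("max_genome_len", self.max_genome_len),
        ]
        for name, value in positive:
            if value <= 0:
                raise ConfigError(f"{name} must be > 0, got {value}")
        if self.min_genome_len >= self.max_genome_len:
            raise ConfigError("min_genome_len must be < max_genome_len")
        if self.genetic_code not in (4, 11):
            raise ConfigError(f"genetic_code must be 4 or 11, got {self.genetic_code}")
        if not (0 <= self.clade_support <= 100):
            raise ConfigError("clade_support must be within [0, 100]")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        flat = {}
        for key, value in data.items():
            if isinstance(value, dict):  # nested sections are flattened
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs).validate()
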