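"""Synthetic Microviridae-like data with the statistical structure the
analysis assumes.

The generator emulates the study system end to end: five subgroup templates
(Microvirus, aquatic and gut Gokushovirinae, Alpavirinae, Pichovirinae)
with their subgroup-specific cyclic core-gene orders, circular genomes of
4.0-6.7 kb, a mushroom-protrusion insertion in VP1 whose mean length is
subgroup-specific (none for Microvirus, ~60 aa for Pichovirinae, ~110 aa
for Alpavirinae), optional horizontally acquired peptidase genes at named
intergenic loci (including antisense orientation), shotgun reads with
configurable length/coverage/substitution error, and host chromosomes with
embedded prophages.

Sequence divergence model: every planted gene is a reverse-translated copy
(uniform synonymous codons) of a subgroup ancestral protein, itself derived
from a single family-level ancestor, then mutated per nucleotide site with
a 2:1 transition bias.  Substitutions that would create an in-frame stop or
touch the start/stop codon are rejected so planted ORFs stay intact.
Intergenic spacers are stop-codon tilings ((TAA)n, and (TTA)n guards around
antisense genes), which pins every planted ORF to exact, maximal
coordinates -- the property the annotation oracle tests rely on.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .annotate import CORE_GENE_ORDERS
from .errors import MicromineError
from .io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "LIVMFA"
POLAR = "DEKNQRST"

#: ancestral protein lengths (aa); VP1 follows the ~427 aa capsid of
#: Microvirus-type phages, to which subgroup insertions are added
ANCESTRAL_LENGTHS = {
    "VP1": 427,
    "VP2": 270,
    "VP3": 170,
    "VP4": 330,
    "VP5": 90,
    "peptidase": 160,
}

#: aa position on the family VP1 where the protrusion insertion is planted
INSERTION_ANCHOR = 260


@dataclasses.dataclass(frozen=True)
class SubgroupTemplate:
    """Statistical description of one Microviridae subgroup."""

    name: str
    gene_order: tuple[str, ...]
    ancestral_lengths: dict = dataclasses.field(default_factory=lambda: dict(ANCESTRAL_LENGTHS))
    mean_insertion: float = 0.0  # aa; 0 disables the VP1 insertion
    insertion_sd: float = 10.0
    min_insertion: int = 20
    insertion_anchor: int = INSERTION_ANCHOR
    nt_divergence: float = 0.12  # per-site substitution rate from subgroup ancestor
    subgroup_divergence: float = 0.35  # aa rate from the family ancestor
    size_bounds: tuple[int, int] = (4000, 6700)
    ecosystem: str = "unknown"
    genetic_code: int = 11

    def __post_init__(self):
        for role in ("VP1", "VP2", "VP4"):
            if self.gene_order.count(role) != 1:
                raise MicromineError(f"gene order must contain {role} exactly once")
        lo, hi = self.size_bounds
        if not (4000 <= lo < hi <= 6700):
            raise MicromineError("size bounds must lie within [4000, 6700]")
        if self.name == "Microvirus" and self.mean_insertion != 0:
            raise MicromineError("Microvirus template must have insertion length 0")


TEMPLATE_ORDER = (
    "Microvirus",
    "Gokushovirinae_aquatic",
    "Gokushovirinae_gut",
    "Alpavirinae",
    "Pichovirinae",
)

DEFAULT_TEMPLATES: dict[str, SubgroupTemplate] = {
    "Microvirus": SubgroupTemplate(
        name="Microvirus",
        gene_order=CORE_GENE_ORDERS["Microvirus"],
        mean_insertion=0.0,
        size_bounds=(4000, 5800),
        ecosystem="human_gut",
    ),
    "Gokushovirinae_aquatic": SubgroupTemplate(
        name="Gokushovirinae_aquatic",
        gene_order=CORE_GENE_ORDERS["Gokushovirinae_aquatic"],
        mean_insertion=85.0,
        size_bounds=(4000, 6000),
        ecosystem="freshwater",
    ),
    "Gokushovirinae_gut": SubgroupTemplate(
        name="Gokushovirinae_gut",
        gene_order=CORE_GENE_ORDERS["Gokushovirinae_gut"],
        mean_insertion=85.0,
        size_bounds=(4000, 6200),
        ecosystem="human_gut",
    ),
    "Alpavirinae": SubgroupTemplate(
        name="Alpavirinae",
        gene_order=CORE_GENE_ORDERS["Alpavirinae"],
        mean_insertion=110.0,
        size_bounds=(4200, 6700),
        ecosystem="human_gut",
    ),
    "Pichovirinae": SubgroupTemplate(
        name="Pichovirinae",
        gene_order=CORE_GENE_ORDERS["Pichovirinae"],
        mean_insertion=60.0,
        size_bounds=(4000, 6000),
        ecosystem="seawater",
    ),
}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_protein(length: int, rng: np.random.Generator, alphabet: str = AA20) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def design_pilot_protein(length: int, rng: np.random.Generator) -> str:
    """A VP2-like (DNA pilot) protein: Met, a 21-aa hydrophobic N-terminal
    transmembrane stretch, a 28-aa heptad region with hydrophobic a/d
    positions (coiled coil), then random sequence."""
    tm = random_protein(21, rng, HYDROPHOBIC)
    heptad = "".join(
        HYDROPHOBIC[rng.integers(0, len(HYDROPHOBIC))]
        if i % 7 in (0, 3)
        else POLAR[rng.integers(0, len(POLAR))]
        for i in range(28)
    )
    rest = random_protein(length - 1 - 21 - 28, rng)
    return "M" + tm + heptad + rest


def make_reference_set(seed, lengths: dict | None = None) -> list[SequenceRecord]:
    """Family-level ancestral proteins for VP1-VP5 plus the M15-like
    peptidase, used as the curated reference database."""
    lengths = dict(ANCESTRAL_LENGTHS if lengths is None else lengths)
    rng = _rng([seed, 901])
    records = []
    for role in ("VP1", "VP2", "VP3", "VP4", "VP5", "peptidase"):
        n = lengths[role]
        if role == "VP2":
            prot = design_pilot_protein(n, rng)
        else:
            prot = "M" + random_protein(n - 1, rng)
        records.append(SequenceRecord(id=role, residues=prot, description="ancestral"))
    return records


def mutate_protein(
    protein: str, rate: float, rng: np.random.Generator, keep_prefix: int = 1
) -> str:
    out = list(protein)
    for i in range(keep_prefix, len(out)):
        if rng.random() < rate:
            choices = AA20.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def derive_subgroup_proteins(
    template: SubgroupTemplate, refs: Sequence[SequenceRecord], seed=None
) -> dict[str, str]:
    """Subgroup ancestral proteins: family ancestors mutated at the
    template's subgroup divergence.  The VP2 N-terminal 50 residues (TM +
    coiled-coil region) are conserved, as those features are family-wide."""
    if seed is None:
        idx = TEMPLATE_ORDER.index(template.name) if template.name in TEMPLATE_ORDER else 99
        seed = [777, idx]
    rng = _rng(seed)
    out = {}
    for rec in refs:
        keep = 50 if rec.id == "VP2" else 1
        out[rec.id] = mutate_protein(rec.residues, template.subgroup_divergence, rng, keep_prefix=keep)
    return out


# -- codon machinery ------------------------------------------------------

def _codon_tables(code: int):
    table = CodonTable.unambiguous_dna_by_id[code]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa, set(table.stop_codons)


def reverse_translate(protein: str, rng: np.random.Generator, code: int = 11) -> str:
    """Reverse-translate with uniform choice among synonymous codons."""
    by_aa, _stops = _codon_tables(code)
    codons = []
    for aa in protein:
        options = by_aa[aa]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def mutate_cds(cds: str, rate: float, rng: np.random.Generator, code: int = 11) -> str:
    """Per-site substitution with a 2:1 transition bias.

    The start codon, the stop codon, and any substitution that would create
    an in-frame stop are left untouched so the planted ORF stays intact.
    """
    _by_aa, stops = _codon_tables(code)
    out = list(cds)
    n = len(cds)
    hits = np.nonzero(rng.random(n) < rate)[0]
    for i in hits:
        if i < 3 or i >= n - 3:
            continue
        base = out[i]
        r = rng.random()
        if r < 0.5:
            new = _TRANSITION[base]
        elif r < 0.75:
            new = _TRANSVERSIONS[base][0]
        else:
            new = _TRANSVERSIONS[base][1]
        ci = (i // 3) * 3
        codon = out[ci] + out[ci + 1] + out[ci + 2]
        trial = list(codon)
        trial[i - ci] = new
        if "".join(trial) in stops:
            continue
        out[i] = new
    return "".join(out)


# -- truth records ---------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TruthOrf:
    start: int
    end: int  # half-open, stop codon included; end > L wraps the origin
    strand: str
    role: str
    protein: str


@dataclasses.dataclass(frozen=True)
class TruthAccessory:
    orf: TruthOrf
    locus: str
    fragment_start: int
    fragment_end: int


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    genome_id: str
    sequence: str
    orfs: tuple[TruthOrf, ...]
    subgroup: str
    ecosystem: str
    insertion_anchor: int
    insertion_length: int
    accessory: tuple[TruthAccessory, ...] = ()
    genetic_code: int = 11

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def all_orfs(self) -> tuple[TruthOrf, ...]:
        return self.orfs + tuple(a.orf for a in self.accessory)

    def core_order(self) -> tuple[str, ...]:
        core = [o for o in self.orfs if o.role.startswith("VP")]
        return tuple(o.role for o in sorted(core, key=lambda o: o.start))


def _spacer(rng: np.random.Generator) -> str:
    return "TAA" * int(rng.integers(2, 9))


def _layout_genome(
    genes: Sequence[tuple[str, str]],  # (role, cds) in final order
    rng: np.random.Generator,
) -> tuple[str, list[TruthOrf], int]:
    parts = []
    orfs = []
    pos = 0
    for role, cds in genes:
        sp = _spacer(rng)
        parts.append(sp)
        pos += len(sp)
        orfs.append((role, pos, pos + len(cds)))
        parts.append(cds)
        pos += len(cds)
    # terminal spacer: the wrap-around intergenic region between the last
    # and first gene (also hosts accessory insertions at the wrap locus)
    sp = _spacer(rng)
    parts.append(sp)
    pos += len(sp)
    return "".join(parts), orfs, pos


def generate_genome(
    template: SubgroupTemplate,
    seed,
    refs: Sequence[SequenceRecord] | None = None,
    subgroup_proteins: dict[str, str] | None = None,
    genome_id: str | None = None,
    vp2_cryptic: bool = False,
) -> TruthRecord:
    """Generate one circular genome following a subgroup template.

    The genome carries the template's cyclic core-gene order, a VP1
    insertion drawn around the template mean (none for Microvirus), short
    stop-tiled intergenic spacers, and enough random filler genes to reach
    the template size bounds (3-9 genes in total).  ``vp2_cryptic``
    replaces VP2 with a sequence-unrelated protein that keeps the VP2
    biophysical features (for testing positional rescue).
    """
    rng = _rng([seed] if isinstance(seed, int) else list(seed))
    if refs is None:
        refs = make_reference_set(0)
    if subgroup_proteins is None:
        subgroup_proteins = derive_subgroup_proteins(template, refs)
    code = template.genetic_code
    # per-genome divergence factor spreads within-subgroup identities
    rate = template.nt_divergence * rng.uniform(0.6, 1.4)

    ins_len = 0
    if template.mean_insertion > 0:
        ins_len = max(
            template.min_insertion,
            int(round(rng.normal(template.mean_insertion, template.insertion_sd))),
        )

    proteins: dict[str, str] = {}
    for role in template.gene_order:
        prot = subgroup_proteins[role]
        if role == "VP1" and ins_len:
            a = template.insertion_anchor
            prot = prot[:a] + random_protein(ins_len, rng) + prot[a:]
        if role == "VP2" and vp2_cryptic:
            prot = design_pilot_protein(len(prot), rng)
        proteins[role] = prot

    def build_cds(prot: str, diverge: bool) -> str:
        cds = reverse_translate(prot, rng, code) + "TAA"
        if diverge:
            cds = mutate_cds(cds, rate, rng, code)
        return cds

    genes: list[tuple[str, str]] = [
        (role, build_cds(proteins[role], diverge=not (role == "VP2" and vp2_cryptic)))
        for role in template.gene_order
    ]

    lo, hi = template.size_bounds
    order: list[tuple[str, str]] = list(genes)
    n_filler = 0
    while True:
        seq, orf_spans, total = _layout_genome(order, _rng([*_as_list(seed), 50, n_filler]))
        if total >= lo:
            break
        if len(order) >= 9:
            raise MicromineError(
                f"template {template.name}: cannot reach size bounds with <= 9 genes"
            )
        n_filler += 1
        filler_prot = "M" + random_protein(int(rng.integers(120, 251)) - 1, rng)
        filler_cds = reverse_translate(filler_prot, rng, code) + "TAA"
        slot = int(rng.integers(0, len(order) + 1))
        order.insert(slot, (f"filler{n_filler}", filler_cds))
    if total > hi:
        raise MicromineError(
            f"template {template.name}: genes do not fit size bounds ({total} > {hi})"
        )

    truth_orfs = []
    for role, s, e in orf_spans:
        cds = seq[s:e]
        prot = "M" + str(Seq(cds[3:-3]).translate(table=code))
        truth_role = role if not role.startswith("filler") else "unknown"
        truth_orfs.append(TruthOrf(start=s, end=e, strand="+", role=truth_role, protein=prot))

    return TruthRecord(
        genome_id=genome_id or f"{template.name}_g{_as_list(seed)[-1]}",
        sequence=seq,
        orfs=tuple(truth_orfs),
        subgroup=template.name,
        ecosystem=template.ecosystem,
        insertion_anchor=template.insertion_anchor if ins_len else -1,
        insertion_length=ins_len,
        genetic_code=code,
    )


def _as_list(seed) -> list:
    return [seed] if isinstance(seed, int) else list(seed)


# -- accessory genes -------------------------------------------------------

def plant_accessory(
    truth: TruthRecord,
    locus: str,
    seed,
    role: str = "peptidase",
    protein: str | None = None,
    antisense: bool = False,
    nt_divergence: float = 0.0,
    max_length: int = 6700,
) -> TruthRecord:
    """Insert an accessory gene at a named cyclic intergenic locus.

    ``locus`` is "X-Y" where X and Y are core genes of the genome and Y is
    the core gene cyclically following X.  The gene lands in the intergenic
    spacer right after X, guarded by stop tilings on its own strand;
    ``antisense`` places it on the complementary strand.
    """
    rng = _rng(_as_list(seed) + [61])
    code = truth.genetic_code
    try:
        x_role, y_role = locus.replace("–", "-").split("-")
    except ValueError as exc:
        raise MicromineError(f"bad locus {locus!r}; expected 'X-Y'") from exc
    core = sorted(
        (o for o in truth.orfs if o.role.startswith("VP")), key=lambda o: o.start
    )
    roles = [o.role for o in core]
    if x_role not in roles or y_role not in roles:
        raise MicromineError(f"unknown locus {locus!r}: flanking genes not annotated")
    xi = roles.index(x_role)
    if roles[(xi + 1) % len(roles)] != y_role:
        raise MicromineError(f"{locus!r} is not a cyclic intergenic interval of this genome")
    x_orf = core[xi]

    if protein is None:
        protein = "M" + random_protein(ANCESTRAL_LENGTHS.get(role, 160) - 1, rng)
    cds = reverse_translate(protein, rng, code) + "TAA"
    if nt_divergence:
        cds = mutate_cds(cds, nt_divergence, rng, code)

    q = x_orf.end + 3  # keep one in-frame TAA guard before the insertion
    # every fragment carries its own in-frame stop tilings so stacked
    # insertions at one locus cannot extend each other's reading frames
    if antisense:
        fragment = "TAATAA" + str(Seq(cds).reverse_complement()) + "TTATTA" + "TAATAA"
        orf = TruthOrf(start=q + 6, end=q + 6 + len(cds), strand="-", role=role, protein=protein_from(cds, code))
    else:
        fragment = "TAATAA" + cds + "TAATAA"
        orf = TruthOrf(start=q + 6, end=q + 6 + len(cds), strand="+", role=role, protein=protein_from(cds, code))

    new_seq = truth.sequence[:q] + fragment + truth.sequence[q:]
    if len(new_seq) > max_length:
        raise MicromineError("accessory insertion exceeds genome size bounds")
    if len(truth.all_orfs) + 1 > 9:
        raise MicromineError("accessory insertion exceeds 9 genes")
    shift = len(fragment)

    def shift_orf(o: TruthOrf) -> TruthOrf:
        if o.start >= q:
            return dataclasses.replace(o, start=o.start + shift, end=o.end + shift)
        return o

    new_orfs = tuple(shift_orf(o) for o in truth.orfs)
    new_acc = tuple(
        dataclasses.replace(
            a,
            orf=shift_orf(a.orf),
            fragment_start=a.fragment_start + shift if a.fragment_start >= q else a.fragment_start,
            fragment_end=a.fragment_end + shift if a.fragment_start >= q else a.fragment_end,
        )
        for a in truth.accessory
    ) + (TruthAccessory(orf=orf, locus=f"{x_role}-{y_role}", fragment_start=q, fragment_end=q + shift),)
    return dataclasses.replace(truth, sequence=new_seq, orfs=new_orfs, accessory=new_acc)


def protein_from(cds: str, code: int) -> str:
    return "M" + str(Seq(cds[3:-3]).translate(table=code))


def delete_accessory(truth: TruthRecord, index: int = -1) -> TruthRecord:
    """Inverse of :func:`plant_accessory` (removes the inserted fragment)."""
    if not truth.accessory:
        raise MicromineError("no accessory gene to delete")
    acc = truth.accessory[index]
    q, e = acc.fragment_start, acc.fragment_end
    shift = e - q
    new_seq = truth.sequence[:q] + truth.sequence[e:]

    def unshift(o: TruthOrf) -> TruthOrf:
        if o.start >= e:
            return dataclasses.replace(o, start=o.start - shift, end=o.end - shift)
        return o

    rest = tuple(a for i, a in enumerate(truth.accessory) if i != (index % len(truth.accessory)))
    rest = tuple(
        dataclasses.replace(
            a,
            orf=unshift(a.orf),
            fragment_start=a.fragment_start - shift if a.fragment_start >= e else a.fragment_start,
            fragment_end=a.fragment_end - shift if a.fragment_start >= e else a.fragment_end,
        )
        for a in rest
    )
    return dataclasses.replace(
        truth,
        sequence=new_seq,
        orfs=tuple(unshift(o) for o in truth.orfs),
        accessory=rest,
    )


# -- reads and prophages ---------------------------------------------------

@dataclasses.dataclass
class ReadSet:
    records: list[SequenceRecord]
    origins: list[tuple]  # (genome_id, start, strand)
    read_len: int
    coverage: float
    error_rate: float


def simulate_reads(
    truth: TruthRecord,
    coverage: float = 20.0,
    read_len: int = 250,
    err: float = 0.0,
    seed=0,
) -> ReadSet:
    """Uniform shotgun reads around the circle (wrap handled); substitution
    errors only.  Read count = ceil(coverage * genome_len / read_len)."""
    if coverage <= 0:
        raise MicromineError("coverage must be > 0")
    L = truth.length
    if read_len >= L:
        raise MicromineError("read length must be smaller than the genome")
    rng = _rng(_as_list(seed) + [7])
    n = math.ceil(coverage * L / read_len)
    doubled = truth.sequence + truth.sequence
    starts = rng.integers(0, L, n)
    strands = rng.integers(0, 2, n)
    records, origins = [], []
    for i in range(n):
        s = int(starts[i])
        read = doubled[s : s + read_len]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            read = str(Seq(read).reverse_complement())
        if err > 0:
            arr = list(read)
            for j in np.nonzero(rng.random(read_len) < err)[0]:
                options = "ACGT".replace(arr[j], "")
                arr[j] = options[rng.integers(0, 3)]
            read = "".join(arr)
        rid = f"{truth.genome_id}_r{i:05d}"
        records.append(SequenceRecord(id=rid, residues=read))
        origins.append((truth.genome_id, s, strand))
    return ReadSet(records=records, origins=origins, read_len=read_len, coverage=coverage, error_rate=err)


def embed_prophage(host_len: int, truth: TruthRecord, position: int, seed=0):
    """A random host chromosome with the linearized genome inserted at
    ``position``; returns (chromosome record, true insert interval)."""
    if not (0 <= position <= host_len):
        raise MicromineError("position must be within [0, host_len]")
    rng = _rng(_as_list(seed) + [13])
    host = "".join("ACGT"[i] for i in rng.integers(0, 4, host_len))
    seq = host[:position] + truth.sequence + host[position:]
    rec = SequenceRecord(id=f"host_{truth.genome_id}", residues=seq)
    return rec, (position, position + truth.length)


def diverged_copy(
    seq: str, rng: np.random.Generator, mean_spacing: int = 10, max_spacing: int = 20
) -> str:
    """A mutated copy with substitutions spread so that no identical run
    longer than ``max_spacing`` nt remains (used to build fixtures of a
    given mutual identity with no residual high-identity windows)."""
    out = list(seq)
    p = int(rng.integers(0, max_spacing))
    while p < len(out):
        options = "ACGT".replace(out[p], "")
        out[p] = options[rng.integers(0, 3)]
        p += int(rng.integers(max(1, mean_spacing // 2), max_spacing + 1))
    return "".join(out)


# -- cohorts ---------------------------------------------------------------

@dataclasses.dataclass
class Cohort:
    refs: list[SequenceRecord]
    templates: dict[str, SubgroupTemplate]
    subgroup_proteins: dict[str, dict[str, str]]
    truths: list[TruthRecord]
    readsets: dict[str, ReadSet]
    sample_of: dict[str, str]
    ecosystem_of: dict[str, str]

    @property
    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.genome_id: t for t in self.truths}


def generate_cohort(
    seed: int,
    n_per_template: int = 4,
    templates: dict[str, SubgroupTemplate] | None = None,
    coverage: float = 20.0,
    read_len: int = 250,
    err: float = 0.0,
    with_reads: bool = True,
    with_accessory: bool = True,
) -> Cohort:
    """The default synthetic study: n genomes per subgroup template, shotgun
    reads per genome, peptidase genes planted in the human-associated
    subgroups (Alpavirinae at alternating VP2-VP4 / VP4-VP1 loci, gut
    Gokushovirinae at VP2-VP4, one with an extra antisense unknown gene)."""
    templates = dict(DEFAULT_TEMPLATES if templates is None else templates)
    refs = make_reference_set(seed)
    subgroup_proteins = {
        name: derive_subgroup_proteins(templates[name], refs, seed=[seed, 10 + i])
        for i, name in enumerate(t for t in TEMPLATE_ORDER if t in templates)
    }
    truths: list[TruthRecord] = []
    readsets: dict[str, ReadSet] = {}
    sample_of: dict[str, str] = {}
    ecosystem_of: dict[str, str] = {}
    gidx = 0
    for name in (t for t in TEMPLATE_ORDER if t in templates):
        template = templates[name]
        sample = f"S_{name}"
        ecosystem_of[sample] = template.ecosystem
        for j in range(n_per_template):
            gid = f"{name}_{j:03d}"
            truth = generate_genome(
                template,
                seed=[seed, 100, gidx],
                refs=refs,
                subgroup_proteins=subgroup_proteins[name],
                genome_id=gid,
            )
            if with_accessory and name == "Alpavirinae":
                locus = "VP2-VP4" if j % 2 == 0 else "VP4-VP1"
                pep = subgroup_proteins[name]["peptidase"]
                truth = plant_accessory(
                    truth,
                    locus,
                    seed=[seed, 301, gidx],
                    role="peptidase",
                    protein=pep,
                    nt_divergence=template.nt_divergence,
                )
            if with_accessory and name == "Gokushovirinae_gut":
                pep = subgroup_proteins[name]["peptidase"]
                truth = plant_accessory(
                    truth,
                    "VP2-VP4",
                    seed=[seed, 302, gidx],
                    role="peptidase",
                    protein=pep,
                    nt_divergence=template.nt_divergence,
                )
                if j == 0:
                    unknown = "M" + random_protein(152, _rng([seed, 303, gidx]))
                    truth = plant_accessory(
                        truth,
                        "VP2-VP4",
                        seed=[seed, 304, gidx],
                        role="unknown",
                        protein=unknown,
                        antisense=True,
                    )
            truths.append(truth)
            sample_of[gid] = sample
            if with_reads:
                readsets[gid] = simulate_reads(
                    truth, coverage=coverage, read_len=read_len, err=err, seed=[seed, 200, gidx]
                )
            gidx += 1
    return Cohort(
        refs=refs,
        templates=templates,
        subgroup_proteins=subgroup_proteins,
        truths=truths,
        readsets=readsets,
        sample_of=sample_of,
        ecosystem_of=ecosystem_of,
    )


def make_recruitment_chain(seed: int = 0):
    """Fixture for iterative recruitment: genome B is detectable from the
    references; genome A shares only B's novel gene (diverged mildly) and is
    essentially random with respect to the references, so A can only be
    recruited through B in a second iteration.  A third random contig is
    never recruited."""
    rng = _rng([seed, 41])
    refs = make_reference_set(seed)
    sub = derive_subgroup_proteins(DEFAULT_TEMPLATES["Gokushovirinae_aquatic"], refs, seed=[seed, 42])
    novel = "M" + random_protein(199, rng)

    def build(genes, tag):
        cds_list = [(role, reverse_translate(p, rng, 11) + "TAA") for role, p in genes]
        seq, _orfs, _total = _layout_genome(cds_list, rng)
        return SequenceRecord(id=tag, residues=seq)

    b = build(
        [("VP4", sub["VP4"]), ("VP1", sub["VP1"]), ("novel", novel)],
        "genomeB",
    )
    novel_div = mutate_protein(novel, 0.10, rng)
    a = build(
        [
            ("x1", "M" + random_protein(329, rng)),
            ("x2", "M" + random_protein(426, rng)),
            ("novel", novel_div),
        ],
        "genomeA",
    )
    noise = SequenceRecord(
        id="noise", residues="".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
    )
    return refs, [a, b, noise]
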