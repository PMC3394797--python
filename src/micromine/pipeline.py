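"""End-to-end orchestration: simulate -> recover -> annotate -> classify ->
capsid -> accessory -> ecology, with TSV/FASTA/Newick reports.

Every stage failure aborts with the stage name and the input id; every
output file carries a comment header naming the seed and thresholds; a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import accessory as accessory_mod
from . import annotate as annotate_mod
from . import assembly, capsid, ecology, phylo, search, simulate
from .config import PipelineConfig
from .errors import MicromineError, StageError
from .io import SequenceRecord, config_header, write_fasta, write_newick, write_tsv


@dataclasses.dataclass
class AnnotatedGenome:
    genome: assembly.CircularGenome
    annotations: list
    signature: tuple[str, ...] | None


@dataclasses.dataclass
class PipelineReport:
    config: PipelineConfig
    genomes: list[assembly.CircularGenome]
    annotated: dict[str, AnnotatedGenome]
    subgroup_calls: dict
    vp1_tree: "phylo.PhyloTree | None"
    insertions: pd.DataFrame
    hotspots: list
    capsid_stats: tuple
    accessory_reports: list
    congruence: dict | None
    ecology_tables: tuple
    log_lines: list


def annotate_genome(
    circ: assembly.CircularGenome,
    refs,
    config: PipelineConfig,
) -> AnnotatedGenome:
    """ORF prediction, role assignment, VP2 rescue and canonical rotation
    for one recovered genome."""
    core_refs = [r for r in refs if r.id.startswith("VP")]
    orfs = annotate_mod.find_orfs_circular(
        circ.residues,
        min_len=config.orf_min_codons,
        code=config.genetic_code,
        genome_id=circ.id,
    )
    anns = annotate_mod.assign_core_genes(orfs, core_refs, bit_threshold=config.bit_threshold)
    circ2, anns = assembly.canonical_rotation(circ, anns)
    ref_vp2 = next((r for r in core_refs if r.id == "VP2"), None)
    if ref_vp2 is not None:
        rescued = annotate_mod.positional_vp2_rescue(
            anns, len(circ2.residues), len(ref_vp2.residues)
        )
        if rescued is not None:
            anns = [
                rescued if a.orf == rescued.orf else a
                for a in anns
            ]
    try:
        signature = annotate_mod.gene_order_signature(anns)
    except MicromineError:
        signature = None
    return AnnotatedGenome(genome=circ2, annotations=anns, signature=signature)


def run_pipeline(
    config: PipelineConfig,
    outdir,
    cohort: "simulate.Cohort | None" = None,
) -> PipelineReport:
    """Run the full recovery-and-characterization pipeline.

    Without an explicit cohort, the bundled generator produces the study
    data from the config (n_per_template genomes per subgroup template,
    shotgun reads at the configured coverage/length/error)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {dataclasses.asdict(config)}"]
    header = config_header(config)

    # ---- simulate -------------------------------------------------------
    if cohort is None:
        try:
            cohort = simulate.generate_cohort(
                seed=config.seed,
                n_per_template=config.n_per_template,
                coverage=config.coverage,
                read_len=config.read_len,
                err=config.error_rate,
            )
        except MicromineError as exc:
            raise StageError("simulate", "cohort", str(exc))
    refs = cohort.refs
    core_refs = [r for r in refs if r.id.startswith("VP")]
    acc_refs = [r for r in refs if not r.id.startswith("VP")]

    # ---- recover --------------------------------------------------------
    genomes: list[assembly.CircularGenome] = []
    all_reads = []
    for sample in sorted(cohort.ecosystem_of):
        sample_reads = []
        for gid, rs in sorted(cohort.readsets.items()):
            if cohort.sample_of[gid] == sample:
                sample_reads.extend(rs.records)
        all_reads.extend(sample_reads)
        if not sample_reads:
            continue
        try:
            contigs = assembly.assemble_greedy(
                sample_reads,
                min_overlap=config.assembly_min_overlap,
                min_identity=config.assembly_min_identity,
            )
            for contig in contigs:
                if len(contig.residues) <= 2 * config.assembly_min_overlap:
                    continue
                circ = assembly.detect_circular(
                    contig,
                    min_overlap=config.assembly_min_overlap,
                    min_identity=config.assembly_min_identity,
                )
                if circ is None:
                    continue
                if not (config.min_genome_len <= circ.length <= config.max_genome_len):
                    continue
                genomes.append(
                    dataclasses.replace(circ, id=f"{sample}_{circ.id}")
                )
        except MicromineError as exc:
            raise StageError("recover", sample, str(exc))
    if not cohort.readsets:
        log.append("warning: empty read set; nothing to recover")
    # homology screen with second-iteration recruitment
    screened: list[assembly.CircularGenome] = []
    if genomes:
        as_records = [SequenceRecord(id=g.id, residues=g.residues) for g in genomes]
        recruited = search.iterative_recruit(
            as_records, refs, max_iter=2, code=config.genetic_code,
            bit_threshold=config.bit_threshold, min_orf_codons=config.orf_min_codons,
        )
        keep = recruited[-1]
        screened = [g for g in genomes if g.id in keep]
    genomes = screened

    # ---- annotate -------------------------------------------------------
    annotated: dict[str, AnnotatedGenome] = {}
    for g in genomes:
        try:
            annotated[g.id] = annotate_genome(g, refs, config)
        except MicromineError as exc:
            raise StageError("annotate", g.id, str(exc))

    # ---- classify -------------------------------------------------------
    vp1_records = []
    for gid, ag in sorted(annotated.items()):
        vp1 = next((a for a in ag.annotations if a.role == "VP1"), None)
        if vp1 is not None:
            vp1_records.append(SequenceRecord(id=gid, residues=vp1.orf.protein))
    labeled_refs = [
        (SequenceRecord(id=f"ref_{name}", residues=prots["VP1"]), name)
        for name, prots in sorted(cohort.subgroup_proteins.items())
    ]
    subgroup_calls: dict = {}
    vp1_tree = None
    if vp1_records and labeled_refs:
        try:
            subgroup_calls = phylo.classify_subgroup(
                vp1_records,
                labeled_refs,
                support_threshold=config.clade_support,
                n_reps=config.bootstrap_reps,
                seed=config.seed,
            )
            aln = phylo.progressive_msa(vp1_records + [r for r, _ in labeled_refs])
            vp1_tree = phylo.bootstrap_support(aln, n_reps=config.bootstrap_reps, seed=config.seed)
        except MicromineError as exc:
            raise StageError("classify", "vp1", str(exc))

    # ---- capsid ---------------------------------------------------------
    ref_vp1 = next(r for r in core_refs if r.id == "VP1")
    ins_rows = []
    all_blocks = []
    vp1_lengths_by_subgroup: dict[str, list[int]] = {}
    interval = (config.protrusion_start, config.protrusion_end)
    for rec in vp1_records:
        blocks = capsid.pairwise_insertions(rec, ref_vp1, min_len=config.insertion_min_len)
        mush = capsid.mushroom_insertion(blocks, interval)
        all_blocks.extend(blocks)
        for b in blocks:
            ins_rows.append(
                {
                    "genome": rec.id,
                    "anchor": b.anchor,
                    "length": b.length,
                    "is_mushroom": int(mush is not None and b == mush),
                }
            )
        call = subgroup_calls.get(rec.id)
        sg = call.subgroup if call else "unclassified"
        vp1_lengths_by_subgroup.setdefault(sg, []).append(len(rec.residues))
    insertions = pd.DataFrame(ins_rows, columns=["genome", "anchor", "length", "is_mushroom"])
    hotspots = capsid.insertion_hotspots(
        all_blocks, min_len=config.hotspot_min_len, merge_tol=config.hotspot_merge_tol
    )
    capsid_stats = capsid.size_stats(vp1_lengths_by_subgroup)

    # ---- accessory ------------------------------------------------------
    accessory_reports = []
    acc_proteins = []
    for gid, ag in sorted(annotated.items()):
        if not acc_refs:
            break
        reports = accessory_mod.detect_accessory(
            ag.annotations,
            acc_refs,
            bit_threshold=config.bit_threshold,
            genome_length=len(ag.genome.residues),
        )
        accessory_reports.extend(reports)
        for rep in reports:
            acc_proteins.append(SequenceRecord(id=gid, residues=rep.orf.protein))
    congruence = None
    if len(acc_proteins) >= 4 and vp1_tree is not None:
        try:
            acc_aln = phylo.progressive_msa(acc_proteins)
            acc_idm = phylo.percent_identity_matrix(acc_aln)
            acc_tree = phylo.nj_tree(acc_idm.ids, phylo.identity_to_distance(acc_idm))
            congruence = accessory_mod.hgt_congruence(acc_tree, vp1_tree)
        except MicromineError as exc:
            log.append(f"warning: congruence skipped ({exc})")

    # ---- ecology --------------------------------------------------------
    # the affiliation database holds the full VP1s of the recovered genomes
    # (insertions included) alongside the labeled references, mirroring a
    # database built from "all VP1" of the study's complete genomes
    vp1_db = list(labeled_refs)
    for rec in vp1_records:
        call = subgroup_calls.get(rec.id)
        if call and call.subgroup != "unclassified":
            vp1_db.append((rec, call.subgroup))
    affiliations_by_sample: dict[str, dict] = {}
    for sample in sorted(cohort.ecosystem_of):
        sample_reads = []
        for gid, rs in sorted(cohort.readsets.items()):
            if cohort.sample_of[gid] == sample:
                sample_reads.extend(rs.records)
        affiliations_by_sample[sample] = ecology.affiliate_reads(
            sample_reads, vp1_db, bit_threshold=config.bit_threshold, code=config.genetic_code
        )
    eco_tables = ecology.presence_matrix(affiliations_by_sample, cohort.ecosystem_of)

    # ---- write reports --------------------------------------------------
    _write_reports(
        outdir, header, config, genomes, annotated, subgroup_calls, vp1_tree,
        insertions, hotspots, capsid_stats, accessory_reports, congruence,
        eco_tables, log,
    )
    return PipelineReport(
        config=config,
        genomes=genomes,
        annotated=annotated,
        subgroup_calls=subgroup_calls,
        vp1_tree=vp1_tree,
        insertions=insertions,
        hotspots=hotspots,
        capsid_stats=capsid_stats,
        accessory_reports=accessory_reports,
        congruence=congruence,
        ecology_tables=eco_tables,
        log_lines=log,
    )


def _write_reports(
    outdir, header, config, genomes, annotated, subgroup_calls, vp1_tree,
    insertions, hotspots, capsid_stats, accessory_reports, congruence,
    eco_tables, log,
):
    recs = [
        SequenceRecord(
            id=g.id,
            residues=g.residues,
            description=f"length={g.length} overlap={g.overlap_len}",
        )
        for g in genomes
    ]
    with open(outdir / "genomes.fasta", "w") as fh:
        for line in header:
            fh.write(f"; {line}\n")
    if recs:
        import io as _io

        buf = _io.StringIO()
        from Bio import SeqIO
        from Bio.Seq import Seq as _Seq
        from Bio.SeqRecord import SeqRecord as _SR

        SeqIO.write(
            [_SR(_Seq(r.residues), id=r.id, description=r.description) for r in recs],
            buf,
            "fasta",
        )
        with open(outdir / "genomes.fasta", "a") as fh:
            fh.write(buf.getvalue())

    feat_rows = []
    for gid, ag in sorted(annotated.items()):
        for ann in sorted(ag.annotations, key=lambda a: (a.orf.start, a.orf.strand)):
            feat_rows.append(
                {
                    "genome": gid,
                    "role": ann.role,
                    "start": ann.orf.start,
                    "end": ann.orf.end,
                    "strand": ann.orf.strand,
                    "wraps": ann.orf.wraps,
                    "length_aa": len(ann.orf.protein),
                    "bit_score": round(ann.bit_score, 2),
                    "evidence": ann.evidence,
                }
            )
    write_tsv(pd.DataFrame(feat_rows), outdir / "features.tsv", header)

    call_rows = []
    for gid in sorted(annotated):
        call = subgroup_calls.get(gid)
        ag = annotated[gid]
        call_rows.append(
            {
                "genome": gid,
                "subgroup": call.subgroup if call else "unclassified",
                "method": (call.method or "none") if call else "none",
                "support": round(call.support, 1) if call and call.support is not None else "",
                "identity": round(call.identity, 1) if call and call.identity is not None else "",
                "gene_order": "-".join(ag.signature) if ag.signature else "",
            }
        )
    write_tsv(pd.DataFrame(call_rows), outdir / "subgroups.tsv", header)

    if vp1_tree is not None:
        write_newick(vp1_tree, outdir / "vp1_tree.nwk")
    write_tsv(insertions, outdir / "insertions.tsv", header)
    hs_rows = [
        {
            "interval_start": h.interval[0],
            "interval_end": h.interval[1],
            "n_members": len(h.members),
            "max_insertion": h.max_length,
        }
        for h in hotspots
    ]
    write_tsv(pd.DataFrame(hs_rows), outdir / "hotspots.tsv", header)
    stats_table, F, p = capsid_stats
    extra = [f"anova_F={F}", f"anova_p={p}"] if F is not None else []
    write_tsv(stats_table, outdir / "capsid_stats.tsv", list(header) + extra)

    acc_rows = [
        {
            "genome": r.genome_id,
            "role": r.role,
            "start": r.orf.start,
            "end": r.orf.end,
            "strand": r.orf.strand,
            "locus": r.locus,
            "antisense": int(r.antisense),
            "bit_score": round(r.bit_score, 2),
        }
        for r in accessory_reports
    ]
    write_tsv(pd.DataFrame(acc_rows), outdir / "accessory.tsv", header)
    with open(outdir / "congruence.txt", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        if congruence:
            for k, v in congruence.items():
                fh.write(f"{k}\t{v}\n")

    table, rollup = eco_tables
    write_tsv(table, outdir / "ecology_presence.tsv", header)
    write_tsv(rollup, outdir / "ecology_biomes.tsv", header)
    with open(outdir / "run.log", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for line in log:
            fh.write(line + "\n")
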