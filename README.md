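# micromine

Recovery and characterization of complete circular ssDNA phage genomes
(Microviridae-like) from virome sequence data.

Small icosahedral ssDNA phages carry circular genomes of roughly 4–7 kb
with three universal core genes — VP1 (major capsid protein), VP2 (DNA
pilot protein) and VP4 (replication initiation protein) — plus VP3/VP5 in
some lineages.  Because the genomes are small and abundant, complete
genomes can be assembled directly from shotgun viromes: a contig whose end
realigns to its own start is a finished circle.  `micromine` implements
that mining procedure and the downstream comparative analyses as a tested,
reusable pipeline for anyone working with viral metagenomes:

- **Recovery** — greedy overlap-layout-consensus assembly at a stringency
  of ≥98% identity over ≥35 nt, terminal-overlap circularity detection
  with redundancy trimming, and canonical rotation (VP1 forward, VP4 start
  at position 0).
- **Screening** — six-frame Smith–Waterman search against curated core
  proteins with BLAST-comparable bit scores,
  `bit = (λ·raw − ln K)/ln 2` (λ = 0.267, K = 0.041), keeping candidates at
  ≥50 bits, with a second recruitment iteration that uses first-round
  genomes as queries to reach more distant relatives; the same machinery
  scans bacterial chromosomes for integrated prophages.
- **Annotation** — circular-aware ORF prediction (origin-spanning ORFs
  included), best-hit core-gene role assignment, rescue of highly divergent
  VP2 genes from their conserved position and biophysical signature
  (N-terminal transmembrane segment + coiled coil), and rotation-normalized
  cyclic gene-order signatures (e.g. VP4–VP2–VP1 distinguishes the
  Pichovirinae from every other subgroup's VP4–VP1–VP2 organization).
- **Phylogeny & classification** — progressive MSA, the alignment-based
  percent-identity matrix, Saitou–Nei neighbor joining (exact on additive
  distances) with column-resampling bootstrap, Robinson–Foulds tree
  comparison, and clade-based subgroup classification (support ≥75).
- **Capsid insertions** — reference-anchored extraction of VP1 insertions
  (the mushroom-like protrusion at the capsid 3-fold axes that all
  subgroups except the ΦX174-like microviruses carry), hot-spot clustering
  of large (≥15 aa) insertions, size statistics with one-way ANOVA.
- **Accessory genes** — detection of horizontally acquired M15-family
  peptidase-like genes, cyclic insertion-locus naming (VP2–VP4 vs VP4–VP1),
  antisense-ORF flagging, and topological congruence of the accessory tree
  with the VP1 phylogeny.
- **Ecology** — best-hit affiliation of unassembled reads against a VP1
  database and per-sample/per-biome presence matrices.

A first-class synthetic-virome generator (`micromine.simulate`) produces
subgroup-faithful genomes, reads, reference proteins and host chromosomes
with full ground truth, so the complete chain is testable without any
external downloads.

## Worked example

```python
from micromine import simulate, assembly
from micromine.config import PipelineConfig
from micromine.pipeline import run_pipeline

cfg = PipelineConfig(seed=11, n_per_template=2, coverage=15.0, bootstrap_reps=50)
report = run_pipeline(cfg, "out")
print(len(report.genomes))
print({g: c.subgroup for g, c in sorted(report.subgroup_calls.items())})
stats, F, p = report.capsid_stats
print(stats.to_string(index=False))
```

prints

```
10
{'S_Alpavirinae_contig0001': 'Alpavirinae', 'S_Alpavirinae_contig0002': 'Alpavirinae',
 'S_Gokushovirinae_aquatic_contig0001': 'Gokushovirinae_aquatic', ...}
                 group  n  mean   min   max
           Alpavirinae  2 532.5 532.0 533.0
Gokushovirinae_aquatic  2 514.0 507.0 521.0
    Gokushovirinae_gut  2 517.0 514.0 520.0
            Microvirus  2 427.0 427.0 427.0
          Pichovirinae  2 490.0 487.0 493.0
```

All ten planted genomes are recovered as circles, classified into their
subgroups, and the capsid size table shows the family-wide pattern: the
microvirus-type capsid stays at its 427-aa core size while every other
subgroup is enlarged by its mushroom-protrusion insertion (shortest in
Pichovirinae, longest in Alpavirinae).  The same run writes TSV/FASTA/
Newick reports (features, subgroup calls with gene orders, VP1 tree,
insertion and hot-spot tables, accessory loci, ecology matrices) into
`out/`, each stamped with the seed and thresholds.

The same stages are exposed as a CLI:
`micromine simulate | recover | annotate | classify | capsid | accessory |
ecology | scan-prophage | all`.

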