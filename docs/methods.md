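# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `micromine`.  Coordinates throughout are 0-based,
half-open, on the forward strand of the canonically rotated circular
genome; a feature with `end > L` wraps across the origin (`wraps=true`).

## Recovery of circular genomes

**Assembly.** Reads are assembled by a greedy overlap-layout-consensus
procedure: the pair of contigs with the longest ungapped overlap of at
least 35 nt at ≥98% identity (both orientations) is merged repeatedly
until no mergeable pair remains.  The 98%/35 nt pair mirrors the
minimum-identity/minimum-overlap stringency commonly used to confine
virome assemblies to a single viral species; both are configurable.
Overlap identity is computed on an ungapped alignment — indels break an
overlap — which is adequate for substitution-only error models.
Tie-breaking is longest overlap, then higher identity, then the
lexicographically smaller contig-id pair; consensus is per-column majority
over supporting reads with ties resolved toward the alphabetically
smaller base, so assembly is fully deterministic.  Candidate overlaps are
discovered by probing each contig's terminal k-mers (k = min(20,
min_overlap)) against contig interiors.  This discovery step is exact for
error-free reads (every true overlap contains the partner's terminal
k-mer verbatim); with sequencing errors an overlap whose terminal k-mer
is mutated can be missed, so a final sweep re-scans all surviving contigs
and merging resumes if anything is found.  The greedy merge order itself
is exact (a lazy heap over verified candidates).

**Circularity.** A contig is a circular genome when its longest
suffix–prefix alignment of length ≥35 nt reaches ≥98% identity; the
redundant suffix copy is trimmed, so the reported length is the true
circle length.  The boundary is sharp: a 34-nt perfect terminal repeat is
rejected, 35 nt is accepted.  Re-running detection on a trimmed genome
finds nothing (idempotence).  Candidate genomes are screened to
3,000–10,000 nt by default, bracketing the family's observed 4.0–6.7 kb
range with margin.

**Canonical rotation.** Given annotations, the genome is
reverse-complemented if needed so VP1 lies on the forward strand, then
rotated so the VP4 start codon sits at position 0; all feature coordinates
are remapped.  This makes gene orders and accessory loci directly
comparable across genomes and invariant to how the assembler happened to
linearize the circle.  Missing VP1/VP4 leaves the genome unrotated with a
warning flag.

## Translated homology search

Six reading frames of the query are translated and split at stop codons;
stop-free segments of ≥20 aa are aligned to each reference protein by
exact Smith–Waterman with affine gaps (BLOSUM62; a gap of length g costs
11 + g, BLAST's default convention).  Raw scores convert to bit scores as
`(λ·raw − ln K)/ln 2` with the published gapped-BLOSUM62 constants
λ = 0.267, K = 0.041, so the 50-bit screening threshold is comparable to
BLAST output; 50 bits corresponds to a raw score of ~118, far beyond what
random 5-kb sequences reach against the reference set (empirically ~20–30
bits).  No E-values are computed — filtering is on bit score only.
Recruitment is iterative: round one keeps contigs with any reference hit
at ≥50 bits; later rounds add the translated ORFs (stop-free segments ≥60
codons) of recruited contigs as queries, so genomes with no direct
similarity to the references are pulled in through intermediates.  The
recruited set grows monotonically and stops at a fixed point or the
configured iteration cap (2 by default).  Prophage scanning projects hits
on either strand of a chromosome to nucleotide coordinates and merges
hits closer than 2 kb into candidate integrated-phage intervals.

## Annotation

ORFs are predicted on both strands of the doubled sequence so they may
span the origin; for each stop codon the maximal ORF (earliest in-frame
start — ATG/GTG/TTG — after the previous stop) is reported,
wrap-equivalent duplicates are removed keyed on (start mod L, strand,
length), and spans above one full circle are dropped.  The minimum length
is 60 codons, below the smallest core gene the generator plants (VP5-like,
90 aa).  Initiator residues are reported as Met regardless of start codon.
Genetic codes 11 (bacterial) and 4 (TGA = Trp, for Spiroplasma-like hosts)
are supported.

Roles are assigned by best local-alignment hit against the reference set
at ≥50 bits; when two ORFs claim one role the higher bit score wins (ties:
longer ORF, then smaller start) and the loser reverts to unknown.

**VP2 rescue.** Pilot proteins diverge fastest, and some genomes carry a
VP2 that escapes similarity search entirely while keeping the family-wide
biophysical signature.  Detection uses a Kyte–Doolittle window (19 aa,
mean ≥1.6, window start within the first 60 residues) for the N-terminal
transmembrane segment, and a deliberately simple heptad-periodicity
heuristic for the coiled coil (some 28-aa window with ≥60% of a/d
positions hydrophobic under its best phase) — a proxy, not a published
profile method, and permissive on its own.  Rescue therefore also requires
position: the candidate must be an unknown, forward-strand ORF that does
not overlap any core gene, sits in the cyclic slot VP2 occupies in a
gene-order-compatible subgroup template, and is within ±50% of the
reference VP2 length.  The ±50% window and slot rule are this package's
choices; evidence is recorded as `feature-based`.

**Gene-order signatures** list the core roles by start coordinate,
rotation-normalized to begin at VP4; equality is cyclic.  All subgroups
share the cyclic VP4…VP1…VP2 sub-order except the Pichovirinae
(VP4–VP2–VP1), which is what makes the signature a classification
character.

## Phylogenetics

The progressive MSA builds a guide tree from 3-mer set distances via
UPGMA, then merges profiles by global affine-gap profile–profile DP
(BLOSUM62 expected score between column frequency vectors; gap cost
10 + 0.5·g).  For two sequences this reduces exactly to pairwise global
alignment under the same scoring.  Percent identity between two rows is
computed over co-aligned columns (pairwise deletion); a variant counting
all occupied columns in the denominator is available
(`--identity-include-gaps`).  Distances are p-distances, d = 1 − pid/100 —
the simplest transform consistent with an alignment-identity script.

Neighbor joining follows Saitou–Nei exactly: Q-matrix ties break toward
the smallest (i, j) index pair in the current matrix, negative branch
lengths clamp to 0.  On additive matrices the generating topology and
branch lengths are recovered to numerical precision (tested against an
independent implementation).  Bootstrap supports come from resampling
alignment columns with replacement (default 100 replicates), rebuilding
the NJ tree per replicate, and scoring each original split by the
percentage of replicates containing it.

**Subgroup classification.** Queries and labeled references are aligned
jointly; a query is assigned subgroup X when the smallest split side
containing it whose references are all X has bootstrap support ≥75.
Failing that, it falls back to the subgroup of its highest-identity
reference if that identity is ≥20%, else `unclassified`.  The fallback
uses the gap-inclusive identity: pairwise-deletion identity between
unrelated ~400-aa proteins is inflated to ~15–22% by alignment artifacts
(the aligner pairs similar residues by construction), whereas the
gap-inclusive null sits at ~9–13%, cleanly below the 20% floor while
genuine within- and between-subgroup identities stay well above it.

Maximum-likelihood inference is out of scope; the accessory-gene tree
uses the same NJ machinery, a documented substitution that is adequate
because the congruence conclusions drawn from it are topology-level
(Robinson–Foulds on shared taxa, normalized by 2(n−3), verdict
"consistent" at ≤0.5 — an operationalization of a qualitative judgment,
configurable and not itself a literature value).

## Capsid insertion analysis

Insertions are read off query-vs-reference alignments as maximal
reference-gap stretches carrying ≥10 query residues (reporting cutoff);
the anchor is the count of reference residues preceding the stretch.
Pairwise alignments are the default basis — large MSAs smear gap columns.
The pairwise aligner uses a near length-independent gap cost (opening
100, extension 0.01): domain-scale insertions are expected to be few and
long, and under this regime a planted insertion stays in one gap run
because splitting it would cost a full extra opening that islands of
chance matches cannot pay.  The residual ambiguity is anchor position,
which can slip ~±15 residues between diverged flanks; the
mushroom-protrusion window (default reference positions 230–290, around
the generator's planting anchor 260) allows for that.  No structural
coordinates are used — the protrusion interval is configuration, since
its exact location is only defined on a structure.  Hot-spots cluster the
anchors of large insertions (≥15 aa) by single linkage with a 10-position
tolerance; the cluster count is non-increasing in the tolerance.  Size
statistics are group summaries plus a standard one-way ANOVA
(scipy `f_oneway`); groups {2,4} vs {6,8} give F = 16/(4/2) = 8, and
identical groups give F = 0, p = 1.

## Accessory genes and ecology

Unknown ORFs are re-scored against accessory references (M15-family
peptidase analogue) at 50 bits — the 90-bit threshold is reserved for
gathering reference homologues, matching its original role.  Loci are
named by the flanking core genes on the canonical circle ("VP2-VP4",
"VP4-VP1"); an accessory overlapping a core gene becomes "within-X".
Antisense ORFs (strand '−' after canonicalization) are listed separately.

Read affiliation translates each read in six frames against a labeled VP1
database — the full VP1s of the recovered genomes alongside the
references, since reads falling inside genome-specific insertion loops
only match the genome's own VP1 — and takes the best hit at ≥50 bits
(ties to the first-listed reference).  Reads under 60 nt are skipped: the
translated segment would be <20 aa, where 50 bits is essentially
unreachable and scores are noise.  Presence matrices count affiliated
reads per sample and roll up to samples-per-biome.

## The synthetic-data generator

The generator emulates the study system, not any particular dataset:

- **Templates.** Five subgroup templates fix the cyclic core-gene order
  (Microvirus and Alpavirinae VP4–VP1–VP2; aquatic Gokushovirinae
  VP4–VP5–VP1–VP2–VP3; gut Gokushovirinae VP4–VP5–VP3–VP1–VP2;
  Pichovirinae VP4–VP2–VP1), genome size bounds within 4.0–6.7 kb, the
  ecosystem label, and the mushroom-insertion mean: 0 aa (Microvirus),
  85 aa (both Gokushovirinae, the middle of the observed 53–114 range),
  110 aa (Alpavirinae), 60 aa (Pichovirinae), each drawn per genome as
  Normal(mean, 10) clamped at ≥20 aa.  The family VP1 ancestor is 427 aa
  (the Microvirus-type capsid average), so each non-Microvirus VP1 is
  longer than it by exactly the planted insertion.
- **Divergence.** One family-level ancestral protein per role; subgroup
  ancestors are aa-level mutants at rate 0.35 (between-subgroup VP1
  identities land in the tens of percent); each genome reverse-translates
  the subgroup proteins with uniform synonymous codons and mutates
  nucleotide sites at rate 0.12 × U(0.6, 1.4) with a 2:1 transition bias.
  Substitutions that would create an in-frame stop or touch a start/stop
  codon are rejected, so planted ORFs always keep their exact boundaries —
  protein-level divergence still emerges naturally.  Within-group protein
  identities fall in the 40–80% band and exceed between-group identities.
- **Layout.** Genes are laid head-to-tail in template order (plus random
  filler genes, 120–250 aa, inserted until the size bound is reached;
  3–9 genes in total) with stop-codon-tiled intergenic spacers: (TAA)ⁿ
  runs contain no start codon in any frame and place an in-frame stop
  immediately upstream of every gene, which pins each planted ORF to
  exact maximal coordinates — the property the annotation oracle tests
  rely on.  Accessory genes (peptidase, optional antisense unknown gene
  of 153 codons) insert into a named intergenic locus wrapped in their
  own guard tilings ((TTA)ⁿ on the forward strand reads as stops on the
  complement), so stacked insertions cannot extend each other's frames;
  planting followed by deletion restores the original sequence exactly.
- **Reads.** ceil(coverage × L / read_len) reads with uniform circular
  start positions, random strand, and independent per-base substitution
  errors; no indels, chimeras, quality scores or amplification bias.
- **Defaults as study conditions.** The default cohort is 4 genomes per
  template (20 genomes), error-free 20× coverage in 250-nt reads, with
  peptidases planted in the human-associated subgroups (all Alpavirinae,
  alternating VP2–VP4/VP4–VP1 loci; all gut Gokushovirinae at VP2–VP4,
  one with the antisense unknown gene).  The acceptance script runs
  exactly these conditions; larger annotation-level cohorts (50 genomes)
  are generated without reads.

Because divergence is substitution-only and spacers are synthetic stop
tilings, passing tests demonstrate algorithmic correctness under the
stated model — exact ORF boundaries, exact insertion lengths, perfect
assembly at 20× — not performance on real viromes, where indels,
uneven coverage, strain mixtures and overlapping genes will all degrade
the corresponding steps.  The 90%-identity co-assembly fixture spreads
its divergence so no identical run reaches 35 nt; two real strains at 90%
average identity can share longer identical tracts and would then merge
at the stated stringency by construction.

## Numerical and determinism notes

All randomness flows through `numpy.random.Generator` seeded from the
run seed; reruns are byte-identical across every report file.  Heap
tie-breaks, consensus ties, NJ Q-matrix ties and duplicate-role conflicts
all have stated deterministic rules.  Known limitations: the assembler's
candidate discovery is heuristic under sequencing errors (exact when
error-free); the coiled-coil detector is a heuristic proxy; profile–profile
MSA quality degrades for deep divergence (as any progressive aligner);
classification of sequences at the 20% identity floor is sensitive to the
identity denominator (hence the gap-inclusive fallback); and no attempt is
made to resolve strain-level variation within an assembled consensus.
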