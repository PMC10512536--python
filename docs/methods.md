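# Methods

## Reference frame and site catalog

All opsin positions are quoted in bovine rhodopsin numbering: queries
are globally aligned (BLOSUM62, gap open 11 / extend 1) to the 348-aa
bovine rod opsin, and "the residue at 296" means the query residue the
alignment places opposite reference position 296. The catalog —
Lys296, the C110/C187 disulfide, counterion candidates 83/94/113/181,
the D83N/A292S blue-shift states, [D/E]-R-[Y/W] at 134–136, NPxxY at
302–306, the G-alpha tripeptide at 310–312 with known states
NKQ/HMK/HKQ, and FR at 313–314 — ships as an editable YAML file next
to the bundled reference FASTA. A Lys-to-Arg-like conservative swap is
deliberately *not* accepted at 296 (only lysine can form the retinal
Schiff base), but Lys at 135 is reported as a distinct
"variant-conservative" ERY state because it preserves the positive
charge. When several counterion candidate sites carry acidic residues
the annotation reports the raw residue at every candidate site and
makes no single-counterion call; which site acts as the counterion is
a biochemical question the sequence alone cannot settle.

### Alignment-rejection threshold

A query is "not alignable" when fewer than 20% of its global-alignment
columns match the reference. The threshold was calibrated against the
null: random 150-aa sequences align to the reference at 8–14% identity
under this scoring, while even opsin-scaffold sequences mutated at half
of all positions stay above 45%. 20% therefore separates the two
distributions with margin on both sides. Queries shorter than 100 aa
are rejected outright; fragments that short cannot be anchored
reliably.

### Transmembrane-span prediction

Spans are maximal runs of Kyte–Doolittle hydropathy windows averaging
above **1.2** with an **11-residue** window, expanded to the window
footprint, merged when separated by fewer than 3 residues, and kept
when 15–35 aa long. The window and threshold were calibrated on the
reference so that exactly seven spans are recovered, one per helix.
The classic 19-residue window cannot achieve this on rhodopsin: helix
7 carries K296 and the NPxxY motif, whose charged and polar residues
cap its 19-window mean hydropathy at ~1.1 while the first six helices
merge below ~1.0, so no single threshold yields seven spans at window
19. The 11-residue window resolves helix 7 cleanly. This predictor is
a hydropathy heuristic for presence/count of the seven-helix
architecture, not a topology predictor.

## Intron phases and shared boundaries

Intron phase is the number of CDS nucleotides 5' of the boundary,
mod 3. A phase-1/2 boundary is assigned to the residue whose codon it
interrupts, a phase-0 boundary to the residue immediately following —
so in both cases `residue = upstream_nt // 3 + 1`. A boundary shared
between two gene groups means the same (alignment column, phase) pair
occurs in at least one member of each group; matching is exact by
default, with an optional ±N column slop for noisy alignments (phase
must always match exactly). Phase is part of the key because an intron
at the same column but a different phase cannot be homologous.

## Artifact filtering

Coding identity alone cannot distinguish a haplotype duplicate from a
true recent tandem paralog; what can is the non-coding flank, which
diverges quickly between real paralogs but not between haplotypes.
The rule: among same-chromosome pairs with CDS identity above 97%, a
pair is an artifact when flank identity also exceeds 97% **or** an
N-run of ≥ 50 nt (an assembly gap) separates the loci; otherwise the
pair stands as distinct paralogs. Identity is computed as matches over
global-alignment columns excluding terminal gap runs, so length
differences at the ends are not penalized. Flanks default to 2000 nt
per side (configurable; the synthetic studies use 400 nt to keep
simulated genomes small), and the same-chromosome restriction can be
lifted for fragmented assemblies. A second assembly, when available,
arbitrates: if both members of a flagged pair best-match a single
locus there, the pair was collapsed in the independent assembly and
the artifact call is corroborated; if they match two distinct loci,
the verdict is overridden to distinct paralogs. Of each confirmed
artifact pair the first-listed locus is retained.

## Reconciliation and ancestral counts

Gene trees are gated on joint branch support — a clade counts as
supported only with SH-aLRT > 80 **and** UFboot > 95 — and failing
branches are collapsed to polytomies. Polytomies are then resolved in
favor of the species tree (children grouped by the side of the
relevant species split they map to), which prevents weakly supported
conflict from inflating duplication counts. LCA reconciliation labels
each node speciation or duplication, attributes losses to bypassed
sibling branches, and counts the gene lineages crossing every species
node; the event total is the duplication-loss parsimony minimum
(verified against exhaustive enumeration over all rooted binary gene
trees with ≤ 5 leaves). Nothing is charged above the root mapping:
the family simply originates there.

Count-only parsimony complements the gene-tree route. Meristic counts
use Sankoff dynamic programming with cost |i − j| over states
0..max+2; the full optimal state set per node is reported, and where a
single number is needed the minimum of the set is printed with a tie
flag, since a printed box can hide a genuinely ambiguous
reconstruction. Cells with no transcriptomic evidence are excluded
(the leaf constrains nothing), while genomic zeros are true absences
and constrain normally. Continuous mode minimizes
Σ (parent − child)²/branch and solves the resulting linear system
exactly; unit branch lengths are assumed when absent. When both a gene
tree and counts are available, reconciliation counts take precedence:
count-only methods cannot see losses that gene-tree topology reveals.

## The synthetic-data generator

The generator emulates the structure of an anthozoan opsin study. Gene
families evolve by a linear birth-death process (per-lineage
duplication rate λ = 0.25, loss rate μ = 0.1 by default) along a fixed
seven-taxon anthozoan-like species tree (two actiniarian lineages,
Scleractinia, Corallimorpharia, Zoantharia, Ceriantharia,
Octocorallia; ultrametric, root-to-tip depth 4). Simulated mean
family sizes agree with the closed-form expectation e^{(λ−μ)T} within
Monte-Carlo error. Duplicates are retrotranspositions with
probability ρ = 0.3, a heritable intronless state. Every gene carries
a coding sequence derived from the bovine rhodopsin scaffold:
catalog-site states are planted (canonical, or drawn from curated
alternatives), all other sites mutate at 5% per residue, and the
protein is back-translated with uniform synonymous codon choice;
nucleotide-level mutation uses a 2:1 transition bias. Non-retro genes
receive introns (default three, 90 nt, at random or at configured
shared CDS offsets), genes sit on one chromosome per species separated
by 600-nt random spacers, and assembly artifacts are injected as
adjacent mutated locus copies (99% CDS / 99.5% flank identity,
optionally split by a 100-nt N-run, absent from the emitted second
assembly) alongside true tandem paralogs (99% CDS / 70% flank
identity, present in both assemblies). Expression matrices cover six
stage/sex groups × two replicates with a designated peak stage (8× the
20-TPM base), optional 10× sex bias, and multiplicative log-normal
noise (σ = 0.25). A transcript whose planted peak falls in one adult
sex is recorded as sex-biased in the truth log, because that is what
the emitted matrix shows.

What the generator does **not** emulate: codon-level selection,
rate variation among sites and lineages, indels inside coding
sequence, alignment uncertainty, fragmented or incomplete assemblies,
and transcript-abundance compositionality. Passing recovery tests
therefore demonstrates correctness of the analysis logic under clean,
fully specified inputs — not robustness to every pathology of real
assemblies. All emitters are deterministic given the seed; downstream
recovery tests read truth only from the generator's truth log, never
from intermediate pipeline state.

## Numerical and procedural choices

* Internal coordinates are 0-based half-open everywhere; GFF3 emission
  and parsing convert to/from 1-based inclusive at the boundary.
* Translation uses the standard code; the terminal stop is stripped;
  an internal stop marks a pseudogene candidate with a warning rather
  than an error.
* Compound Newick internal labels parse as "SH-aLRT/UFboot" in that
  order; a single numeric label is taken as both values.
* Pairwise DNA identity uses match 2 / mismatch −3 / gap −5,−2; the
  protein anchor uses BLOSUM62 11/1. Both are deterministic for fixed
  inputs.
* Exact peak-stage ties go to the earliest developmental stage and are
  flagged. Sex bias requires ≥ 2-fold between sex means with the
  higher mean ≥ 1 TPM; both thresholds are reported alongside the
  calls. These operationalize qualitative heatmap-level judgments and
  are deliberately configurable.
* Pipeline problem sizes: the bundled study-level suites run ~200
  simulated families for duplication recovery, 200 simulated proteins
  for annotation recovery, 50 genomes for artifact filtering and 100
  for shared-boundary false positives, with 400-nt flanks — sizes at
  which every property is exercised while a full run stays fast on one
  CPU.

## Known limitations

* LCA reconciliation assumes the rooted gene tree is correct after
  support gating; it cannot rescue a wrong rooting.
* The duplication count inferred under loss is a lower bound by
  construction; with losses, true history is not identifiable from
  topology alone.
* The TM-span heuristic under-performs on opsins with long insertions
  inside helices; it is used only for the 7-domain presence check.
* The artifact filter's thresholds (flank window, N-run length) are
  declared defaults, not estimates; genuinely ambiguous pairs (flank
  identity near 97%) will follow whichever side of the threshold they
  fall on and should be inspected manually.
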