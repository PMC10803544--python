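# Methods

This note records the models, conventions and design choices behind
`fcgrseq`, in the order the pipeline applies them.

## Gene models and coordinates

Each FcγR gene is described by an ordered exon list, an ORF-based reference
transcript, a signal-peptide (leader) length, mature-numbered protein
domain intervals, and an Fc-contact residue set. Two coordinate systems
coexist:

* **ORF numbering** — nucleotide/residue 1 at the start codon, leader
  included.
* **Mature numbering** — residue 1 after leader cleavage; leader residues
  are negative and zero is skipped (…, −2, −1, 1, 2, …). With leader
  length *L*: residue *i* → *i − L* if *i > L*, else *i − L − 1*;
  nucleotide *p* → *p − 3L* (values ≤ 0 flagged as leader region).

Within an exon the genomic↔transcript map is affine: `gpos + tpos = K`
(minus strand) or `gpos − tpos = K` (plus strand); FCGR1, FCGR2A and
FCGR2B are minus-strand, FCGR3 plus-strand, and alleles are
reverse-complemented accordingly. The map is validated to be a bijection
on exonic positions.

**The packaged gene fixtures are synthetic.** Reference screens of these
genes publish per-variant coordinate pairs but neither exon boundaries nor
transcript sequences. The packaged models therefore encode exactly what
those pairs over-determine — one affine constant per exon, the leader
lengths (17/35/45/54 residues for FCGR1/2A/2B/3), and the reference codon
at every published variant position — and pad everything else: exon
boundaries are plausible but arbitrary, and filler codons are drawn once
from a stop-free pool with a fixed seed. Leader lengths of 45 and 54
residues are long for true signal peptides; they are the offsets the
published coordinate pairs imply (the "mature" convention evidently counts
a longer leader), and are used without further biological interpretation.

Two bookkeeping quirks inherited from the source numbering are worth
noting. First, one published FcγRIII row pairs nucleotide 184 with ORF
residue 61 although ⌈184/3⌉ = 62; the package computes 62 (mature A8S
agrees either way) and does not special-case the row. Second, the FcγRIIb
cassette exon is conventionally called exon 6 while the exon carrying ORF
position 846 is called exon 7, yet the cassette's insertion point (ORF
904) lies *past* position 846 — no single ordered numbering satisfies
both. The fixture keeps the published labels ("7" for the 781–903 exon)
and treats "6" as the cassette's annotation name, placed between exons 7
and 8.

## Isoform construction

Isoforms are expressed as edits against the principal transcript: cassette
exon inclusion (FcγRIIb exon 6, 57 nt → 19 residues inserted at mature
257), 5′ splice-site extension (FcγRIIa exon 5, 15 nt → 5 residues at
mature 207–211), and single-codon leader insertions/deletions (FcγRIIa
alanine deletion; FcγRIII leader insertion). In-frame edits must preserve
the downstream frame, and isoform transcripts/proteins are materialized
and re-translated rather than patched. FcγRI has a single isoform and is
excluded from quantification. The published FcγRIII isoform list contains
seven accessions said to differ only by the one-residue leader insertion;
since accession-level duplicates of the same structure are not
sequence-identifiable, the fixture models the two distinguishable
structures. Assignments of accession labels to edit combinations are
synthetic placeholders.

## Read simulation

The generator emulates the emulated study's design: full-length amplicons
(no fragmentation, matching RT-PCR amplicon sequencing), one FASTQ per
animal and gene, truth returned separately. Per animal: genotypes per
variant (Hardy–Weinberg from an allele frequency, or exact carrier counts
with heterozygous carriers — published tables report carriers only, so
carrier-count mode reproduces them without sampling noise), heterozygous
variants assigned to a random haplotype with no linkage structure, and a
per-gene isoform mixture (fixed weights or a Dirichlet draw). Reads are
drawn from (isoform × haplotype) templates with diploid fairness (½/½) and
carry independent substitutions plus rare single-base indels.

Defaults: 206 animals, depth 50, substitution rate 2×10⁻³, indel rate
2×10⁻⁴. The emulated study reports no per-animal depth or error profile;
these are round numbers representative of high-accuracy circular-consensus
reads. The error model has no homopolymer bias and constant base quality,
so passing recovery tests demonstrates the pipeline's bookkeeping and
thresholds, not robustness to instrument-specific artifacts, chimeras, or
paralog cross-amplification — none of which the simulator produces.

## Alignment and genotyping

Global (Needleman–Wunsch/Gotoh) affine-gap alignment, scoring match +2,
mismatch −4, gap open −4, gap extend −2, with a gap of length *k* costing
`open + k·extend`. Global alignment is appropriate because amplicons span
the whole transcript, making both ends informative. The kernel is exact
(full dynamic-programming matrix, no banding) and is checked against an
independent three-state memoized aligner on random instances. A
score-per-base validity floor (default 1.0, i.e. half the perfect score)
stands in for a mapping-quality cutoff, which has no meaning with a single
reference.

Genotype thresholds (het window 0.25–0.75, hom ≥ 0.8, ≥ 3 alternate reads,
≥ 10× depth) target CCS-grade accuracy at depth ~50: error-driven false
calls are suppressed because a het call needs ≥ 13 concordant alternate
reads at depth 50, while a true het misses the window with probability
~10⁻⁴. Fractions between 0.75 and 0.8 are deliberately uncalled.
Multi-allelic columns report the top two alleles. Indels are
left-normalized on the transcript (duplications detected and named `dup`);
genomic representations are additionally left-aligned on the plus strand,
which for minus-strand genes corresponds to a transcript *right*-shift —
this reproduces published insertion anchors exactly.

When a gene is simulated with a multi-isoform mixture, splice differences
appear in the pileup as large insertions against the principal transcript
and will be called as such; variant-calling analyses should use
single-isoform mixtures (isoform structure is analyzed by the
quantification stage instead). This mirrors the separation between
genome-based variant calling and isoform-reference quantification in the
emulated workflow.

## Cohort statistics

Carriers are animals with ≥ 1 alternate allele regardless of zygosity.
Retention requires carrier fraction ≥ 2% (boundary: 4/206 removed, 5/206
kept). Percentages print at one decimal, half-to-even, dropping a trailing
`.0`. Published tables are internally inconsistent about
truncation-vs-rounding (e.g. 4.8 for 10/206 = 4.854 but 0.48 for
1/206 = 0.485), so comparisons against printed percentages use a ±0.1
tolerance while carrier *counts* are compared exactly.

## Isoform quantification

Compatibility weights are exponentiated score differences,
`w_ij = exp(s_ij − max_j s_ij)`, zeroed below the validity floor; reads
aligning to no isoform are dropped and counted. This is an alignment-score
proxy rather than a full read-error likelihood, and no read-length bias
correction is applied — full-length amplicons make length bias negligible.
Ambiguous reads are retained with fractional weights. EM runs to a 10⁻⁸
log-likelihood gain (max 1000 iterations, non-convergence flagged);
likelihood monotonicity and superiority over a 0.01-step simplex grid
search are tested properties. The >1% reporting filter is a display mask —
abundances are not renormalized after filtering. The carrier threshold for
the isoform carrier table is not defined by the emulated study; it
defaults to the same 1% as the inclusion filter and is configurable.

## Interface classification

Adjacency is sequence-position distance to the contact set, not 3-D
distance (no structures are computed): distance 0 → `contact`, ≤ window →
`adjacent`, else `distal`; non-extracellular residues are `distal` by
definition. The window defaults to 2, the smallest value reproducing the
published FcγRIIb adjacency narration (I125K at distance 1, N133D at
distance 2). Under that same rule FcγRIIa N128K (distance 1 from contacts
127/129) classifies as `adjacent` although the source narration calls it
outside the interface — the rule is applied uniformly rather than
special-cased. The FcγRIII contact set is not enumerated in the source
methods; the fixture uses {158} (the residue narrated as an Fc-contact
position), configurable. Glycosylation-site loss is a sequence-motif scan
(N-X-S/T, X ≠ P) over the mature protein.

## Determinism, sizes, numerical choices

Every stochastic step flows from one integer seed through
`numpy.random.default_rng`; identical config + seed gives byte-identical
outputs (reports carry a config digest and a report digest). Ties in
carrier-sorted tables are broken by first observation; EM starts uniform;
alignment traceback prefers diagonal, then read-insertion, then deletion
states, with normalization making indel placement canonical regardless.
Test problem sizes are chosen desk-scale: the end-to-end acceptance cohort
runs 206 animals × depth 50 on the FcγRI amplicon; recovery and EM
property tests use 4–12 animals at depths 20–100, sizes at which the
statistical assertions (e.g. mean absolute abundance error < 0.03 at depth
100) are already stable.

## Known limitations

No read-level phasing or allotype reconstruction; no paralog
disambiguation between FcγRIIa/FcγRIIb beyond separate amplicon
references; no novel-isoform discovery (impossible with
reference-isoform quantification); no genome-scale annotation or real
reference-genome ingestion; interface classes are sequence proximity, not
structural contact analysis.
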