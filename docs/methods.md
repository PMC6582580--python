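# Methods

This note documents the models and procedures implemented in `gulotrace`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where the design was genuinely open.

## Translated homology search (`tsearch`)

The search emulates a protein-vs-genome (tblastn-style) run. Each scaffold
is translated in all six frames under the standard genetic code (codons
containing any non-ACGT letter translate to X, which never matches a motif
position; a trailing partial codon is dropped). Word seeds of length 3
(discovery) or 2 (annotation-guide mode) scoring at least a neighbourhood
threshold under BLOSUM62 (T = 11 for w=3, T = 8 for w=2; standard
neighbourhood values, configurable) are extended ungapped along their
diagonal with x-drop termination (x_drop = 20). Seeds whose ungapped
extension reaches a trigger score (default 18) get a gapped Smith–Waterman
extension (affine gaps, a gap of length k costs 11 + k) in a window of one
query length around the hit; the window dominates any realistic local
alignment, and on fixtures ≤ 300 nt the top raw score equals an independent
full six-frame Smith–Waterman (tested).

Raw scores convert to bit scores and E-values with fixed Karlin–Altschul
parameters for gapped BLOSUM62 (λ = 0.267, K = 0.041):
`E = K·m·n·exp(−λS)` with m the query length in residues and n the searched
target size in residues. Because all six frames of both strands are
scanned, n = 2L/3 for total scaffold length L; with n = L/3 the empirical
null (random 20-kb genomes vs the default query) yields hits at E ≤ 0.05 in
~12% of genomes, while 2L/3 restores the intended cutoff semantics
(≤ 5% of random genomes non-empty, tested on fixed seeds). Effective-length
(edge) corrections and composition-based statistics are deliberately
omitted; exact parity with NCBI BLAST E-values is a non-goal — only the
behaviour of the 0.05 cutoff matters downstream.

Hits are reported in forward-strand nucleotide coordinates with the frame
sign carrying orientation. Regions of ± 5000 nt around each hit (clipped to
the scaffold) are extracted and coordinate-overlapping regions merged.

## Region growing (`growmerge`)

Regions from the same assembly overlap exactly, so overlap detection is
exact string matching: the longest suffix/prefix agreement of length
≥ 2500 nt, or full containment. Merging is greedy, longest overlap first,
with lexicographic region-id tie-breaks, iterated to a fixpoint — the
result is invariant to input order, merged length is |a|+|b|−overlap, and
hit provenance is unioned. Reverse-complement overlaps are not merged by
default (`merge_revcomp=False`): regions carry forward-strand sequence and
orientation is resolved during annotation; merging across orientations
would make region coordinates ambiguous.

## Spliced CDS reconstruction (`genemodel`)

A human annotator was the reference implementation for this stage; the
package replaces them with a similarity-guided exon-chaining dynamic
program run on both strands of each grown region.

**Candidates.** Ungapped diagonal segments between the region's three
forward-frame translations and the query (word size 2, threshold 8,
segment score ≥ 15) seed exon candidates. Because x-drop extension
overruns *into* introns, splice sites are searched asymmetrically around
segment ends: up to 130 nt inward and 40 nt outward, keeping the 14
nearest AG (acceptor, upstream of the exon) and GT (donor, downstream)
dinucleotides per side, plus the terminal positions implied by the query
ends. Every start phase (0/1/2) is tried; a candidate whose in-phase
translation contains a stop codon is discarded. Candidate scores are
ungapped BLOSUM62 fits against the query at the diagonal-implied offset
(± 3 residues). An ATG immediately followed by a GT donor, at intron
distance upstream of a candidate covering the query start, becomes a
lone-ATG first-exon candidate — GULO genes are known to begin with a
first coding exon holding only the start codon.

**Chaining.** The DP maximises Σ exon scores + Σ junction scores over
chains that are colinear in region and query coordinates, start and end at
phase 0, and whose junctions are ≥ 20 nt (≤ 20 kb) GT…AG introns with
exact phase complementarity. Each junction contributes −5 (intron
penalty); when the intron splits a codon, the reconstituted codon (tail of
the upstream exon + head of the downstream one) is translated and scored
against the query residue it should encode, and every query residue
skipped or double-claimed across a junction costs 12 — more than any
substitution score, so a shifted splice pair can never profit from
re-encoding a residue. Chains scoring below 40 are rejected. Ties break
toward fewer exons, then leftmost start; a +2 start-codon bonus makes a
genuine lone-ATG first exon (M match +5 against intron penalty −5,
otherwise score-neutral) preferred over dropping it. The DP optimum equals
brute-force enumeration over candidate subsets on small inputs (tested);
`exon_min_score`, `chain_min_score` and the junction penalties are package
inventions with no counterpart in the reference procedure, and are
configurable.

**Classification and validity.** The reconstructed protein is scanned for
H-W-x-K (x any standard residue; the unknown X never matches): HWAK marks
a GULO candidate, any other variant a related VAO-family FAD-domain
enzyme, and a motif-less reconstruction is rejected outright — no
annotation is retained, mirroring the screening rule for raw genomes. The
motif test is applied to the chained protein rather than per candidate
exon so that a codon-splitting intron inside the motif cannot mask it. A
model is acceptable iff it has no internal stop, carries a motif, and a
local alignment to the query spans ≥ 50% of it (`coverage_min`, a package
choice — the reference procedure reports coverage but fixes no
threshold). A missing start codon does not disqualify a model.

## Presence calls and loss mapping (`orthocall`)

Contamination screening aligns a reconstructed CDS (translated) against a
labelled panel; the verdict is positive iff the best bacterial reference
outscores the best animal reference by ≥ 10% in bits.

Species-call precedence: (1) an acceptable, non-contaminated HWAK model →
PRESENT; (2) motif-bearing models exist but all look bacterial →
CONTAMINATION; (3) hits scattered over ≥ 3 scaffolds without an acceptable
single-scaffold model → INCONCLUSIVE; (4) no hits, or union query coverage
< 0.25 ("residual" homology, package threshold) → ABSENT; (5) otherwise
INCONCLUSIVE. When evidence is scattered, rule (1) additionally requires
the model to be near-complete (coverage ≥ 0.9): a fragment carrying half
the gene is not an ortholog "with all expected features", and without this
qualifier fragmented assemblies could be called present. The numeric
choices for "scattered" (3 scaffolds) and "residual" (0.25) are
operationalisations of qualitative rules and are configurable.

Lineage calls: any PRESENT member → PRESENT; else ABSENT only with ≥ 3
ABSENT member species; else INCONCLUSIVE. CONTAMINATION counts as neither.

Dollo loss mapping fixes the root state to present and finds the minimum
set of loss edges such that every absent tip is below exactly one loss and
no present tip below any; unknown tips are unconstrained. The greedy
placement — one loss on each maximal present-free clade containing an
absent tip — is provably minimal (such clades are disjoint and each needs
a loss) and is verified against exhaustive enumeration in tests. Losses
are reported rootward-most ("deepest") by construction. Gene regain is
outside the model.

## Codon-aware alignment and tree utilities (`codonphylo`)

CDS sets are aligned at the protein level and the nucleotide alignment
obtained by threading codons through the protein rows, so gaps come in
triplets and degapping returns each input CDS exactly. The aligner is
centre-star progressive: all sequences are pairwise-globally aligned
(BLOSUM62, 11/1 gaps, free end gaps) to the most central sequence and
merged under "once a gap, always a gap". This is adequate for the
near-homologous CDS sets the pipeline produces; it is not a
guide-tree/profile MSA and will degrade on deeply diverged inputs.

Column support is a pairwise-consistency score scaled to 0–9:
`round(9 × fraction of record pairs whose residues in the column are
identical or score > 0 under BLOSUM62)`, gapped pairs counting as
inconsistent; columns with support above two are kept. The formula is a
package stand-in for an external aligner's unpublished support value —
only the "above two" cutoff is inherited.

Trees come from neighbour joining on protein p-distances over the filtered
columns (pairwise gap deletion; ids sorted so ties resolve by label
order) — a deliberate desk-scale stand-in for Bayesian inference, which is
out of scope. For ortholog confirmation the tree is rooted at the midpoint
of the fungal-outgroup stem (viewed from an animal reference) and a query
is confirmed GULO-like iff it falls inside the smallest clade containing
the animal references; queries branching outside — external to the fungi —
are flagged.

MCMC utilities are generic arithmetic: burn-in count =
⌊generations / sample_every × burnin_frac⌋ (5,000,000 / 100 × 0.25 =
12,500), and the Gelman–Rubin potential scale reduction factor
`psrf = sqrt((n−1)/n + B/(nW))` with B/W the between/within-chain
variances, defined as 1.0 when both vanish.

## Ascorbate quantitation (`ascorbquant`)

Chromatograms (absorbance at 265 nm vs seconds) are baseline-corrected
with a rolling median (90 s window, wider than twice the peak width, so a
peak never dominates its window; a rolling minimum would sit ~2.5 noise
SDs low and lift noise spikes above the prominence threshold). Peaks are
local maxima with prominence ≥ 0.5 a.u.; each is integrated by the
trapezoidal rule over a fixed ± 3.5 σ window, with σ estimated from the
noise-robust half-height width — this captures > 99.9% of a Gaussian
while keeping bounds independent of the noise floor. Calibration is
ordinary least squares of area on concentration for 25/50/100 μM
standards; quantitation inverts the line for the largest peak in the
retention-time window and clips negative results to zero. Peak identity
is confirmed by the ascorbate-oxidase test: ≥ 90% area reduction after
enzymatic oxidation (the reference behaviour is complete "extinction";
90% is the package's operational threshold). Unit conversion uses an
ascorbate molar mass of 176.12 g/mol; group comparisons use an unpaired
two-tailed pooled-variance t-test (Welch behind a flag), with no
multiple-testing correction, matching per-comparison reporting.

## Synthetic data (`synthgen`)

Planted genes encode a 180-residue protein containing exactly one HWxK
site, back-translated with uniformly random synonymous codons and split
into 1–5 exons at uniformly random points (codon-interior allowed, each
exon ≥ 33 nt, no exon over ~45% of the CDS — multi-exon genes have modest
exons, and a dominant exon would make a single assembly fragment
indistinguishable from a full gene). Introns are GT…AG with uniform
lengths (default 50–2000 nt; real intron length distributions are unknown
for the taxa of interest and the value is configurable). Background is iid
nucleotide sequence at a given GC (default 0.45); there is no repeat,
paralog or sequencing-error model, so passing recovery tests demonstrates
correctness of the reconstruction machinery, not robustness to repetitive
or error-rich real assemblies. Fragmented variants cut the gene scaffold
inside introns — preferentially those flanking the motif exon — across
≥ 3 scaffolds; contaminated variants append an intron-less ≥ 98%-identity
copy of a bacterial panel CDS (the panel's "bacterial" decoys are ~35%
diverged HWGK copies of the query, so they are findable by the search but
separable by the screen). Chromatograms are Gaussian peaks (σ = 4 s) on a
low-order polynomial baseline with iid Gaussian noise; planted area =
response × concentration.

All generators are deterministic given a seed.

## Problem sizes used by the test suite

The standard corpus is 50 intact genomes (12 kb background, exon counts
1–5 cycling, both strands, every third plant with a lone-ATG first exon),
plus 10 fragmented, 10 contaminated and 10 homology-free genomes; the
empirical-null check uses 20 random 20-kb genomes; quantitation error is
measured over 200 chromatograms with concentrations uniform in 5–100 μM
at 1% noise. On these conditions the suite observes 100% exact CDS
recovery, a clean four-mode confusion matrix and < 1% median quantitation
error; the asserted thresholds (≥ 95%, < 3%) leave room for seed-to-seed
variation.

## Known limitations

- Exact NCBI BLAST statistics (edge corrections, SEG masking,
  composition-based adjustment) are not reproduced.
- The exon chainer assumes GT-AG introns only; GC-AG and AT-AC splice
  sites are rejected by design.
- The centre-star aligner and NJ trees are stand-ins adequate for
  near-homologous sets, not replacements for MSA + Bayesian inference on
  deep phylogenies.
- The synthetic genomes contain no repeats or paralogs, which in real
  assemblies are the main source of spurious hits and chimeric models.
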