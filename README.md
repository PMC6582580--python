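# gulotrace

Tracing *L-gulonolactone oxidase* (*GULO*) genes — the last enzyme of animal
vitamin C biosynthesis — through raw genome assemblies, and quantifying
L-ascorbate from HPLC chromatograms.

Most invertebrate genomes are deposited without gene annotations, so asking
"does this species still have a *GULO* gene?" means running a homology hunt
by hand: a translated search of a reference GULO protein against the
scaffolds, stitching the hit regions together, reconstructing a spliced CDS
under the canonical GT-AG intron rule, and checking the diagnostic
His-Trp-x-Lys (HWxK) motif — in animals, true GULO orthologs carry **HWAK**,
while related FAD-domain enzymes of the VAO family carry other variants such
as HWGK. `gulotrace` automates that hunt end to end and aggregates the
evidence into per-species and per-lineage presence/absence calls, then maps
independent gene-loss events onto a species cladogram under Dollo parsimony
(presence is ancestral; a gene may be lost repeatedly but never regained).

Because real assemblies are gigabytes of third-party data, the package ships
a first-class synthetic-data module: genomes with planted multi-exon genes
(exact exon coordinates, strand, motif variant and CDS recorded as ground
truth), fragmented and bacterially contaminated variants of them, and
Gaussian-peak chromatograms with a linear area–concentration response.
Every pipeline stage is tested against planted truth or an independent
oracle (full Smith–Waterman, exhaustive chain/loss enumeration).

## What is inside

| module | role |
|---|---|
| `gulotrace.core_io` | FASTA / Newick / GFF3 I/O, translation, reverse complement |
| `gulotrace.synthgen` | synthetic genomes, contaminants, chromatograms with planted truth |
| `gulotrace.tsearch` | six-frame translated seeded search (BLOSUM62, x-drop, Karlin–Altschul E-values), flank extraction |
| `gulotrace.growmerge` | merging of regions sharing long exact overlaps (default ≥ 2500 nt) |
| `gulotrace.genemodel` | exon-chaining DP under the GT-AG rule, HWxK motif scan and classification |
| `gulotrace.orthocall` | species/lineage presence calls, contamination screen, Dollo loss mapping |
| `gulotrace.codonphylo` | codon-aware alignment, column support filter, NJ tree, outgroup placement, PSRF/burn-in utilities |
| `gulotrace.ascorbquant` | peak detection/integration, linear calibration, ascorbate-oxidase confirmation, t-tests |

## Worked example

```python
from gulotrace.synthgen import PlantSpec, default_query, synth_genome
from gulotrace.pipeline import analyze_genome

query = default_query()                      # synthetic GULO-like protein, HWAK motif
spec = PlantSpec(protein=query, exon_count=3, intron_length_range=(50, 2000))
genome = synth_genome(spec, background_length=12000, gc=0.45, seed=1)

result = analyze_genome(query, genome.scaffolds, species="demo")
model = result.models[0]
print(result.call.status)                              # PRESENT
print(model.motif, model.n_introns, model.coverage_frac)  # HWAK 2 1.0
print(model.cds.residues == genome.genes[0].cds)       # True
```

The call is `PRESENT` because an acceptable gene model was reconstructed:
its protein carries the HWAK motif, has no internal stop codons, and covers
the full query (`coverage_frac` 1.0). The reconstructed CDS is base-for-base
identical to the planted one, introns and all.

Loss mapping on a lineage cladogram:

```python
from gulotrace.orthocall import (PROTOSTOMIA_CLADOGRAM, PROTOSTOMIA_STATES,
                                 dollo_losses)
lm = dollo_losses(PROTOSTOMIA_CLADOGRAM, PROTOSTOMIA_STATES)
print(lm.n_losses)        # 4  (Pancrustacea, Nematoda, Platyhelminthes, Bivalvia)
```

A command-line interface mirrors the library:

```bash
gulotrace scan --query q.faa --genome g.fna --evalue 0.05 --flank 5000
gulotrace grow --regions regions.fna --min-overlap 2500
gulotrace call --query q.faa --genome g.fna --species "I. scapularis"
gulotrace map-losses --tree tree.nwk --calls calls.tsv
gulotrace quantify --standards standards.tsv --sample s1.tsv
```

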