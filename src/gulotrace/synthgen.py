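"""Synthetic genomes and chromatograms with planted ground truth.

Every downstream stage of the pipeline is exercised against data produced
here: genome scaffolds carrying planted multi-exon genes with canonical
GT-AG introns (intact, fragmented across scaffolds, or accompanied by a
bacterial-contaminant scaffold), homology-free "absent" genomes, and HPLC
chromatograms built from Gaussian peaks with a linear area-concentration
response.  All generators are deterministic given a seed and record full
truth annotations (exon coordinates, CDS, motif variant, peak areas) so
tests can assert exact recovery.

Background sequence is iid with a given GC content; there is no repeat or
sequencing-error model.  Planted proteins contain exactly one H-W-x-K site
(or none, for null plants).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from gulotrace.core_io import (
    NucSeq, ProtSeq, gene_to_gff3, revcomp, translate_cds, write_fasta, write_gff3,
)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
# amino acid -> sorted list of codons, standard code
CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    CODONS_FOR_AA.setdefault(aa, []).append(codon)
for aa in CODONS_FOR_AA:
    CODONS_FOR_AA[aa].sort()

MOTIF_RE = re.compile(r"HW[^X\*]K")


@dataclass
class PlantSpec:
    """Recipe for one planted gene.

    ``protein`` must contain exactly one H-W-x-K site for positive plants
    (motif_variant HWAK or HWGK) and none for null plants.  ``exon_count``
    coding exons are joined by GT..AG introns with lengths drawn uniformly
    from ``intron_length_range``; when ``lone_atg_first`` is set an extra
    first exon encoding only the ATG codon is prepended, mimicking GULO
    gene structure where the first coding exon holds just the start codon.
    """

    protein: ProtSeq
    exon_count: int = 3
    intron_length_range: tuple[int, int] = (50, 2000)
    strand: str = "+"
    motif_variant: str = "HWAK"  # HWAK | HWGK | none
    lone_atg_first: bool = False

    def __post_init__(self):
        if self.exon_count < 1:
            raise ValueError("exon_count must be >= 1")
        lo, hi = self.intron_length_range
        if lo < 20 or hi < lo:
            raise ValueError("intron lengths must be >= 20 nt and min <= max")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if "*" in self.protein.residues:
            raise ValueError("planted protein must not contain stop codons")
        hits = MOTIF_RE.findall(self.protein.residues)
        if self.motif_variant == "none":
            if hits:
                raise ValueError("null plant protein must not contain an HWxK site")
        else:
            if len(hits) != 1 or hits[0][2] != self.motif_variant[2]:
                raise ValueError(
                    f"protein must contain exactly one {self.motif_variant} site, found {hits}"
                )


@dataclass
class TruthGene:
    """Ground-truth annotation of one planted gene."""

    gene_id: str
    scaffold_id: str
    exons: list[tuple[int, int]]  # forward-strand 0-based half-open, transcription order
    strand: str
    cds: str
    protein: str
    motif_variant: str
    has_start_codon: bool
    exon_scaffolds: list[str] = field(default_factory=list)  # parallel to exons


@dataclass
class GenomeTruth:
    scaffolds: list[NucSeq]
    genes: list[TruthGene]
    mode: str  # intact | fragmented | contaminated | absent
    contaminant_scaffold: str | None = None

    def fasta(self) -> str:
        return write_fasta(self.scaffolds)

    def gff3(self) -> str:
        feats = []
        for g in self.genes:
            if len(set(g.exon_scaffolds or [g.scaffold_id])) == 1:
                feats.extend(gene_to_gff3(g.scaffold_id, g.gene_id, g.exons, g.strand))
        return write_gff3(feats)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)]) if n else ""


def random_protein(length: int, seed: int, motif: str | None = "HWAK",
                   motif_pos: int | None = None) -> ProtSeq:
    """A random protein with exactly one H-W-x-K site (or none if motif=None).

    Starts with M so that back-translated plants begin with ATG.
    """
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVY"  # no W: tryptophans placed only in the motif
    aa = ["M"] + list(np.array(list(alphabet))[rng.integers(0, len(alphabet),
                                                            size=length - 1)])
    if motif is not None:
        if len(motif) != 4 or motif[0] != "H" or motif[1] != "W" or motif[3] != "K":
            raise ValueError("motif must be of the form HWxK")
        if motif_pos is None:
            motif_pos = length // 2
        aa[motif_pos : motif_pos + 4] = list(motif)
    return ProtSeq(f"synthprot_{seed}", "".join(aa))


def backtranslate(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein as DNA, choosing uniformly among synonymous codons."""
    return "".join(CODONS_FOR_AA[aa][rng.integers(0, len(CODONS_FOR_AA[aa]))]
                   for aa in protein)


def _make_intron(rng: np.random.Generator, lo: int, hi: int, gc: float) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "GT" + _random_dna(rng, n - 4, gc) + "AG"


def synth_genome(spec: PlantSpec, background_length: int = 10000, gc: float = 0.45,
                 seed: int = 0, scaffold_id: str | None = None) -> GenomeTruth:
    """Plant one gene in an iid background scaffold; returns truth annotations.

    The CDS is split into ``exon_count`` pieces at codon-boundary or
    codon-interior points (recorded in truth), joined by GT..AG introns.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cds = backtranslate(spec.protein.residues, rng)
    lo, hi = spec.intron_length_range

    # exon cut points within the CDS (any nucleotide position; >=33 nt per exon)
    min_exon = 33
    pieces = []
    n_cuts = spec.exon_count - 1
    if spec.lone_atg_first:
        pieces_start = 3
    else:
        pieces_start = 0
    body = cds[pieces_start:]
    if n_cuts > 0:
        if len(body) < (n_cuts + 1) * min_exon:
            raise ValueError("protein too short to split into requested exons")
        # no exon may dominate the CDS (multi-exon genes have modest exons);
        # keeps any single assembly fragment well below full gene coverage
        max_frac = 0.45 if n_cuts >= 2 else 0.65
        max_piece = max(int(max_frac * len(body)), min_exon + 1)
        while True:
            cuts = sorted(rng.integers(min_exon, len(body) - min_exon, size=n_cuts))
            bounds_try = [0, *cuts, len(body)]
            sizes = [bounds_try[i + 1] - bounds_try[i]
                     for i in range(len(bounds_try) - 1)]
            if min(sizes) >= min_exon and max(sizes) <= max_piece:
                break
        bounds = [0, *cuts, len(body)]
        pieces = [body[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    else:
        pieces = [body]
    if spec.lone_atg_first:
        pieces = [cds[:3], *pieces]

    introns = [_make_intron(rng, lo, hi, gc) for _ in range(len(pieces) - 1)]
    gene_parts = []
    for i, p in enumerate(pieces):
        gene_parts.append(p)
        if i < len(introns):
            gene_parts.append(introns[i])
    gene_seq = "".join(gene_parts)

    if background_length < len(gene_seq):
        raise ValueError(
            f"background_length {background_length} < planted gene length {len(gene_seq)}"
        )
    left_len = int(rng.integers(0, background_length - len(gene_seq) + 1))
    right_len = background_length - len(gene_seq) - left_len
    left = _random_dna(rng, left_len, gc)
    right = _random_dna(rng, right_len, gc)

    # exon coordinates relative to gene start (transcription order)
    exons_rel = []
    off = 0
    for i, p in enumerate(pieces):
        exons_rel.append((off, off + len(p)))
        off += len(p)
        if i < len(introns):
            off += len(introns[i])

    sid = scaffold_id or f"scaffold_{seed}"
    if spec.strand == "+":
        scaffold = left + gene_seq + right
        exons = [(left_len + s, left_len + e) for s, e in exons_rel]
    else:
        scaffold = left + revcomp(gene_seq) + right
        L = len(gene_seq)
        # transcription order preserved; forward-strand coordinates
        exons = [(left_len + L - e, left_len + L - s) for s, e in exons_rel]

    gene = TruthGene(
        gene_id=f"gene_{seed}",
        scaffold_id=sid,
        exons=exons,
        strand=spec.strand,
        cds=cds,
        protein=spec.protein.residues,
        motif_variant=spec.motif_variant,
        has_start_codon=cds.startswith("ATG"),
        exon_scaffolds=[sid] * len(exons),
    )
    return GenomeTruth(scaffolds=[NucSeq(sid, scaffold)], genes=[gene], mode="intact")


def synth_absent_genome(background_length: int = 10000, gc: float = 0.45,
                        seed: int = 0, n_scaffolds: int = 2) -> GenomeTruth:
    """A genome with no planted gene at all (homology-free background)."""
    rng = np.random.default_rng(seed)
    per = background_length // n_scaffolds
    scaffolds = [NucSeq(f"scaffold_{seed}_{i}", _random_dna(rng, per, gc))
                 for i in range(n_scaffolds)]
    return GenomeTruth(scaffolds=scaffolds, genes=[], mode="absent")


def fragment_assembly(gt: GenomeTruth, pieces: int = 3, seed: int = 0) -> GenomeTruth:
    """Scatter the planted gene's exons over >= 3 scaffolds.

    The gene-bearing scaffold is cut inside introns so that no resulting
    scaffold carries a complete motif-bearing CDS; this emulates a highly
    fragmented assembly where translated-search hits land on many scaffolds
    and gene presence cannot be confidently inferred.
    """
    if gt.mode != "intact":
        raise ValueError("can only fragment an intact genome")
    if pieces < 3:
        raise ValueError("pieces must be >= 3 for a scattered assembly")
    gene = gt.genes[0]
    if pieces > len(gene.exons):
        raise ValueError(
            f"cannot spread {len(gene.exons)} exons over {pieces} scaffolds"
        )
    rng = np.random.default_rng(seed)
    scaffold = next(s for s in gt.scaffolds if s.id == gene.scaffold_id)
    others = [s for s in gt.scaffolds if s.id != gene.scaffold_id]

    ordered = sorted(gene.exons)  # genomic order on the forward strand
    # choose pieces-1 introns (gaps between consecutive exons) to cut at
    # midpoint, preferring the introns flanking the motif-bearing exon so no
    # fragment retains the motif plus a large share of the CDS
    n_gaps = len(ordered) - 1
    motif_gaps: list[int] = []
    m = MOTIF_RE.search(gene.protein)
    if m is not None:
        lo_nt, hi_nt = 3 * m.start(), 3 * m.end()
        cum = 0
        tx_exons = gene.exons  # transcription order
        for k, (s, e) in enumerate(tx_exons):
            if cum < hi_nt and lo_nt < cum + (e - s):
                gi = ordered.index((s, e))
                for g in (gi - 1, gi):
                    if 0 <= g < n_gaps:
                        motif_gaps.append(g)
            cum += e - s
    motif_gaps = sorted(set(motif_gaps))
    other_gaps = [g for g in range(n_gaps) if g not in motif_gaps]
    take = pieces - 1
    gap_idx = motif_gaps[:take]
    if len(gap_idx) < take:
        gap_idx += [int(g) for g in rng.choice(other_gaps,
                                               size=take - len(gap_idx),
                                               replace=False)]
    gap_idx = sorted(gap_idx)
    cut_points = [ (ordered[i][1] + ordered[i + 1][0]) // 2 for i in gap_idx ]
    bounds = [0, *cut_points, len(scaffold)]
    new_scaffolds = []
    new_exons = []
    new_exon_scaffolds = []
    for i in range(len(bounds) - 1):
        s0, s1 = bounds[i], bounds[i + 1]
        sid = f"{scaffold.id}_frag{i}"
        new_scaffolds.append(NucSeq(sid, scaffold.residues[s0:s1]))
    for (es, ee) in gene.exons:
        piece = max(i for i in range(len(bounds) - 1) if bounds[i] <= es)
        new_exons.append((es - bounds[piece], ee - bounds[piece]))
        new_exon_scaffolds.append(new_scaffolds[piece].id)
    frag_gene = TruthGene(
        gene_id=gene.gene_id, scaffold_id=new_exon_scaffolds[0],
        exons=new_exons, strand=gene.strand, cds=gene.cds,
        protein=gene.protein, motif_variant=gene.motif_variant,
        has_start_codon=gene.has_start_codon, exon_scaffolds=new_exon_scaffolds,
    )
    return GenomeTruth(scaffolds=new_scaffolds + others, genes=[frag_gene],
                       mode="fragmented")


def contaminate(gt: GenomeTruth, bacterial_ref: NucSeq, seed: int = 0,
                identity: float = 0.99) -> GenomeTruth:
    """Append a scaffold carrying a near-copy (>=98% identity) of a bacterial CDS.

    The copy is intron-less, as expected of a prokaryotic gene; original
    scaffolds are left untouched.
    """
    if identity < 0.98:
        raise ValueError("contaminant identity must be >= 0.98")
    rng = np.random.default_rng(seed)
    seq = list(bacterial_ref.residues)
    n_mut = int(round((1 - identity) * len(seq)))
    # substitute codon third positions only (mostly synonymous), sparing the
    # HWxK motif codons so the contaminant stays classifiable
    prot = translate_cds(bacterial_ref.residues)
    m = MOTIF_RE.search(prot)
    excluded = range(3 * m.start(), 3 * m.end()) if m else range(0)
    third = np.array([i for i in range(2, len(seq) - 2, 3) if i not in excluded])
    sites = rng.choice(third, size=min(n_mut, len(third)), replace=False)
    for i in sites:
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    sid = f"contam_{bacterial_ref.id}"
    contam = NucSeq(sid, "".join(seq))
    return GenomeTruth(scaffolds=[*gt.scaffolds, contam], genes=list(gt.genes),
                       mode="contaminated", contaminant_scaffold=sid)


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

@dataclass
class ChromTruth:
    """A synthetic HPLC trace plus the planted truth behind it."""

    times: np.ndarray            # seconds, strictly increasing
    signal: np.ndarray           # absorbance, arbitrary units
    peaks: list[tuple[float, float]]   # (retention time s, concentration uM)
    response: float              # planted area per uM
    noise_sd: float
    baseline: tuple[float, ...]  # polynomial coefficients, ascending order

    def tsv(self) -> str:
        lines = ["time_s\tsignal"]
        lines += [f"{t:.3f}\t{s:.6f}" for t, s in zip(self.times, self.signal)]
        return "\n".join(lines) + "\n"


PEAK_WIDTH_SD = 4.0  # s; fixed Gaussian peak width of the synthetic traces


def synth_chromatogram(peaks: list[tuple[float, float]], response: float = 2.0,
                       noise_sd: float = 0.0, seed: int = 0,
                       t_max: float = 600.0, dt: float = 0.5,
                       baseline: tuple[float, ...] = (0.5, 5e-4),
                       width_sd: float = PEAK_WIDTH_SD) -> ChromTruth:
    """Baseline + Gaussian peaks with area = response x concentration + noise.

    Peak areas scale linearly with planted concentration (uM), emulating a
    fixed-wavelength absorbance detector in its linear range; the baseline
    is a low-order polynomial drift and the noise is iid Gaussian.
    """
    if response <= 0:
        raise ValueError("response must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    signal = np.polynomial.polynomial.polyval(times, np.asarray(baseline))
    for rt, conc in peaks:
        if conc < 0:
            raise ValueError(f"negative concentration {conc} at rt {rt}")
        if not (times[0] <= rt <= times[-1]):
            raise ValueError(f"retention time {rt} outside the time grid")
        area = response * conc
        amp = area / (width_sd * np.sqrt(2 * np.pi))
        signal = signal + amp * np.exp(-0.5 * ((times - rt) / width_sd) ** 2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=times.shape)
    return ChromTruth(times=times, signal=signal, peaks=list(peaks),
                      response=response, noise_sd=noise_sd, baseline=baseline)


# ---------------------------------------------------------------------------
# Reference panels (synthetic stand-ins for GenBank reference sequences)
# ---------------------------------------------------------------------------

def default_query(seed: int = 20190618, length: int = 180) -> ProtSeq:
    """The pipeline's synthetic GULO-like query protein (HWAK motif)."""
    p = random_protein(length, seed=seed, motif="HWAK")
    return ProtSeq("synthetic_GULO_query", p.residues)


def make_reference_panel(seed: int = 7) -> dict[str, list[NucSeq]]:
    """Synthetic labelled CDS panel: animal GULO-like references plus
    bacterial HWGK-bearing decoys, for contamination screening tests."""
    rng = np.random.default_rng(seed)
    query = default_query()
    animals = []
    for i in range(2):
        prot = list(query.residues)
        n_mut = int(0.08 * len(prot))
        sites = rng.choice(len(prot), size=n_mut, replace=False)
        alphabet = "ACDEFGHIKLMNPQRSTVY"
        for s in sites:
            if prot[s] in "HWK":  # keep the motif intact
                continue
            prot[s] = alphabet[rng.integers(0, len(alphabet))]
        animals.append(NucSeq(f"animal_ref_{i}",
                              backtranslate("".join(prot), rng)))
    bacteria = []
    for i in range(2):
        # bacterial decoys are distant GULO-like homologues (findable by a
        # translated search) carrying the HWGK motif instead of HWAK
        prot = list(query.residues)
        alphabet = "ACDEFGHIKLMNPQRSTVY"
        sites = rng.choice(len(prot), size=int(0.35 * len(prot)), replace=False)
        for s in sites:
            if prot[s] in "HWK":
                continue
            prot[s] = alphabet[rng.integers(0, len(alphabet))]
        m = MOTIF_RE.search("".join(prot))
        prot[m.start() + 2] = "G"
        bacteria.append(NucSeq(f"bacterial_decoy_{i}",
                               backtranslate("".join(prot), rng)))
    return {"animal": animals, "bacterial": bacteria}
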