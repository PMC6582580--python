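"""Sequence containers, FASTA/Newick/GFF3 I/O and basic sequence arithmetic.

Internal coordinates are 0-based half-open everywhere; GFF3 output converts
to 1-based inclusive.  Only the standard genetic code is supported (the
taxa of interest carry nuclear GULO genes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
from Bio.Data import CodonTable as _CodonTable

NUC_ALPHABET = set("ACGTN")
PROT_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "X*")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STD = _CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STD.forward_table)
for _stop in _STD.stop_codons:
    CODON_TO_AA[_stop] = "*"


class ParseError(ValueError):
    """Raised when a sequence or tree file cannot be parsed."""


@dataclass(frozen=True)
class NucSeq:
    """A nucleotide sequence over {A,C,G,T,N} with a non-empty identifier."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c.upper() in bad)
            raise ParseError(
                f"record {self.id!r}: invalid nucleotide {self.residues[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class ProtSeq:
    """An amino-acid sequence over the 20 standard letters plus X and *."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - PROT_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c.upper() in bad)
            raise ParseError(
                f"record {self.id!r}: invalid amino acid {self.residues[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self):
        return len(self.residues)


def parse_fasta(text: str, kind: str = "nuc") -> list:
    """Parse FASTA text into NucSeq (kind='nuc') or ProtSeq (kind='prot') records.

    Sequence lines may be wrapped arbitrarily and are uppercased.  Empty
    input yields an empty list.  Characters outside the alphabet raise a
    :class:`ParseError` naming the record and position.
    """
    cls = {"nuc": NucSeq, "prot": ProtSeq}[kind]
    records = []
    header = None
    chunks: list[str] = []
    for line in io.StringIO(text):
        line = line.rstrip("\n").rstrip("\r")
        if line.startswith(">"):
            if header is not None:
                records.append(cls(header, "".join(chunks)))
            header = line[1:].split()[0] if line[1:].split() else ""
            chunks = []
        elif line.strip():
            if header is None:
                raise ParseError("sequence data before first FASTA header")
            chunks.append(line.strip())
    if header is not None:
        records.append(cls(header, "".join(chunks)))
    return records


def write_fasta(records, width: int = 70) -> str:
    """Serialise records to FASTA; round-trips with :func:`parse_fasta`."""
    out = []
    for rec in records:
        out.append(f">{rec.id}")
        for i in range(0, len(rec.residues), width):
            out.append(rec.residues[i : i + width])
    return "\n".join(out) + ("\n" if out else "")


def revcomp(seq: NucSeq | str) -> NucSeq | str:
    if isinstance(seq, str):
        return seq.translate(COMPLEMENT)[::-1]
    return NucSeq(seq.id, seq.residues.translate(COMPLEMENT)[::-1])


def translate(seq: NucSeq | str, frame: int = 1) -> ProtSeq:
    """Translate one reading frame under the standard genetic code.

    frame in {+1,+2,+3} reads the forward strand starting at offset
    |frame|-1; negative frames read the reverse complement.  Codons
    containing N translate to X; stop codons yield '*'; a trailing partial
    codon is dropped.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be in ±{{1,2,3}}, got {frame}")
    sid = seq.id if isinstance(seq, NucSeq) else "seq"
    s = seq.residues if isinstance(seq, NucSeq) else seq.upper()
    if frame < 0:
        s = s.translate(COMPLEMENT)[::-1]
    s = s[abs(frame) - 1 :]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ProtSeq(sid, "")
    get = CODON_TO_AA.get
    aa = "".join(get(s[i : i + 3], "X") for i in range(0, len(s), 3))
    return ProtSeq(sid, aa)


def translate_cds(cds: str) -> str:
    """Translate a CDS string (frame +1), dropping any trailing partial codon."""
    return translate(NucSeq("cds", cds), 1).residues


# ---------------------------------------------------------------------------
# Newick trees (thin wrapper over dendropy)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick tree; duplicate leaf labels are rejected."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ParseError(f"duplicate leaf labels: {dup}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]


# ---------------------------------------------------------------------------
# GFF3 writing (gene / mRNA / CDS features)
# ---------------------------------------------------------------------------

@dataclass
class GffFeature:
    seqid: str
    type: str
    start: int  # 0-based half-open internally
    end: int
    strand: str = "+"
    phase: str = "."
    attributes: dict = field(default_factory=dict)


def write_gff3(features: list[GffFeature], source: str = "gulotrace") -> str:
    """Serialise features as GFF3 (1-based inclusive coordinates on disk)."""
    lines = ["##gff-version 3"]
    for f in features:
        attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
        lines.append(
            "\t".join([
                f.seqid, source, f.type,
                str(f.start + 1), str(f.end),
                ".", f.strand, str(f.phase), attrs,
            ])
        )
    return "\n".join(lines) + "\n"


def gene_to_gff3(scaffold_id: str, gene_id: str, exons: list[tuple[int, int]],
                 strand: str = "+") -> list[GffFeature]:
    """Build gene/mRNA/CDS features for a spliced CDS.

    ``exons`` are 0-based half-open genomic intervals in transcription
    order; CDS phase is computed from cumulative coding length.
    """
    if not exons:
        raise ValueError("gene must have at least one exon")
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    feats = [
        GffFeature(scaffold_id, "gene", lo, hi, strand, ".", {"ID": gene_id}),
        GffFeature(scaffold_id, "mRNA", lo, hi, strand, ".",
                   {"ID": f"{gene_id}.t1", "Parent": gene_id}),
    ]
    cum = 0
    for s, e in exons:
        phase = (3 - cum % 3) % 3
        feats.append(GffFeature(scaffold_id, "CDS", s, e, strand, phase,
                                {"ID": f"{gene_id}.cds", "Parent": f"{gene_id}.t1"}))
        cum += e - s
    return feats
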