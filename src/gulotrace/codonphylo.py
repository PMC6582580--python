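"""Codon-aware alignment, column-support filtering, distance trees and
MCMC run diagnostics.

CDS sets are aligned translate-align-backtranslate style: proteins are
aligned by a centre-star progressive scheme (pairwise global alignments
against the most central sequence, merged under "once a gap, always a
gap"), and the nucleotide alignment is obtained by threading each CDS's
codons through its protein row, so gaps always come in triplets and
degapping returns the input CDS exactly.

Each codon column gets a 0-9 support value from pairwise residue
consistency; columns with support above two are retained for tree
building, which uses neighbour joining on protein p-distances as a
desk-scale stand-in for Bayesian inference.  Rooting on a fungal outgroup
lets queries be confirmed as GULO-like (attached inside the animal
ingroup) or flagged as external to the fungi.  Burn-in arithmetic and the
Gelman-Rubin potential scale reduction factor are provided as generic
MCMC run utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import Align
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from gulotrace.core_io import NucSeq, ProtSeq, parse_newick, translate_cds
from gulotrace.tsearch import B62, encode


@dataclass
class CodonAlignment:
    ids: list[str]
    cds_rows: list[str]       # aligned CDS, gaps in triplets
    protein_rows: list[str]   # aligned proteins, same column count / 3
    column_support: list[int] | None = None  # per codon column, 0-9

    @property
    def n_codon_columns(self) -> int:
        return len(self.protein_rows[0]) if self.protein_rows else 0

    def degap(self, i: int) -> str:
        return self.cds_rows[i].replace("-", "")


@dataclass
class MCMCConfig:
    """Arithmetic of a Metropolis-coupled MCMC tree-sampling run."""

    generations: int = 5_000_000
    sample_every: int = 100
    burnin_frac: float = 0.25
    n_runs: int = 2
    n_chains: int = 4

    def __post_init__(self):
        if self.generations < self.sample_every:
            raise ValueError("generations must be >= sample_every")
        if not (0 <= self.burnin_frac < 1):
            raise ValueError("burnin_frac must be in [0, 1)")


def burnin_count(cfg: MCMCConfig) -> int:
    """Number of discarded samples: floor(generations/sample_every * burnin_frac)."""
    return int(cfg.generations // cfg.sample_every * cfg.burnin_frac)


def psrf(chains: list) -> float:
    """Gelman-Rubin potential scale reduction factor of >= 2 equal-length chains.

    sqrt(((n-1)/n + B/(n*W)) ) with B the between-chain and W the
    within-chain variance; defined as 1.0 when both variances vanish.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = arr.shape
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0 and B == 0:
        return 1.0
    if W == 0:
        return float("inf")
    return float(np.sqrt((n - 1) / n + B / (n * W)))


# ---------------------------------------------------------------------------
# Codon-aware alignment
# ---------------------------------------------------------------------------

_GLOBAL = Align.PairwiseAligner(mode="global", open_gap_score=-12,
                                extend_gap_score=-1)
try:  # biopython >= 1.86 naming
    _GLOBAL.end_insertion_score = 0.0
    _GLOBAL.end_deletion_score = 0.0
except (AttributeError, ValueError):
    _GLOBAL.target_end_gap_score = 0.0
    _GLOBAL.query_end_gap_score = 0.0
_GLOBAL.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")


def _pair_align(a: str, b: str) -> tuple[str, str]:
    aln = _GLOBAL.align(a, b)[0]
    rows = str(aln).splitlines()
    # biopython >=1.80 pretty format: target / match / query lines; use indices
    ta, tb = aln[0], aln[1]
    return ta, tb


def _pid(a: str, b: str) -> float:
    ra, rb = _pair_align(a, b)
    same = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    cols = sum(1 for x, y in zip(ra, rb) if x != "-" and y != "-")
    return same / cols if cols else 0.0


def align_codons(cds_set: list[NucSeq]) -> CodonAlignment:
    """Align CDSs at the protein level and thread codons through the result.

    Every CDS must have length divisible by three and no internal stop.
    Centre-star progressive alignment: the sequence with the highest mean
    pairwise identity is the centre; all others are merged onto it under
    "once a gap, always a gap".
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    prots = []
    for rec in cds_set:
        if len(rec) % 3:
            raise ValueError(f"CDS {rec.id!r} length not a multiple of 3")
        p = translate_cds(rec.residues)
        if "*" in p[:-1]:
            raise ValueError(f"CDS {rec.id!r} contains an internal stop codon")
        prots.append(p.rstrip("*"))
    n = len(prots)
    if n == 1:
        return CodonAlignment([cds_set[0].id], [cds_set[0].residues], [prots[0]])
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = _pid(prots[i], prots[j])
    centre = int(np.argmax(sim.sum(axis=1)))

    # msa rows as lists of columns; start with the centre alone
    msa = [list(prots[centre])]
    order = [centre]
    centre_cols = list(range(len(prots[centre])))  # map centre residue -> column

    for i in range(n):
        if i == centre:
            continue
        centre_row = "".join(msa[0])
        degapped_centre = centre_row.replace("-", "")
        rc, ri = _pair_align(degapped_centre, prots[i])
        # walk the pairwise alignment, inserting new columns where the
        # pairwise alignment gaps the centre
        new_rows = [[] for _ in msa] + [[]]
        msa_col = 0  # column index in current msa
        centre_res_in_col = [c != "-" for c in centre_row]
        for ca, cb in zip(rc, ri):
            if ca != "-":
                # advance msa to the column holding this centre residue,
                # copying any all-centre-gap columns in between
                while not centre_res_in_col[msa_col]:
                    for r, row in enumerate(msa):
                        new_rows[r].append(row[msa_col])
                    new_rows[-1].append("-")
                    msa_col += 1
                for r, row in enumerate(msa):
                    new_rows[r].append(row[msa_col])
                new_rows[-1].append(cb)
                msa_col += 1
            else:
                for r in range(len(msa)):
                    new_rows[r].append("-")
                new_rows[-1].append(cb)
        while msa_col < len(msa[0]):
            for r, row in enumerate(msa):
                new_rows[r].append(row[msa_col])
            new_rows[-1].append("-")
            msa_col += 1
        msa = new_rows
        order.append(i)

    prot_rows_by_input = [None] * n
    for r, i in enumerate(order):
        prot_rows_by_input[i] = "".join(msa[r])
    cds_rows = []
    for i, rec in enumerate(cds_set):
        codons = [rec.residues[k:k + 3] for k in range(0, len(rec), 3)]
        it = iter(codons)
        row = "".join(next(it) if c != "-" else "---" for c in prot_rows_by_input[i])
        cds_rows.append(row)
    return CodonAlignment([r.id for r in cds_set], cds_rows,
                          list(prot_rows_by_input))


def column_support(aln: CodonAlignment) -> tuple[list[int], CodonAlignment]:
    """0-9 per-codon-column support from pairwise residue consistency.

    support(col) = round(9 x fraction of record pairs whose residues in
    that protein column are identical or score > 0 under BLOSUM62); gapped
    pairs count as inconsistent.  The filtered alignment keeps columns with
    support >= 3 ("above two").
    """
    rows = aln.protein_rows
    if len(rows) < 3:
        raise ValueError("column support needs >= 3 records")
    n = len(rows)
    ncol = aln.n_codon_columns
    supports = []
    keep = []
    npairs = n * (n - 1) // 2
    enc_rows = [encode(r.replace("-", "X").replace("*", "X")) for r in rows]
    for c in range(ncol):
        good = 0
        for i in range(n):
            if rows[i][c] == "-":
                continue
            for j in range(i + 1, n):
                if rows[j][c] == "-":
                    continue
                a, b = rows[i][c], rows[j][c]
                if a == b or B62[enc_rows[i][c], enc_rows[j][c]] > 0:
                    good += 1
        s = round(9 * good / npairs)
        supports.append(s)
        if s >= 3:
            keep.append(c)
    filtered = CodonAlignment(
        ids=list(aln.ids),
        cds_rows=["".join(r[3 * c:3 * c + 3] for c in keep) for r in aln.cds_rows],
        protein_rows=["".join(r[c] for c in keep) for r in aln.protein_rows],
        column_support=[supports[c] for c in keep],
    )
    return supports, filtered


# ---------------------------------------------------------------------------
# Distance tree (neighbour joining) and outgroup-based classification
# ---------------------------------------------------------------------------

def p_distance_matrix(aln: CodonAlignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise protein p-distances over the alignment's columns (pairwise
    deletion of gapped columns)."""
    rows = aln.protein_rows
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cols = [(a, b) for a, b in zip(rows[i], rows[j])
                    if a != "-" and b != "-"]
            if not cols:
                d[i, j] = d[j, i] = 1.0
                continue
            diff = sum(1 for a, b in cols if a != b)
            d[i, j] = d[j, i] = diff / len(cols)
    return d, list(aln.ids)


def nj_tree(aln: CodonAlignment | tuple[np.ndarray, list[str]]) -> dendropy.Tree:
    """Unrooted neighbour-joining tree; exact on additive distance matrices.

    Ids are sorted before joining so equal-distance ties resolve by label
    order.
    """
    if isinstance(aln, CodonAlignment):
        d, ids = p_distance_matrix(aln)
    else:
        d, ids = aln
    if len(ids) < 3:
        raise ValueError("neighbour joining needs >= 3 records")
    order = sorted(range(len(ids)), key=lambda k: ids[k])
    d = d[np.ix_(order, order)]
    ids = [ids[k] for k in order]
    dm = DistanceMatrix(d, ids=ids)
    sk = _skbio_nj(dm)
    return parse_newick(str(sk))


def place_and_classify(tree: dendropy.Tree | str, query_ids: list[str],
                       animal_ref_ids: list[str],
                       fungal_outgroup_ids: list[str]) -> dict[str, bool]:
    """Root on the fungal outgroup stem and confirm queries attaching inside
    the animal ingroup clade; queries branching outside the fungi (toward
    the root) are flagged non-GULO (False)."""
    if isinstance(tree, str):
        tree = parse_newick(tree)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = (set(query_ids) | set(animal_ref_ids) | set(fungal_outgroup_ids)) - labels
    if missing:
        raise ValueError(f"tree lacks leaves: {sorted(missing)}")
    if len(fungal_outgroup_ids) < 2:
        raise ValueError("need >= 2 fungal outgroup leaves to locate the stem")
    # view the unrooted tree from the animal side so the fungal clade is well
    # defined, then root at the midpoint of the fungal stem edge
    anchor = next(l for l in tree.leaf_node_iter()
                  if l.taxon.label == animal_ref_ids[0])
    tree.reroot_at_edge(anchor.edge, update_bipartitions=True)
    mrca = tree.mrca(taxon_labels=fungal_outgroup_ids)
    if mrca.edge.length is not None:
        tree.reroot_at_edge(mrca.edge, length1=mrca.edge.length / 2,
                            length2=mrca.edge.length / 2,
                            update_bipartitions=True)
    else:
        tree.reroot_at_edge(mrca.edge, update_bipartitions=True)
    ingroup_node = tree.mrca(taxon_labels=animal_ref_ids)
    ingroup_leaves = {lf.taxon.label for lf in ingroup_node.leaf_iter()}
    return {q: q in ingroup_leaves for q in query_ids}
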