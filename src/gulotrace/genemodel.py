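"""Spliced CDS reconstruction from a genomic region, guided by a query protein.

Replaces the manual annotation step of a homology-based gene hunt with a
similarity-guided exon-chaining dynamic program.  Ungapped diagonal
segments between the region's six-frame translations and the query seed
exon candidates whose boundaries are placed at canonical splice
dinucleotides (AG acceptor upstream, GT donor downstream) or at terminal
positions implied by the query ends; the DP then selects the colinear,
phase-compatible chain maximising total similarity minus an intron
penalty.  Non-canonical splice sites (GC-AG, AT-AC) are rejected outright.

The reconstructed protein is classified by its H-W-x-K motif: HWAK marks a
GULO candidate, any other HWxK a related FAD-domain (VAO-family) enzyme,
and a model with no motif is rejected, mirroring the rule that true animal
GULO orthologs always carry HWAK.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio import Align

from gulotrace.core_io import NucSeq, ProtSeq, revcomp, translate, translate_cds
from gulotrace.growmerge import GenomicRegion
from gulotrace.tsearch import B62, _ungapped_extend, encode

MOTIF_RE = re.compile(r"HW[^X*]K")

GULO_CANDIDATE = "GULO_CANDIDATE"
VAO_OTHER = "VAO_OTHER"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class AnnotateParams:
    word_size: int = 2           # guide-search word size (annotation mode)
    seed_threshold: int = 8
    x_drop: int = 20
    exon_min_score: int = 15
    chain_min_score: int = 40
    intron_penalty: int = 5
    min_intron: int = 20
    max_intron: int = 20000
    # splice sites are searched asymmetrically around a segment end: x-drop
    # extension overruns *into* the intron, so the true site tends to lie
    # inward (toward the exon) of the segment boundary
    boundary_window_in: int = 130
    boundary_window_out: int = 40
    max_splice_options: int = 14  # nearest AG/GT sites considered per side
    max_segments: int = 30       # highest-scoring diagonal segments kept
    coverage_min: float = 0.5
    start_bonus: int = 2         # favours chains beginning with ATG at query pos 0
    query_gap_slack: int = 5     # max aa skipped between consecutive exons


@dataclass
class ExonCandidate:
    """A candidate exon on the working (transcription-strand) sequence.

    ``start_phase`` is the number of leading nucleotides that complete a
    codon opened in the previous exon; ``end_phase`` the number of trailing
    nucleotides opening a codon finished downstream.
    """

    start: int            # 0-based half-open on the working sequence
    end: int
    start_phase: int
    q_start: int          # aa interval on the query covered by whole codons
    q_end: int
    score: int
    has_acceptor: bool    # AG immediately upstream of start
    has_donor: bool       # GT immediately downstream of end
    is_atg_start: bool = False

    @property
    def end_phase(self) -> int:
        return ((3 - self.start_phase) % 3 + (self.end - self.start)) % 3

    def __len__(self):
        return self.end - self.start


@dataclass
class GeneModel:
    """A reconstructed spliced CDS and its classification evidence."""

    region_id: str
    scaffold_ids: list[str]
    exons: list[ExonCandidate]          # transcription order, working coords
    exons_fwd: list[tuple[int, int]]    # forward-strand region coords
    strand: str
    cds: NucSeq
    protein: ProtSeq
    score: int
    motif: str | None = None            # 'HWAK', 'HWGK', other HWxK, or None
    motif_pos: int | None = None
    has_internal_stop: bool = False
    has_start_codon: bool = False
    coverage_frac: float = 0.0
    acceptable: bool = False
    rejected: bool = False
    contaminated: bool = False

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


def scan_motif(protein: ProtSeq | str) -> tuple[int, str] | None:
    """First H-W-x-K match (x = any standard residue, never unknown X).

    Returns (0-based position, concrete x residue) or None.
    """
    s = protein.residues if isinstance(protein, ProtSeq) else protein
    m = MOTIF_RE.search(s.upper())
    if m is None:
        return None
    return m.start(), m.group(0)[2]


def classify_sequence(model: GeneModel) -> str:
    """HWAK -> GULO candidate; other HWxK -> related VAO-family enzyme;
    no motif -> unclassified (model rejected, no annotation retained)."""
    if model.protein is None:
        raise ValueError("model has no protein")
    hit = scan_motif(model.protein)
    if hit is None:
        model.rejected = True
        return UNCLASSIFIED
    return GULO_CANDIDATE if hit[1] == "A" else VAO_OTHER


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def _diagonal_segments(S: str, query: ProtSeq, params: AnnotateParams):
    """Ungapped high-scoring diagonal segments between the three forward
    frame translations of S and the query.

    Yields (frame_offset, a0, a1, q0, q1, score) with aa coordinates on the
    frame translation and the query.
    """
    qi = encode(query.residues)
    w = params.word_size
    out = []
    for off in range(3):
        tr = translate(NucSeq("w", S), off + 1)
        ti = encode(tr.residues)
        nq, nt = len(qi) - w + 1, len(ti) - w + 1
        if nq <= 0 or nt <= 0:
            continue
        sc = np.zeros((nq, nt), dtype=np.int16)
        for k in range(w):
            sc += B62[qi[k:k + nq]][:, ti[k:k + nt]]
        qpos, tpos = np.nonzero(sc >= params.seed_threshold)
        order = np.lexsort((tpos, tpos - qpos))
        covered: dict[int, int] = {}
        for idx in order:
            q, t = int(qpos[idx]), int(tpos[idx])
            d = t - q
            if covered.get(d, -1) >= t:
                continue
            q0, q1, t0, t1, score = _ungapped_extend(qi, ti, q, t, w,
                                                     params.x_drop)
            covered[d] = t1
            if score >= params.exon_min_score:
                out.append((off, t0, t1, q0, q1, score))
    # dedupe identical segments
    return sorted(set(out))


def _nearest_sites(S: str, pattern: str, centre: int, lo: int, hi: int, k: int,
                   offset: int) -> list[int]:
    """Boundary positions p in [lo, hi] whose dinucleotide at p+offset equals
    ``pattern``; the k nearest to ``centre`` are returned."""
    lo = max(0, lo)
    hi = min(len(S), hi)
    hits = []
    for p in range(lo, hi + 1):
        i = p + offset
        if 0 <= i and i + 2 <= len(S) and S[i:i + 2] == pattern:
            hits.append(p)
    hits.sort(key=lambda p: abs(p - centre))
    return hits[:k]


def _query_offset_fit(T: str, query: str, q_exp: int, slack: int = 3):
    """Best ungapped placement of translated exon T on the query near q_exp.

    Returns (q_start, q_end, score); alignment is scored over the
    overlapping span only.
    """
    ti = encode(T)
    qi = encode(query)
    best = None
    for d in range(-slack, slack + 1):
        qs = q_exp + d
        a0 = max(0, -qs)
        a1 = min(len(T), len(query) - qs)
        if a1 - a0 <= 0:
            continue
        sc = int(B62[ti[a0:a1], qi[qs + a0:qs + a1]].sum())
        cand = (sc, -(abs(d)), qs + a0, qs + a1)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    sc, _, qs, qe = best
    return qs, qe, sc


def candidate_exons(region: GenomicRegion | str, query: ProtSeq,
                    params: AnnotateParams | None = None,
                    _working_seq: str | None = None) -> list[ExonCandidate]:
    """Exon candidates on the forward strand of the region (or of a supplied
    working sequence).  Candidates record whole-codon query intervals, all
    valid start phases, and splice-site context flags; translations with an
    in-frame stop in the recorded phase are discarded."""
    params = params or AnnotateParams()
    S = _working_seq if _working_seq is not None else region.sequence.residues
    segs = _diagonal_segments(S, query, params)
    segs = sorted(segs, key=lambda s: -s[5])[:params.max_segments]
    Wi, Wo = params.boundary_window_in, params.boundary_window_out
    K = params.max_splice_options
    qlen = len(query)
    cands: list[ExonCandidate] = []
    seen = set()
    for off, a0, a1, q0, q1, seg_score in segs:
        g0 = off + 3 * a0
        g1 = off + 3 * a1
        # left boundary options: AG acceptors, canonical query-start point, ATG starts
        lefts: list[tuple[int, bool, bool]] = []  # (pos, has_acceptor, is_atg)
        for p in _nearest_sites(S, "AG", g0, g0 - Wo, g0 + Wi, K, offset=-2):
            lefts.append((p, True, False))
        canon_start = g0 - 3 * q0
        if 0 <= canon_start <= len(S) - 3 and abs(canon_start - g0) <= Wi + 3 * q0:
            lefts.append((canon_start, False, S[canon_start:canon_start + 3] == "ATG"))
        lefts.append((max(0, g0), False, S[g0:g0 + 3] == "ATG" if g0 + 3 <= len(S) else False))
        if g0 <= Wo:
            lefts.append((0, False, S[:3] == "ATG"))
        # right boundary options: GT donors, canonical query-end point, natural end
        rights: list[tuple[int, bool]] = []
        for p in _nearest_sites(S, "GT", g1, g1 - Wi, g1 + Wo, K, offset=0):
            rights.append((p, True))
        canon_end = g1 + 3 * (qlen - q1)
        if canon_end <= len(S) and abs(canon_end - g1) <= Wi + 3 * (qlen - q1):
            rights.append((canon_end, False))
        rights.append((min(len(S), g1), False))
        if len(S) - g1 <= Wo:
            rights.append((len(S), False))
        for s, has_acc, is_atg in lefts:
            for e, has_don in rights:
                if e - s < 3:
                    continue
                for p in range(3):
                    r = (e - s - p) % 3
                    if e - s - p - r < 0:
                        continue
                    T = translate_cds(S[s + p:e - r])
                    if "*" in T:
                        continue
                    if not T and not (is_atg and e - s == 3):
                        continue
                    q_exp = q0 + round((s + p - g0) / 3)
                    fit = _query_offset_fit(T, query.residues, q_exp) if T else (0, 1, 5)
                    if fit is None:
                        continue
                    qs, qe, sc = fit
                    if sc < params.exon_min_score and not (is_atg and e - s == 3):
                        continue
                    atg = is_atg and qs == 0 and p == 0
                    if atg:
                        sc += params.start_bonus
                    key = (s, e, p)
                    if key in seen:
                        continue
                    seen.add(key)
                    cands.append(ExonCandidate(s, e, p, qs, qe, sc,
                                               has_acc, has_don, atg))
    # lone-ATG first exons: an ATG immediately followed by a GT donor, at
    # intron distance upstream of a candidate that covers the query start
    if query.residues.startswith("M") and cands:
        targets = sorted({c.start for c in cands
                          if c.has_acceptor
                          and c.q_start <= params.query_gap_slack + 1})
        if targets:
            lo = max(0, min(targets) - params.max_intron)
            for m in re.finditer("ATG(?=GT)", S[lo:max(targets)]):
                s = lo + m.start()
                if not any(params.min_intron <= t - (s + 3) <= params.max_intron
                           for t in targets):
                    continue
                key = (s, s + 3, 0)
                if key not in seen:
                    seen.add(key)
                    cands.append(ExonCandidate(s, s + 3, 0, 0, 1,
                                               5 + params.start_bonus,
                                               has_acceptor=False,
                                               has_donor=True,
                                               is_atg_start=True))
    cands.sort(key=lambda c: (c.start, c.end, c.start_phase))
    return cands


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def _compatible(j: ExonCandidate, i: ExonCandidate, S: str,
                params: AnnotateParams) -> bool:
    """Can exon i directly follow exon j across a canonical intron?"""
    gap = i.start - j.end
    if not (params.min_intron <= gap <= params.max_intron):
        return False
    if not (j.has_donor and i.has_acceptor):
        return False
    if S[j.end:j.end + 2] != "GT" or S[i.start - 2:i.start] != "AG":
        return False
    if i.start_phase != (3 - j.end_phase) % 3:
        return False
    dq = i.q_start - j.q_end
    if dq < 0 or dq > params.query_gap_slack:
        return False
    return True


def _junction_score(j: ExonCandidate, i: ExonCandidate, S: str,
                    query: ProtSeq, params: AnnotateParams) -> int:
    """Score of the intron junction j -> i beyond the exon scores.

    When the intron splits a codon, the reconstituted codon (tail of j plus
    head of i) is translated and scored against the query residue it should
    encode; skipped query residues beyond the one legitimately consumed by
    a split codon are penalised.
    """
    score = -params.intron_penalty
    dq = i.q_start - j.q_end
    if i.start_phase != 0:
        ep = j.end_phase
        codon = S[j.end - ep:j.end] + S[i.start:i.start + i.start_phase]
        aa = translate_cds(codon)
        if aa and j.q_end < len(query.residues):
            score += int(B62[encode(aa)[0], encode(query.residues[j.q_end])[0]])
        expected_dq = 1
    else:
        expected_dq = 0
    # slippage: each query residue skipped or double-claimed across the
    # junction costs more than the best possible substitution score, so a
    # shifted splice pair can never profit from re-encoding a residue
    score -= 12 * abs(dq - expected_dq)
    return score


def chain_score(chain: list[ExonCandidate], params: AnnotateParams,
                S: str = "", query: ProtSeq | None = None) -> int:
    total = sum(c.score for c in chain)
    if query is None:
        return total - params.intron_penalty * (len(chain) - 1)
    for a, b in zip(chain, chain[1:]):
        total += _junction_score(a, b, S, query, params)
    return total


def chain_exons(cands: list[ExonCandidate], query: ProtSeq, S: str,
                params: AnnotateParams | None = None
                ) -> list[ExonCandidate] | None:
    """Best colinear, phase-compatible exon chain by dynamic programming.

    A chain must start at phase 0 and end at phase 0 (complete codons);
    ties break toward fewer exons, then leftmost start.  Returns None when
    the best chain scores below ``chain_min_score``.
    """
    params = params or AnnotateParams()
    order = sorted(range(len(cands)), key=lambda k: (cands[k].start, cands[k].end))
    # dp value: (score, -n_exons, -start) to maximise
    best_val: list[tuple | None] = [None] * len(cands)
    parent: list[int | None] = [None] * len(cands)
    for oi, i in enumerate(order):
        ci = cands[i]
        if ci.start_phase == 0:
            best_val[i] = (ci.score, -1, -ci.start)
        for oj in range(oi):
            j = order[oj]
            cj = cands[j]
            if best_val[j] is None:
                continue
            if cands[j].end + params.max_intron < ci.start:
                continue
            if _compatible(cj, ci, S, params):
                sc, ne, st = best_val[j]
                cand_val = (sc + ci.score + _junction_score(cj, ci, S, query,
                                                            params),
                            ne - 1, st)
                if best_val[i] is None or cand_val > best_val[i]:
                    best_val[i] = cand_val
                    parent[i] = j
    finish = [i for i in range(len(cands))
              if best_val[i] is not None and cands[i].end_phase == 0]
    if not finish:
        return None
    end = max(finish, key=lambda i: best_val[i])
    if best_val[end][0] < params.chain_min_score:
        return None
    chain = []
    k: int | None = end
    while k is not None:
        chain.append(cands[k])
        k = parent[k]
    return chain[::-1]


def chain_exons_bruteforce(cands: list[ExonCandidate], query: ProtSeq, S: str,
                           params: AnnotateParams
                           ) -> list[ExonCandidate] | None:
    """Exhaustive-enumeration oracle for the chaining DP (small inputs only)."""
    n = len(cands)
    if n > 16:
        raise ValueError("brute force limited to <= 16 candidates")
    order = sorted(range(n), key=lambda k: (cands[k].start, cands[k].end))
    best = None
    for mask in range(1, 1 << n):
        sub = [cands[order[k]] for k in range(n) if mask >> k & 1]
        if sub[0].start_phase != 0 or sub[-1].end_phase != 0:
            continue
        if any(not _compatible(sub[k], sub[k + 1], S, params)
               for k in range(len(sub) - 1)):
            continue
        val = (chain_score(sub, params, S, query), -len(sub), -sub[0].start)
        if best is None or val > best[0]:
            best = (val, sub)
    if best is None or best[0][0] < params.chain_min_score:
        return None
    return best[1]


# ---------------------------------------------------------------------------
# Model assembly and validation
# ---------------------------------------------------------------------------

_ALIGNER = Align.PairwiseAligner(
    mode="local", open_gap_score=-12, extend_gap_score=-1)
_ALIGNER.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")


def _coverage(protein: str, query: str) -> float:
    """Fraction of the query spanned by a local alignment to the protein."""
    clean = protein.replace("*", "X")
    if not clean:
        return 0.0
    aln = _ALIGNER.align(query, clean)
    if len(aln) == 0 or aln.score <= 0:
        return 0.0
    qa = aln[0].aligned[0]
    return (qa[-1][1] - qa[0][0]) / len(query)


def validate_model(model: GeneModel, query: ProtSeq,
                   params: AnnotateParams | None = None) -> GeneModel:
    """Set stop-codon, start-codon and coverage flags and the acceptability
    verdict: no internal stop, motif present, coverage >= coverage_min.
    A missing start codon alone does not disqualify a model."""
    params = params or AnnotateParams()
    prot = model.protein.residues
    model.has_internal_stop = "*" in prot[:-1] if prot else False
    model.has_start_codon = model.cds.residues.startswith("ATG")
    model.coverage_frac = _coverage(prot, query.residues)
    hit = scan_motif(prot)
    if hit is not None:
        model.motif_pos = hit[0]
        model.motif = f"HW{hit[1]}K"
    model.acceptable = (not model.has_internal_stop and hit is not None
                        and model.coverage_frac >= params.coverage_min)
    return model


def _build_model(chain: list[ExonCandidate], S: str, region: GenomicRegion,
                 strand: str, query: ProtSeq,
                 params: AnnotateParams) -> GeneModel:
    cds = "".join(S[c.start:c.end] for c in chain)
    prot = translate_cds(cds)
    L = len(S)
    if strand == "+":
        fwd = [(c.start, c.end) for c in chain]
    else:
        fwd = [(L - c.end, L - c.start) for c in chain]
    model = GeneModel(
        region_id=region.region_id,
        scaffold_ids=list(region.scaffold_ids),
        exons=chain, exons_fwd=fwd, strand=strand,
        cds=NucSeq(f"{region.region_id}|cds", cds),
        protein=ProtSeq(f"{region.region_id}|prot", prot),
        score=chain_score(chain, params, S, query),
    )
    return validate_model(model, query, params)


def annotate_region(region: GenomicRegion, query: ProtSeq,
                    params: AnnotateParams | None = None) -> GeneModel | None:
    """Reconstruct the best gene model on either strand of a region.

    Returns None when no chain reaches ``chain_min_score`` or when the
    reconstructed protein lacks the H-W-x-K pattern entirely (in which
    case no annotation is retained, matching the screening rule that
    motif-less hits are not annotated)."""
    params = params or AnnotateParams()
    best: GeneModel | None = None
    fwd = region.sequence.residues
    for strand, S in (("+", fwd), ("-", revcomp(fwd))):
        cands = candidate_exons(region, query, params, _working_seq=S)
        if not cands:
            continue
        chain = chain_exons(cands, query, S, params)
        if chain is None:
            continue
        model = _build_model(chain, S, region, strand, query, params)
        if best is None or model.score > best.score:
            best = model
    if best is None:
        return None
    if scan_motif(best.protein) is None:
        return None
    return best
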