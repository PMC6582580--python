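"""Six-frame translated search of a protein query against nucleotide scaffolds.

The search mirrors a tblastn run: each scaffold is translated in all six
frames, word seeds scoring above a neighbourhood threshold under BLOSUM62
are extended ungapped with x-drop termination, and surviving seeds trigger
a gapped Smith-Waterman extension in a window around the hit.  Scores are
converted to bit scores and E-values with fixed Karlin-Altschul parameters
for gapped BLOSUM62 (lambda = 0.267, K = 0.041); effective-length
corrections are omitted, since only the E <= 0.05 cutoff semantics matter
downstream.  Reverse-strand hits are reported in forward-strand nucleotide
coordinates with the frame sign carrying orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from gulotrace.core_io import NucSeq, ProtSeq, translate
from gulotrace.growmerge import GenomicRegion

_B62 = substitution_matrices.load("BLOSUM62")
ALPHABET = _B62.alphabet  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_IDX = {c: i for i, c in enumerate(ALPHABET)}
B62 = np.array(_B62, dtype=np.int16)


def encode(residues: str) -> np.ndarray:
    """Map protein residues to BLOSUM62 row indices (unknowns -> X)."""
    x = _IDX["X"]
    return np.fromiter((_IDX.get(c, x) for c in residues), dtype=np.int16,
                       count=len(residues))


@dataclass
class SearchParams:
    evalue_max: float = 0.05
    word_size: int = 3
    flank: int = 5000
    gap_open: int = 11      # cost of a gap of length k is gap_open + k*gap_extend
    gap_extend: int = 1
    x_drop: int = 20
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    seed_threshold: int | None = None  # None -> 11 for w=3, 8 for w=2
    gapped_trigger: int = 18           # min ungapped score to attempt gapped extension

    def __post_init__(self):
        if self.word_size not in (2, 3):
            raise ValueError("word_size must be 2 or 3")
        if self.flank < 0 or self.evalue_max <= 0:
            raise ValueError("flank must be >= 0 and evalue_max > 0")

    @property
    def seed_t(self) -> int:
        if self.seed_threshold is not None:
            return self.seed_threshold
        return 11 if self.word_size == 3 else 8


@dataclass
class HSP:
    """One high-scoring segment pair in forward-strand nt coordinates."""

    scaffold_id: str
    frame: int                   # +-1, +-2, +-3
    q_start: int                 # aa, 0-based half-open on the query
    q_end: int
    s_start: int                 # nt, 0-based half-open, forward strand
    s_end: int
    raw_score: int
    bit_score: float
    evalue: float
    identity_frac: float
    hsp_id: str = ""

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValueError("invalid query interval")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError("invalid subject interval")
        if not self.hsp_id:
            self.hsp_id = (f"{self.scaffold_id}:{self.s_start}-{self.s_end}"
                           f"({self.frame:+d})")


def karlin_stats(raw_score: int, m: int, n: int, params: SearchParams):
    """Bit score and E-value for a raw score; m query aa, n subject aa letters."""
    lam, k = params.karlin_lambda, params.karlin_k
    bits = (lam * raw_score - math.log(k)) / math.log(2)
    evalue = k * m * n * math.exp(-lam * raw_score)
    return bits, evalue


def seed_hits(query: ProtSeq, frame_translation: ProtSeq,
              params: SearchParams) -> list[tuple[int, int]]:
    """All (q_pos, t_pos) whose word of ``word_size`` scores >= the seed
    threshold under BLOSUM62; exact-match words are always included."""
    w = params.word_size
    if w > len(query):
        raise ValueError("word_size exceeds query length")
    qi, ti = encode(query.residues), encode(frame_translation.residues)
    nq, nt = len(qi) - w + 1, len(ti) - w + 1
    if nq <= 0 or nt <= 0:
        return []
    score = np.zeros((nq, nt), dtype=np.int16)
    exact = np.ones((nq, nt), dtype=bool)
    for k in range(w):
        score += B62[qi[k:k + nq]][:, ti[k:k + nt]]
        exact &= qi[k:k + nq, None] == ti[None, k:k + nt]
    qpos, tpos = np.nonzero((score >= params.seed_t) | exact)
    return list(zip(qpos.tolist(), tpos.tolist()))


def _ungapped_extend(qi: np.ndarray, ti: np.ndarray, q: int, t: int, w: int,
                     x_drop: int) -> tuple[int, int, int, int, int]:
    """X-drop ungapped extension of a word seed along its diagonal.

    Returns (q_start, q_end, t_start, t_end, score), aa coordinates.
    """
    score = int(B62[qi[q:q + w], ti[t:t + w]].sum())
    best = score
    # extend right
    bq, bt = q + w, t + w
    cq, ct, cur = bq, bt, score
    while cq < len(qi) and ct < len(ti):
        cur += int(B62[qi[cq], ti[ct]])
        cq += 1
        ct += 1
        if cur > best:
            best, bq, bt = cur, cq, ct
        elif best - cur > x_drop:
            break
    q_end, t_end = bq, bt
    # extend left
    bq, bt = q, t
    cq, ct, cur = q, t, best
    best_l = best
    while cq > 0 and ct > 0:
        cq -= 1
        ct -= 1
        cur += int(B62[qi[cq], ti[ct]])
        if cur > best_l:
            best_l, bq, bt = cur, cq, ct
        elif best_l - cur > x_drop:
            break
    return bq, q_end, bt, t_end, best_l


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard runtime dependency
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]


@_njit(cache=False)
def _sw_kernel(qi, ti, B, gap_open, gap_extend):  # pragma: no cover - jit
    m, n = len(qi), len(ti)
    NEG = -(10 ** 6)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    tb = np.zeros((m + 1, n + 1), dtype=np.uint8)
    Fcol = np.full(n + 1, NEG, dtype=np.int32)
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        e = NEG
        for j in range(1, n + 1):
            diag = H[i - 1, j - 1] + B[qi[i - 1], ti[j - 1]]
            e = max(e - gap_extend, H[i, j - 1] - open_cost)
            f = max(Fcol[j] - gap_extend, H[i - 1, j] - open_cost)
            Fcol[j] = f
            h = max(0, max(diag, max(e, f)))
            H[i, j] = h
            if h == 0:
                tb[i, j] = 0
            elif h == diag:
                tb[i, j] = 1
            elif h == f:
                tb[i, j] = 2
            else:
                tb[i, j] = 3
    best = 0
    bi = 0
    bj = 0
    for i in range(m + 1):
        for j in range(n + 1):
            if H[i, j] > best:
                best = H[i, j]
                bi, bj = i, j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    i, j = bi, bj
    n_ident = 0
    n_cols = 0
    while tb[i, j] != 0 and H[i, j] > 0:
        if tb[i, j] == 1:
            n_cols += 1
            if qi[i - 1] == ti[j - 1]:
                n_ident += 1
            i -= 1
            j -= 1
        elif tb[i, j] == 2:
            n_cols += 1
            i -= 1
        else:
            n_cols += 1
            j -= 1
    return best, i, bi, j, bj, n_ident, n_cols


def smith_waterman(qi: np.ndarray, ti: np.ndarray, gap_open: int, gap_extend: int):
    """Affine-gap local alignment (a gap of length k costs open + k*extend).

    Returns (score, q_start, q_end, t_start, t_end, n_ident, n_cols).
    """
    res = _sw_kernel(np.asarray(qi, np.int16), np.asarray(ti, np.int16),
                     B62.astype(np.int32), gap_open, gap_extend)
    return tuple(int(x) for x in res)


def _frame_to_forward(frame: int, scaffold_len: int, aa_start: int, aa_end: int):
    """Map aa coordinates in a frame translation to forward-strand nt."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start, off + 3 * aa_end
    return scaffold_len - off - 3 * aa_end, scaffold_len - off - 3 * aa_start


def extend_hsp(seed: tuple[int, int], query: ProtSeq, scaffold: NucSeq,
               frame: int, params: SearchParams,
               n_total_aa: int | None = None) -> HSP:
    """Gapped extension of a seed: Smith-Waterman in a window around the
    ungapped x-drop extension of the seed's diagonal."""
    ft = translate(scaffold, frame)
    qi, ti = encode(query.residues), encode(ft.residues)
    q, t = seed
    q0, q1, t0, t1, _ = _ungapped_extend(qi, ti, q, t, params.word_size,
                                         params.x_drop)
    pad = len(qi) + 10
    w0, w1 = max(0, t0 - pad), min(len(ti), t1 + pad)
    score, qs, qe, ts, te, n_ident, n_cols = smith_waterman(
        qi, ti[w0:w1], params.gap_open, params.gap_extend)
    if score == 0:
        raise ValueError("seed did not extend to a positive-scoring alignment")
    ts, te = ts + w0, te + w0
    n = n_total_aa if n_total_aa is not None else len(scaffold) // 3
    bits, ev = karlin_stats(score, len(query), n, params)
    s_start, s_end = _frame_to_forward(frame, len(scaffold), ts, te)
    return HSP(scaffold.id, frame, qs, qe, s_start, s_end, score, bits, ev,
               n_ident / n_cols if n_cols else 0.0)


def _search_frame(query_enc: np.ndarray, scaffold: NucSeq, frame: int,
                  params: SearchParams, m: int, n: int) -> list[HSP]:
    ft = translate(scaffold, frame)
    ti = encode(ft.residues)
    w = params.word_size
    nq, nt = len(query_enc) - w + 1, len(ti) - w + 1
    if nq <= 0 or nt <= 0:
        return []
    score = np.zeros((nq, nt), dtype=np.int16)
    for k in range(w):
        score += B62[query_enc[k:k + nq]][:, ti[k:k + nt]]
    qpos, tpos = np.nonzero(score >= params.seed_t)
    if len(qpos) == 0:
        return []
    # visit seeds per diagonal, skipping seeds inside an already-extended span
    order = np.lexsort((tpos, tpos - qpos))
    covered: dict[int, int] = {}  # diagonal -> t covered up to
    hsps: list[HSP] = []
    seen_spans: set[tuple[int, int]] = set()
    for idx in order:
        q, t = int(qpos[idx]), int(tpos[idx])
        d = t - q
        if covered.get(d, -1) >= t:
            continue
        q0, q1, t0, t1, ug_score = _ungapped_extend(ti=ti, qi=query_enc, q=q,
                                                    t=t, w=w,
                                                    x_drop=params.x_drop)
        covered[d] = t1
        if ug_score < params.gapped_trigger:
            continue
        pad = len(query_enc) + 10
        w0, w1 = max(0, t0 - pad), min(len(ti), t1 + pad)
        sw = smith_waterman(query_enc, ti[w0:w1], params.gap_open,
                            params.gap_extend)
        raw, qs, qe, ts, te, n_ident, n_cols = sw
        if raw == 0:
            continue
        ts, te = ts + w0, te + w0
        if (ts, te) in seen_spans:
            continue
        seen_spans.add((ts, te))
        bits, ev = karlin_stats(raw, m, n, params)
        if ev > params.evalue_max:
            continue
        s_start, s_end = _frame_to_forward(frame, len(scaffold), ts, te)
        hsps.append(HSP(scaffold.id, frame, qs, qe, s_start, s_end, raw, bits,
                        ev, n_ident / n_cols if n_cols else 0.0))
    return hsps


def search_genome(query: ProtSeq, scaffolds: list[NucSeq],
                  params: SearchParams | None = None) -> list[HSP]:
    """Translated search over all six frames of all scaffolds.

    Returns HSPs with E-value <= params.evalue_max, containment-deduplicated
    (an HSP nested inside a higher-scoring HSP on the same scaffold and
    frame is dropped) and sorted by bit score, descending.
    """
    if not query.residues:
        raise ValueError("empty query")
    if not scaffolds:
        raise ValueError("no scaffolds to search")
    params = params or SearchParams()
    qi = encode(query.residues)
    m = len(query)
    # six-frame search space: both strands contribute, ~2L/3 target letters
    n = 2 * sum(len(s) for s in scaffolds) // 3
    hsps: list[HSP] = []
    for sc in scaffolds:
        if len(sc) < 3:
            continue
        for frame in (1, 2, 3, -1, -2, -3):
            hsps.extend(_search_frame(qi, sc, frame, params, m, n))
    hsps.sort(key=lambda h: (-h.raw_score, h.scaffold_id, h.s_start))
    kept: list[HSP] = []
    for h in hsps:
        contained = any(
            k.scaffold_id == h.scaffold_id and k.frame == h.frame
            and k.s_start <= h.s_start and h.s_end <= k.s_end
            for k in kept)
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (-h.bit_score, h.scaffold_id, h.s_start))
    return kept


def extract_flanked_regions(hsps: list[HSP], scaffolds: list[NucSeq],
                            flank: int = 5000) -> list[GenomicRegion]:
    """Flank each HSP by ``flank`` nt on both sides (clipped to the scaffold)
    and merge coordinate-overlapping regions on the same scaffold."""
    by_id = {s.id: s for s in scaffolds}
    per_scaffold: dict[str, list[tuple[int, int, str]]] = {}
    for h in hsps:
        if h.scaffold_id not in by_id:
            raise KeyError(f"HSP references unknown scaffold {h.scaffold_id!r}")
        sc = by_id[h.scaffold_id]
        lo = max(0, h.s_start - flank)
        hi = min(len(sc), h.s_end + flank)
        per_scaffold.setdefault(h.scaffold_id, []).append((lo, hi, h.hsp_id))
    regions: list[GenomicRegion] = []
    for sid in sorted(per_scaffold):
        ivals = sorted(per_scaffold[sid])
        cur_lo, cur_hi, ids = ivals[0][0], ivals[0][1], [ivals[0][2]]
        merged = []
        for lo, hi, hid in ivals[1:]:
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
                ids.append(hid)
            else:
                merged.append((cur_lo, cur_hi, ids))
                cur_lo, cur_hi, ids = lo, hi, [hid]
        merged.append((cur_lo, cur_hi, ids))
        sc = by_id[sid]
        for lo, hi, ids in merged:
            regions.append(GenomicRegion(
                region_id=f"{sid}:{lo}-{hi}",
                scaffold_ids=[sid], start=lo, end=hi,
                sequence=NucSeq(f"{sid}:{lo}-{hi}", sc.residues[lo:hi]),
                origin_hsp_ids=sorted(set(ids)),
            ))
    return regions


def hsps_to_tsv(hsps: list[HSP], query_id: str = "query") -> str:
    """Tabular output mirroring BLAST outfmt 6 column order."""
    lines = []
    for h in hsps:
        lines.append("\t".join(map(str, [
            query_id, h.scaffold_id, f"{100 * h.identity_frac:.1f}",
            h.q_end - h.q_start, h.frame, h.q_start + 1, h.q_end,
            h.s_start + 1, h.s_end, f"{h.evalue:.2g}", f"{h.bit_score:.1f}",
        ])))
    return "\n".join(lines) + ("\n" if lines else "")
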