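"""Region growing: merge retrieved genomic regions sharing long exact overlaps.

Regions retrieved around translated-search hits from the same assembly can
overlap each other exactly; iteratively merging any pair whose suffix/prefix
overlap reaches a minimum length (default 2500 nt) yields longer contiguous
regions and simplifies downstream annotation.  Overlap detection is exact
string matching; reverse-complement overlaps are not merged by default
(regions carry forward-strand sequence, orientation is resolved later).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from gulotrace.core_io import NucSeq, revcomp

log = logging.getLogger(__name__)


@dataclass
class GenomicRegion:
    """A contiguous stretch of assembly sequence with provenance.

    ``start``/``end`` are 0-based half-open scaffold coordinates and only
    meaningful while the region derives from a single scaffold.
    """

    region_id: str
    scaffold_ids: list[str]
    sequence: NucSeq
    start: int | None = None
    end: int | None = None
    origin_hsp_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("region sequence must be non-empty")
        if (self.start is not None and self.end is not None
                and len(self.scaffold_ids) == 1
                and self.end - self.start != len(self.sequence)):
            raise ValueError("region length inconsistent with coordinates")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class Overlap:
    """Descriptor of an exact overlap between two regions.

    kind: 'a_then_b' (suffix of a = prefix of b), 'b_then_a', or
    'containment' (the shorter string occurs inside the longer).
    """

    kind: str
    length: int


def _longest_suffix_prefix(a: str, b: str, min_len: int) -> int:
    """Longest L >= min_len with a[-L:] == b[:L]; 0 if none."""
    best = 0
    start = 0
    limit = min(len(a), len(b))
    # scan occurrences of b's min_len-prefix inside a's tail
    probe = b[:min_len]
    pos = a.find(probe, max(0, len(a) - limit))
    while pos != -1:
        L = len(a) - pos
        if L <= limit and a[pos:] == b[:L] and L >= min_len:
            best = max(best, L)
        pos = a.find(probe, pos + 1)
    return best


def find_overlap(a: NucSeq, b: NucSeq, min_overlap: int = 2500) -> Overlap | None:
    """Longest exact suffix/prefix overlap of length >= min_overlap, or full
    containment of one sequence in the other; None otherwise."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    sa, sb = a.residues, b.residues
    if len(sa) >= len(sb) and sb in sa:
        return Overlap("containment", len(sb))
    if len(sb) > len(sa) and sa in sb:
        return Overlap("containment", len(sa))
    ab = _longest_suffix_prefix(sa, sb, min_overlap)
    ba = _longest_suffix_prefix(sb, sa, min_overlap)
    if ab == 0 and ba == 0:
        return None
    if ab >= ba:
        return Overlap("a_then_b", ab)
    return Overlap("b_then_a", ba)


def _merge(a: GenomicRegion, b: GenomicRegion, ov: Overlap) -> GenomicRegion:
    if ov.kind == "containment":
        big = a if len(a) >= len(b) else b
        merged_seq = big.sequence.residues
    elif ov.kind == "a_then_b":
        merged_seq = a.sequence.residues + b.sequence.residues[ov.length:]
    else:
        merged_seq = b.sequence.residues + a.sequence.residues[ov.length:]
    rid = min(a.region_id, b.region_id)
    return GenomicRegion(
        region_id=rid,
        scaffold_ids=sorted(set(a.scaffold_ids) | set(b.scaffold_ids)),
        sequence=NucSeq(rid, merged_seq),
        origin_hsp_ids=sorted(set(a.origin_hsp_ids) | set(b.origin_hsp_ids)),
    )


def grow_sequences(regions: list[GenomicRegion],
                   min_overlap: int = 2500,
                   merge_revcomp: bool = False) -> list[GenomicRegion]:
    """Iteratively merge overlapping regions until no pair overlaps.

    Greedy longest-overlap-first with lexicographic region-id tie-breaks, so
    the result is invariant to input order.  Merged length is
    |a| + |b| - overlap; HSP provenance is unioned.  When ``merge_revcomp``
    is set, a reverse-complemented copy of each region is also considered.
    """
    pool = {r.region_id: r for r in sorted(regions, key=lambda r: r.region_id)}
    if len(pool) != len(regions):
        raise ValueError("region_ids must be unique")
    changed = True
    while changed and len(pool) > 1:
        changed = False
        ids = sorted(pool)
        best = None  # (length, id_a, id_b, overlap)
        for i, ia in enumerate(ids):
            for ib in ids[i + 1:]:
                ov = find_overlap(pool[ia].sequence, pool[ib].sequence, min_overlap)
                if ov is None and merge_revcomp:
                    rc = GenomicRegion(
                        region_id=pool[ib].region_id,
                        scaffold_ids=pool[ib].scaffold_ids,
                        sequence=revcomp(pool[ib].sequence),
                        origin_hsp_ids=pool[ib].origin_hsp_ids)
                    ov_rc = find_overlap(pool[ia].sequence, rc.sequence, min_overlap)
                    if ov_rc is not None:
                        log.warning("reverse-complement overlap %s/%s merged", ia, ib)
                        pool[ib] = rc
                        ov = ov_rc
                if ov is not None and (best is None or ov.length > best[0]):
                    best = (ov.length, ia, ib, ov)
        if best is not None:
            _, ia, ib, ov = best
            merged = _merge(pool[ia], pool[ib], ov)
            del pool[ia], pool[ib]
            pool[merged.region_id] = merged
            changed = True
    return [pool[k] for k in sorted(pool)]
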