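"""Segment search against the structural-alphabet sequence database (SADB).

Each binding segment's structural-alphabet slice is aligned locally
(Smith-Waterman with affine gaps, Gotoh recurrences) under the SASM against
every database string.  Databases here are desk-scale, so the search is
exhaustive rather than heuristically seeded; an optional exact k-mer
prefilter can skip entries sharing no 3-mer with the query segment.
Proteins hit on at least 75% of the query's segments become candidate
polypharmacological targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP, SASM, SAString

__all__ = [
    "SegmentHit",
    "Candidate",
    "smith_waterman",
    "search_segment",
    "collect_candidates",
    "self_score",
]

NEG = -(10**9)


@dataclass
class SegmentHit:
    segment_index: int
    db_id: str
    score: int  # half-bits
    query_span: tuple[int, int]  # 0-based half-open, in segment-slice coords
    db_span: tuple[int, int]  # 0-based half-open, in db-string coords
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (q0, d0), (q1, d1) in zip(self.aligned_pairs, self.aligned_pairs[1:]):
            if q1 <= q0 or d1 <= d0:
                raise ValueError("aligned pairs must strictly increase in both coordinates")


@dataclass
class Candidate:
    db_id: str
    matched_segments: frozenset[int]
    n_query_segments: int
    hits: list[SegmentHit] = field(default_factory=list)

    @property
    def match_fraction(self) -> float:
        return len(self.matched_segments) / self.n_query_segments

    @property
    def total_score(self) -> int:
        return sum(h.score for h in self.hits)


def smith_waterman(
    query: str, subject: str, sasm: SASM
) -> tuple[int, tuple[int, int], tuple[int, int], list[tuple[int, int]]]:
    """Best local alignment of two letter strings under the SASM with affine
    gap penalties.  Returns (score, query_span, subject_span, aligned_pairs),
    spans half-open.  Ties break to the smallest (query_end, subject_end) so
    the leftmost maximal alignment is reported deterministically.
    """
    n, m = len(query), len(subject)
    go, ge = sasm.gap_open, sasm.gap_extend
    # H: best ending in a match at (i, j); E: gap in query; F: gap in subject
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    sub = np.empty((n, m), dtype=np.int64)
    for i, a in enumerate(query):
        for j, b in enumerate(subject):
            sub[i, j] = sasm.score(a, b)

    best, best_pos = 0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            H[i, j] = max(0, H[i - 1, j - 1] + sub[i - 1, j - 1], E[i, j], F[i, j])
            if H[i, j] > best:
                best, best_pos = int(H[i, j]), (i, j)

    if best == 0:
        return 0, (0, 0), (0, 0), []

    # traceback
    pairs: list[tuple[int, int]] = []
    i, j = best_pos
    state = "H"
    end_q, end_s = i, j
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i, j] == H[i, j - 1] - go:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F
            if F[i, j] == H[i - 1, j] - go:
                i -= 1
                state = "H"
            else:
                i -= 1
    pairs.reverse()
    start_q = pairs[0][0] if pairs else i
    start_s = pairs[0][1] if pairs else j
    return best, (start_q, end_q), (start_s, end_s), pairs


def self_score(letters: str, sasm: SASM) -> int:
    """Ungapped score of a string against itself, skipping '-' positions."""
    return sum(sasm.score(c, c) for c in letters if c != GAP)


def _kmers(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1) if GAP not in s[i : i + k]}


def search_segment(
    query_slice: str,
    db: list[SAString],
    sasm: SASM,
    min_score: int,
    segment_index: int = 0,
    kmer_prefilter: bool = False,
    k: int = 3,
) -> list[SegmentHit]:
    """Best hit per database entry with score >= ``min_score``.

    The query slice is trimmed of leading/trailing '-' (undefined angles at
    chain ends); reported query coordinates are relative to the untrimmed
    slice.  Ordering and tie-breaks are deterministic: db input order, and
    within an entry the leftmost maximal alignment.
    """
    trim_left = len(query_slice) - len(query_slice.lstrip(GAP))
    trimmed = query_slice.strip(GAP)
    if not trimmed:
        raise ValueError("query segment has no defined structural letters")
    query_kmers = _kmers(trimmed, k) if kmer_prefilter else None

    hits: list[SegmentHit] = []
    for entry in db:
        if kmer_prefilter and not (query_kmers & _kmers(entry.letters, k)):
            continue
        score, qspan, sspan, pairs = smith_waterman(trimmed, entry.letters, sasm)
        if score >= min_score and pairs:
            hits.append(
                SegmentHit(
                    segment_index=segment_index,
                    db_id=entry.complex_id,
                    score=score,
                    query_span=(qspan[0] + trim_left, qspan[1] + trim_left),
                    db_span=sspan,
                    aligned_pairs=[(q + trim_left, d) for q, d in pairs],
                )
            )
    return hits


def collect_candidates(
    hits_per_segment: list[list[SegmentHit]],
    n_segments: int,
    threshold: float = 0.75,
    inclusive: bool = True,
) -> list[Candidate]:
    """Proteins hit on a sufficient fraction of query segments.

    ``inclusive=True`` accepts match_fraction == threshold (3 of 4 segments
    at the default 0.75); sorted by match fraction, then total score, then id.
    """
    if n_segments < 1:
        raise ValueError("need at least one query segment")
    by_db: dict[str, dict[int, SegmentHit]] = {}
    for seg_hits in hits_per_segment:
        for hit in seg_hits:
            slot = by_db.setdefault(hit.db_id, {})
            prev = slot.get(hit.segment_index)
            if prev is None or hit.score > prev.score:
                slot[hit.segment_index] = hit
    candidates = []
    for db_id, best in by_db.items():
        cand = Candidate(
            db_id=db_id,
            matched_segments=frozenset(best),
            n_query_segments=n_segments,
            hits=[best[i] for i in sorted(best)],
        )
        frac = cand.match_fraction
        ok = frac >= threshold if inclusive else frac > threshold
        if ok:
            candidates.append(cand)
    candidates.sort(key=lambda c: (-c.match_fraction, -c.total_score, c.db_id))
    return candidates
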