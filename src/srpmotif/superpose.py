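"""Structural alignment of discontinuous binding segments onto candidates.

Residue correspondences are seeded by each segment's structural-alphabet
local alignment, then refined geometrically: Kabsch least-squares
superposition over all aligned Calphas of all segments jointly, re-pairing
by nearest Calpha within 5 A along matched segments, and repeating until the
pairing is stable (at most five rounds).  A candidate becomes a
polypharmacological target when the joint Calpha RMSD is at most 2.0 A and
the average aligned ratio — aligned residues over segment length, averaged
over segments with unmatched segments counting 0 — is at least 0.85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding_interface import BindingInterface
from .sa_search import Candidate
from .structio import Chain

__all__ = [
    "SegmentAlignment",
    "PolypharmTarget",
    "segment_correspondence",
    "kabsch_superpose",
    "refine_correspondence",
    "align_candidate",
    "select_targets",
    "sequence_identity",
]

REFINE_CUTOFF = 5.0  # A; re-pairing radius during refinement
MAX_REFINE_ITER = 20  # refinement stops early once the pairing is stable


@dataclass
class SegmentAlignment:
    """Residue pairing between the query's binding segments and one candidate.

    ``pairs_per_segment[k]`` holds (query_pos, target_pos) chain-coordinate
    pairs for segment k (empty when the segment went unmatched)."""

    pairs_per_segment: list[list[tuple[int, int]]]
    segment_lengths: list[int]

    def aligned_ratios(self) -> list[float]:
        return [
            len(pairs) / length
            for pairs, length in zip(self.pairs_per_segment, self.segment_lengths)
        ]

    @property
    def avg_aligned_ratio(self) -> float:
        ratios = self.aligned_ratios()
        return sum(ratios) / len(ratios) if ratios else 0.0

    def all_pairs(self) -> list[tuple[int, int]]:
        return [p for seg in self.pairs_per_segment for p in seg]


@dataclass
class PolypharmTarget:
    db_id: str
    rmsd: float
    avg_aligned_ratio: float
    seq_identity_pct: float | None
    rotation: np.ndarray  # (3, 3) proper rotation applied to target coords
    translation: np.ndarray  # (3,)
    alignment: SegmentAlignment = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")


def segment_correspondence(
    interface: BindingInterface,
    candidate: Candidate,
    query_chain: Chain,
    target_chain: Chain,
) -> SegmentAlignment:
    """Initial residue pairing from the candidate's per-segment hits.

    Hit pairs are in segment-slice / db-string coordinates; here they are
    mapped to chain positions and restricted to residues with a Calpha.
    Unmatched segments contribute no pairs (aligned ratio 0).
    """
    by_segment = {h.segment_index: h for h in candidate.hits}
    query_ca = query_chain.ca_coords()
    target_ca = target_chain.ca_coords()
    pairs_per_segment: list[list[tuple[int, int]]] = []
    for k, seg in enumerate(interface.segments):
        pairs: list[tuple[int, int]] = []
        hit = by_segment.get(k)
        if hit is not None:
            for q_rel, d_pos in hit.aligned_pairs:
                q_pos = seg.start + q_rel
                if not np.any(np.isnan(query_ca[q_pos])) and not np.any(
                    np.isnan(target_ca[d_pos])
                ):
                    pairs.append((q_pos, d_pos))
        pairs_per_segment.append(pairs)
    return SegmentAlignment(
        pairs_per_segment=pairs_per_segment,
        segment_lengths=[len(seg) for seg in interface.segments],
    )


def kabsch_superpose(
    query_xyz: np.ndarray, target_xyz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of target onto query coordinates.

    Returns (rotation, translation, rmsd) with the reflection corrected so
    the rotation is proper; applying ``xyz @ R.T + t`` to target coordinates
    moves them onto the query frame.
    """
    query_xyz = np.asarray(query_xyz, dtype=float)
    target_xyz = np.asarray(target_xyz, dtype=float)
    if query_xyz.shape != target_xyz.shape or query_xyz.ndim != 2 or query_xyz.shape[0] < 3:
        raise ValueError("underdetermined superposition: need >= 3 coordinate pairs")
    qc = query_xyz.mean(axis=0)
    tc = target_xyz.mean(axis=0)
    P = target_xyz - tc
    Q = query_xyz - qc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10:
        raise ValueError("underdetermined superposition: degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ tc
    moved = target_xyz @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - query_xyz) ** 2, axis=1))))
    return R, t, rmsd


def _monotone_nearest(
    seg_positions: range,
    query_ca: np.ndarray,
    moved_target_ca: np.ndarray,
    db_window: range,
    cutoff: float = REFINE_CUTOFF,
) -> list[tuple[int, int]]:
    """Nearest-Calpha re-pairing within a segment, kept strictly increasing
    in both coordinates (longest increasing subsequence on target index,
    ties resolved toward shorter distance)."""
    candidates: list[tuple[int, int, float]] = []
    for q in seg_positions:
        if np.any(np.isnan(query_ca[q])):
            continue
        best_d, best_t = None, None
        for t_pos in db_window:
            if t_pos < 0 or t_pos >= len(moved_target_ca):
                continue
            if np.any(np.isnan(moved_target_ca[t_pos])):
                continue
            d = float(np.linalg.norm(query_ca[q] - moved_target_ca[t_pos]))
            if d < cutoff and (best_d is None or d < best_d):
                best_d, best_t = d, t_pos
        if best_t is not None:
            candidates.append((q, best_t, best_d))
    # longest strictly-increasing chain in target positions (q already increasing)
    if not candidates:
        return []
    n = len(candidates)
    length = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if candidates[j][1] < candidates[i][1] and length[j] + 1 > length[i]:
                length[i] = length[j] + 1
                prev[i] = j
    best_i = int(np.argmax(length))
    chain: list[tuple[int, int]] = []
    while best_i != -1:
        chain.append(candidates[best_i][:2])
        best_i = prev[best_i]
    chain.reverse()
    return chain


def refine_correspondence(
    alignment: SegmentAlignment,
    interface: BindingInterface,
    query_chain: Chain,
    target_chain: Chain,
    matched_segments: frozenset[int] | None = None,
    max_iter: int = MAX_REFINE_ITER,
) -> tuple[SegmentAlignment, np.ndarray, np.ndarray, float]:
    """Alternate Kabsch superposition and nearest-Calpha re-pairing until the
    pairing is fixed.  Returns the refined alignment plus (R, t, rmsd).

    ``matched_segments`` limits re-pairing to segments the search matched
    (segments without a hit stay unaligned and count 0 toward the aligned
    ratio); by default it is the set of segments seeded with pairs.
    """
    query_ca = query_chain.ca_coords()
    target_ca = target_chain.ca_coords()
    if matched_segments is None:
        matched_segments = frozenset(
            k for k, pairs in enumerate(alignment.pairs_per_segment) if pairs
        )

    current = alignment
    R = np.eye(3)
    t = np.zeros(3)
    rmsd = float("inf")
    for _ in range(max_iter):
        pairs = current.all_pairs()
        if len(pairs) < 3:
            break
        q_idx = [p[0] for p in pairs]
        t_idx = [p[1] for p in pairs]
        try:
            R, t, rmsd = kabsch_superpose(query_ca[q_idx], target_ca[t_idx])
        except ValueError:
            break
        moved = target_ca @ R.T + t
        new_segments: list[list[tuple[int, int]]] = []
        for k, seg in enumerate(interface.segments):
            if k not in matched_segments:
                new_segments.append([])  # unmatched segments stay unmatched
                continue
            new_segments.append(
                _monotone_nearest(
                    seg.positions, query_ca, moved, range(len(target_ca))
                )
            )
        new = SegmentAlignment(
            pairs_per_segment=new_segments,
            segment_lengths=current.segment_lengths,
        )
        if new.pairs_per_segment == current.pairs_per_segment:
            current = new
            break
        current = new
    # final superposition on the settled pairing
    pairs = current.all_pairs()
    if len(pairs) >= 3:
        q_idx = [p[0] for p in pairs]
        t_idx = [p[1] for p in pairs]
        try:
            R, t, rmsd = kabsch_superpose(query_ca[q_idx], target_ca[t_idx])
        except ValueError:
            pass
    return current, R, t, rmsd


def sequence_identity(
    alignment: SegmentAlignment, query_chain: Chain, target_chain: Chain
) -> float | None:
    """Percent identical amino acids over aligned pairs; None when nothing
    is aligned."""
    pairs = alignment.all_pairs()
    if not pairs:
        return None
    same = sum(
        1
        for q, t in pairs
        if query_chain.residues[q].aa == target_chain.residues[t].aa
    )
    return 100.0 * same / len(pairs)


def align_candidate(
    interface: BindingInterface,
    candidate: Candidate,
    query_chain: Chain,
    target_chain: Chain,
) -> PolypharmTarget | None:
    """Full alignment of one candidate: SA-seeded correspondence, iterative
    Kabsch refinement, aligned ratio and sequence identity.  None when the
    correspondence is too small to superpose."""
    seed = segment_correspondence(interface, candidate, query_chain, target_chain)
    if len(seed.all_pairs()) < 3:
        return None
    matched = frozenset(k for k, pairs in enumerate(seed.pairs_per_segment) if pairs)

    # A repeated local geometry can tie a segment's best alignment onto the
    # wrong copy, or shift its register within a regular run, and poison the
    # joint superposition.  Refinement is therefore multi-start — the full
    # seeding plus every subset of one or two matched segments — and the
    # consensus is the start whose refined superposition places the most
    # residue pairs tightly (within 1.5 A), then highest aligned ratio, then
    # lowest RMSD.
    subsets: list[tuple[int, ...]] = [tuple(sorted(matched))]
    singles = sorted(matched)
    subsets += [(k,) for k in singles]
    subsets += [
        (a, b) for i, a in enumerate(singles) for b in singles[i + 1 :]
    ]
    query_ca = query_chain.ca_coords()
    target_ca = target_chain.ca_coords()

    refined, R, t, rmsd, best_key = None, None, None, float("inf"), None
    for subset in subsets:
        per_segment = [
            list(pairs) if k in subset else []
            for k, pairs in enumerate(seed.pairs_per_segment)
        ]
        start = SegmentAlignment(
            pairs_per_segment=per_segment, segment_lengths=seed.segment_lengths
        )
        if len(start.all_pairs()) < 3:
            continue
        cand_refined, cand_R, cand_t, cand_rmsd = refine_correspondence(
            start, interface, query_chain, target_chain, matched_segments=matched
        )
        pairs = cand_refined.all_pairs()
        if len(pairs) < 3 or not np.isfinite(cand_rmsd):
            continue
        moved = target_ca @ cand_R.T + cand_t
        dists = [
            float(np.linalg.norm(query_ca[q] - moved[d])) for q, d in pairs
        ]
        n_tight = sum(1 for d in dists if d < 1.5)
        key = (n_tight, cand_refined.avg_aligned_ratio, -cand_rmsd)
        if best_key is None or key > best_key:
            refined, R, t, rmsd, best_key = cand_refined, cand_R, cand_t, cand_rmsd, key
    if refined is None:
        return None
    return PolypharmTarget(
        db_id=candidate.db_id,
        rmsd=rmsd,
        avg_aligned_ratio=refined.avg_aligned_ratio,
        seq_identity_pct=sequence_identity(refined, query_chain, target_chain),
        rotation=R,
        translation=t,
        alignment=refined,
    )


def select_targets(
    aligned: list[PolypharmTarget],
    rmsd_max: float = 2.0,
    ar_min: float = 0.85,
    inclusive: bool = True,
) -> list[PolypharmTarget]:
    """Keep candidates passing the similarity thresholds; boundaries are
    inclusive by default (RMSD <= 2.0 and AR >= 0.85).  Sorted by RMSD then
    id, the ordering used for reporting."""
    kept = []
    for target in aligned:
        if inclusive:
            ok = target.rmsd <= rmsd_max and target.avg_aligned_ratio >= ar_min
        else:
            ok = target.rmsd < rmsd_max and target.avg_aligned_ratio > ar_min
        if ok:
            kept.append(target)
    kept.sort(key=lambda t: (t.rmsd, t.db_id))
    return kept
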