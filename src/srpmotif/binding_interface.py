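"""Contact residues and discontinuous binding segments.

A residue is a ligand contact when any of its atoms lies strictly within
4 A of any ligand atom.  Each contact seeds a segment extended seven
residues up- and downstream (15 residues when not clipped by a terminus);
segments sharing at least one position merge transitively, so the binding
environment comes out as a set of disjoint, spatially discontinuous
segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import Complex

__all__ = [
    "BindingSegment",
    "BindingInterface",
    "contact_residues",
    "extract_segments",
]


@dataclass
class BindingSegment:
    chain_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based inclusive
    contact_positions: frozenset[int]
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")
        if not self.contact_positions:
            raise ValueError("segment must contain a contact position")
        if not all(self.start <= p <= self.end for p in self.contact_positions):
            raise ValueError("contacts must lie inside the segment")
        if len(self) < 15 and not self.truncated:
            raise ValueError("untruncated segments are at least 15 residues")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class BindingInterface:
    complex_id: str
    segments: list[BindingSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start <= a.end:
                raise ValueError("segments must be disjoint after merging")

    def __len__(self) -> int:
        return len(self.segments)

    def to_tsv(self) -> str:
        lines = ["# complex_id\tstart\tend_exclusive\tcontacts (0-based half-open spans)"]
        for seg in self.segments:
            contacts = ",".join(str(p) for p in sorted(seg.contact_positions))
            lines.append(f"{self.complex_id}\t{seg.start}\t{seg.end + 1}\t{contacts}")
        return "\n".join(lines) + "\n"


def contact_residues(complex_: Complex, cutoff: float = 4.0) -> set[int]:
    """0-based indices of residues with any atom strictly within ``cutoff`` A
    of any ligand atom.  A residue with no atoms is never a contact."""
    ligand_xyz = np.array([a.coords for a in complex_.ligand.atoms])
    if ligand_xyz.size == 0:
        raise ValueError("ligand has no atoms")
    contacts: set[int] = set()
    for i, res in enumerate(complex_.chain.residues):
        if not res.atoms:
            continue
        res_xyz = np.array([a.coords for a in res.atoms])
        if cdist(res_xyz, ligand_xyz).min() < cutoff:  # strict
            contacts.add(i)
    return contacts


def extract_segments(
    contacts: set[int],
    chain_length: int,
    extend: int = 7,
    complex_id: str = "",
) -> BindingInterface:
    """Binding segments from contact indices: extend each contact ``extend``
    residues both ways, clamp at chain bounds (flagging truncation), and merge
    intervals sharing at least one residue.  Order-independent."""
    if any(c < 0 or c >= chain_length for c in contacts):
        raise ValueError("contact index outside chain")
    if not contacts:
        warnings.warn("no binding environment: contact set is empty", stacklevel=2)
        return BindingInterface(complex_id=complex_id, segments=[])

    intervals = []
    for c in sorted(contacts):
        start, end = c - extend, c + extend
        truncated = start < 0 or end > chain_length - 1
        intervals.append(
            (max(0, start), min(chain_length - 1, end), {c}, truncated)
        )

    merged: list[list] = []
    for start, end, cset, truncated in intervals:  # sorted by start
        if merged and start <= merged[-1][1]:  # share >= 1 position
            last = merged[-1]
            last[1] = max(last[1], end)
            last[2] |= cset
            last[3] = last[3] or truncated
        else:
            merged.append([start, end, set(cset), truncated])

    chain_id = complex_id[-1] if complex_id else ""
    segments = [
        BindingSegment(
            chain_id=chain_id,
            start=s,
            end=e,
            contact_positions=frozenset(cs),
            truncated=t,
        )
        for s, e, cs, t in merged
    ]
    return BindingInterface(complex_id=complex_id, segments=segments)
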