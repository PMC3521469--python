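"""Pharma-motifs: structure-anchored MSA, conservation grades, PROSITE
patterns, and motif-consistency arithmetic.

The MSA is master-slave: columns are the query's binding-segment positions,
and each accepted target contributes one row by dropping its aligned residue
into the paired query column (gap elsewhere); targets are never re-aligned
against each other.

Conservation grading is a deterministic surrogate for a Rate4Site run: each
column scores the mean BLOSUM62 similarity (normalised to [0, 1]) of target
residues to the query residue, gaps scoring 0, and the [0, 1] score range is
cut into nine equal-width bins giving grades 1..9 with 9 the most conserved.
Grading each column on a fixed scale (rather than ranking columns against
each other) keeps grades monotone: adding a target identical to the query
can never demote a column.  Genuine Rate4Site per-site output can be
imported instead, bypassing the surrogate.

Positions graded below 4 render as the PROSITE wildcard 'x'; other columns
render the observed residue set as a literal or bracket set, and runs of
wildcards compress to x(n).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .binding_interface import BindingInterface
from .structio import Chain
from .superpose import PolypharmTarget

__all__ = [
    "InterfaceMSA",
    "ConservationProfile",
    "PharmaMotif",
    "build_msa",
    "conservation_grades",
    "read_rate4site_grades",
    "emit_pattern",
    "prosite_to_regex",
    "pattern_matches",
    "overlapped_ratio",
    "consistency_percent",
    "motifs_per_complex",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

MSA_GAP = "-"
X_THRESHOLD = 4  # grades below this render as 'x'


@dataclass
class InterfaceMSA:
    """Query-anchored alignment of the binding segments across all targets.

    ``rows`` maps row id -> list of per-segment strings; each string has one
    character per query position of that segment (residue letter or '-').
    The query row, first in ``row_ids``, never contains gaps."""

    query_id: str
    segments: list[tuple[int, int]]  # (start, end) inclusive, query coords
    row_ids: list[str]
    rows: dict[str, list[str]]

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def columns(self, segment_index: int) -> list[str]:
        """Column strings (one char per row) for a segment, query row first."""
        start, end = self.segments[segment_index]
        length = end - start + 1
        return [
            "".join(self.rows[rid][segment_index][i] for rid in self.row_ids)
            for i in range(length)
        ]

    def to_fasta(self) -> str:
        out = []
        for rid in self.row_ids:
            out.append(f">{rid}")
            out.append("".join(self.rows[rid]))
        return "\n".join(out) + "\n"


@dataclass
class ConservationProfile:
    """Per-query-position conservation grade, 1 (variable) .. 9 (conserved)."""

    grades: dict[int, int]  # query position -> grade
    method_tag: str = "surrogate"

    def __post_init__(self) -> None:
        for pos, grade in self.grades.items():
            if not 1 <= grade <= 9:
                raise ValueError(f"grade out of range at position {pos}: {grade}")


@dataclass
class PharmaMotif:
    segment_index: int
    pattern: str
    elements: list[str]  # one per column, pre-compression
    span: tuple[int, int]  # query coords, inclusive
    interacting_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if len(self.elements) != self.span[1] - self.span[0] + 1:
            raise ValueError("one pattern element per segment column required")
        prosite_to_regex(self.pattern)  # must parse

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


def build_msa(
    interface: BindingInterface,
    query_chain: Chain,
    targets: list[PolypharmTarget],
    target_chains: dict[str, Chain],
    query_id: str = "query",
) -> InterfaceMSA:
    """Master-slave MSA over the binding segments.

    Each target row places its aligned residue at the paired query column and
    a gap everywhere else; a target missing a segment yields an all-gap row
    for that segment.
    """
    if not targets:
        raise ValueError("no pharma-interface: zero polypharmacological targets")
    segments = [(seg.start, seg.end) for seg in interface.segments]
    row_ids = [query_id] + [t.db_id for t in targets]
    rows: dict[str, list[str]] = {
        query_id: [
            query_chain.sequence()[start : end + 1] for start, end in segments
        ]
    }
    for target in targets:
        chain = target_chains[target.db_id]
        seg_rows = []
        for k, (start, end) in enumerate(segments):
            cells = [MSA_GAP] * (end - start + 1)
            for q_pos, t_pos in target.alignment.pairs_per_segment[k]:
                cells[q_pos - start] = chain.residues[t_pos].aa
            seg_rows.append("".join(cells))
        rows[target.db_id] = seg_rows
    return InterfaceMSA(query_id=query_id, segments=segments, row_ids=row_ids, rows=rows)


def _similarity(a: str, b: str) -> float:
    """BLOSUM62 similarity normalised to [0, 1]: the score clipped at zero
    over the geometric mean of the two self-scores, so identical residues
    score exactly 1; gaps and unknown letters score 0."""
    if MSA_GAP in (a, b):
        return 0.0
    try:
        s = float(_BLOSUM62[a, b])
        saa = float(_BLOSUM62[a, a])
        sbb = float(_BLOSUM62[b, b])
    except (KeyError, IndexError):
        return 0.0
    return max(0.0, s) / np.sqrt(saa * sbb)


def conservation_grades(msa: InterfaceMSA) -> ConservationProfile:
    """Surrogate conservation grades from the MSA (see module docstring).

    The column score is the mean similarity of the non-query rows to the
    query residue; grade = 1 + floor(9 * score), capped at 9.
    """
    if msa.n_rows < 2:
        raise ValueError("conservation needs at least two MSA rows")
    grades: dict[int, int] = {}
    for k, (start, _end) in enumerate(msa.segments):
        for offset, column in enumerate(msa.columns(k)):
            query_aa = column[0]
            sims = [_similarity(query_aa, c) for c in column[1:]]
            score = sum(sims) / len(sims)
            grades[start + offset] = min(9, 1 + int(score * 9.0))
    return ConservationProfile(grades=grades, method_tag="surrogate")


def read_rate4site_grades(text: str, positions: list[int]) -> ConservationProfile:
    """Import per-site conservation grades from a Rate4Site-style output.

    Expects whitespace-separated data lines ``site residue grade`` (comment
    lines start with '#'); sites are 1-based over the query interface
    positions given in ``positions`` order, grades integral in 1..9.
    """
    grades: dict[int, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        site = int(fields[0])
        grade = int(round(float(fields[2])))
        grades[positions[site - 1]] = grade
    return ConservationProfile(grades=grades, method_tag="rate4site-import")


def _column_element(column: str, grade: int, x_threshold: int) -> str:
    if grade < x_threshold:
        return "x"
    observed = [c for c in column if c != MSA_GAP]
    # distinct residues ordered by descending column frequency, then alphabet
    distinct = sorted(set(observed), key=lambda c: (-observed.count(c), c))
    if len(distinct) == 1:
        return distinct[0]
    return "[" + "".join(distinct) + "]"


def _compress(elements: list[str]) -> str:
    out: list[str] = []
    i = 0
    while i < len(elements):
        if elements[i] == "x":
            j = i
            while j < len(elements) and elements[j] == "x":
                j += 1
            run = j - i
            out.append("x" if run == 1 else f"x({run})")
            i = j
        else:
            out.append(elements[i])
            i += 1
    return "-".join(out)


def emit_pattern(
    msa: InterfaceMSA,
    profile: ConservationProfile,
    interface: BindingInterface,
    x_threshold: int = X_THRESHOLD,
) -> list[PharmaMotif]:
    """One PROSITE-syntax pharma-motif per binding segment.

    Columns graded below ``x_threshold`` become the wildcard 'x'; others list
    the residues observed in the column (single residue -> literal, several
    -> bracket set).  Runs of two or more wildcards compress to x(n).
    """
    motifs: list[PharmaMotif] = []
    for k, (start, end) in enumerate(msa.segments):
        elements = [
            _column_element(column, profile.grades[start + offset], x_threshold)
            for offset, column in enumerate(msa.columns(k))
        ]
        motifs.append(
            PharmaMotif(
                segment_index=k,
                pattern=_compress(elements),
                elements=elements,
                span=(start, end),
                interacting_positions=interface.segments[k].contact_positions,
            )
        )
    return motifs


_ELEMENT_RE = re.compile(
    r"^(?:(?P<literal>[A-Z])|\[(?P<set>[A-Z]{2,})\]|\{(?P<notset>[A-Z]+)\}"
    r"|(?P<x>x)(?:\((?P<count>\d+)\))?)$"
)


def prosite_to_regex(pattern: str) -> str:
    """Translate a PROSITE pattern into a Python regular expression.

    Supports literals, bracket sets [ST], exclusion sets {P}, and wildcards
    x / x(n); raises ValueError on anything that does not parse.
    """
    parts = []
    for element in pattern.split("-"):
        m = _ELEMENT_RE.match(element)
        if not m:
            raise ValueError(f"invalid PROSITE element: {element!r}")
        if m.group("literal"):
            parts.append(m.group("literal"))
        elif m.group("set"):
            parts.append(f"[{m.group('set')}]")
        elif m.group("notset"):
            parts.append(f"[^{m.group('notset')}]")
        else:
            count = m.group("count")
            parts.append("." * (int(count) if count else 1))
    return "".join(parts)


def pattern_matches(pattern: str, sequence: str) -> bool:
    """True when the PROSITE pattern matches the sequence exactly end to end."""
    return re.fullmatch(prosite_to_regex(pattern), sequence) is not None


def overlapped_ratio(span_a: tuple[int, int], span_b: tuple[int, int]) -> float:
    """Motif-consistency overlap on a shared coordinate system.

    Spans are inclusive residue intervals of the two motifs on the same
    protein; the ratio is the overlap length divided by the shorter motif's
    length (the max of the two per-motif fractions)."""
    lo = max(span_a[0], span_b[0])
    hi = min(span_a[1], span_b[1])
    overlap = max(0, hi - lo + 1)
    len_a = span_a[1] - span_a[0] + 1
    len_b = span_b[1] - span_b[0] + 1
    return max(overlap / len_a, overlap / len_b)


def consistency_percent(flags: list[bool]) -> int:
    """Percent of motifs consistent with a reference set, nearest percent."""
    if not flags:
        raise ValueError("no motif comparisons to summarize")
    return round(100.0 * sum(flags) / len(flags))


def motifs_per_complex(counts: list[int]) -> int:
    """Average number of motifs per complex, reported to the nearest integer."""
    if not counts:
        raise ValueError("no complexes to summarize")
    return round(sum(counts) / len(counts))
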