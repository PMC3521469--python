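"""Precision/recall of predicted polypharmacological targets against GO
biological-process and molecular-function terms, SCOP sccs codes, and CATH
codes.

A prediction is a true positive when it shares at least one annotation term
with its query under the chosen scheme; database proteins sharing a term
with the query but not predicted are false negatives.  Targets with no
annotation under the scheme are counted as false positives by default (the
conservative convention) or excluded.  Counts are pooled (micro-averaged)
over all queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

__all__ = [
    "AnnotationTable",
    "EvaluationResult",
    "SCHEMES",
    "is_same_annotation",
    "precision_recall",
    "evaluate_run",
]

SCHEMES = ("BP", "MF", "SCOP", "CATH")
UNANNOTATED = "unannotated"


@dataclass
class AnnotationTable:
    """Per-protein term sets under each scheme; empty set = unannotated."""

    terms: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def get(self, protein_id: str, scheme: str) -> set[str]:
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        return self.terms.get(protein_id, {}).get(scheme, set())

    def add(self, protein_id: str, scheme: str, term: str) -> None:
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        self.terms.setdefault(protein_id, {}).setdefault(scheme, set()).add(term)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        """Read a TSV of (protein id, scheme, term), one term per line."""
        table = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            protein_id, scheme, term = line.split("\t")
            table.add(protein_id, scheme.upper(), term)
        return table

    def to_tsv(self, path) -> None:
        lines = []
        for protein_id in sorted(self.terms):
            for scheme in SCHEMES:
                for term in sorted(self.terms[protein_id].get(scheme, ())):
                    lines.append(f"{protein_id}\t{scheme}\t{term}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EvaluationResult:
    scheme: str
    tp: int
    fp: int
    fn: int
    n_predicted: int
    n_positives_db: int
    precision: float | None
    recall: float | None

    def as_percent(self) -> tuple[float | None, float | None]:
        """(precision, recall) on the reporting scale: percent, 1 decimal."""
        pct = lambda x: None if x is None else round(100 * x, 1)
        return pct(self.precision), pct(self.recall)


def is_same_annotation(
    query_id: str, target_id: str, table: AnnotationTable, scheme: str, match_mode: str = "any"
) -> bool | str:
    """Whether a target shares the query's annotation under a scheme.

    Returns True/False, or the string "unannotated" when the target carries
    no term under the scheme.  ``match_mode='any'`` requires a non-empty term
    intersection (proteins carry many GO terms; requiring full equality would
    be far stricter); ``'all'`` requires set equality.
    """
    query_terms = table.get(query_id, scheme)
    if not query_terms:
        raise ValueError(f"query {query_id!r} unannotated under {scheme}")
    target_terms = table.get(target_id, scheme)
    if not target_terms:
        return UNANNOTATED
    if match_mode == "any":
        return bool(query_terms & target_terms)
    if match_mode == "all":
        return query_terms == target_terms
    raise ValueError(f"unknown match_mode {match_mode!r}")


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float | None, float | None]:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), exact rational arithmetic;
    None where the denominator is zero (undefined, reported as missing)."""
    precision = float(Fraction(tp, tp + fp)) if tp + fp else None
    recall = float(Fraction(tp, tp + fn)) if tp + fn else None
    if tp == 0 and tp + fp and tp + fn:
        return 0.0, 0.0
    return precision, recall


def evaluate_run(
    predictions: dict[str, list[str]],
    db_ids: list[str],
    table: AnnotationTable,
    scheme: str,
    unannotated_policy: str = "count-as-fp",
    match_mode: str = "any",
) -> EvaluationResult:
    """Pooled evaluation over all queries.

    ``predictions`` maps each query id to its predicted target ids;
    ``db_ids`` is the searchable database (the universe for false
    negatives).  Queries unannotated under the scheme are skipped.
    ``unannotated_policy`` decides whether predicted targets without
    annotations count as false positives (default, the conservative
    convention) or are excluded from the counts.
    """
    if unannotated_policy not in ("count-as-fp", "exclude"):
        raise ValueError(f"unknown unannotated_policy {unannotated_policy!r}")
    tp = fp = fn = n_predicted = n_positives = 0
    for query_id, target_ids in predictions.items():
        if not table.get(query_id, scheme):
            continue  # scheme not applicable to this query
        predicted = set(target_ids)
        for target_id in target_ids:
            verdict = is_same_annotation(query_id, target_id, table, scheme, match_mode)
            if verdict == UNANNOTATED:
                if unannotated_policy == "count-as-fp":
                    fp += 1
                    n_predicted += 1
                continue
            n_predicted += 1
            if verdict:
                tp += 1
            else:
                fp += 1
        for db_id in db_ids:
            if db_id in predicted:
                continue
            verdict = is_same_annotation(query_id, db_id, table, scheme, match_mode)
            if verdict is True:
                fn += 1
    n_positives = tp + fn
    precision, recall = precision_recall(tp, fp, fn)
    return EvaluationResult(
        scheme=scheme,
        tp=tp,
        fp=fp,
        fn=fn,
        n_predicted=n_predicted,
        n_positives_db=n_positives,
        precision=precision,
        recall=recall,
    )
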