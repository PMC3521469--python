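"""End-to-end orchestration: build a structural-alphabet database, run a
query complex through segment extraction, search, superposition and motif
emission, and write the report files.

Every numeric threshold lives in :class:`RunConfig` and is serialized into
the run manifest, so a report can always be traced back to the exact
settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import defaults
from .alphabet import GAP, SASM, Codebook, SAString, encode
from .binding_interface import BindingInterface, contact_residues, extract_segments
from .motifs import InterfaceMSA, PharmaMotif, build_msa, conservation_grades, emit_pattern
from .sa_search import collect_candidates, search_segment, self_score
from .structio import Complex, read_complex
from .superpose import PolypharmTarget, align_candidate, select_targets

logger = logging.getLogger("srpmotif")

__all__ = ["RunConfig", "QueryResult", "build_db", "run_query", "run_query_paths"]


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline with their published defaults."""

    contact_cutoff: float = 4.0  # A, strict upper bound for contacts
    extend: int = 7  # residues added both ways around a contact
    segment_match: float = 0.75  # fraction of segments a candidate must hit
    segment_match_inclusive: bool = True
    rmsd_max: float = 2.0  # A
    ar_min: float = 0.85
    filter_inclusive: bool = True
    x_threshold: int = 4  # grades below this render as 'x'
    overlap_cutoff: float = 0.5
    min_score_frac: float = 0.6  # hit threshold as fraction of self-score
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.segment_match <= 1:
            raise ValueError("segment_match must be in (0, 1]")
        if not 0 <= self.ar_min <= 1:
            raise ValueError("ar_min must be in [0, 1]")
        if self.contact_cutoff <= 0 or self.rmsd_max < 0 or self.extend < 0:
            raise ValueError("invalid threshold")
        if not 0 < self.min_score_frac <= 1:
            raise ValueError("min_score_frac must be in (0, 1]")
        if not 1 <= self.x_threshold <= 9:
            raise ValueError("x_threshold must be a grade in 1..9")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class QueryResult:
    query: Complex
    interface: BindingInterface
    targets: list[PolypharmTarget]
    msa: InterfaceMSA | None
    motifs: list[PharmaMotif]
    config: RunConfig

    def target_table(self) -> str:
        """TSV report of the accepted targets (RMSD 1 decimal, AR 2, SI 1)."""
        lines = ["db_id\trmsd\taligned_ratio\tseq_identity_pct"]
        for t in self.targets:
            si = "-" if t.seq_identity_pct is None else f"{t.seq_identity_pct:.1f}"
            lines.append(f"{t.db_id}\t{t.rmsd:.1f}\t{t.avg_aligned_ratio:.2f}\t{si}")
        return "\n".join(lines) + "\n"

    def motif_flatfile(self) -> str:
        """PROSITE-style flat text: ID/PA lines per pharma-motif."""
        lines = []
        for motif in self.motifs:
            lines.append(f"ID   {self.query.id}_motif{motif.segment_index + 1}; PATTERN.")
            lines.append(f"PA   {motif.pattern}.")
            lines.append("//")
        return "\n".join(lines) + "\n"


def build_db(
    complexes: list[Complex], codebook: Codebook | None = None
) -> list[SAString]:
    """Encode complexes into the searchable structural-alphabet database."""
    if not complexes:
        raise ValueError("no structures to index")
    codebook = codebook or defaults.default_codebook()
    db = []
    for cpx in complexes:
        sa = encode(cpx.chain, codebook)
        sa.complex_id = cpx.id
        db.append(sa)
    return db


def write_sadb(db: list[SAString], path) -> None:
    Path(path).write_text(
        "".join(f">{sa.complex_id}\n{sa.letters}\n" for sa in db)
    )


def read_sadb(path) -> list[SAString]:
    db = []
    current_id = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            current_id = line[1:].strip()
        elif line.strip():
            db.append(SAString(complex_id=current_id, letters=line.strip()))
    return db


def build_db_from_dir(pdb_dir, chain_id: str, het_code: str, codebook=None):
    """Index every parseable PDB file in a directory; unparseable files are
    skipped with a logged warning."""
    complexes, skipped = [], 0
    for path in sorted(Path(pdb_dir).glob("*.pdb")):
        try:
            complexes.append(read_complex(path, chain_id, het_code))
        except Exception as exc:  # corrupt entry: skip, keep building
            skipped += 1
            logger.warning("skipping %s: %s", path.name, exc)
    if not complexes:
        raise ValueError(f"no parseable structures in {pdb_dir}")
    if skipped:
        logger.warning("skipped %d unparseable file(s)", skipped)
    return build_db(complexes), complexes


def run_query(
    query: Complex,
    db: list[SAString],
    db_complexes: dict[str, Complex],
    config: RunConfig | None = None,
    codebook: Codebook | None = None,
    sasm: SASM | None = None,
) -> QueryResult:
    """The full pipeline for one query complex against a database.

    Stages: contact residues -> binding segments -> structural-alphabet
    search per segment -> candidate filter -> iterative Kabsch superposition
    -> RMSD/aligned-ratio target filter -> master-slave MSA -> conservation
    grades -> PROSITE pharma-motifs.
    """
    config = config or RunConfig()
    codebook = codebook or defaults.default_codebook()
    sasm = sasm or defaults.default_sasm()

    contacts = contact_residues(query, cutoff=config.contact_cutoff)
    if not contacts:
        raise ValueError("no binding environment: no residue within contact cutoff")
    interface = extract_segments(
        contacts, len(query.chain), extend=config.extend, complex_id=query.id
    )
    logger.info("%s: %d contacts, %d binding segments", query.id, len(contacts), len(interface))

    query_sa = encode(query.chain, codebook)
    query_sa.complex_id = query.id
    hits_per_segment = []
    for k, seg in enumerate(interface.segments):
        segment_slice = query_sa.letters[seg.start : seg.end + 1]
        min_score = int(round(config.min_score_frac * self_score(segment_slice, sasm)))
        hits = search_segment(segment_slice, db, sasm, min_score, segment_index=k)
        hits_per_segment.append(hits)
        logger.info("segment %d [%d..%d]: %d hits", k, seg.start, seg.end, len(hits))

    candidates = collect_candidates(
        hits_per_segment,
        n_segments=len(interface),
        threshold=config.segment_match,
        inclusive=config.segment_match_inclusive,
    )
    logger.info("%d candidate(s) pass the segment-match filter", len(candidates))

    aligned = []
    for cand in candidates:
        target = align_candidate(
            interface, cand, query.chain, db_complexes[cand.db_id].chain
        )
        if target is not None:
            aligned.append(target)
    targets = select_targets(
        aligned,
        rmsd_max=config.rmsd_max,
        ar_min=config.ar_min,
        inclusive=config.filter_inclusive,
    )
    logger.info("%d polypharmacological target(s)", len(targets))

    if not targets:
        logger.warning("zero targets: motif stage skipped")
        return QueryResult(query, interface, [], None, [], config)

    msa = build_msa(
        interface,
        query.chain,
        targets,
        {t.db_id: db_complexes[t.db_id].chain for t in targets},
        query_id=query.id,
    )
    profile = conservation_grades(msa)
    motifs = emit_pattern(msa, profile, interface, x_threshold=config.x_threshold)
    logger.info("%d pharma-motif(s)", len(motifs))
    return QueryResult(query, interface, targets, msa, motifs, config)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_query_paths(
    pdb_path,
    chain_id: str,
    het_code: str,
    db_dir,
    out_dir,
    config: RunConfig | None = None,
    db_chain_id: str = "A",
    db_het_code: str = "LIG",
) -> QueryResult:
    """File-level entry point: read query and database from PDB files, run
    the pipeline, and write the report files plus a JSON manifest."""
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    query = read_complex(pdb_path, chain_id, het_code)
    db, db_complexes = build_db_from_dir(db_dir, db_chain_id, db_het_code)
    result = run_query(query, db, {c.id: c for c in db_complexes}, config=config)

    (out_dir / "targets.tsv").write_text(result.target_table())
    (out_dir / "interface.tsv").write_text(result.interface.to_tsv())
    if result.msa is not None:
        (out_dir / "interface_msa.fasta").write_text(result.msa.to_fasta())
        (out_dir / "pharma_motifs.prosite").write_text(result.motif_flatfile())
    manifest = {
        "config": dataclasses.asdict(config),
        "query": {"path": str(pdb_path), "sha256": _sha256(pdb_path)},
        "db": {
            str(p.name): _sha256(p) for p in sorted(Path(db_dir).glob("*.pdb"))
        },
        "counts": {
            "segments": len(result.interface),
            "targets": len(result.targets),
            "motifs": len(result.motifs),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
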