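# Methods

This note records the models, conventions and numerical choices behind
`srpmotif`, and what the synthetic world does and does not establish.

## Coordinate model

Structures are reduced to one chain of ordered residues plus one HET ligand.
All segment arithmetic uses 0-based positional indices into the residue list;
author numbering (seq id + insertion code) is carried only for reporting.
Alternate locations keep the highest-occupancy copy (ties: first in file);
modified residues map to their parent amino acid where known, else `X`; only
the first model of multi-model files is read. Multi-chain interfaces are out
of contract: a query is a single chain and its ligand.

## Binding segments

Contact rule: strict `min_atom_pair_distance < 4.0 Å` (an atom at exactly
4.0 Å is not a contact). Each contact extends ±7 residues; windows are
clamped at chain bounds (the segment is kept and flagged `truncated` rather
than discarded, so terminal interface chemistry is not silently dropped) and
merged when they share at least one residue. Clamp-then-merge makes the
result independent of contact processing order, which is property-tested.

## Structural alphabet

Angles per residue i (defined for 2 ≤ i ≤ n−3 when all five Cα exist):

* κ(i): bend between (Cα<sub>i</sub>−Cα<sub>i−2</sub>) and
  (Cα<sub>i+2</sub>−Cα<sub>i</sub>), 0° = straight. 0°-straight is the
  convention recorded in `Codebook.version_tag`, so encodings from different
  conventions can never be mixed silently.
* α(i): torsion over Cα<sub>i−1</sub>..Cα<sub>i+2</sub>, IUPAC sign
  (right-handed α-helix ≈ +50°). Collinear windows have an undefined torsion
  and encode as `-`.

The codebook holds 23 (κ, α) centroids under
d = √(Δκ² + Δα²<sub>circ</sub>) with α circular. Training is
farthest-point seeding (first seed drawn from the given rng) plus Lloyd
refinement with a circular mean for α — deterministic for a fixed seed and
input order. Letters `A..W` are assigned in descending cluster-population
order. Encoding takes the nearest centroid; ties break to the alphabetically
first letter; undefined positions encode `-`.

The substitution matrix (SASM) follows the BLOSUM recipe on structural
letters: counts over aligned columns with +1 pseudocount per unordered pair
cell, q<sub>ij</sub> normalised frequencies, p<sub>i</sub> marginals,
s<sub>ij</sub> = round(2·log₂(q<sub>ij</sub>/(p<sub>i</sub>p<sub>j</sub>(2−δ<sub>ij</sub>)))),
i.e. half-bit units. Gap penalties default to open 8 / extend 2 (half-bits);
`-` scores −4 against everything. The published encoder's codebook and
matrix are not public, so the shipped defaults are trained at import time,
fully seeded, on synthetic geometry: block-regular traces, a helix, a
strand, random walks, and noise-0.3 Å perturbed copies of each — 0.3 Å
being the homolog noise level assumed throughout, so the matrix learns
exactly the letter confusions rigid-body noise induces. Externally trained
codebook/SASM files are accepted in their plain-text formats.

## Segment search

Exhaustive Smith–Waterman (Gotoh affine-gap recurrences) of each segment's
trimmed letter string against every database string; desk-scale databases
make heuristic seeding unnecessary. Per database entry the best local
alignment is kept if its score reaches `min_score_frac` (default 0.6) of the
segment's ungapped self-score — a length-adaptive threshold standing in for
E-values. An optional exact 3-mer prefilter skips entries sharing no 3-mer;
it is off by default because it is not provably lossless, and a property
test checks it leaves the hit set unchanged on the synthetic world.
Candidates must match ≥ 75 % of query segments; the boundary is inclusive
(3 of 4 segments qualifies) and exposed as a flag.

## Superposition and target selection

Correspondence seeding takes each segment's aligned letter pairs, then
alternates joint Kabsch superposition (SVD, reflection corrected) with
re-pairing each query-segment residue to its nearest target Cα within 5 Å,
kept strictly increasing along both chains (longest-increasing-subsequence
filter), until the pairing is stable, at most 20 rounds. Because a repeated
block of local geometry can tie a segment's best letter alignment onto the
wrong copy — or shift its register inside a regular run — refinement is
multi-start: seeded from the full pairing and from every one- and
two-segment subset, and the winner is the start whose final superposition
places the most pairs within 1.5 Å (then highest aligned ratio, then lowest
RMSD). Targets pass at RMSD ≤ 2.0 Å and average aligned ratio ≥ 0.85;
segments without a hit count ratio 0 in the average; boundaries are
inclusive and configurable. RMSD is over Cα only. External correspondences
(e.g. from a dedicated structure-alignment program) can be supplied in place
of the internal seeding.

## Conservation surrogate and patterns

The MSA is master–slave: columns are query positions; each target drops its
paired residue into the query column, gap elsewhere; targets are never
re-aligned to each other. Full Bayesian rate estimation over a phylogeny is
out of scope, so the per-column grade is a deterministic surrogate: the mean
over target rows of BLOSUM62 similarity to the query residue, normalised as
max(0, s(a,b)) / √(s(a,a)·s(b,b)) so identity scores exactly 1 and gaps 0,
then binned on the fixed [0, 1] range as grade = min(9, 1 + ⌊9·score⌋).
Grading each column on a fixed scale (instead of ranking columns against
each other) makes grades monotone — appending a row identical to the query
can never demote a column — and keeps a fully conserved column at grade 9
regardless of context. Genuine per-site Rate4Site output can be imported
instead; the profile records which path produced it.

Columns with grade < 4 (the wildcard calibration threshold) render as `x`;
other columns render every residue observed in the column (no frequency
floor), ordered by descending frequency then alphabetically — single residue
as a literal, several as a bracket set. Runs of ≥ 2 wildcards compress to
`x(n)`. By construction every emitted pattern matches the query's own
sequence, which is asserted as an invariant. Motif-vs-reference consistency
uses span intersection on the same protein: ratio = max(overlap/len_a,
overlap/len_b), consistent at ≥ 0.5.

## Evaluation

"Same annotation" means a non-empty term-set intersection (GO terms as
given, no ancestor propagation; SCOP at full sccs; CATH at the full
four-number code) — set equality is far stricter than how multi-term
annotations are used in practice, but is available via `match_mode="all"`.
Counts are pooled across queries; predicted targets without annotation under
a scheme count as false positives by default or can be excluded; false
negatives are annotation-sharing database proteins that were not predicted.
Precision/recall use exact rational arithmetic before rounding to the
1-decimal-percent reporting scale.

## Synthetic world

Templates are 60-residue traces built from blocks (8–14 residues) of
constant virtual bend/torsion drawn from a palette of eight well-separated
geometries — locally regular like real secondary structure, globally
non-repetitive. An ideal helix is deliberately *not* used as a template: it
encodes as a single repeated letter and its screw symmetry lets wrong
registers superpose at RMSD ≈ 0, a degeneracy real binding sites lack (the
helix, strand and random-walk generators exist for unit tests and decoys).
The pseudo-ligand places one heavy atom 3.5 Å from each designated contact
Cα along the direction of maximal clearance from all other residues
(deterministic Fibonacci-sphere search), padded to ≥ 6 heavy atoms.
Planted homologs get i.i.d. Gaussian coordinate jitter (default σ = 0.3 Å
per axis), a random rigid motion, and residue mutations at rate 0.5 except
at contact positions, which never mutate; decoys are self-avoiding random
walks with 3.8 Å bonds. All generators are pure functions of their seeds.

A green synthetic run establishes the machinery — strict contact rule,
extension/merging, encoding stability, search selectivity, superposition
filters, conservation contrast between planted-conserved and free columns,
pattern round-trips — with exact ground truth. It does not establish
performance on real crystal structures: side chains, solvent, crystal
contacts, genuine evolutionary substitution patterns and real fold-space
letter statistics are all absent, and the dataset-scale published figures
(counts of motifs, conservation percentages, per-scheme precision levels)
depend on a specific historical database snapshot that is not reproduced
here.

## Known limitations

* Single chain, single ligand, first model only; no multi-chain interfaces.
* The internal correspondence engine replaces a contact-map structural
  aligner; it preserves the accept/reject contract but not that program's
  scores or Z-statistics.
* The conservation surrogate is not an evolutionary rate model; for
  fidelity runs import real per-site output.
* No E-value statistics for the letter search; the self-score fraction
  threshold is length-adaptive but database-size blind.
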