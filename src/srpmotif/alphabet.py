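"""23-state structural alphabet over (kappa, alpha) backbone angles, plus the
BLOSUM-style structural-alphabet substitution matrix (SASM).

Local backbone geometry at residue i is summarized by two internal
coordinates computed from the Calpha trace alone:

* kappa(i) — virtual bend angle between the direction vectors
  (Ca_i - Ca_{i-2}) and (Ca_{i+2} - Ca_i); 0 deg means a straight trace.
* alpha(i) — virtual torsion over Ca_{i-1}, Ca_i, Ca_{i+1}, Ca_{i+2},
  in (-180, 180].

Both need two flanking Calphas, so they are defined exactly at 0-based
positions 2..n-4 intersected with 1..n-3, i.e. 2..n-3; a chain therefore
always encodes '-' at its first two and last two positions.  A codebook of 23
(kappa, alpha) centroids turns each defined pair into a letter, giving a 1D
string that a sequence-search engine can handle; a log-odds substitution
matrix over those letters, built by the BLOSUM62 recipe from aligned string
pairs, scores the search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AnglePair",
    "Codebook",
    "SAString",
    "SASM",
    "compute_angles",
    "train_codebook",
    "encode",
    "build_sasm",
    "LETTERS",
]

LETTERS = "ABCDEFGHIJKLMNOPQRSTUVW"  # 23 symbols
GAP = "-"

#: degenerate torsions (collinear neighbours) flagged undefined below this
_DEGENERATE_CROSS = 1e-8


@dataclass(frozen=True)
class AnglePair:
    kappa: float | None  # degrees in [0, 180], None if undefined
    alpha: float | None  # degrees in (-180, 180], None if undefined

    @property
    def defined(self) -> bool:
        return self.kappa is not None and self.alpha is not None


@dataclass
class Codebook:
    letters: str
    centroids: list[tuple[float, float]]  # (kappa, alpha) per letter
    version_tag: str = "bend0-kappa/dssp-alpha"

    def __post_init__(self) -> None:
        if len(self.letters) != len(self.centroids):
            raise ValueError("one centroid per letter required")
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("letters must be distinct")

    def to_text(self) -> str:
        lines = [f"# codebook version_tag={self.version_tag}"]
        for letter, (kappa, alpha) in zip(self.letters, self.centroids):
            lines.append(f"{letter}\t{kappa:.4f}\t{alpha:.4f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Codebook":
        tag = "unknown"
        letters, centroids = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "version_tag=" in line:
                    tag = line.split("version_tag=", 1)[1].strip()
                continue
            letter, kappa, alpha = line.split("\t")
            letters.append(letter)
            centroids.append((float(kappa), float(alpha)))
        return cls(letters="".join(letters), centroids=centroids, version_tag=tag)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "Codebook":
        return cls.from_text(Path(path).read_text())


@dataclass
class SAString:
    complex_id: str
    letters: str  # over codebook letters + '-' for undefined positions

    def __len__(self) -> int:
        return len(self.letters)


@dataclass
class SASM:
    letters: str
    scores: np.ndarray  # (k, k) int, half-bit units
    gap_open: int = 8
    gap_extend: int = 2
    undefined_score: int = -4  # '-' positions are hard mismatches

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        k = len(self.letters)
        if self.scores.shape != (k, k):
            raise ValueError("score matrix shape must match letters")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("SASM must be symmetric")
        self._index = {c: i for i, c in enumerate(self.letters)}

    def score(self, a: str, b: str) -> int:
        if a == GAP or b == GAP:
            return self.undefined_score
        return int(self.scores[self._index[a], self._index[b]])

    def to_text(self) -> str:
        lines = [
            f"# sasm gap_open={self.gap_open} gap_extend={self.gap_extend}"
            f" undefined={self.undefined_score}",
            "\t".join(self.letters),
        ]
        for row in self.scores:
            lines.append("\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SASM":
        gap_open, gap_extend, undefined = 8, 2, -4
        rows: list[list[int]] = []
        letters = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        key, val = tok.split("=")
                        if key == "gap_open":
                            gap_open = int(val)
                        elif key == "gap_extend":
                            gap_extend = int(val)
                        elif key == "undefined":
                            undefined = int(val)
                continue
            if letters is None:
                letters = "".join(line.split("\t"))
            else:
                rows.append([int(v) for v in line.split("\t")])
        return cls(
            letters=letters,
            scores=np.array(rows),
            gap_open=gap_open,
            gap_extend=gap_extend,
            undefined_score=undefined,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "SASM":
        return cls.from_text(Path(path).read_text())


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(p0, p1, p2, p3) -> float | None:
    """Signed torsion, IUPAC convention (a right-handed alpha-helix trace
    gives approximately +50 deg)."""
    if (
        np.linalg.norm(np.cross(p1 - p0, p2 - p1)) < _DEGENERATE_CROSS
        or np.linalg.norm(np.cross(p2 - p1, p3 - p2)) < _DEGENERATE_CROSS
    ):
        return None  # collinear segment: torsion undefined
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return math.degrees(math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def compute_angles(chain) -> list[AnglePair]:
    """(kappa, alpha) per residue; ``None`` components where any required
    Calpha is missing or the torsion is geometrically degenerate."""
    ca = chain.ca_coords()
    n = len(ca)
    out: list[AnglePair] = []
    for i in range(n):
        kappa = alpha = None
        if 2 <= i <= n - 3:
            window = ca[i - 2 : i + 3]
            if not np.any(np.isnan(window)):
                u = ca[i] - ca[i - 2]
                v = ca[i + 2] - ca[i]
                if np.linalg.norm(u) > 1e-9 and np.linalg.norm(v) > 1e-9:
                    kappa = _angle_between(u, v)
                alpha = _dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
        out.append(AnglePair(kappa=kappa, alpha=alpha))
    return out


def _angle_dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    dk = a[0] - b[0]
    da = abs(a[1] - b[1])
    da = min(da, 360.0 - da)
    return math.hypot(dk, da)


def _circular_mean_deg(values: np.ndarray) -> float:
    rad = np.deg2rad(values)
    mean = math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    return mean if mean > -180.0 else 180.0


def train_codebook(
    angles: list[AnglePair],
    k: int = 23,
    rng_seed: int = 0,
    n_iter: int = 50,
    version_tag: str = "bend0-kappa/dssp-alpha",
) -> Codebook:
    """Cluster defined (kappa, alpha) pairs into ``k`` centroids.

    Nearest-neighbour clustering under d = sqrt(dkappa^2 + dalpha_circ^2)
    with alpha treated circularly: farthest-point seeding (first seed drawn
    from the rng) followed by Lloyd-style refinement with a circular mean for
    alpha.  Deterministic for a fixed seed and input order.  Letters are
    assigned to centroids in descending cluster-population order.
    """
    points = [(ap.kappa, ap.alpha) for ap in angles if ap.defined]
    if len(points) < k:
        raise ValueError(f"need at least k={k} defined angle pairs, got {len(points)}")
    rng = np.random.default_rng(rng_seed)
    pts = np.array(points)

    # farthest-point seeding
    centroids = [tuple(pts[rng.integers(len(pts))])]
    dist = np.array([_angle_dist(tuple(p), centroids[0]) for p in pts])
    while len(centroids) < k:
        idx = int(np.argmax(dist))
        centroids.append(tuple(pts[idx]))
        dist = np.minimum(dist, [_angle_dist(tuple(p), centroids[-1]) for p in pts])

    assign = np.zeros(len(pts), dtype=int)
    for _ in range(n_iter):
        new_assign = np.array(
            [int(np.argmin([_angle_dist(tuple(p), c) for c in centroids])) for p in pts]
        )
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for j in range(k):
            member = pts[assign == j]
            if len(member):
                centroids[j] = (
                    float(np.mean(member[:, 0])),
                    _circular_mean_deg(member[:, 1]),
                )

    # letters in descending population order; ties by centroid order
    population = np.bincount(assign, minlength=k)
    order = sorted(range(k), key=lambda j: (-population[j], j))
    ordered = [centroids[j] for j in order]
    return Codebook(letters=LETTERS[:k], centroids=ordered, version_tag=version_tag)


def encode(chain, codebook: Codebook) -> SAString:
    """Structural-alphabet string for a chain: nearest centroid per defined
    (kappa, alpha) pair (ties break to the alphabetically first letter),
    '-' elsewhere.  Invariant under rigid motion of the coordinates."""
    letters = []
    for pair in compute_angles(chain):
        if not pair.defined:
            letters.append(GAP)
            continue
        best_letter, best_d = None, None
        for letter, centroid in sorted(zip(codebook.letters, codebook.centroids)):
            d = _angle_dist((pair.kappa, pair.alpha), centroid)
            if best_d is None or d < best_d - 1e-12:
                best_letter, best_d = letter, d
        letters.append(best_letter)
    complex_id = getattr(chain, "chain_id", "?")
    return SAString(complex_id=complex_id, letters="".join(letters))


def build_sasm(
    pairs: list[tuple[str, str]],
    letters: str = LETTERS,
    scale: float = 2.0,
    gap_open: int = 8,
    gap_extend: int = 2,
) -> SASM:
    """BLOSUM-style log-odds matrix from aligned structural-letter strings.

    Each input pair contributes its aligned columns (equal-length strings;
    columns containing '-' are skipped).  With a +1 pseudocount per unordered
    letter pair: q_ij = f_ij / sum(f); background p_i from marginals;
    s_ij = round(scale * log2(q_ij / (p_i p_j (2 - delta_ij)))).  ``scale=2``
    gives half-bit units as in BLOSUM62.
    """
    k = len(letters)
    index = {c: i for i, c in enumerate(letters)}
    counts = np.ones((k, k))  # +1 pseudocount per unordered pair cell
    counts = np.triu(counts)
    n_columns = 0
    for s1, s2 in pairs:
        if len(s1) != len(s2):
            raise ValueError("aligned strings must have equal length")
        for a, b in zip(s1, s2):
            if a == GAP or b == GAP:
                continue
            i, j = sorted((index[a], index[b]))
            counts[i, j] += 1
            n_columns += 1
    if n_columns == 0:
        raise ValueError("no aligned columns to train on")

    total = counts[np.triu_indices(k)].sum()
    q = counts / total  # upper-triangular q_ij
    p = np.zeros(k)
    for i in range(k):
        p[i] = q[i, i] + 0.5 * (q[i, i + 1 :].sum() + q[:i, i].sum())

    scores = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            expected = p[i] * p[j] * (1.0 if i == j else 2.0)
            s = round(scale * math.log2(q[min(i, j), max(i, j)] / expected))
            scores[i, j] = scores[j, i] = s
    return SASM(letters=letters, scores=scores, gap_open=gap_open, gap_extend=gap_extend)
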