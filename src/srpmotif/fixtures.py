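"""Synthetic complexes with known ground truth.

Real inputs to the pipeline are drug-bound crystal structures and a structure
database; neither can be bundled, so this module generates a stand-in world:
ideal Calpha traces (helices, strands), pseudo-ligands planted within contact
range of chosen residues, noisy/mutated homolog copies of a template (the
planted true targets), and self-avoiding random-walk decoys.  All generators
are pure functions of their seeds.

The whole method runs on Calpha + ligand coordinates only (contacts use any
atom a residue has; the structural alphabet uses Calpha), so fixtures emit
Calpha-only chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Atom, Chain, Complex, Ligand, Residue

__all__ = [
    "SyntheticTruth",
    "make_helix",
    "make_strand",
    "make_random_walk",
    "plant_ligand",
    "perturb_homolog",
    "build_synthetic_db",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: contact positions used for the synthetic template query
TEMPLATE_CONTACTS = (10, 30, 50)
TEMPLATE_LENGTH = 60


@dataclass
class SyntheticTruth:
    """Which database entries are planted homologs vs. decoys, and which
    query positions carry conserved (never-mutated) residues."""

    db_ids: list[str]
    planted_target_ids: list[str]
    decoy_ids: list[str]
    conserved_positions: list[int]
    seed: int

    def __post_init__(self) -> None:
        planted, decoys = set(self.planted_target_ids), set(self.decoy_ids)
        if planted & decoys:
            raise ValueError("planted and decoy ids overlap")
        if planted | decoys != set(self.db_ids):
            raise ValueError("planted + decoys must partition db_ids")


def _chain_from_coords(coords: np.ndarray, sequence: str, chain_id: str = "A") -> Chain:
    residues = [
        Residue(
            chain_id=chain_id,
            seq_id=i + 1,
            insertion_code="",
            aa=sequence[i],
            atoms=[Atom(name="CA", element="C", coords=coords[i])],
        )
        for i in range(len(coords))
    ]
    return Chain(chain_id=chain_id, residues=residues)


def _sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def make_helix(
    n: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    seq_seed: int = 0,
) -> Chain:
    """Calpha-only chain on an ideal helix (defaults approximate an alpha-helix:
    1.5 A rise, 100 deg twist, 2.3 A radius -> 3.8 A Calpha-Calpha).

    ``radius=0`` degenerates to a collinear trace (bend angle 0 everywhere).
    """
    if n < 5:
        raise ValueError("need n >= 5: bend/torsion angles undefined otherwise")
    theta = np.deg2rad(twist) * np.arange(n)
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)]
    )
    rng = np.random.default_rng(seq_seed)
    return _chain_from_coords(coords, _sequence(n, rng))


def make_strand(n: int, seq_seed: int = 0) -> Chain:
    """Extended zigzag trace approximating a beta-strand (3.8 A bonds,
    ~3.3 A rise per residue)."""
    if n < 5:
        raise ValueError("need n >= 5")
    rise = 3.3
    amp = np.sqrt(3.8**2 - rise**2) / 2.0
    x = amp * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    coords = np.column_stack([x, np.zeros(n), rise * np.arange(n)])
    rng = np.random.default_rng(seq_seed)
    return _chain_from_coords(coords, _sequence(n, rng))


def make_random_walk(n: int, rng_seed: int, bond: float = 3.8, min_sep: float = 3.4) -> Chain:
    """Self-avoiding random walk with fixed 3.8 A bond length — a decoy trace
    with no homology to any regular secondary structure."""
    if n < 5:
        raise ValueError("need n >= 5")
    rng = np.random.default_rng(rng_seed)
    coords = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    while len(coords) < n:
        for _ in range(200):
            # bounded turn keeps adjacent geometry chain-like
            perturbation = rng.normal(scale=0.8, size=3)
            cand_dir = direction + perturbation
            cand_dir /= np.linalg.norm(cand_dir)
            cand = coords[-1] + bond * cand_dir
            prior = np.array(coords[:-1]) if len(coords) > 1 else np.empty((0, 3))
            if prior.size == 0 or np.min(np.linalg.norm(prior - cand, axis=1)) >= min_sep:
                coords.append(cand)
                direction = cand_dir
                break
        else:  # pragma: no cover - restart on a dead end
            coords, direction = [np.zeros(3)], np.array([1.0, 0.0, 0.0])
    return _chain_from_coords(np.array(coords), _sequence(n, rng))


def _fibonacci_sphere(n: int = 256) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _clearest_direction(ca_all: np.ndarray, p: int, offset: float) -> np.ndarray:
    """Unit direction from residue p's Calpha that keeps a point ``offset``
    away as far as possible from every *other* residue — so planting there
    creates exactly the intended contact regardless of chain geometry."""
    ca = ca_all[p]
    others = np.delete(ca_all, p, axis=0)
    others = others[~np.any(np.isnan(others), axis=1)]
    dirs = _fibonacci_sphere()
    points = ca + offset * dirs  # (n_dirs, 3)
    # min distance to any other residue, per candidate direction
    dmin = np.min(np.linalg.norm(points[:, None, :] - others[None, :, :], axis=2), axis=1)
    return dirs[int(np.argmax(dmin))]


#: (virtual bond angle, virtual torsion) palette for locally regular traces;
#: well separated in angle space so encodings are stable under coordinate noise
GEOMETRY_PALETTE = (
    (92.0, 50.0),    # alpha-helix-like
    (120.0, -170.0), # extended / strand-like
    (100.0, 100.0),
    (130.0, 60.0),
    (95.0, -60.0),
    (110.0, 150.0),
    (85.0, -130.0),
    (125.0, -40.0),
)


def _extend_trace(p1, p2, p3, bond: float, angle_deg: float, torsion_deg: float):
    """Next point from three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(torsion) * np.sin(angle),
            bond * np.sin(torsion) * np.sin(angle),
        ]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def make_varied_chain(n: int, rng_seed: int, block_len: tuple[int, int] = (8, 14)) -> Chain:
    """Irregular but locally regular Calpha trace: consecutive blocks of
    constant (bend, torsion) internal coordinates drawn from a palette of
    well-separated geometries.

    This is the model of a real single-domain backbone used for synthetic
    queries and homolog templates: proteins are mostly runs of regular
    secondary structure, so their structural-letter strings are stable under
    coordinate noise yet varied enough along the chain to anchor local
    alignments unambiguously (an ideal helix, by contrast, encodes as one
    repeated letter and every window matches every other).
    """
    if n < 5:
        raise ValueError("need n >= 5")
    rng = np.random.default_rng(rng_seed)
    bond = 3.8
    coords = [
        np.zeros(3),
        np.array([bond, 0.0, 0.0]),
        np.array([bond + bond * np.cos(np.deg2rad(60)), bond * np.sin(np.deg2rad(60)), 0.0]),
    ]
    while len(coords) < n:
        block = int(rng.integers(block_len[0], block_len[1] + 1))
        angle, torsion = GEOMETRY_PALETTE[rng.integers(len(GEOMETRY_PALETTE))]
        for _ in range(block):
            if len(coords) >= n:
                break
            coords.append(
                _extend_trace(coords[-3], coords[-2], coords[-1], bond, angle, torsion)
            )
    return _chain_from_coords(np.array(coords), _sequence(n, rng))


def plant_ligand(
    chain: Chain,
    positions: list[int],
    offset: float = 3.5,
    het_code: str = "LIG",
    min_heavy: int = 6,
) -> Complex:
    """Place a pseudo-ligand so that exactly the listed residues are within
    ``offset`` A of an atom: one heavy atom per position, ``offset`` A from
    the residue's Calpha along the outward radial direction (away from the
    chain centroid), padded to ``min_heavy`` atoms with a stack of extra
    atoms further out along the first position's radial direction.
    """
    n = len(chain)
    if any(p < 0 or p >= n for p in positions):
        raise ValueError("ligand positions out of chain range")
    ca_all = chain.ca_coords()
    atoms: list[Atom] = []
    outward_first = None
    for p in positions:
        ca = chain.residues[p].ca.coords
        outward = _clearest_direction(ca_all, p, offset)
        if outward_first is None:
            outward_first = (ca, outward)
        # bias one part in 1e12 outward so the realized distance never
        # rounds below the nominal offset (the contact rule is strict)
        atoms.append(
            Atom(
                name=f"C{len(atoms) + 1}",
                element="C",
                coords=ca + offset * (1.0 + 1e-12) * outward,
            )
        )
    k = 1
    while len(atoms) < min_heavy:
        ca, outward = outward_first
        atoms.append(
            Atom(
                name=f"C{len(atoms) + 1}",
                element="C",
                coords=ca + (offset + 0.4 * k) * outward,
            )
        )
        k += 1
    return Complex(id="synthetic", chain=chain, ligand=Ligand(het_code=het_code, atoms=atoms))


def perturb_homolog(
    complex_: Complex,
    noise_sd: float,
    mutation_rate: float,
    rng_seed: int,
    conserved_positions: tuple[int, ...] = (),
    new_id: str | None = None,
) -> Complex:
    """Noisy, mutated, rigidly moved copy of a complex — an idealized remote
    homolog sharing the binding environment.

    Coordinates get i.i.d. Gaussian jitter per axis plus a random rotation and
    translation; residue identities mutate at ``mutation_rate`` except at
    ``conserved_positions``.  Deterministic for a fixed seed.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20.0, 20.0, size=3)
    conserved = set(conserved_positions)

    def move(xyz: np.ndarray) -> np.ndarray:
        return rot @ (xyz + rng.normal(scale=noise_sd, size=3)) + trans

    residues = []
    for i, res in enumerate(complex_.chain.residues):
        aa = res.aa
        if i not in conserved and rng.random() < mutation_rate:
            choices = [c for c in AA20 if c != aa]
            aa = choices[rng.integers(len(choices))]
        residues.append(
            Residue(
                chain_id=res.chain_id,
                seq_id=res.seq_id,
                insertion_code=res.insertion_code,
                aa=aa,
                atoms=[Atom(name=a.name, element=a.element, coords=move(a.coords)) for a in res.atoms],
            )
        )
    ligand = Ligand(
        het_code=complex_.ligand.het_code,
        atoms=[Atom(name=a.name, element=a.element, coords=move(a.coords)) for a in complex_.ligand.atoms],
    )
    return Complex(
        id=new_id or f"{complex_.id}_h{rng_seed}",
        chain=Chain(chain_id=complex_.chain.chain_id, residues=residues),
        ligand=ligand,
    )


def make_template_query(seed: int = 0) -> Complex:
    """The canonical synthetic query: a 60-residue self-avoiding trace with a
    pseudo-ligand contacting residues 10, 30 and 50 (three disjoint binding
    segments).

    Built from blocks of regular local geometry (see make_varied_chain) so
    the structural-letter string is noise-stable yet non-repetitive."""
    chain = make_varied_chain(TEMPLATE_LENGTH, rng_seed=seed * 11 + 7)
    query = plant_ligand(chain, list(TEMPLATE_CONTACTS), offset=3.5)
    query.id = "query0"
    return query


def build_synthetic_db(
    n_planted: int,
    n_decoys: int,
    rng_seed: int,
    noise_sd: float = 0.3,
    mutation_rate: float = 0.5,
) -> tuple[list[Complex], SyntheticTruth]:
    """Database of ``n_planted`` perturbed homologs of the template query plus
    ``n_decoys`` random-walk traces, with the truth table.

    Contact positions of the template are the conserved positions: homologs
    never mutate there (the conservation signal the motif stage must find)
    while free positions mutate at 0.5.
    """
    if n_planted < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    template = make_template_query(seed=rng_seed)
    conserved = TEMPLATE_CONTACTS
    complexes: list[Complex] = []
    planted_ids, decoy_ids = [], []
    for i in range(n_planted):
        hom = perturb_homolog(
            template,
            noise_sd=noise_sd,
            mutation_rate=mutation_rate,
            rng_seed=rng_seed * 1000 + i,
            conserved_positions=conserved,
            new_id=f"planted{i}",
        )
        complexes.append(hom)
        planted_ids.append(hom.id)
    for i in range(n_decoys):
        walk = make_random_walk(TEMPLATE_LENGTH, rng_seed=rng_seed * 2000 + 500 + i)
        decoy = plant_ligand(walk, [TEMPLATE_LENGTH // 2], offset=3.5)
        decoy.id = f"decoy{i}"
        complexes.append(decoy)
        decoy_ids.append(decoy.id)
    truth = SyntheticTruth(
        db_ids=planted_ids + decoy_ids,
        planted_target_ids=planted_ids,
        decoy_ids=decoy_ids,
        conserved_positions=list(conserved),
        seed=rng_seed,
    )
    return complexes, truth
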