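"""Structure input/output: a minimal coordinate model over PDB files.

The pipeline only needs, per protein chain, an ordered list of residues with
their atoms (contacts are any-atom), the Calpha trace (structural alphabet),
and a single HET ligand.  Everything downstream addresses residues by their
0-based position in ``Chain.residues``; author numbering (seq id + insertion
code) is carried along purely for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1_extended

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Ligand",
    "Complex",
    "read_complex",
    "write_structure",
    "ChainNotFoundError",
    "LigandNotFoundError",
]


class ChainNotFoundError(KeyError):
    """Requested chain id absent from the file."""


class LigandNotFoundError(KeyError):
    """Requested HET group absent from the file."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError("atom element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    insertion_code: str
    aa: str  # one-letter code or 'X'
    atoms: list[Atom] = field(default_factory=list)

    @property
    def ca(self) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.name == "CA":
                return atom
        return None

    @property
    def author_label(self) -> str:
        return f"{self.seq_id}{self.insertion_code}".strip()


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of Calpha coordinates; NaN rows where Calpha missing."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, res in enumerate(self.residues):
            ca = res.ca
            if ca is not None:
                out[i] = ca.coords
        return out

    def sequence(self) -> str:
        return "".join(res.aa for res in self.residues)


@dataclass
class Ligand:
    het_code: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if not a.is_hydrogen)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if not a.is_hydrogen])


@dataclass
class Complex:
    id: str
    chain: Chain
    ligand: Ligand


_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue name to one letter; modified residues fall back
    to their parent amino acid where known, else 'X'."""
    one = protein_letters_3to1_extended.get(resname.upper().strip(), "X")
    return one if one in _STANDARD else "X"


def _pick_altloc(bio_residue) -> list:
    """Keep highest-occupancy alternate location; ties resolve to file order."""
    chosen: dict[str, object] = {}
    for atom in bio_residue:
        if atom.is_disordered():
            best = max(
                atom.disordered_get_list(),
                key=lambda a: (a.get_occupancy() or 0.0),
            )
            chosen.setdefault(atom.get_id(), best)
        else:
            chosen.setdefault(atom.get_id(), atom)
    return list(chosen.values())


def read_complex(path, chain_id: str, het_code: str) -> Complex:
    """Read one chain's polymer plus one HET ligand from a PDB file.

    Only the first model is used.  Residues missing a Calpha are kept (with a
    warning); they simply encode as '-' in the structural alphabet and can
    still be ligand contacts through their other atoms.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())

    if chain_id not in [c.id for c in model]:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} in {path}")
    bio_chain = model[chain_id]

    residues: list[Residue] = []
    ligand_atoms: list[Atom] = []
    found_het = False
    for bio_res in bio_chain:
        hetflag, seq_id, icode = bio_res.get_id()
        atoms = [
            Atom(
                name=a.get_name(),
                element=(a.element or a.get_name()[0]).strip() or "X",
                coords=np.array(a.get_coord(), dtype=float),
            )
            for a in _pick_altloc(bio_res)
        ]
        if hetflag.strip() and hetflag != "W":
            if bio_res.get_resname().strip() == het_code:
                found_het = True
                ligand_atoms.extend(atoms)
            continue
        if hetflag == "W":
            continue
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_id=seq_id,
                insertion_code=icode.strip(),
                aa=three_to_one(bio_res.get_resname()),
                atoms=atoms,
            )
        )

    # the ligand may sit in its own chain in the file
    if not found_het:
        for other in model:
            for bio_res in other:
                hetflag = bio_res.get_id()[0]
                if hetflag.strip() and bio_res.get_resname().strip() == het_code:
                    found_het = True
                    ligand_atoms.extend(
                        Atom(
                            name=a.get_name(),
                            element=(a.element or a.get_name()[0]).strip() or "X",
                            coords=np.array(a.get_coord(), dtype=float),
                        )
                        for a in _pick_altloc(bio_res)
                    )
    if not found_het:
        raise LigandNotFoundError(f"ligand not found: {het_code!r} in {path}")

    n_no_ca = sum(1 for r in residues if r.ca is None)
    if n_no_ca:
        warnings.warn(
            f"{path.name}:{chain_id}: {n_no_ca} residue(s) without Calpha kept",
            stacklevel=2,
        )
    return Complex(
        id=f"{path.stem}{chain_id}",
        chain=Chain(chain_id=chain_id, residues=residues),
        ligand=Ligand(het_code=het_code, atoms=ligand_atoms),
    )


_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _atom_record(record, serial, atom, resname, chain_id, seq_id, icode):
    name = atom.name if len(atom.name) >= 4 else f" {atom.name}"
    return _ATOM_FMT.format(
        record=record,
        serial=serial,
        name=name[:4],
        altloc=" ",
        resname=resname[:3],
        chain=chain_id[:1] or "A",
        seq=seq_id,
        icode=icode[:1] or " ",
        x=atom.coords[0],
        y=atom.coords[1],
        z=atom.coords[2],
        occ=1.00,
        b=0.00,
        element=atom.element[:2].upper(),
    )


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


def write_structure(complex_: Complex, path) -> None:
    """Emit standard fixed-column PDB ATOM/HETATM records (8.3 coordinates)."""
    path = Path(path)
    serial = 1
    lines: list[str] = []
    for res in complex_.chain.residues:
        resname = _ONE_TO_THREE.get(res.aa, "UNK")
        for atom in res.atoms:
            lines.append(
                _atom_record(
                    "ATOM", serial, atom, resname,
                    res.chain_id, res.seq_id, res.insertion_code,
                )
            )
            serial += 1
    if complex_.chain.residues:
        lines.append("TER\n")
    for atom in complex_.ligand.atoms:
        lines.append(
            _atom_record(
                "HETATM", serial, atom, complex_.ligand.het_code,
                complex_.chain.chain_id, 1, " ",
            )
        )
        serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))
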