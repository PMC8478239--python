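"""Lightweight structural model over PDB files.

Parsing delegates to Bio.PDB; the classes here expose exactly what feature
extraction needs: heavy-atom coordinates, Cα B-factors, and het-group
(ligand) atoms. Alternate locations are collapsed to the highest-occupancy
conformer (ties broken by altloc identifier, so "A" wins) so that all
downstream geometry is single-conformer and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})
#: common monoatomic ions excluded from ligand candidates by default
ION_NAMES = frozenset({"NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD", "HG", "IOD", "BR"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for unparseable files, empty selections and bad queries."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    b_factor: float  # Å²

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if self.b_factor < 0:
            warnings.warn(f"atom {self.name}: negative B-factor {self.b_factor}", stacklevel=3)


@dataclass
class Residue:
    chain_id: str
    seq_number: int  # author numbering (the numbering variant names use)
    insertion_code: str
    aa_type: str  # three-letter label, standard or not
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.aa_type, "X")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """Parsed atomic model: ordered polymer residues per chain + het groups."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    het_groups: list[Residue] = field(default_factory=list)

    def residues(self, chain: Optional[str] = None) -> list[Residue]:
        if chain is not None:
            if chain not in self.chains:
                raise StructureError(
                    f"chain {chain!r} not present; available: {sorted(self.chains)}"
                )
            return list(self.chains[chain])
        return [r for ch in self.chains.values() for r in ch]

    def find_residue(self, seq_number: int, chain: Optional[str] = None,
                     insertion_code: str = "") -> Residue:
        for r in self.residues(chain):
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        raise StructureError(f"residue {seq_number}{insertion_code} not found"
                             + (f" in chain {chain}" if chain else ""))


def _pick_altloc(bio_atom):
    """Highest-occupancy conformer; ties resolved by altloc id (A first)."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def read_pdb(path, chain: Optional[str] = None) -> Structure:
    """Parse a PDB file into a Structure.

    Parameters
    ----------
    path : str or Path
        PDB-format text file.
    chain : str, optional
        Restrict polymer residues to this chain. Het groups on any chain are
        retained (ligands are often assigned their own chain id).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            model = parser.get_structure(path.stem, str(path))[0]
        except Exception as exc:  # noqa: BLE001 - normalise parser failures
            raise StructureError(f"could not parse PDB file {path}: {exc}") from exc

    structure = Structure()
    for bio_chain in model:
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.get_id()
            atoms = []
            for bio_atom in bio_res:
                a = _pick_altloc(bio_atom)
                atoms.append(Atom(
                    name=a.get_name(),
                    element=(a.element or "").strip() or a.get_name()[0],
                    coords=np.array(a.get_coord(), dtype=float),
                    b_factor=float(a.get_bfactor() or 0.0),
                ))
            res = Residue(
                chain_id=bio_chain.id,
                seq_number=int(resseq),
                insertion_code=icode.strip(),
                aa_type=bio_res.get_resname().strip(),
                atoms=atoms,
                is_polymer=(hetflag == " "),
            )
            if res.is_polymer:
                structure.chains.setdefault(bio_chain.id, []).append(res)
            else:
                structure.het_groups.append(res)

    if chain is not None:
        if chain not in structure.chains:
            raise StructureError(
                f"chain {chain!r} has no polymer residues; available: {sorted(structure.chains)}"
            )
        structure.chains = {chain: structure.chains[chain]}
    if not structure.chains and not structure.het_groups:
        raise StructureError(f"no atoms parsed from {path}")
    return structure


def ca_b_factor(structure: Structure, seq_number: int, chain: Optional[str] = None) -> float:
    """Crystallographic B-factor (Å²) of a residue's α-carbon.

    Returns NaN (an explicit missing value, never a silent 0) if the residue
    has no Cα atom.
    """
    res = structure.find_residue(seq_number, chain)
    ca = res.get_atom("CA")
    if ca is None:
        return float("nan")
    return ca.b_factor


def ligand_atoms(structure: Structure, ligand_selector: str,
                 include_ions: bool = False) -> list[Atom]:
    """Heavy atoms of all het groups matching ``ligand_selector``.

    Waters never match; monoatomic ions are excluded unless
    ``include_ions=True``.
    """
    name = ligand_selector.strip().upper()
    if name in WATER_NAMES:
        raise StructureError("waters are never ligand candidates")
    candidates = [g for g in structure.het_groups if g.aa_type.upper() not in WATER_NAMES]
    if not include_ions:
        candidates = [g for g in candidates if g.aa_type.upper() not in ION_NAMES]
    matched = [g for g in candidates if g.aa_type.upper() == name]
    if not matched:
        available = sorted({g.aa_type for g in candidates})
        raise StructureError(
            f"no het group named {ligand_selector!r}; available: {available}"
        )
    return [a for g in matched for a in g.heavy_atoms()]


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure back to minimal PDB text (ATOM/HETATM/TER/END)."""
    lines = []
    serial = 1

    def fmt(record: str, res: Residue, atom: Atom, serial: int) -> str:
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = atom.coords
        return (
            f"{record:<6s}{serial:>5d} {name:<4s} {res.aa_type:>3s} {res.chain_id:1s}"
            f"{res.seq_number:>4d}{res.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{atom.b_factor:6.2f}"
            f"          {atom.element:>2s}"
        )

    for chain_id in structure.chains:
        for res in structure.chains[chain_id]:
            for atom in res.atoms:
                lines.append(fmt("ATOM", res, atom, serial))
                serial += 1
        lines.append("TER")
    for res in structure.het_groups:
        for atom in res.atoms:
            lines.append(fmt("HETATM", res, atom, serial))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
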