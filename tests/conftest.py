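"""Shared fixtures: a small hand-built PDB file and synthetic structures."""

import numpy as np
import pytest

from pctopo.structure import read_pdb
from pctopo.synthetic import SyntheticStructureSpec, make_structure


def pdb_line(record, serial, name, resname, chain, resseq, x, y, z,
             occ=1.0, b=20.0, element="C", altloc=" ", icode=" "):
    name_f = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {name_f:<4s}{altloc}{resname:>3s} {chain}"
            f"{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def mini_pdb(tmp_path):
    """Three polymer residues, a glycerol het group, a water, and one
    altloc'd atom (A occupancy 0.6, B occupancy 0.4)."""
    lines = [
        pdb_line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N", b=10.0),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, b=10.0),
        pdb_line("ATOM", 3, "C", "ALA", "A", 1, 2.2, 1.2, 0.0, b=12.0),
        pdb_line("ATOM", 4, "N", "LEU", "A", 2, 3.5, 1.2, 0.0, element="N", b=20.0),
        pdb_line("ATOM", 5, "CA", "LEU", "A", 2, 4.4, 2.3, 0.0, b=20.5),
        # altloc pair for LEU CB: A wins on occupancy
        pdb_line("ATOM", 6, "CB", "LEU", "A", 2, 5.0, 3.0, 0.0, occ=0.6, altloc="A"),
        pdb_line("ATOM", 7, "CB", "LEU", "A", 2, 5.5, 3.5, 0.0, occ=0.4, altloc="B"),
        pdb_line("ATOM", 8, "N", "GLY", "A", 3, 5.0, 1.5, 1.0, element="N", b=30.0),
        pdb_line("ATOM", 9, "CA", "GLY", "A", 3, 6.2, 1.8, 1.5, b=30.0),
        "TER",
        pdb_line("HETATM", 10, "C1", "GOL", "B", 101, 8.0, 0.0, 0.0),
        pdb_line("HETATM", 11, "O1", "GOL", "B", 101, 8.8, 0.9, 0.0, element="O"),
        pdb_line("HETATM", 12, "C2", "GOL", "B", 101, 8.5, -1.3, 0.3),
        pdb_line("HETATM", 13, "O2", "GOL", "B", 101, 9.7, -1.5, 0.9, element="O"),
        pdb_line("HETATM", 14, "C3", "GOL", "B", 101, 7.5, -2.3, 0.1),
        pdb_line("HETATM", 15, "O3", "GOL", "B", 101, 7.9, -3.6, 0.2, element="O"),
        pdb_line("HETATM", 16, "O", "HOH", "B", 201, 20.0, 20.0, 20.0, element="O"),
        "END",
    ]
    path = tmp_path / "mini.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def mini_structure(mini_pdb):
    return read_pdb(mini_pdb)


@pytest.fixture
def nested_structure(tmp_path):
    """Synthetic nested-loops structure on disk plus its declared contacts."""
    text, expected = make_structure(SyntheticStructureSpec(12, "nested-loops", seed=7))
    path = tmp_path / "nested.pdb"
    path.write_text(text)
    return read_pdb(path), expected
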