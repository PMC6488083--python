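"""Shared fixtures: a hand-written PDB micro-structure and toy assemblies."""

from __future__ import annotations

import numpy as np
import pytest

from dipole_assembly.synthetic_fixtures import (
    HelixSpec,
    ToyCharge,
    ToyMonomerSpec,
    make_helical_assembly,
)


def pdb_atom(serial, name, resname, chain, resnum, x, y, z,
             altloc=" ", occ=1.00, element=None, record="ATOM"):
    """One fixed-column PDB coordinate line."""
    element = element or name[0]
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
        f"          {element:>2s}"
    )


@pytest.fixture
def micro_pdb(tmp_path):
    """Three protein chains plus water/ligand/altloc edge cases.

    Chain A: Asp1 (full side chain), Gly2, Lys3 (with NZ).
    Chain B: Ile1 (side chain), Glu2 (OE1/OE2).
    Chain C: Arg1 whose CA has two altlocs (B has the higher occupancy).
    Plus a HOH water and a heme HETATM that must be ignored.
    """
    lines = [
        pdb_atom(1, "N", "ASP", "A", 1, 0.0, 1.0, 0.0),
        pdb_atom(2, "CA", "ASP", "A", 1, 1.0, 1.0, 0.0),
        pdb_atom(3, "C", "ASP", "A", 1, 2.0, 1.0, 0.0),
        pdb_atom(4, "O", "ASP", "A", 1, 2.5, 2.0, 0.0),
        pdb_atom(5, "CB", "ASP", "A", 1, 1.0, 2.0, 1.0),
        pdb_atom(6, "CG", "ASP", "A", 1, 1.0, 3.0, 1.0),
        pdb_atom(7, "OD1", "ASP", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom(8, "OD2", "ASP", "A", 1, 2.0, 0.0, 0.0),
        pdb_atom(9, "N", "GLY", "A", 2, 3.0, 1.0, 0.0),
        pdb_atom(10, "CA", "GLY", "A", 2, 4.0, 1.0, 0.0),
        pdb_atom(11, "C", "GLY", "A", 2, 5.0, 1.0, 0.0),
        pdb_atom(12, "O", "GLY", "A", 2, 5.5, 2.0, 0.0),
        pdb_atom(13, "N", "LYS", "A", 3, 6.0, 1.0, 0.0),
        pdb_atom(14, "CA", "LYS", "A", 3, 7.0, 1.0, 0.0),
        pdb_atom(15, "C", "LYS", "A", 3, 8.0, 1.0, 0.0),
        pdb_atom(16, "O", "LYS", "A", 3, 8.5, 2.0, 0.0),
        pdb_atom(17, "CB", "LYS", "A", 3, 7.0, 2.0, 1.0),
        pdb_atom(18, "NZ", "LYS", "A", 3, 7.0, 5.0, 3.0, element="N"),
        "TER",
        pdb_atom(19, "N", "ILE", "B", 1, 10.0, 0.0, 0.0),
        pdb_atom(20, "CA", "ILE", "B", 1, 11.0, 0.0, 0.0),
        pdb_atom(21, "C", "ILE", "B", 1, 12.0, 0.0, 0.0),
        pdb_atom(22, "O", "ILE", "B", 1, 12.5, 1.0, 0.0),
        pdb_atom(23, "CB", "ILE", "B", 1, 11.0, 1.0, 1.0),
        pdb_atom(24, "CG1", "ILE", "B", 1, 11.0, 2.0, 2.0),
        pdb_atom(25, "CG2", "ILE", "B", 1, 12.0, 1.0, 2.0),
        pdb_atom(26, "CD1", "ILE", "B", 1, 11.0, 3.0, 3.0),
        pdb_atom(27, "N", "GLU", "B", 2, 13.0, 0.0, 0.0),
        pdb_atom(28, "CA", "GLU", "B", 2, 14.0, 0.0, 0.0),
        pdb_atom(29, "C", "GLU", "B", 2, 15.0, 0.0, 0.0),
        pdb_atom(30, "O", "GLU", "B", 2, 15.5, 1.0, 0.0),
        pdb_atom(31, "OE1", "GLU", "B", 2, 14.0, 2.0, 2.0),
        pdb_atom(32, "OE2", "GLU", "B", 2, 14.0, 4.0, 2.0),
        "TER",
        pdb_atom(33, "N", "ARG", "C", 1, 20.0, 0.0, 0.0),
        pdb_atom(34, "CA", "ARG", "C", 1, 21.0, 0.0, 0.0, altloc="A", occ=0.40),
        pdb_atom(35, "CA", "ARG", "C", 1, 21.5, 0.0, 0.0, altloc="B", occ=0.60),
        pdb_atom(36, "C", "ARG", "C", 1, 22.0, 0.0, 0.0),
        pdb_atom(37, "O", "ARG", "C", 1, 22.5, 1.0, 0.0),
        pdb_atom(38, "NE", "ARG", "C", 1, 21.0, 2.0, 0.0, element="N"),
        pdb_atom(39, "NH1", "ARG", "C", 1, 20.0, 3.0, 0.0, element="N"),
        pdb_atom(40, "NH2", "ARG", "C", 1, 22.0, 3.0, 0.0, element="N"),
        "TER",
        pdb_atom(41, "O", "HOH", "C", 101, 30.0, 30.0, 30.0, record="HETATM"),
        pdb_atom(42, "FE", "HEM", "C", 102, 31.0, 31.0, 31.0,
                 element="FE", record="HETATM"),
        "END",
    ]
    path = tmp_path / "micro.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def hydrophobic_template(label="hydro"):
    """Template monomer whose H moment points along z (ILE above, ARG below)
    and whose D moment also points along z (Lys above, Asp below)."""
    return ToyMonomerSpec(
        (
            ToyCharge("hydrophobic", 1.38, (0.0, 0.0, 1.0)),
            ToyCharge("hydrophobic", -2.53, (0.0, 0.0, -1.0)),
            ToyCharge("electrostatic", 1.0, (0.3, 0.0, 1.0)),
            ToyCharge("electrostatic", -1.0, (0.3, 0.0, -1.0)),
        ),
        label,
    )


@pytest.fixture
def hydrophobic_stack():
    """Side-by-side stack: moments ⊥ separation and parallel, so enH < 0
    (aligned hydrophobic attraction) and enD > 0 for every consecutive pair."""
    return make_helical_assembly(
        HelixSpec(
            n_monomers=6, radius=4.0, rise_per_monomer=0.0,
            twist_per_monomer=18.0, template=hydrophobic_template(),
        )
    )


@pytest.fixture
def electrostatic_stack():
    """Alternating stack (180° twist): consecutive moments antiparallel and
    ⊥ separation, so enD < 0 (counter-aligned electric attraction) and
    enH > 0 for every consecutive pair."""
    tmpl = ToyMonomerSpec(
        (
            ToyCharge("hydrophobic", 1.38, (0.0, 1.0, 0.0)),
            ToyCharge("hydrophobic", -2.53, (0.0, -1.0, 0.0)),
            ToyCharge("electrostatic", 1.0, (0.3, 1.0, 0.0)),
            ToyCharge("electrostatic", -1.0, (0.3, -1.0, 0.0)),
        ),
        "electro",
    )
    return make_helical_assembly(
        HelixSpec(
            n_monomers=6, radius=1.0, rise_per_monomer=8.0,
            twist_per_monomer=180.0, template=tmpl,
        )
    )


def assembly_dipoles(assembly, kind):
    return [m.dipole(kind) for m in assembly]
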