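"""Synthetic toy monomers and assemblies with known closed-form energies.

Every downstream operation — dipole construction, pair energies, growth
curves, scans, classification, structure round-trips — is testable without
any database download by building assemblies from explicit point-charge
specs:

* :func:`make_toy_monomer` turns a list of (kind, q, position) charges into
  a CA-only :class:`~dipole_assembly.structure_io.MonomerStructure` plus
  ready-made charge sets (the charge sets bypass the residue tables, so
  arbitrary charge magnitudes are allowed);
* :func:`make_helical_assembly` replicates a template monomer along a rigid
  screw (twist about the z axis plus rise per monomer), the geometry class
  of helical and spiral protein assemblies;
* :func:`write_toy_pdb` serializes a toy assembly as a minimal PDB file
  (one CA pseudo-atom per charge site, one chain per monomer) that
  round-trips through ``structure_io`` with ``site_mode="calpha"``.

Residue names in the written PDB are chosen so the real residue tables
reproduce the intended charges where the magnitudes allow it (±1
electrostatic → Lys/Asp; hydrophobic magnitudes matching an Eisenberg
index → that residue), so the full pipeline, not just the math core, is
exercised.  All generators are pure functions of their spec (and seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .charge_model import EISENBERG_CONSENSUS, ChargeSet, empty_charge_set
from .dipoles import PseudoDipole, pseudo_dipole
from .structure_io import MonomerStructure, _ResidueAtoms

KINDS = ("electrostatic", "hydrophobic")

#: Eisenberg index → residue, for round-trippable hydrophobic toy charges
_EISENBERG_BY_VALUE = {round(v, 6): r for r, v in EISENBERG_CONSENSUS.items()}


@dataclass(frozen=True)
class ToyCharge:
    kind: str
    q: float
    position: tuple[float, float, float]
    residue_name: str | None = None  # explicit override for the PDB writer


@dataclass(frozen=True)
class ToyMonomerSpec:
    charges: tuple[ToyCharge, ...]
    label: str = "toy"

    def __post_init__(self) -> None:
        if not self.charges:
            raise ValueError("a toy monomer needs at least one charge")
        for c in self.charges:
            if c.kind not in KINDS:
                raise ValueError(f"unknown charge kind {c.kind!r}")
            if not np.all(np.isfinite(c.position)):
                raise ValueError("charge positions must be finite")


@dataclass(frozen=True)
class HelixSpec:
    """Rigid screw: monomer k is the template rotated by k·twist about z,
    offset radially by ``radius`` and raised by k·rise."""

    n_monomers: int
    radius: float  # Å
    rise_per_monomer: float  # Å
    twist_per_monomer: float  # degrees
    template: ToyMonomerSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("a helix needs at least 2 monomers")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class ToyMonomer:
    """A toy monomer: structure plus its per-kind charge sets."""

    structure: MonomerStructure
    charge_sets: dict[str, ChargeSet]

    def dipole(self, kind: str, **kwargs) -> PseudoDipole:
        return pseudo_dipole(self.charge_sets[kind], warn_separation=False, **kwargs)


def _residue_name_for(charge: ToyCharge) -> str:
    if charge.residue_name is not None:
        return charge.residue_name
    if charge.kind == "electrostatic":
        if charge.q == 1.0:
            return "LYS"
        if charge.q == -1.0:
            return "ASP"
    else:
        match = _EISENBERG_BY_VALUE.get(round(charge.q, 6))
        if match is not None:
            return match
    return "ALA"  # placeholder: charge not representable through the tables


def make_toy_monomer(
    spec: ToyMonomerSpec, ordinal: int = 1, chain_id: str = "A"
) -> ToyMonomer:
    """Deterministically build a monomer and its charge sets from a spec."""
    residues = []
    for i, charge in enumerate(spec.charges, start=1):
        residues.append(
            _ResidueAtoms(
                chain_id, i, "", _residue_name_for(charge),
                {"CA": np.asarray(charge.position, dtype=float)},
            )
        )
    structure = MonomerStructure(
        f"{spec.label}:{chain_id}", ordinal, residues, site_mode="calpha"
    )
    charge_sets: dict[str, ChargeSet] = {}
    for kind in KINDS:
        sel = [c for c in spec.charges if c.kind == kind]
        if sel:
            charge_sets[kind] = ChargeSet(
                kind,
                np.array([c.q for c in sel]),
                np.array([c.position for c in sel], dtype=float),
                structure.monomer_id,
            )
        else:
            charge_sets[kind] = empty_charge_set(kind, structure.monomer_id)
    return ToyMonomer(structure, charge_sets)


def _chain_ids(n: int) -> list[str]:
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n > len(alphabet):
        raise ValueError(f"cannot assign single-character chain ids to {n} monomers")
    return list(alphabet[:n])


def _transform_spec(
    spec: ToyMonomerSpec, R: np.ndarray, t: np.ndarray, label: str
) -> ToyMonomerSpec:
    charges = tuple(
        ToyCharge(
            c.kind,
            c.q,
            tuple(R @ np.asarray(c.position, float) + t),
            c.residue_name,
        )
        for c in spec.charges
    )
    return ToyMonomerSpec(charges, label)


def make_helical_assembly(spec: HelixSpec) -> list[ToyMonomer]:
    """Replicate the template along the screw; dipoles transform rigidly.

    Monomer k (k = 0..n−1) carries the template coordinates offset by
    (radius, 0, 0), rotated about z by k·twist and raised by k·rise, so
    consecutive pairs are congruent: the pair separation |r| and every
    pairwise energy are constant along the helix.
    """
    monomers = []
    offset = np.array([spec.radius, 0.0, 0.0])
    shifted = _transform_spec(spec.template, np.eye(3), offset, spec.template.label)
    for k, chain in enumerate(_chain_ids(spec.n_monomers)):
        R = Rotation.from_euler("z", k * spec.twist_per_monomer, degrees=True).as_matrix()
        t = np.array([0.0, 0.0, k * spec.rise_per_monomer])
        mono_spec = _transform_spec(shifted, R, t, f"{spec.template.label}[{k}]")
        monomers.append(make_toy_monomer(mono_spec, ordinal=k + 1, chain_id=chain))
    return monomers


def make_linear_assembly(
    specs: Sequence[ToyMonomerSpec],
    spacing: float,
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> list[ToyMonomer]:
    """Place explicit per-monomer specs at equal steps along ``axis``.

    Unlike the rigid screw this allows per-monomer variation (e.g. a
    constant hydrophobic moment with an alternating electric one).
    """
    if len(specs) < 2:
        raise ValueError("a linear assembly needs at least 2 monomer specs")
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    monomers = []
    for k, (mono_spec, chain) in enumerate(zip(specs, _chain_ids(len(specs)))):
        moved = _transform_spec(mono_spec, np.eye(3), k * spacing * u, mono_spec.label)
        monomers.append(make_toy_monomer(moved, ordinal=k + 1, chain_id=chain))
    return monomers


def random_charge_set(
    kind: str,
    n: int,
    seed: int,
    box: float = 10.0,
    neutral: bool = False,
    monomer_id: str = "random",
) -> ChargeSet:
    """Seeded random charge cloud for property tests.

    ``neutral`` balances the set exactly by appending the sign-flipped
    mirror of each drawn charge at an independent position.
    """
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.2, 2.0, size=n) * rng.choice([-1.0, 1.0], size=n)
    pos = rng.uniform(-box, box, size=(n, 3))
    if neutral:
        q = np.concatenate([q, -q])
        pos = np.concatenate([pos, rng.uniform(-box, box, size=(n, 3))])
    return ChargeSet(kind, q, pos, monomer_id)


def dipole_pair(
    m1: np.ndarray,
    m2: np.ndarray,
    r_vec: np.ndarray,
    kind: str = "hydrophobic",
) -> tuple[PseudoDipole, PseudoDipole]:
    """Two bare dipoles with prescribed moments and separation.

    A convenience for closed-form checks: dipole 1 sits at the origin,
    dipole 2 at ``r_vec``; centroids are synthesized half a moment apart so
    the invariant moment = q⁺(c⁺−c⁻) holds with q⁺ = |moment|.
    """
    def bare(moment: np.ndarray, at: np.ndarray, tag: str) -> PseudoDipole:
        moment = np.asarray(moment, float)
        at = np.asarray(at, float)
        norm = float(np.linalg.norm(moment))
        if norm == 0.0:
            return PseudoDipole(kind, 0.0, None, None, np.zeros(3), at, False, tag)
        half = 0.5 * moment / norm
        return PseudoDipole(kind, norm, at + half, at - half, moment, at, True, tag)

    return bare(np.asarray(m1, float), np.zeros(3), "d1"), bare(
        np.asarray(m2, float), np.asarray(r_vec, float), "d2"
    )


def toy_spec_from_json(path: str | Path) -> ToyMonomerSpec:
    """Load a toy monomer spec from JSON.

    Schema::

        {"label": "name",
         "charges": [{"kind": "hydrophobic" | "electrostatic",
                      "q": 1.38,
                      "position": [x, y, z],
                      "residue_name": "ILE"}, ...]}

    ``residue_name`` is optional (inferred from kind/magnitude otherwise).
    """
    import json

    data = json.loads(Path(path).read_text())
    charges = tuple(
        ToyCharge(
            c["kind"], float(c["q"]), tuple(float(x) for x in c["position"]),
            c.get("residue_name"),
        )
        for c in data.get("charges", [])
    )
    return ToyMonomerSpec(charges, data.get("label", "toy"))


def write_toy_pdb(assembly: Sequence[ToyMonomer], path: str | Path) -> Path:
    """Write a minimal CA-only PDB file, one chain per monomer.

    Coordinates survive to the 1e-3 Å column precision of the PDB format;
    loading the file back with ``site_mode="calpha"`` reproduces the sites.
    """
    lines = []
    serial = 1
    for mono in assembly:
        for res in mono.structure.residues:
            x, y, z = res.atoms["CA"]
            if max(abs(x), abs(y), abs(z)) >= 10000:
                raise ValueError("coordinate overflows PDB columns")
            lines.append(
                f"ATOM  {serial:5d}  CA  {res.residue_name:>3s} {res.chain_id}"
                f"{res.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
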