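"""Assignment of electrostatic and hydrophobic "charges" to residue sites.

Two kinds of signed point charges are placed on a monomer's representative
sites:

* **electrostatic** — formal side-chain charges at pH ~7: Asp/Glu −1,
  Lys/Arg +1 (His +1 optionally; terminal NH3+/COO− optionally);
* **hydrophobic** — the residue's hydrophobicity index treated formally as a
  signed charge.  The default scale is the Eisenberg normalized consensus
  scale, in which positive values mark the classically hydrophobic residues
  and negative values the hydrophilic ones.

Hydrophobic charges of equal sign attract and opposite signs repel — the
inverse of electrostatics — which is handled downstream by the sign
convention of the two energy kernels, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .structure_io import STANDARD_AA, MonomerStructure, ResidueSite

ACIDIC = frozenset({"ASP", "GLU"})
BASIC = frozenset({"LYS", "ARG"})

#: Eisenberg normalized consensus hydrophobicity scale
#: (Eisenberg, Schwarz, Komaromy & Wall, J Mol Biol 179:125-142, 1984).
EISENBERG_CONSENSUS: dict[str, float] = {
    "ALA": 0.62, "ARG": -2.53, "ASN": -0.78, "ASP": -0.90, "CYS": 0.29,
    "GLN": -0.85, "GLU": -0.74, "GLY": 0.48, "HIS": -0.40, "ILE": 1.38,
    "LEU": 1.06, "LYS": -1.50, "MET": 0.64, "PHE": 1.19, "PRO": 0.12,
    "SER": -0.18, "THR": -0.05, "TRP": 0.81, "TYR": 0.26, "VAL": 1.08,
}


class ScaleCoverageError(KeyError):
    """A residue has no entry in the hydrophobicity scale."""


@dataclass(frozen=True)
class HydrophobicityScale:
    """Named map from 3-letter residue codes to hydrophobicity indices."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        vals = np.array(list(self.values.values()))
        if not (np.any(vals > 0) and np.any(vals < 0)):
            raise ValueError(
                f"scale {self.name!r} must contain both hydrophobic (positive) "
                "and hydrophilic (negative) values"
            )

    def __getitem__(self, residue_name: str) -> float:
        try:
            return self.values[residue_name]
        except KeyError:
            raise ScaleCoverageError(
                f"residue {residue_name!r} not covered by scale {self.name!r}"
            ) from None


EISENBERG_SCALE = HydrophobicityScale("eisenberg-consensus", EISENBERG_CONSENSUS)


@dataclass
class ChargeSet:
    """Signed point charges (one kind) with positions for one monomer."""

    kind: str  # "electrostatic" | "hydrophobic"
    q: np.ndarray  # (n,) signed magnitudes, all non-zero
    positions: np.ndarray  # (n, 3) Å
    monomer_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("electrostatic", "hydrophobic"):
            raise ValueError(f"unknown charge kind {self.kind!r}")
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.q.shape[0] != self.positions.shape[0]:
            raise ValueError("q and positions length mismatch")
        if np.any(self.q == 0.0):
            raise ValueError("zero charges must be excluded from a ChargeSet")

    def __len__(self) -> int:
        return int(self.q.shape[0])

    @property
    def charges(self) -> list[tuple[float, np.ndarray]]:
        return [(float(qi), pi) for qi, pi in zip(self.q, self.positions)]

    def translated(self, t: np.ndarray) -> "ChargeSet":
        return ChargeSet(self.kind, self.q.copy(), self.positions + np.asarray(t, float),
                         self.monomer_id)

    def rotated(self, R: np.ndarray) -> "ChargeSet":
        return ChargeSet(self.kind, self.q.copy(), self.positions @ np.asarray(R, float).T,
                         self.monomer_id)


def empty_charge_set(kind: str, monomer_id: str = "") -> ChargeSet:
    cs = ChargeSet.__new__(ChargeSet)
    cs.kind = kind
    cs.q = np.empty(0)
    cs.positions = np.empty((0, 3))
    cs.monomer_id = monomer_id
    return cs


def electrostatic_charges(
    sites: Sequence[ResidueSite],
    include_his: bool = False,
    include_termini: bool = False,
    monomer: MonomerStructure | None = None,
) -> ChargeSet:
    """Unit formal charges at the charged residues' sites.

    Asp and Glu contribute −1, Lys and Arg +1; His contributes +1 only when
    ``include_his`` is set.  With ``include_termini`` (requires ``monomer``
    for the backbone atoms) a +1 charge is placed on the first residue's N
    atom and a −1 on the last residue's C atom.  An empty result is a valid
    outcome (peptides with no charged residues carry no electric dipole).
    """
    positive = BASIC | ({"HIS"} if include_his else set())
    qs: list[float] = []
    pos: list[np.ndarray] = []
    for site in sites:
        if site.residue_name in ACIDIC:
            qs.append(-1.0)
            pos.append(site.position)
        elif site.residue_name in positive:
            qs.append(+1.0)
            pos.append(site.position)
    if include_termini:
        if monomer is None:
            raise ValueError("include_termini requires the monomer for backbone atoms")
        first, last = monomer.residues[0], monomer.residues[-1]
        if "N" in first.atoms:
            qs.append(+1.0)
            pos.append(first.atoms["N"])
        if "C" in last.atoms:
            qs.append(-1.0)
            pos.append(last.atoms["C"])
    monomer_id = monomer.monomer_id if monomer is not None else (
        sites[0].chain_id if sites else ""
    )
    if not qs:
        return empty_charge_set("electrostatic", monomer_id)
    return ChargeSet("electrostatic", np.array(qs), np.stack(pos), monomer_id)


def hydrophobic_charges(
    sites: Sequence[ResidueSite],
    scale: HydrophobicityScale = EISENBERG_SCALE,
    monomer_id: str = "",
) -> ChargeSet:
    """One hydrophobic charge per residue, q = the residue's scale index.

    Residues whose scale value is exactly zero are excluded; a residue
    absent from the scale raises :class:`ScaleCoverageError` naming it.
    """
    qs: list[float] = []
    pos: list[np.ndarray] = []
    for site in sites:
        value = scale[site.residue_name]
        if value == 0.0:
            continue
        qs.append(value)
        pos.append(site.position)
    if not monomer_id and sites:
        monomer_id = sites[0].chain_id
    if not qs:
        return empty_charge_set("hydrophobic", monomer_id)
    return ChargeSet("hydrophobic", np.array(qs), np.stack(pos), monomer_id)


def load_scale(path: str | Path, name: str | None = None) -> HydrophobicityScale:
    """Read an alternative scale from a two-column text table (residue, value).

    Blank lines and ``#`` comments are ignored; residue codes are
    case-insensitive.
    """
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path.name}:{lineno}: expected 'RES value', got {line!r}")
        values[parts[0].upper()] = float(parts[1])
    return HydrophobicityScale(name or path.stem, values)
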