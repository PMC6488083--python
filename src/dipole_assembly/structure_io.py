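"""Reading multimeric structures into ordered lists of monomers.

A *monomer* is one element of a growing assembly: by default one polymer
chain of the deposited structure, optionally a user-defined group of chains
(e.g. a heterodimer or a pentameric building block).  Each monomer exposes
per-residue representative coordinates ("sites") in one of three modes:

``calpha``
    the CA atom position;
``sidechain_centroid``
    the unweighted mean of all side-chain heavy atoms (Gly falls back to CA);
``charged_group_centroid``
    the mean of the residue's charged-group atoms (Asp: OD1/OD2, Glu:
    OE1/OE2, Lys: NZ, Arg: NH1/NH2/NE, His: ND1/NE2); residues without a
    charged group fall back to the side-chain centroid.

Parsing is delegated to gemmi (PDB, mmCIF, gzip-compressed accepted).
Hetero compounds, waters and hydrogens are dropped; for alternate locations
only the highest-occupancy conformer is kept (ties broken by altloc label
order).
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: atoms carrying the formal charge of the titratable side chains
CHARGED_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}

SITE_MODES = ("calpha", "sidechain_centroid", "charged_group_centroid")


class StructureFormatError(ValueError):
    """Raised when a file cannot be parsed as the requested format."""


class EmptyAssemblyError(ValueError):
    """Raised when the selection yields no monomers."""


@dataclass(frozen=True)
class ResidueSite:
    """Representative point for one residue."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    position: np.ndarray  # (3,) Å
    site_mode: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"site position must be a finite 3-vector, got {pos!r}")
        object.__setattr__(self, "position", pos)


@dataclass
class _ResidueAtoms:
    """Heavy-atom record for one standard residue (internal)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atoms: dict[str, np.ndarray]


@dataclass
class MonomerStructure:
    """One assembly element with its residues and representative sites."""

    monomer_id: str
    ordinal: int
    residues: list[_ResidueAtoms]
    site_mode: str = "calpha"
    sites: list[ResidueSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyAssemblyError(f"monomer {self.monomer_id!r} has no residues")
        if not self.sites:
            self.sites = residue_sites(self, self.site_mode)

    @property
    def geometric_center(self) -> np.ndarray:
        """Mean position of all heavy atoms, Å."""
        coords = np.concatenate(
            [np.stack(list(r.atoms.values())) for r in self.residues]
        )
        return coords.mean(axis=0)

    def atom_coordinates(self) -> np.ndarray:
        return np.concatenate([np.stack(list(r.atoms.values())) for r in self.residues])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MonomerStructure":
        """Return a copy with every atom mapped through ``R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        residues = [
            _ResidueAtoms(
                r.chain_id,
                r.residue_number,
                r.insertion_code,
                r.residue_name,
                {name: R @ pos + t for name, pos in r.atoms.items()},
            )
            for r in self.residues
        ]
        return MonomerStructure(self.monomer_id, self.ordinal, residues, self.site_mode)


def residue_sites(monomer: MonomerStructure, site_mode: str) -> list[ResidueSite]:
    """One representative site per standard residue of ``monomer``.

    Residues lacking the atoms needed for the requested mode fall back to
    coarser modes (charged group → side chain → CA) with a logged warning;
    residues with no usable atoms at all are skipped, never silently.
    """
    if site_mode not in SITE_MODES:
        raise ValueError(f"unknown site_mode {site_mode!r}; expected one of {SITE_MODES}")
    sites: list[ResidueSite] = []
    for res in monomer.residues:
        pos = _site_position(res, site_mode)
        if pos is None:
            logger.warning(
                "residue %s %s%d%s has no usable atoms for mode %s; skipped",
                res.residue_name, res.chain_id, res.residue_number,
                res.insertion_code, site_mode,
            )
            continue
        sites.append(
            ResidueSite(
                res.chain_id, res.residue_number, res.insertion_code,
                res.residue_name, pos, site_mode,
            )
        )
    return sites


def _site_position(res: _ResidueAtoms, site_mode: str) -> np.ndarray | None:
    if site_mode == "charged_group_centroid":
        names = CHARGED_GROUP_ATOMS.get(res.residue_name)
        if names is not None:
            found = [res.atoms[n] for n in names if n in res.atoms]
            if found:
                return np.mean(found, axis=0)
            logger.warning(
                "residue %s %s%d missing charged-group atoms; falling back",
                res.residue_name, res.chain_id, res.residue_number,
            )
        return _site_position(res, "sidechain_centroid")
    if site_mode == "sidechain_centroid":
        side = [p for n, p in res.atoms.items() if n not in BACKBONE_ATOMS]
        if side:
            return np.mean(side, axis=0)
        return _site_position(res, "calpha")  # Gly and truncated side chains
    # calpha
    if "CA" in res.atoms:
        return res.atoms["CA"]
    if res.atoms:
        logger.warning(
            "residue %s %s%d has no CA; using mean of its atoms",
            res.residue_name, res.chain_id, res.residue_number,
        )
        return np.mean(list(res.atoms.values()), axis=0)
    return None


def load_assembly(
    path: str | Path,
    format: str = "auto",
    model_index: int = 0,
    monomer_spec: Sequence[Sequence[str]] | None = None,
    site_mode: str = "calpha",
) -> list[MonomerStructure]:
    """Read a multimeric structure and return its monomers in assembly order.

    Parameters
    ----------
    path:
        PDB or mmCIF file, optionally gzip-compressed.
    format:
        ``pdb``, ``mmcif`` or ``auto`` (detect from contents/extension).
    model_index:
        0-based model for multi-model (NMR) files; the first model is the
        single-conformer default.
    monomer_spec:
        Optional grouping rule: a sequence of chain-id tuples, each tuple
        becoming one monomer, in the given order.  Default: one monomer per
        polymer chain in deposition order.
    site_mode:
        Default representative-site mode attached to the returned monomers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        structure = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    structure.setup_entities()
    structure.remove_hydrogens()
    structure.remove_waters()
    if not 0 <= model_index < len(structure):
        raise IndexError(
            f"model_index {model_index} out of range for {len(structure)} model(s)"
        )
    model = structure[model_index]

    chain_residues: dict[str, list[_ResidueAtoms]] = {}
    chain_order: list[str] = []
    for chain in model:
        for residue in chain:
            if residue.name not in STANDARD_AA:
                info = gemmi.find_tabulated_residue(residue.name)
                if info is not None and info.is_amino_acid():
                    logger.warning(
                        "non-standard residue %s %s%d dropped",
                        residue.name, chain.name, residue.seqid.num,
                    )
                continue
            atoms = _best_altloc_atoms(residue)
            if not atoms:
                continue
            rec = _ResidueAtoms(
                chain.name, residue.seqid.num, (residue.seqid.icode or " ").strip(),
                residue.name, atoms,
            )
            if chain.name not in chain_residues:
                chain_residues[chain.name] = []
                chain_order.append(chain.name)
            chain_residues[chain.name].append(rec)

    if monomer_spec is None:
        groups: list[tuple[str, ...]] = [(c,) for c in chain_order]
    else:
        groups = [tuple(g) for g in monomer_spec]
        missing = [c for g in groups for c in g if c not in chain_residues]
        if missing:
            raise EmptyAssemblyError(f"chains {missing} not found in {path.name}")
    monomers: list[MonomerStructure] = []
    for ordinal, group in enumerate(groups, start=1):
        residues = [r for c in group for r in chain_residues.get(c, [])]
        if not residues:
            continue
        monomers.append(
            MonomerStructure("+".join(group), ordinal, residues, site_mode)
        )
    if not monomers:
        raise EmptyAssemblyError(f"no protein monomers selected from {path.name}")
    # re-number in case empty groups were dropped
    for i, m in enumerate(monomers, start=1):
        m.ordinal = i
    return monomers


def _best_altloc_atoms(residue: gemmi.Residue) -> dict[str, np.ndarray]:
    """Heavy atoms of one residue, keeping the highest-occupancy altloc."""
    best: dict[str, tuple[float, str, np.ndarray]] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
        key = atom.name
        cand = (atom.occ, atom.altloc or "", pos)
        prev = best.get(key)
        # higher occupancy wins; on a tie the lexicographically first altloc
        if prev is None or cand[0] > prev[0] or (cand[0] == prev[0] and cand[1] < prev[1]):
            best[key] = cand
    return {name: pos for name, (_, _, pos) in best.items()}


def fetch_structure(accession: str, cache_dir: str | Path, timeout: float = 60.0) -> Path:
    """Download an mmCIF entry from the PDB into ``cache_dir`` (opt-in helper).

    Returns the cached path without re-downloading when present.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{accession.lower()}.cif.gz"
    if target.exists():
        return target
    url = f"https://files.rcsb.org/download/{accession.upper()}.cif.gz"
    logger.info("fetching %s", url)
    with urllib.request.urlopen(url, timeout=timeout) as resp, open(target, "wb") as fh:
        fh.write(resp.read())
    return target


def transform_monomers(
    monomers: Iterable[MonomerStructure],
    rotation: np.ndarray,
    translation: np.ndarray,
) -> list[MonomerStructure]:
    """Apply one rigid motion to every monomer of an assembly."""
    return [m.transformed(rotation, translation) for m in monomers]
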