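"""Run configuration and end-to-end orchestration behind the CLI.

A :class:`RunConfig` captures every convention knob of the analysis (site
modes, His/termini flags, the Eq-exponent distance unit, the dipole
application-point convention, pair set, scan step).  Each output file
embeds a *settings fingerprint* — a short hash of the effective config —
so that any two result files can be checked for convention agreement, and
identical config + input always yields byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .charge_model import (
    EISENBERG_SCALE,
    HydrophobicityScale,
    electrostatic_charges,
    hydrophobic_charges,
    load_scale,
)
from .dipoles import PseudoDipole, pseudo_dipole, write_bild, write_pml
from .energies import (
    DEFAULT_R0,
    classification_json,
    classify_driver,
    consecutive_pair_stats,
    growth_curve,
    growth_curve_table,
    pair_energy_table,
)
from .scans import minima_summary, rotation_scan, scan_table, translation_scan
from .structure_io import MonomerStructure, fetch_structure, load_assembly, residue_sites

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every convention knob of one analysis run (YAML-serializable)."""

    input: str = ""
    accession: str = ""
    fetch: bool = False
    cache_dir: str = "pdb_cache"
    format: str = "auto"
    model_index: int = 0
    monomer_grouping: list[list[str]] | None = None
    electrostatic_site_mode: str = "charged_group_centroid"
    hydrophobic_site_mode: str = "sidechain_centroid"
    scale: str = "eisenberg-consensus"  # name of the built-in or a file path
    include_his: bool = False
    include_termini: bool = False
    distance_unit: str = "scaled"
    r0: float = DEFAULT_R0
    application_point: str = "midpoint"
    n_pairs: int | None = None
    center_ordinal: int | None = None
    scan_step_deg: float = 10.0
    pair: tuple[int, int] = (1, 2)  # 1-based ordinals for dimer scans
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.pair is not None:
            cfg.pair = tuple(cfg.pair)  # YAML lists → tuple
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pair"] = list(self.pair)
        return d

    def fingerprint(self) -> str:
        # out_dir is an output location, not an analysis convention
        d = self.to_dict()
        d.pop("out_dir")
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def resolve_scale(self) -> HydrophobicityScale:
        if self.scale in ("", "eisenberg-consensus", "eisenberg"):
            return EISENBERG_SCALE
        return load_scale(self.scale)


@dataclass
class AssemblyDipoles:
    """Per-monomer dipoles of both kinds, in assembly order."""

    monomers: list[MonomerStructure]
    hydrophobic: list[PseudoDipole]
    electrostatic: list[PseudoDipole]

    def of_kind(self, kind: str) -> list[PseudoDipole]:
        return self.hydrophobic if kind == "hydrophobic" else self.electrostatic


def monomer_dipoles(
    monomer: MonomerStructure, config: RunConfig, scale: HydrophobicityScale
) -> tuple[PseudoDipole, PseudoDipole]:
    """(hydrophobic, electrostatic) pseudo dipoles of one monomer."""
    center = monomer.geometric_center
    h_sites = residue_sites(monomer, config.hydrophobic_site_mode)
    e_sites = residue_sites(monomer, config.electrostatic_site_mode)
    cs_h = hydrophobic_charges(h_sites, scale, monomer_id=monomer.monomer_id)
    cs_e = electrostatic_charges(
        e_sites,
        include_his=config.include_his,
        include_termini=config.include_termini,
        monomer=monomer,
    )
    kwargs = dict(application_point=config.application_point, geometric_center=center)
    return pseudo_dipole(cs_h, **kwargs), pseudo_dipole(cs_e, **kwargs)


def prepare_assembly(config: RunConfig) -> AssemblyDipoles:
    """Load the structure named by the config and compute every dipole."""
    path = config.input
    if not path and config.accession:
        if not config.fetch:
            raise ValueError(
                f"accession {config.accession!r} given without --fetch and no input file"
            )
        path = str(fetch_structure(config.accession, config.cache_dir))
    if not path:
        raise ValueError("config names neither an input file nor an accession")
    monomers = load_assembly(
        path,
        format=config.format,
        model_index=config.model_index,
        monomer_spec=config.monomer_grouping,
    )
    scale = config.resolve_scale()
    hs, es = [], []
    for m in monomers:
        h, e = monomer_dipoles(m, config, scale)
        hs.append(h)
        es.append(e)
    return AssemblyDipoles(monomers, hs, es)


def _out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["settings_fingerprint"] = config.fingerprint()
    df["version"] = __version__
    return df


def run_vectors(config: RunConfig, assembly: AssemblyDipoles | None = None) -> Path:
    """Per-monomer dipole table + ChimeraX/PyMOL arrow scripts."""
    asm = assembly or prepare_assembly(config)
    rows = []
    for m, h, d in zip(asm.monomers, asm.hydrophobic, asm.electrostatic):
        for dip, tag in ((h, "H"), (d, "D")):
            rows.append(
                {
                    "ordinal": m.ordinal,
                    "monomer_id": m.monomer_id,
                    "kind": tag,
                    "defined": dip.defined,
                    "Px": dip.moment[0],
                    "Py": dip.moment[1],
                    "Pz": dip.moment[2],
                    "moment_norm": float(np.linalg.norm(dip.moment)),
                    "centroid_separation": dip.centroid_separation,
                }
            )
    out = _out(config)
    table = _stamp(pd.DataFrame(rows), config)
    csv_path = out / "vectors.csv"
    table.to_csv(csv_path, index=False, float_format="%.6f")
    every = asm.hydrophobic + asm.electrostatic
    write_bild(every, out / "vectors.bild")
    write_pml(every, out / "vectors.pml")
    return csv_path


def run_classify(config: RunConfig, assembly: AssemblyDipoles | None = None) -> Path:
    """Consecutive-pair stats for both kinds and the driver label (JSON)."""
    asm = assembly or prepare_assembly(config)
    opts = dict(distance_unit=config.distance_unit, r0=config.r0)
    stats_h = consecutive_pair_stats(asm.hydrophobic, n_pairs=config.n_pairs, **opts)
    stats_d = consecutive_pair_stats(asm.electrostatic, n_pairs=config.n_pairs, **opts)
    cls = classify_driver(stats_h, stats_d)
    out = _out(config)
    payload = classification_json(cls, config.fingerprint())
    payload["version"] = __version__
    path = out / "classification.json"
    path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    pairs = pair_energy_table(asm.hydrophobic, asm.electrostatic, **opts)
    _stamp(pairs, config).to_csv(out / "pair_energies.csv", index=False,
                                 float_format="%.6f")
    return path


def run_growth(config: RunConfig, assembly: AssemblyDipoles | None = None) -> list[Path]:
    """Sequential (and, when a center is given, around-center) growth curves."""
    asm = assembly or prepare_assembly(config)
    opts = dict(distance_unit=config.distance_unit, r0=config.r0)
    out = _out(config)
    paths = []
    for kind in ("hydrophobic", "electrostatic"):
        dips = asm.of_kind(kind)
        curves = [growth_curve(dips, mode="sequential", **opts)]
        if config.center_ordinal is not None:
            curves.append(
                growth_curve(
                    dips, mode="around_center",
                    center_ordinal=config.center_ordinal, **opts,
                )
            )
        for curve in curves:
            table = _stamp(growth_curve_table(curve), config)
            name = f"growth_{kind}_{curve.mode}.csv"
            table.to_csv(out / name, index=False, float_format="%.6f")
            paths.append(out / name)
    return paths


def run_scan(config: RunConfig, assembly: AssemblyDipoles | None = None) -> Path:
    """Rotation and translation scans of the configured dimer."""
    asm = assembly or prepare_assembly(config)
    i, j = config.pair
    out = _out(config)
    opts = dict(
        step_deg=config.scan_step_deg,
        distance_unit=config.distance_unit,
        r0=config.r0,
    )
    all_scans = []
    summary: dict = {
        "pair": [i, j],
        "settings_fingerprint": config.fingerprint(),
        "version": __version__,
        "scans": [],
    }
    for kind in ("hydrophobic", "electrostatic"):
        d1 = asm.of_kind(kind)[i - 1]
        d2 = asm.of_kind(kind)[j - 1]
        if not (d1.defined and d2.defined):
            logger.warning("%s dipole undefined for pair (%d, %d); scan skipped",
                           kind, i, j)
            continue
        rot = rotation_scan(d1, d2, **opts)
        for axis, s in rot.items():
            s.axis = f"native:{axis}"
        all_scans.extend(rot.values())
        for arrangement in translation_scan(d1, d2, **opts).values():
            all_scans.extend(arrangement.values())
    summary["scans"] = minima_summary(all_scans)
    _stamp(scan_table(all_scans), config).to_csv(
        out / "scans.csv", index=False, float_format="%.6f"
    )
    path = out / "scan_minima.json"
    path.write_text(json.dumps(summary, indent=2) + "\n")
    return path
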