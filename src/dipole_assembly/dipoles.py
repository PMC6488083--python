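"""Pseudo dipole moments of a monomer's charge distribution.

Because a protein's net (electrostatic or hydrophobic) charge is rarely
zero, the exact dipole Σ qᵢ·rᵢ is origin-dependent and a surrogate is used:

    P = Q⁺ · (c⁺ − c⁻)

where Q⁺ is the total positive charge and c⁺, c⁻ the charge-weighted
centroids of the positive and negative subsets.  For a neutral charge set
this coincides exactly with Σ qᵢ·rᵢ.  The electrostatic instance is the
assembly literature's D vector and the hydrophobic instance its H vector.

A dipole is *undefined* when either charge subset is empty (e.g. a peptide
with no acidic residues has no electric dipole); undefined dipoles carry a
zero moment and propagate as zero-energy contributions downstream.

The dipole's *application point* — where the vector sits when measuring
inter-dipole distances — is the midpoint of the two centroids by default,
with the monomer geometric center available as an alternative convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .charge_model import ChargeSet

logger = logging.getLogger(__name__)

#: centroid separations observed for real protein monomers, Å (soft check)
CENTROID_SEPARATION_RANGE = (1.0, 10.0)


@dataclass
class PseudoDipole:
    kind: str
    q_plus: float
    c_plus: np.ndarray | None
    c_minus: np.ndarray | None
    moment: np.ndarray
    application_point: np.ndarray
    defined: bool
    monomer_id: str = ""

    @property
    def centroid_separation(self) -> float:
        """|c⁺ − c⁻| in Å; NaN when undefined."""
        if not self.defined:
            return float("nan")
        return float(np.linalg.norm(self.c_plus - self.c_minus))


def charge_centroids(
    cs: ChargeSet,
) -> tuple[float, float, np.ndarray | None, np.ndarray | None]:
    """Total positive/negative charge and their weighted centroids.

    Returns ``(q_plus, q_minus, c_plus, c_minus)`` with q_minus = Σ|q| over
    the negative subset; an empty subset yields a ``None`` centroid.
    """
    pos_mask = cs.q > 0
    neg_mask = cs.q < 0
    q_plus = float(cs.q[pos_mask].sum())
    q_minus = float(-cs.q[neg_mask].sum())
    c_plus = c_minus = None
    if pos_mask.any():
        w = cs.q[pos_mask]
        c_plus = (w[:, None] * cs.positions[pos_mask]).sum(axis=0) / w.sum()
    if neg_mask.any():
        w = -cs.q[neg_mask]
        c_minus = (w[:, None] * cs.positions[neg_mask]).sum(axis=0) / w.sum()
    return q_plus, q_minus, c_plus, c_minus


def pseudo_dipole(
    cs: ChargeSet,
    application_point: str = "midpoint",
    geometric_center: np.ndarray | None = None,
    warn_separation: bool = True,
) -> PseudoDipole:
    """The monomer's pseudo dipole P = Q⁺·(c⁺ − c⁻) for one charge kind.

    ``application_point`` is ``"midpoint"`` (of the two centroids) or
    ``"geometric_center"`` (requires ``geometric_center``).  Centroid
    separations outside the 1–10 Å range typical of real monomers are
    warned about, never rejected: toy systems legitimately fall outside.
    """
    q_plus, _, c_plus, c_minus = charge_centroids(cs)
    if c_plus is None or c_minus is None:
        app = geometric_center
        if app is None:
            app = cs.positions.mean(axis=0) if len(cs) else np.zeros(3)
        return PseudoDipole(
            cs.kind, q_plus, c_plus, c_minus, np.zeros(3), np.asarray(app, float),
            defined=False, monomer_id=cs.monomer_id,
        )
    moment = q_plus * (c_plus - c_minus)
    if application_point == "midpoint":
        app = 0.5 * (c_plus + c_minus)
    elif application_point == "geometric_center":
        if geometric_center is None:
            raise ValueError("geometric_center convention requires the center")
        app = np.asarray(geometric_center, float)
    else:
        raise ValueError(f"unknown application_point {application_point!r}")
    sep = float(np.linalg.norm(c_plus - c_minus))
    lo, hi = CENTROID_SEPARATION_RANGE
    if warn_separation and not lo <= sep <= hi:
        logger.warning(
            "%s centroid separation %.2f Å outside the typical %g-%g Å range (%s)",
            cs.kind, sep, lo, hi, cs.monomer_id or "monomer",
        )
    return PseudoDipole(
        cs.kind, q_plus, c_plus, c_minus, moment, app,
        defined=True, monomer_id=cs.monomer_id,
    )


def exact_dipole(cs: ChargeSet) -> np.ndarray:
    """The textbook dipole Σ qᵢ·rᵢ (origin-dependent unless neutral)."""
    if len(cs) == 0:
        return np.zeros(3)
    return (cs.q[:, None] * cs.positions).sum(axis=0)


def alternative_moment(cs: ChargeSet, convention: str) -> tuple[np.ndarray, bool]:
    """Moment under an alternative definition, for sensitivity analysis only.

    ``q_plus`` → Q⁺·(c⁺−c⁻) (the default), ``q_minus`` → Q⁻·(c⁺−c⁻),
    ``exact`` → Σ qᵢ·rᵢ.  Returns ``(vector, defined)``; conventions must
    never be mixed within one analysis.
    """
    q_plus, q_minus, c_plus, c_minus = charge_centroids(cs)
    if convention == "exact":
        return exact_dipole(cs), len(cs) > 0
    if c_plus is None or c_minus is None:
        return np.zeros(3), False
    if convention == "q_plus":
        return q_plus * (c_plus - c_minus), True
    if convention == "q_minus":
        return q_minus * (c_plus - c_minus), True
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# visualization exports

def write_bild(dipoles: Iterable[PseudoDipole], path: str | Path,
               scale: float = 1.0) -> None:
    """ChimeraX BILD script drawing each defined moment as an arrow.

    H (hydrophobic) arrows are green and D (electrostatic) arrows yellow,
    anchored at the application points.
    """
    lines = [".comment pseudo dipole vectors"]
    for d in dipoles:
        if not d.defined:
            continue
        color = "green" if d.kind == "hydrophobic" else "yellow"
        a = d.application_point - 0.5 * scale * d.moment
        b = d.application_point + 0.5 * scale * d.moment
        lines.append(f".color {color}")
        lines.append(
            ".arrow {:.3f} {:.3f} {:.3f} {:.3f} {:.3f} {:.3f} 0.2 0.4 0.75".format(
                *a, *b
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pml(dipoles: Iterable[PseudoDipole], path: str | Path,
              scale: float = 1.0) -> None:
    """PyMOL script (cgo arrows) for the same vectors as :func:`write_bild`."""
    lines = ["from pymol.cgo import CYLINDER, CONE", "from pymol import cmd", "obj = []"]
    for d in dipoles:
        if not d.defined:
            continue
        rgb = (0.0, 0.8, 0.0) if d.kind == "hydrophobic" else (0.9, 0.8, 0.0)
        a = d.application_point - 0.5 * scale * d.moment
        b = d.application_point + 0.5 * scale * d.moment
        tip = b + 0.15 * scale * d.moment
        lines.append(
            "obj += [CYLINDER, {:.3f},{:.3f},{:.3f}, {:.3f},{:.3f},{:.3f}, 0.2, "
            "{r},{g},{b}, {r},{g},{b}]".format(*a, *b, r=rgb[0], g=rgb[1], b=rgb[2])
        )
        lines.append(
            "obj += [CONE, {:.3f},{:.3f},{:.3f}, {:.3f},{:.3f},{:.3f}, 0.4, 0.0, "
            "{r},{g},{b}, {r},{g},{b}, 1.0, 1.0]".format(*b, *tip, r=rgb[0], g=rgb[1], b=rgb[2])
        )
    lines.append('cmd.load_cgo(obj, "pseudo_dipoles")')
    Path(path).write_text("\n".join(lines) + "\n")
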