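"""Rotation and translation scans around a dimer's native geometry.

To test whether the native orientation of the second monomer in a dimer is
an energy minimum, its moment vector is rotated in 10° steps about three
orthogonal axes of a local frame anchored at that dipole's application
point:

* **x** — along the inter-dipole distance vector r;
* **y** — perpendicular to the plane spanned by x and the original moment;
* **z** — completing the right-handed triad (x × y).

Only the moment vector rotates; the monomer's coordinates, the pair
separation and the other kind's dipole are untouched, so the energy
denominator is constant across a grid and the minimum location depends
only on orientation.

Three alternative rigid *translation arrangements* of the pair are also
scanned, each preserving the native center distance |r| and setting the
second moment parallel to the first: ``side_by_side`` (displacement
perpendicular to the first moment), ``top_down`` (displacement along it)
and ``staggered`` (the normalized combination of both).  Each arrangement
is then subjected to the same rotation scan.

Steric clashes are not modelled: scans annotate the energy landscape, they
never exclude angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .dipoles import PseudoDipole
from .energies import DEFAULT_R0, PairGeometry, pair_energy

logger = logging.getLogger(__name__)

AXES = ("x", "y", "z")
ARRANGEMENTS = ("side_by_side", "top_down", "staggered")

_PARALLEL_TOL = 1e-9


class DegenerateScanError(ValueError):
    """A scan cannot be set up (undefined dipole or coincident points)."""


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal triad anchored at dipole 2's application
    point, with x along the inter-dipole distance vector."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def axis(self, name: str) -> np.ndarray:
        return {"x": self.x_axis, "y": self.y_axis, "z": self.z_axis}[name]


@dataclass
class ScanResult:
    kind: str
    axis: str  # "x" | "y" | "z" or an arrangement id
    angles_deg: np.ndarray
    energies: np.ndarray
    native_energy: float
    min_angle_deg: int
    min_energy: float
    tie: bool = False

    @property
    def min_angle_signed(self) -> int:
        """The minimum angle mapped to (−180°, 180°]."""
        a = self.min_angle_deg % 360
        return a - 360 if a > 180 else a


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero vector has no direction")
    return v / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to unit vector ``v``."""
    basis = np.eye(3)
    helper = basis[int(np.argmin(np.abs(v)))]
    return _unit(np.cross(v, helper))


def local_frame(d1: PseudoDipole, d2: PseudoDipole) -> LocalFrame:
    """The rotation frame of a dimer: x ∥ r, y ⊥ (x, moment₂), z = x × y.

    When the second moment is (numerically) parallel to r the y axis is
    ambiguous; an arbitrary perpendicular is chosen and logged.
    """
    if not (d1.defined and d2.defined):
        raise DegenerateScanError("both dipoles must be defined to build a frame")
    g = PairGeometry.between(d1, d2)
    x = g.u_r
    cross = np.cross(x, d2.moment)
    norm_m = np.linalg.norm(d2.moment)
    if norm_m == 0.0 or np.linalg.norm(cross) <= _PARALLEL_TOL * norm_m:
        logger.warning(
            "moment of %s is parallel to the inter-dipole axis; "
            "picking an arbitrary perpendicular for the y axis",
            d2.monomer_id or "dipole 2",
        )
        y = _any_perpendicular(x)
    else:
        y = _unit(cross)
    z = np.cross(x, y)
    return LocalFrame(np.asarray(d2.application_point, float), x, y, z)


def rotate_vector(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation of ``v`` about unit vector ``axis``."""
    axis = np.asarray(axis, float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("rotation axis must be unit-norm")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    return rot.apply(np.asarray(v, float))


def find_min_angle(s: ScanResult, rel_tol: float = 1e-12) -> tuple[int, float]:
    """Grid angle of the global minimum; ties resolved toward 0°.

    Ties (within ``rel_tol`` relative to the energy span) are broken toward
    the angle whose signed alias is closest to 0°, preferring the positive
    one, and flagged on the result.
    """
    energies = np.asarray(s.energies, float)
    angles = np.asarray(s.angles_deg)
    e_min = energies.min()
    span = float(energies.max() - e_min)
    tol = rel_tol * max(span, abs(e_min), 1.0)
    candidates = np.flatnonzero(energies <= e_min + tol)
    def signed_key(i: int) -> tuple[float, int]:
        a = int(angles[i]) % 360
        signed = a - 360 if a > 180 else a
        return (abs(signed), 0 if signed >= 0 else 1)
    best = min(candidates, key=signed_key)
    s.tie = len(candidates) > 1
    s.min_angle_deg = int(angles[best])
    s.min_energy = float(energies[best])
    return s.min_angle_deg, s.min_energy


def _scan_axis(
    d1: PseudoDipole,
    d2: PseudoDipole,
    g: PairGeometry,
    axis_name: str,
    axis_vec: np.ndarray,
    step_deg: float,
    distance_unit: str,
    r0: float,
) -> ScanResult:
    angles = np.arange(0, 360, step_deg)
    energies = np.empty(len(angles))
    for i, ang in enumerate(angles):
        rotated = replace(d2, moment=rotate_vector(d2.moment, axis_vec, float(ang)))
        energies[i] = pair_energy(
            d1, rotated, g, distance_unit=distance_unit, r0=r0
        ).value
    result = ScanResult(
        kind=d1.kind,
        axis=axis_name,
        angles_deg=angles.astype(int),
        energies=energies,
        native_energy=float(energies[0]),
        min_angle_deg=0,
        min_energy=float(energies[0]),
    )
    find_min_angle(result)
    return result


def rotation_scan(
    d1: PseudoDipole,
    d2: PseudoDipole,
    step_deg: float = 10.0,
    distance_unit: str = "scaled",
    r0: float = DEFAULT_R0,
) -> dict[str, ScanResult]:
    """Energy over a full turn of dipole 2's moment about each frame axis.

    Returns one :class:`ScanResult` per axis (``x``, ``y``, ``z``); the
    native orientation is angle 0 and the geometry is held fixed, so
    ``energies[0]`` equals the native pair energy on every axis.  The scan
    is pure — the input dipoles are never mutated.
    """
    if not (d1.defined and d2.defined):
        raise DegenerateScanError("rotation scan requires two defined dipoles")
    frame = local_frame(d1, d2)
    g = PairGeometry.between(d1, d2)
    return {
        name: _scan_axis(
            d1, d2, g, name, frame.axis(name), step_deg, distance_unit, r0
        )
        for name in AXES
    }


def translation_arrangements(
    d1: PseudoDipole,
    d2: PseudoDipole,
) -> dict[str, PseudoDipole]:
    """The three alternative pair arrangements as repositioned dipoles.

    Each arrangement keeps dipole 1 fixed and returns a re-posed dipole 2:
    its moment made parallel to dipole 1's (magnitude preserved) and its
    application point moved to the native center distance |r| along the
    arrangement's displacement direction.  The perpendicular displacement
    direction is the component of the native separation orthogonal to the
    first moment (an arbitrary perpendicular when that vanishes).
    """
    if not (d1.defined and d2.defined):
        raise DegenerateScanError("translation arrangements require defined dipoles")
    if np.linalg.norm(d1.moment) == 0.0 or np.linalg.norm(d2.moment) == 0.0:
        raise DegenerateScanError("zero moment: arrangement undefined")
    g = PairGeometry.between(d1, d2)
    m1 = _unit(d1.moment)
    perp = g.r_vec - (g.r_vec @ m1) * m1
    if np.linalg.norm(perp) <= _PARALLEL_TOL * g.r_mag:
        perp = _any_perpendicular(m1)
    else:
        perp = _unit(perp)
    along = m1 if g.r_vec @ m1 >= 0 else -m1
    displacements = {
        "side_by_side": perp,
        "top_down": along,
        "staggered": _unit(perp + along),
    }
    new_moment = m1 * float(np.linalg.norm(d2.moment))
    origin = np.asarray(d1.application_point, float)
    out = {}
    for name, direction in displacements.items():
        out[name] = replace(
            d2,
            moment=new_moment.copy(),
            application_point=origin + g.r_mag * direction,
        )
    return out


def translation_scan(
    d1: PseudoDipole,
    d2: PseudoDipole,
    step_deg: float = 10.0,
    distance_unit: str = "scaled",
    r0: float = DEFAULT_R0,
) -> dict[str, dict[str, ScanResult]]:
    """Rotation scans re-run in each translation arrangement.

    Returns ``{arrangement: {axis: ScanResult}}``; the arrangement's 0°
    energy is its parallel-moments pair energy.
    """
    out = {}
    for name, moved in translation_arrangements(d1, d2).items():
        scans = rotation_scan(d1, moved, step_deg, distance_unit, r0)
        for axis_name, s in scans.items():
            s.axis = f"{name}:{axis_name}"
        out[name] = scans
    return out


# ---------------------------------------------------------------------------
# tabular writers

def scan_table(scans: Sequence[ScanResult]) -> pd.DataFrame:
    """Long-format table (axis/arrangement, angle_deg, energy)."""
    rows = []
    for s in scans:
        for ang, en in zip(s.angles_deg, s.energies):
            rows.append({"axis": s.axis, "angle_deg": int(ang), "energy": float(en)})
    return pd.DataFrame(rows, columns=["axis", "angle_deg", "energy"])


def minima_summary(scans: Sequence[ScanResult]) -> list[dict]:
    """JSON-ready minima per scan: location, signed alias, energies, tie flag."""
    return [
        {
            "axis": s.axis,
            "kind": s.kind,
            "min_angle_deg": s.min_angle_deg,
            "min_angle_signed": s.min_angle_signed,
            "min_energy": s.min_energy,
            "native_energy": s.native_energy,
            "tie": s.tie,
        }
        for s in scans
    ]
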