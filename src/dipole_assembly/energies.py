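"""Dipole–dipole pseudo-energies and assembly-level statistics.

Two kernels, both in arbitrary units (their constants are set to 1), with
negative = attractive throughout:

* electrostatic, the classical point-dipole interaction (4πε₀ = 1)::

      enD = −[3(u_r·D₁)(u_r·D₂) − D₁·D₂] / r³

* hydrophobic, the same orientational form with the overall sign flipped
  (equal hydrophobic charges attract) and a short-range exponential law
  replacing the power law (k = 1)::

      enH = +[3(u_r·H₁)(u_r·H₂) − H₁·H₂] / (k·e^r)

r is the distance between the two dipoles' application points.  For enH the
distance entering the exponent is expressed in a configurable unit: the
default ``scaled`` mode uses r/r₀ with r₀ = 10 Å, keeping the exponential
in a numerically meaningful regime at inter-monomer distances; ``angstrom``
and ``nanometer`` are available for calibration.  The unit choice is a pure
positive rescaling across a rotation grid, so it never moves a scan
minimum.

Because the two kernels have unrelated arbitrary units, enH and enD
magnitudes are never compared with each other; only their signs enter the
driver classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dipoles import PseudoDipole

DISTANCE_UNITS = ("angstrom", "nanometer", "scaled")
DEFAULT_R0 = 10.0  # Å, for the "scaled" exponent unit

CLASSIFICATION_LABELS = (
    "hydrophobic_driven",
    "electrostatic_driven",
    "dual_attractive",
    "dual_repulsive",
    "indeterminate",
)


class SingularGeometryError(ZeroDivisionError):
    """Two dipoles share an application point (r = 0)."""


class MixedKindError(TypeError):
    """An energy kernel was handed dipoles of the wrong kind."""


@dataclass(frozen=True)
class PairGeometry:
    """Separation of two dipoles: vector from dipole 1's application point
    to dipole 2's, its magnitude and unit vector."""

    r_vec: np.ndarray
    r_mag: float
    u_r: np.ndarray

    @classmethod
    def between(cls, d1: PseudoDipole, d2: PseudoDipole) -> "PairGeometry":
        r_vec = np.asarray(d2.application_point, float) - np.asarray(
            d1.application_point, float
        )
        r_mag = float(np.linalg.norm(r_vec))
        if r_mag == 0.0:
            raise SingularGeometryError("dipole application points coincide")
        return cls(r_vec, r_mag, r_vec / r_mag)

    def reversed(self) -> "PairGeometry":
        return PairGeometry(-self.r_vec, self.r_mag, -self.u_r)


@dataclass(frozen=True)
class EnergyValue:
    kind: str
    value: float
    defined: bool = True

    def __float__(self) -> float:
        return self.value


def _orientation_term(m1: np.ndarray, m2: np.ndarray, u_r: np.ndarray) -> float:
    return float(3.0 * (u_r @ m1) * (u_r @ m2) - m1 @ m2)


def energy_electrostatic(
    d1: PseudoDipole, d2: PseudoDipole, g: PairGeometry
) -> EnergyValue:
    """enD of two electric dipoles; 0 and flagged undefined if either is."""
    if d1.kind != "electrostatic" or d2.kind != "electrostatic":
        raise MixedKindError("energy_electrostatic requires electrostatic dipoles")
    if g.r_mag == 0.0:
        raise SingularGeometryError("r = 0")
    if not (d1.defined and d2.defined):
        return EnergyValue("electrostatic", 0.0, defined=False)
    value = -_orientation_term(d1.moment, d2.moment, g.u_r) / g.r_mag**3
    return EnergyValue("electrostatic", value)


def _exponent_distance(r_mag: float, distance_unit: str, r0: float) -> float:
    if distance_unit == "angstrom":
        return r_mag
    if distance_unit == "nanometer":
        return r_mag / 10.0
    if distance_unit == "scaled":
        return r_mag / r0
    raise ValueError(f"unknown distance_unit {distance_unit!r}")


def energy_hydrophobic(
    d1: PseudoDipole,
    d2: PseudoDipole,
    g: PairGeometry,
    distance_unit: str = "scaled",
    r0: float = DEFAULT_R0,
) -> EnergyValue:
    """enH of two hydrophobic dipoles (note the flipped overall sign)."""
    if d1.kind != "hydrophobic" or d2.kind != "hydrophobic":
        raise MixedKindError("energy_hydrophobic requires hydrophobic dipoles")
    if g.r_mag == 0.0:
        raise SingularGeometryError("r = 0")
    if not (d1.defined and d2.defined):
        return EnergyValue("hydrophobic", 0.0, defined=False)
    r_eff = _exponent_distance(g.r_mag, distance_unit, r0)
    value = _orientation_term(d1.moment, d2.moment, g.u_r) / np.exp(r_eff)
    return EnergyValue("hydrophobic", value)


def pair_energy(
    d1: PseudoDipole,
    d2: PseudoDipole,
    g: PairGeometry | None = None,
    distance_unit: str = "scaled",
    r0: float = DEFAULT_R0,
) -> EnergyValue:
    """Kind-dispatching pairwise energy; geometry derived from the
    application points when not supplied."""
    if d1.kind != d2.kind:
        raise MixedKindError(f"cannot mix kinds {d1.kind!r} and {d2.kind!r}")
    if g is None:
        g = PairGeometry.between(d1, d2)
    if d1.kind == "electrostatic":
        return energy_electrostatic(d1, d2, g)
    return energy_hydrophobic(d1, d2, g, distance_unit, r0)


# ---------------------------------------------------------------------------
# assembly statistics

@dataclass
class PairStats:
    kind: str
    mean: float
    sd: float
    n_pairs: int
    defined: bool = True


@dataclass
class GrowthCurve:
    kind: str
    points: list[tuple[int, float]]
    mode: str  # "sequential" | "around_center"
    center_ordinal: int | None = None

    @property
    def n(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def energy(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class DriverClassification:
    mean_enH: float
    sd_enH: float
    mean_enD: float
    sd_enD: float
    n_pairs: int
    label: str


def consecutive_pair_stats(
    dipoles: Sequence[PseudoDipole],
    n_pairs: int | None = None,
    distance_unit: str = "scaled",
    r0: float = DEFAULT_R0,
) -> PairStats:
    """Mean ± sample SD of the pairwise energy over consecutive pairs.

    Pairs are ordinal neighbours (i, i+1) in assembly order; pairs with an
    undefined dipole on either side are dropped.  ``n_pairs`` truncates the
    consecutive-pair list before the defined-filter.  With fewer than one
    defined pair the result is flagged indeterminate; SD is NaN for a
    single pair (sample SD needs n ≥ 2).
    """
    if len(dipoles) < 2:
        return PairStats(dipoles[0].kind if dipoles else "", float("nan"),
                         float("nan"), 0, defined=False)
    kind = dipoles[0].kind
    pairs = list(zip(dipoles[:-1], dipoles[1:]))
    if n_pairs is not None:
        pairs = pairs[:n_pairs]
    values = [
        pair_energy(a, b, distance_unit=distance_unit, r0=r0).value
        for a, b in pairs
        if a.defined and b.defined
    ]
    if not values:
        return PairStats(kind, float("nan"), float("nan"), 0, defined=False)
    arr = np.array(values)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return PairStats(kind, float(arr.mean()), sd, len(arr))


def _all_pairs_sum(
    dipoles: Sequence[PseudoDipole], distance_unit: str, r0: float
) -> float:
    total = 0.0
    for i in range(len(dipoles)):
        for j in range(i + 1, len(dipoles)):
            total += pair_energy(
                dipoles[i], dipoles[j], distance_unit=distance_unit, r0=r0
            ).value
    return total


def growth_curve(
    dipoles: Sequence[PseudoDipole],
    mode: str = "sequential",
    center_ordinal: int | None = None,
    distance_unit: str = "scaled",
    r0: float = DEFAULT_R0,
) -> GrowthCurve:
    """Cumulative all-pairs energy E(N) of a growing assembly.

    ``sequential``: elements enter in assembly order, so the point at N is
    the all-pairs sum over elements 1..N.  ``around_center``: the element
    with ordinal ``center_ordinal`` (1-based) enters first and the rest
    join by increasing distance of their application points from its own;
    the point at N covers the center plus its N−1 nearest elements.
    Undefined dipoles contribute zero energy to every pair.
    """
    if len(dipoles) < 2:
        raise ValueError("growth curve requires at least two monomers")
    kind = dipoles[0].kind
    if mode == "sequential":
        order = list(dipoles)
    elif mode == "around_center":
        if center_ordinal is None or not 1 <= center_ordinal <= len(dipoles):
            raise ValueError(f"invalid center_ordinal {center_ordinal!r}")
        center = dipoles[center_ordinal - 1]
        rest = [d for i, d in enumerate(dipoles) if i != center_ordinal - 1]
        rest.sort(
            key=lambda d: float(
                np.linalg.norm(d.application_point - center.application_point)
            )
        )
        order = [center] + rest
    else:
        raise ValueError(f"unknown growth mode {mode!r}")

    points: list[tuple[int, float]] = []
    total = 0.0
    for n in range(2, len(order) + 1):
        new = order[n - 1]
        for prev in order[: n - 1]:
            if prev.defined and new.defined:
                total += pair_energy(
                    prev, new, distance_unit=distance_unit, r0=r0
                ).value
        points.append((n, total))
    return GrowthCurve(kind, points, mode, center_ordinal)


def classify_driver(stats_H: PairStats, stats_D: PairStats) -> DriverClassification:
    """Driver label from the signs of the mean consecutive-pair energies.

    Magnitudes of enH and enD are never compared across kinds — their
    arbitrary units are unrelated — so only the sign pattern enters:
    both means negative → dual_attractive; enH<0≤enD → hydrophobic_driven;
    enD<0≤enH → electrostatic_driven; both ≥0 → dual_repulsive; an
    undefined mean → indeterminate.
    """
    if not (stats_H.defined and stats_D.defined):
        label = "indeterminate"
    elif stats_H.mean < 0 and stats_D.mean < 0:
        label = "dual_attractive"
    elif stats_H.mean < 0 <= stats_D.mean:
        label = "hydrophobic_driven"
    elif stats_D.mean < 0 <= stats_H.mean:
        label = "electrostatic_driven"
    else:
        label = "dual_repulsive"
    return DriverClassification(
        stats_H.mean, stats_H.sd, stats_D.mean, stats_D.sd,
        min(stats_H.n_pairs, stats_D.n_pairs)
        if stats_H.defined and stats_D.defined
        else max(stats_H.n_pairs, stats_D.n_pairs),
        label,
    )


# ---------------------------------------------------------------------------
# tabular writers

def pair_energy_table(
    dipoles_H: Sequence[PseudoDipole],
    dipoles_D: Sequence[PseudoDipole],
    distance_unit: str = "scaled",
    r0: float = DEFAULT_R0,
    consecutive_only: bool = True,
) -> pd.DataFrame:
    """Per-pair energy table: ordinal_i, ordinal_j, r (Å), enH, enD.

    Undefined energies appear as NaN.  ``consecutive_only`` limits rows to
    ordinal neighbours; otherwise all pairs are tabulated.
    """
    if len(dipoles_H) != len(dipoles_D):
        raise ValueError("kind lists must cover the same monomers")
    n = len(dipoles_H)
    idx_pairs = (
        [(i, i + 1) for i in range(n - 1)]
        if consecutive_only
        else [(i, j) for i in range(n) for j in range(i + 1, n)]
    )
    rows = []
    for i, j in idx_pairs:
        hi, hj = dipoles_H[i], dipoles_H[j]
        di, dj = dipoles_D[i], dipoles_D[j]
        gh = PairGeometry.between(hi, hj) if hi.defined and hj.defined else None
        gd = PairGeometry.between(di, dj) if di.defined and dj.defined else None
        enH = (
            energy_hydrophobic(hi, hj, gh, distance_unit, r0).value
            if gh is not None
            else float("nan")
        )
        enD = energy_electrostatic(di, dj, gd).value if gd is not None else float("nan")
        r_ref = gh if gh is not None else gd
        rows.append(
            {
                "ordinal_i": i + 1,
                "ordinal_j": j + 1,
                "r": r_ref.r_mag if r_ref is not None else float("nan"),
                "enH": enH,
                "enD": enD,
            }
        )
    return pd.DataFrame(rows, columns=["ordinal_i", "ordinal_j", "r", "enH", "enD"])


def growth_curve_table(curve: GrowthCurve) -> pd.DataFrame:
    return pd.DataFrame({"N": curve.n, "energy": curve.energy})


def classification_json(
    cls: DriverClassification, settings_fingerprint: str, path: str | Path | None = None
) -> dict:
    payload = {
        "mean_enH": cls.mean_enH,
        "sd_enH": cls.sd_enH,
        "mean_enD": cls.mean_enD,
        "sd_enD": cls.sd_enD,
        "n_pairs": cls.n_pairs,
        "label": cls.label,
        "settings_fingerprint": settings_fingerprint,
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    return payload
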