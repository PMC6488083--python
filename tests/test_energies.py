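"""Energy kernels, pair statistics, growth curves and driver labels."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dipole_assembly.energies import (
    MixedKindError,
    PairGeometry,
    PairStats,
    SingularGeometryError,
    classify_driver,
    consecutive_pair_stats,
    energy_electrostatic,
    energy_hydrophobic,
    growth_curve,
    pair_energy,
    pair_energy_table,
)
from dipole_assembly.synthetic_fixtures import dipole_pair

from .conftest import assembly_dipoles


def pair(m1, m2, r_vec, kind):
    d1, d2 = dipole_pair(m1, m2, r_vec, kind)
    return d1, d2, PairGeometry.between(d1, d2)


E = math.e


class TestClosedForms:
    """The canonical dipole geometries, exact to machine precision."""

    @pytest.mark.parametrize(
        "m1, m2, r_vec, expected",
        [
            ([0, 0, 1], [0, 0, 1], [1, 0, 0], +1.0),  # ⊥ r, parallel: repulsive
            ([1, 0, 0], [1, 0, 0], [1, 0, 0], -2.0),  # collinear head-to-tail
            ([0, 0, 1], [0, 0, -1], [2, 0, 0], -1 / 8),  # ⊥ r, antiparallel, r=2
        ],
    )
    def test_electrostatic(self, m1, m2, r_vec, expected):
        d1, d2, g = pair(m1, m2, r_vec, "electrostatic")
        assert energy_electrostatic(d1, d2, g).value == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize(
        "m1, m2, r_vec, expected",
        [
            ([0, 0, 1], [0, 0, 1], [1, 0, 0], -1 / E),  # aligned H attract
            ([0, 0, 1], [0, 0, -1], [1, 0, 0], +1 / E),  # counter-aligned repel
            ([1, 0, 0], [1, 0, 0], [1, 0, 0], +2 / E),  # collinear: repulsive
        ],
    )
    def test_hydrophobic_angstrom_unit(self, m1, m2, r_vec, expected):
        d1, d2, g = pair(m1, m2, r_vec, "hydrophobic")
        value = energy_hydrophobic(d1, d2, g, distance_unit="angstrom").value
        assert value == pytest.approx(expected, abs=1e-12)

    def test_exponent_distance_units(self):
        d1, d2, g = pair([0, 0, 1], [0, 0, 1], [10, 0, 0], "hydrophobic")
        ang = energy_hydrophobic(d1, d2, g, "angstrom").value
        nm = energy_hydrophobic(d1, d2, g, "nanometer").value
        scaled = energy_hydrophobic(d1, d2, g, "scaled", r0=10.0).value
        assert ang == pytest.approx(-math.exp(-10), abs=1e-15)
        assert nm == pytest.approx(-math.exp(-1), abs=1e-12)
        assert scaled == nm  # r0 = 10 Å makes "scaled" and nm coincide here


class TestKernelContracts:
    def test_mixed_kinds_rejected(self):
        dh, _, g = pair([0, 0, 1], [0, 0, 1], [1, 0, 0], "hydrophobic")
        de, _, _ = pair([0, 0, 1], [0, 0, 1], [1, 0, 0], "electrostatic")
        with pytest.raises(MixedKindError):
            pair_energy(dh, de)
        with pytest.raises(MixedKindError):
            energy_electrostatic(dh, dh, g)

    def test_coincident_points_singular(self):
        d1, d2 = dipole_pair([0, 0, 1], [0, 0, 1], [0, 0, 0], "hydrophobic")
        with pytest.raises(SingularGeometryError):
            PairGeometry.between(d1, d2)

    def test_undefined_dipole_gives_flagged_zero(self):
        d1, d2, g = pair([0, 0, 1], [0, 0, 0], [1, 0, 0], "hydrophobic")
        assert not d2.defined
        result = energy_hydrophobic(d1, d2, g)
        assert result.value == 0.0 and not result.defined

    @pytest.mark.parametrize("kind", ["electrostatic", "hydrophobic"])
    def test_pair_symmetry(self, kind):
        rng = np.random.default_rng(42)
        for _ in range(10):
            d1, d2 = dipole_pair(
                rng.normal(size=3), rng.normal(size=3), rng.normal(size=3) * 5, kind
            )
            g = PairGeometry.between(d1, d2)
            forward = pair_energy(d1, d2, g).value
            backward = pair_energy(d2, d1, g.reversed()).value
            assert forward == pytest.approx(backward, rel=1e-12)

    def test_electrostatic_follows_inverse_cube(self):
        distances = np.linspace(5, 40, 12)
        values = []
        for r in distances:
            d1, d2, g = pair([0, 0, 1], [0, 0, 1], [r, 0, 0], "electrostatic")
            values.append(abs(energy_electrostatic(d1, d2, g).value))
        slope = np.polyfit(np.log(distances), np.log(values), 1)[0]
        assert slope == pytest.approx(-3.0, abs=1e-9)

    def test_hydrophobic_follows_exponential(self):
        distances = np.linspace(5, 40, 12)
        values = []
        for r in distances:
            d1, d2, g = pair([0, 0, 1], [0, 0, 1], [r, 0, 0], "hydrophobic")
            values.append(abs(energy_hydrophobic(d1, d2, g, "angstrom").value))
        slope = np.polyfit(distances, np.log(values), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_rigid_motion_leaves_pair_energy_unchanged(self):
        rng = np.random.default_rng(0)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 20
        for kind in ("electrostatic", "hydrophobic"):
            d1, d2 = dipole_pair([0.4, 1.0, -0.2], [1.1, 0.3, 0.8], [9, 2, -4], kind)
            before = pair_energy(d1, d2).value
            m1, m2 = dipole_pair(
                R @ d1.moment, R @ d2.moment, R @ (d2.application_point - d1.application_point), kind
            )
            after = pair_energy(m1, m2).value
            assert after == pytest.approx(before, rel=1e-12)


class TestConsecutivePairStats:
    def test_identical_equally_spaced_monomers_have_zero_sd(self):
        dips = [
            dipole_pair([0, 0, 1], [0, 0, 1], [0, 0, 0], "hydrophobic")[0]
        ]
        # four copies of the same dipole marched along x
        from dataclasses import replace

        dips = [
            replace(dips[0], application_point=np.array([8.0 * i, 0.0, 0.0]))
            for i in range(4)
        ]
        stats = consecutive_pair_stats(dips)
        assert stats.sd == pytest.approx(0.0, abs=1e-15)
        assert stats.mean == pytest.approx(
            pair_energy(dips[0], dips[1]).value, rel=1e-12
        )

    def test_three_monomer_mean_matches_hand_sum(self):
        from dataclasses import replace

        base, _ = dipole_pair([0, 1, 0], [0, 1, 0], [1, 0, 0], "hydrophobic")
        d1 = replace(base, application_point=np.array([0.0, 0.0, 0.0]))
        d2 = replace(base, moment=np.array([0.0, 0.5, 0.5]),
                     application_point=np.array([6.0, 0.0, 0.0]))
        d3 = replace(base, moment=np.array([1.0, 0.0, 0.0]),
                     application_point=np.array([11.0, 0.0, 0.0]))
        e12 = pair_energy(d1, d2).value
        e23 = pair_energy(d2, d3).value
        stats = consecutive_pair_stats([d1, d2, d3])
        assert stats.n_pairs == 2
        assert stats.mean == pytest.approx((e12 + e23) / 2, rel=1e-12)
        assert stats.sd == pytest.approx(np.std([e12, e23], ddof=1), rel=1e-12)

    def test_n_pairs_truncation(self, hydrophobic_stack):
        dips = assembly_dipoles(hydrophobic_stack, "hydrophobic")
        full = consecutive_pair_stats(dips)
        first3 = consecutive_pair_stats(dips, n_pairs=3)
        assert full.n_pairs == len(dips) - 1
        assert first3.n_pairs == 3

    def test_undefined_dipoles_are_dropped(self):
        d1, undef = dipole_pair([0, 0, 1], [0, 0, 0], [7, 0, 0], "hydrophobic")
        stats = consecutive_pair_stats([d1, undef])
        assert not stats.defined and stats.n_pairs == 0


class TestGrowthCurve:
    def test_first_point_is_the_single_pair_energy(self, hydrophobic_stack):
        dips = assembly_dipoles(hydrophobic_stack, "hydrophobic")
        curve = growth_curve(dips)
        assert curve.points[0][0] == 2
        assert curve.points[0][1] == pytest.approx(
            pair_energy(dips[0], dips[1]).value, rel=1e-12
        )

    @pytest.mark.parametrize("kind", ["electrostatic", "hydrophobic"])
    def test_points_match_bruteforce_all_pairs(self, kind):
        from dataclasses import replace

        rng = np.random.default_rng(123)
        base, _ = dipole_pair([0, 0, 1], [0, 0, 1], [1, 0, 0], kind)
        dips = [
            replace(base, moment=rng.normal(size=3),
                    application_point=rng.normal(size=3) * 15)
            for _ in range(9)
        ]
        curve = growth_curve(dips)
        for n, energy in curve.points:
            brute = sum(
                pair_energy(dips[i], dips[j]).value
                for i in range(n)
                for j in range(i + 1, n)
            )
            assert energy == pytest.approx(brute, rel=1e-10, abs=1e-12)

    def test_additivity_between_consecutive_points(self, hydrophobic_stack):
        dips = assembly_dipoles(hydrophobic_stack, "hydrophobic")
        curve = growth_curve(dips)
        for (n0, e0), (n1, e1) in zip(curve.points, curve.points[1:]):
            shell = sum(
                pair_energy(dips[i], dips[n1 - 1]).value for i in range(n1 - 1)
            )
            assert e1 - e0 == pytest.approx(shell, rel=1e-10)

    def test_around_center_orders_by_distance(self):
        from dataclasses import replace

        base, _ = dipole_pair([0, 0, 1], [0, 0, 1], [1, 0, 0], "hydrophobic")
        xs = [0.0, 30.0, 8.0, 16.0]  # center no. 3 at x=8: nearest is x=0 then 16, 30
        dips = [
            replace(base, application_point=np.array([x, 0.0, 0.0])) for x in xs
        ]
        curve = growth_curve(dips, mode="around_center", center_ordinal=3)
        assert curve.points[0][1] == pytest.approx(
            pair_energy(dips[2], dips[0]).value, rel=1e-12
        )
        # the full set: curve end equals the all-pairs sum regardless of order
        total = sum(
            pair_energy(dips[i], dips[j]).value
            for i in range(4)
            for j in range(i + 1, 4)
        )
        assert curve.points[-1][1] == pytest.approx(total, rel=1e-12)

    def test_invalid_center_rejected(self, hydrophobic_stack):
        dips = assembly_dipoles(hydrophobic_stack, "hydrophobic")
        with pytest.raises(ValueError, match="center_ordinal"):
            growth_curve(dips, mode="around_center", center_ordinal=99)


class TestDriverClassification:
    @pytest.mark.parametrize(
        "mean_H, mean_D, label",
        [
            (-2.34, +2.01, "hydrophobic_driven"),
            (+0.225, -31.79, "electrostatic_driven"),
            (-0.135, -1.475, "dual_attractive"),
            (+0.5, +0.5, "dual_repulsive"),
        ],
    )
    def test_sign_pattern_labels(self, mean_H, mean_D, label):
        stats_H = PairStats("hydrophobic", mean_H, 0.1, 10)
        stats_D = PairStats("electrostatic", mean_D, 0.1, 10)
        assert classify_driver(stats_H, stats_D).label == label

    def test_undefined_mean_is_indeterminate(self):
        stats_H = PairStats("hydrophobic", float("nan"), float("nan"), 0, defined=False)
        stats_D = PairStats("electrostatic", -1.0, 0.1, 5)
        assert classify_driver(stats_H, stats_D).label == "indeterminate"


def test_pair_energy_table_flags_undefined_as_nan(hydrophobic_stack):
    dips_H = assembly_dipoles(hydrophobic_stack, "hydrophobic")
    d_undef, _ = dipole_pair([0, 0, 0], [0, 0, 1], [1, 0, 0], "electrostatic")
    from dataclasses import replace

    dips_D = [
        replace(d_undef, application_point=h.application_point) for h in dips_H
    ]
    table = pair_energy_table(dips_H, dips_D)
    assert list(table.columns) == ["ordinal_i", "ordinal_j", "r", "enH", "enD"]
    assert len(table) == len(dips_H) - 1
    assert table["enD"].isna().all()
    assert np.isfinite(table["enH"]).all()
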