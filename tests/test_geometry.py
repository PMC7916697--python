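"""Point-charge interference model: closed forms against coordinate oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tccsel.geometry import (
    DEFAULT_CHARGES,
    DEFAULT_CONSTANTS,
    ChargeSet,
    GeometryError,
    InfeasibleGeometryError,
    InterferenceGeometry,
    PhysicalConstants,
    PointCharge,
    coulomb_force,
    force_profile,
    implied_phi,
    lysine_distance,
    minimal_interference,
    net_attraction,
    repellent_component,
)

CA = PointCharge("Ca2+", +2)
ASP = PointCharge("D", -1)
LYS = PointCharge("K", +1)


def embed_scene(a, theta_deg, r):
    """Place ion at origin, aspartate at (a, 0), lysine on the θ ray at r.

    Returns (b, phi_deg) measured from the coordinates: b is the
    aspartate–lysine distance, phi the angle at the lysine between its
    directions to the ion and to the aspartate.
    """
    theta = math.radians(theta_deg)
    kx, ky = r * math.cos(theta), r * math.sin(theta)
    b = math.hypot(kx - a, ky)
    to_ion = np.array([-kx, -ky]) / r
    to_asp = np.array([a - kx, -ky]) / b
    phi = math.degrees(math.acos(float(np.clip(to_ion @ to_asp, -1.0, 1.0))))
    return b, phi


class TestCoulombForce:
    def test_reference_attraction(self):
        f = coulomb_force(CA, ASP, 4.3)
        assert f.interaction == "attraction"
        assert f.magnitude == pytest.approx(2.489e-9, rel=1e-3)

    def test_reference_repulsion(self):
        f = coulomb_force(CA, LYS, 8.1)
        assert f.interaction == "repulsion"
        assert f.magnitude == pytest.approx(0.702e-9, rel=1e-3)

    def test_zero_charge_gives_zero(self):
        f = coulomb_force(CA, PointCharge("X", 0.0), 3.0)
        assert f.magnitude == 0.0 and f.interaction == "none"

    @given(
        q1=st.floats(-3, 3, allow_nan=False).filter(lambda q: abs(q) > 1e-3),
        q2=st.floats(-3, 3, allow_nan=False).filter(lambda q: abs(q) > 1e-3),
        d=st.floats(0.5, 50),
    )
    @settings(max_examples=100, derandomize=True)
    def test_inverse_square_scaling(self, q1, q2, d):
        a = PointCharge("a", q1)
        b = PointCharge("b", q2)
        near = coulomb_force(a, b, d).magnitude
        far = coulomb_force(a, b, 2 * d).magnitude
        assert far == pytest.approx(near / 4, rel=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(GeometryError):
            coulomb_force(CA, ASP, 0.0)

    def test_codata_charge_shifts_reference_force(self):
        codata = PhysicalConstants(e=1.602176634e-19)
        f = coulomb_force(CA, ASP, 4.3, codata)
        assert f.magnitude == pytest.approx(2.495e-9, rel=1e-3)


class TestLysineDistance:
    def test_collinear_far_side_sums_distances(self):
        geom = InterferenceGeometry(a=4.3, b=3.8, theta=0.0, phi=0.0)
        assert lysine_distance(geom) == pytest.approx(8.1, abs=1e-12)

    def test_collinear_near_side_subtracts(self):
        geom = InterferenceGeometry(a=4.3, b=3.8, theta=0.0, phi=180.0)
        assert lysine_distance(geom) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_overlap_rejected(self):
        geom = InterferenceGeometry(a=4.3, b=4.3, theta=0.0, phi=180.0)
        with pytest.raises(InfeasibleGeometryError):
            lysine_distance(geom)

    def test_infeasible_triangle_rejected(self):
        # b < a·sinθ: the lysine circle never meets the ion ray
        with pytest.raises(InfeasibleGeometryError):
            InterferenceGeometry(a=10.0, b=1.0, theta=60.0, phi=0.0)

    def test_tangent_case_requires_discriminant_zero(self):
        geom = InterferenceGeometry(a=4.0, b=3.0, theta=10.0, phi=90.0)
        with pytest.raises(InfeasibleGeometryError):
            lysine_distance(geom)

    def test_inconsistent_phi_rejected_in_strict_mode(self):
        geom = InterferenceGeometry(a=4.3, b=3.8, theta=0.0, phi=45.0)
        with pytest.raises(InfeasibleGeometryError):
            lysine_distance(geom, strict_phi=True)

    def test_matches_coordinate_embedding_on_random_scenes(self):
        """The ± solver agrees with explicit 2-D placement to 1e-9 Å."""
        rng = np.random.default_rng(20260923)
        checked = 0
        while checked < 1200:
            a = rng.uniform(1.0, 10.0)
            theta = rng.uniform(0.0, 89.0)
            r_true = rng.uniform(0.1, 15.0)
            b, phi = embed_scene(a, theta, r_true)
            geom = InterferenceGeometry(a=a, b=b, theta=theta, phi=phi)
            r = lysine_distance(geom, strict_phi=True, phi_tol_deg=1e-5)
            assert abs(r - r_true) < 1e-9
            assert implied_phi(a, b, theta, r) == pytest.approx(phi, abs=1e-6)
            checked += 1


class TestRepellentComponent:
    def test_reference_value(self):
        f = repellent_component(CA, LYS, 8.1, 0.0)
        assert f == pytest.approx(0.702e-9, rel=1e-3)

    def test_vanishes_toward_perpendicular(self):
        f = repellent_component(CA, LYS, 5.0, 89.999)
        assert f == pytest.approx(0.0, abs=1e-13)

    def test_matches_vector_projection_oracle(self):
        """Axial component equals the projected exact Coulomb vector."""
        rng = np.random.default_rng(7)
        ke, e = DEFAULT_CONSTANTS.ke, DEFAULT_CONSTANTS.e
        for _ in range(300):
            r = rng.uniform(0.5, 15.0)
            theta = rng.uniform(0.0, 89.0)
            th = math.radians(theta)
            kx, ky = r * math.cos(th), r * math.sin(th)
            mag = ke * 2 * 1 * e**2 / (r * 1e-10) ** 2
            force_vec = mag * np.array([-kx, -ky]) / r  # repulsion on the ion
            axial_toward_asp = -force_vec[0]  # +x is the ion→aspartate axis
            assert abs(
                repellent_component(CA, LYS, r, theta) - axial_toward_asp
            ) < 1e-18


class TestNetAttraction:
    def test_minimal_configuration_difference(self):
        geom = InterferenceGeometry(a=4.3, b=3.8, theta=0.0, phi=0.0)
        assert net_attraction(geom) == pytest.approx(2.489e-9 - 0.702e-9, rel=1e-3)

    def test_zero_lysine_charge_leaves_pure_attraction(self):
        geom = InterferenceGeometry(a=4.3, b=3.8, theta=0.0, phi=0.0)
        charges = ChargeSet(lys=PointCharge("K0", 0.0))
        assert net_attraction(geom, charges) == pytest.approx(
            coulomb_force(CA, ASP, 4.3).magnitude
        )

    def test_strictly_increasing_in_r_and_crosses_zero(self):
        """F_net(r) = F_a − C/r² rises with r; root at r* = a·√(q_K·cosθ/|q_D|)."""
        a, theta = 4.3, 0.0
        attraction = coulomb_force(CA, ASP, a).magnitude

        def f_net(r):
            return attraction - repellent_component(CA, LYS, r, theta)

        rs = np.linspace(0.5, 12.0, 200)
        nets = [f_net(r) for r in rs]
        assert all(x < y for x, y in zip(nets, nets[1:]))
        from scipy.optimize import brentq

        root = brentq(f_net, 0.5, 12.0, xtol=1e-12)
        closed_form = a * math.sqrt(1.0 * math.cos(math.radians(theta)) / 1.0)
        assert root == pytest.approx(closed_form, abs=1e-9)


class TestMinimalInterference:
    def test_reference_reduction(self):
        res = minimal_interference(4.3, 3.8)
        assert res.r == pytest.approx(8.1)
        assert res.reduction_percent >= 28.0
        assert res.reduction_percent == pytest.approx(28.18, abs=0.01)

    def test_equal_distances_quarter_ratio(self):
        # ke, q_Ca and e cancel: 100·(q_K/|q_D|)·a²/(a+b)² = 25 for a = b
        res = minimal_interference(5.0, 5.0)
        assert res.reduction_percent == pytest.approx(25.0, abs=1e-9)

    def test_distant_lysine_vanishes(self):
        assert minimal_interference(4.3, 1e9).reduction_percent < 1e-14

    @given(a=st.floats(0.5, 20), b=st.floats(0.5, 20))
    @settings(max_examples=100, derandomize=True)
    def test_reduction_is_charge_scaled_distance_ratio(self, a, b):
        res = minimal_interference(a, b)
        assert res.reduction_percent == pytest.approx(
            100.0 * a**2 / (a + b) ** 2, rel=1e-9
        )


class TestForceProfile:
    def test_single_point_reproduces_reference_forces(self):
        table = force_profile(4.3, 3.8, [8.1], sweep_var="r", theta=0.0)
        row = table.iloc[0]
        assert row.f_attract_N == pytest.approx(2.489e-9, rel=1e-3)
        assert row.f_repel_axis_N == pytest.approx(0.702e-9, rel=1e-3)
        assert bool(row.feasible)

    def test_empty_sweep_gives_empty_table(self):
        table = force_profile(4.3, 3.8, [])
        assert len(table) == 0
        assert list(table.columns)[:5] == [
            "theta_deg",
            "r_angstrom",
            "f_attract_N",
            "f_repel_axis_N",
            "f_net_N",
        ]

    def test_descending_r_sweep_monotonically_decreases_net_force(self):
        rs = np.arange(8.1, 2.9, -0.1)
        table = force_profile(4.3, 3.8, rs, sweep_var="r")
        nets = table.f_net_N.to_numpy()
        assert all(x > y for x, y in zip(nets, nets[1:]))

    def test_infeasible_points_flagged_not_fatal(self):
        table = force_profile(2.0, 1.0, [0.0, 10.0, 60.0, 80.0], sweep_var="theta")
        # sin(60°)·2 > 1 and sin(80°)·2 > 1: no lysine placement exists
        assert list(table.feasible) == [True, True, False, False]
        assert table.f_net_N.isna().tolist() == [False, False, True, True]
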