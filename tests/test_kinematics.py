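"""Closed-form Compton kinematics and cone geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgcc.events import Event
from pgcc.kinematics import (
    DegenerateGeometryError,
    KinematicallyForbiddenError,
    compton_scatter_angle,
    cone_from_event,
    ds_initial_energy,
    geometric_angle,
    scattered_energy,
    ts_initial_energy,
)


def _event(energies, positions):
    energies = np.asarray(energies, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = energies.size
    return Event(energies=energies, positions=positions, module=0,
                 crystals=np.zeros(n, dtype=int), timestamp=0.0)


class TestScatterAngle:
    def test_hand_computed_example(self):
        # 2.22 MeV photon deposits 1.22 MeV: cos = 1 - 0.511*(1/1.0 - 1/2.22)
        theta = compton_scatter_angle(2.22, 1.22)
        assert np.isclose(np.cos(theta), 0.71918, atol=1e-5)
        assert np.isclose(theta, 0.76817, atol=1e-4)

    def test_vanishing_deposit_gives_vanishing_angle(self):
        assert compton_scatter_angle(2.0, 1e-9) < 1e-3

    def test_forbidden_split_raises(self):
        # 0.10 MeV photon cannot transfer 0.05 MeV in a single scatter
        with pytest.raises(KinematicallyForbiddenError):
            compton_scatter_angle(0.10, 0.05)

    @pytest.mark.parametrize("bad", [(1.0, 0.0), (1.0, 1.0), (1.0, 1.5), (0.0, 0.1)])
    def test_invalid_preconditions(self, bad):
        with pytest.raises(ValueError):
            compton_scatter_angle(*bad)

    def test_strictly_increasing_in_deposit(self):
        e0 = 2.22
        deposits = np.linspace(0.01, 1.9, 60)
        angles = [compton_scatter_angle(e0, d) for d in deposits]
        assert (np.diff(angles) > 0).all()

    def test_consistent_with_scattered_energy(self):
        # theta(E, E - E'(theta)) round-trips through the Compton formula
        for theta in (0.3, 1.0, 2.5):
            e_sc = scattered_energy(2.0, theta)
            assert np.isclose(compton_scatter_angle(2.0, 2.0 - e_sc), theta, atol=1e-12)


class TestDsInitialEnergy:
    def test_sum(self):
        assert ds_initial_energy(2.00, 2.44) == pytest.approx(4.44)
        assert ds_initial_energy(1.11, 1.11) == pytest.approx(2.22)

    def test_zero_deposit_rejected(self):
        with pytest.raises(ValueError):
            ds_initial_energy(0.511, 0.0)


class TestGeometricAngle:
    def test_collinear_is_zero(self):
        assert geometric_angle([0, 0, 0], [1, 1, 1], [2, 2, 2]) == pytest.approx(0.0)

    def test_right_angle(self):
        assert geometric_angle([0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(np.pi / 2)

    def test_l_shape_direction_convention(self):
        # The angle is the direction change of the second leg relative to the
        # first; traversing an asymmetric 3-point track backwards probes the
        # other corner, so brute-force vector arithmetic fixes both values.
        p1, p2, p3 = [0, 0, 0], [2, 0, 0], [2, 1, 0]

        def brute(a, b, c):
            u = np.subtract(b, a)
            v = np.subtract(c, b)
            return np.arccos(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v))

        assert geometric_angle(p1, p2, p3) == pytest.approx(brute(p1, p2, p3))
        assert geometric_angle(p3, p2, p1) == pytest.approx(brute(p3, p2, p1))
        assert geometric_angle(p1, p2, p3) == pytest.approx(np.pi / 2)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            geometric_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


class TestTsInitialEnergy:
    def test_hand_computed_example(self):
        # e1=1.0, e2=0.5, theta2=pi/2: E0 = 1.25 + sqrt(0.0625 + 0.5*0.511)
        ev = _event([1.0, 0.5, 0.1],
                    [[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert ts_initial_energy(ev) == pytest.approx(1.8139, abs=2e-4)

    def test_exceeds_first_two_deposits(self):
        ev = _event([1.0, 0.5, 0.1], [[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert ts_initial_energy(ev) > 1.5

    def test_collinear_track_raises(self):
        ev = _event([1.0, 0.5, 0.1], [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            ts_initial_energy(ev)

    def test_forward_simulated_roundtrip(self):
        # build a noiseless triple: known E0, consistent geometry + deposits
        e0 = 4.44
        rng = np.random.default_rng(7)
        for _ in range(20):
            theta1 = rng.uniform(0.2, 1.2)
            theta2 = rng.uniform(0.2, 1.2)
            e_after1 = scattered_energy(e0, theta1)
            e_after2 = scattered_energy(e_after1, theta2)
            e1, e2 = e0 - e_after1, e_after1 - e_after2
            p1 = np.zeros(3)
            d1 = np.array([0.0, -1.0, 0.0])
            p2 = p1 + 2.0 * d1
            # rotate d1 by theta2 about a random azimuth for the second leg
            phi = rng.uniform(0, 2 * np.pi)
            perp = np.array([np.cos(phi), 0.0, np.sin(phi)])
            d2 = np.cos(theta2) * d1 + np.sin(theta2) * perp
            p3 = p2 + 1.5 * d2
            ev = _event([e1, e2, 0.05], [p1, p2, p3])
            assert ts_initial_energy(ev) == pytest.approx(e0, rel=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0.3, 2.8), st.floats(0.05, 2 * np.pi - 0.05),
           st.floats(-5.0, 5.0), st.floats(-5.0, 5.0), st.floats(-5.0, 5.0))
    def test_rigid_motion_invariance(self, angle, az, tx, ty, tz):
        ev = _event([1.0, 0.5, 0.1], [[0, 0, 0], [1, 0, 0], [1, 1, 0.3]])
        base = ts_initial_energy(ev)
        c, s = np.cos(angle), np.sin(angle)
        # rotation about an axis built from the azimuth draw
        ax = np.array([np.cos(az), np.sin(az), 0.4])
        ax /= np.linalg.norm(ax)
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
        moved = _event(ev.energies, ev.positions @ R.T + np.array([tx, ty, tz]))
        assert ts_initial_energy(moved) == pytest.approx(base, rel=1e-9)


class TestConeFromEvent:
    def test_geometry_and_angle(self):
        ev = _event([1.22, 1.0], [[0, -30, 0], [0, -31, 0.5]])
        cone = cone_from_event(ev, 2.22)
        assert np.allclose(cone.apex, [0, -30, 0])
        assert np.isclose(np.linalg.norm(cone.axis), 1.0)
        assert cone.axis @ np.array([0, 1, -0.5]) > 0  # points away from p2
        assert cone.half_angle == pytest.approx(compton_scatter_angle(2.22, 1.22))

    def test_first_deposit_at_least_estimate_rejected(self):
        ev = _event([2.3, 1.0], [[0, -30, 0], [0, -31, 0]])
        with pytest.raises(KinematicallyForbiddenError):
            cone_from_event(ev, 2.2)

    def test_order_swap_changes_cone(self):
        a = _event([1.0, 1.22], [[0, -30, 0], [0, -31, 0.5]])
        b = _event([1.22, 1.0], [[0, -31, 0.5], [0, -30, 0]])
        ca, cb = cone_from_event(a, 2.22), cone_from_event(b, 2.22)
        assert not np.allclose(ca.apex, cb.apex)
        assert not np.allclose(ca.axis, cb.axis)

    def test_emission_point_on_cone_surface(self):
        # noiseless double: emission at known point, first scatter consistent
        e0 = 2.22
        emission = np.array([0.3, 0.0, 12.0])
        p1 = np.array([0.5, -30.5, 13.0])
        d_in = p1 - emission
        d_in /= np.linalg.norm(d_in)
        theta = 0.6
        e1 = e0 - scattered_energy(e0, theta)
        # place p2 along a direction deflected from d_in by exactly theta
        perp = np.cross(d_in, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        d_out = np.cos(theta) * d_in + np.sin(theta) * perp
        p2 = p1 + 1.7 * d_out
        cone = cone_from_event(_event([e1, e0 - e1], [p1, p2]), e0)
        v = emission - cone.apex
        ang = np.arccos(np.clip(v @ cone.axis / np.linalg.norm(v), -1, 1))
        assert abs(ang - cone.half_angle) < 1e-6
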