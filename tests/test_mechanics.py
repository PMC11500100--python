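"""Force laws, fibre rotation/pushing and the cell velocity assembly."""

import numpy as np
import pytest

from fibresim.agents import CellAgent, CellFibreParams, CellParams, FibreAgent
from fibresim.geometry import Segment
from fibresim.initialization import Domain
from fibresim.mechanics import (add_potentials_from_cell,
                                add_potentials_from_fibre, angular_velocity,
                                cell_cell_potential, force_parallel,
                                force_perpendicular, impulse, moment_arm,
                                rotate_orientation, update_cell_velocity)


def make_cell(cid, pos, radius=10.0, **kw):
    cp_keys = {"cell_cell_repulsion", "cell_cell_adhesion", "adhesion_scale"}
    cp = CellParams(radius=radius, **{k: v for k, v in kw.items() if k in cp_keys})
    fp = CellFibreParams(**{k: v for k, v in kw.items() if k not in cp_keys})
    return CellAgent(id=cid, position=np.asarray(pos, dtype=float),
                     radius=radius, params=cp, fibre_params=fp)


def make_fibre(fid, centre, angle, length=30.0, radius=2.0):
    return FibreAgent(id=fid, segment=Segment.from_angle(centre, angle, length, radius))


class TestCellCellPotential:
    def test_zero_beyond_adhesion_range(self):
        a = make_cell(0, (0.0, 0.0))
        b = make_cell(1, (30.0, 0.0))  # d = 30 >= 1.25 * 20
        assert np.allclose(cell_cell_potential(a, b), 0.0)

    def test_pure_adhesion_at_contact_distance(self):
        a = make_cell(0, (0.0, 0.0))
        b = make_cell(1, (20.0, 0.0))  # d = R exactly: repulsion term vanishes
        f = cell_cell_potential(a, b)
        expected = 0.4 * (1 - 20.0 / 25.0) ** 2  # adhesion only, towards b (+x)
        assert f == pytest.approx([expected, 0.0], abs=1e-12)

    def test_hand_evaluated_piecewise_polynomial(self):
        a = make_cell(0, (0.0, 0.0))
        b = make_cell(1, (8.0, 0.0))
        f = cell_cell_potential(a, b)
        rep = -10.0 * (1 - 8.0 / 20.0) ** 2      # repulsion pushes a to -x
        adh = 0.4 * (1 - 8.0 / 25.0) ** 2        # adhesion pulls a to +x
        assert f == pytest.approx([rep + adh, 0.0], abs=1e-12)

    def test_antisymmetric(self, rng):
        for _ in range(200):
            a = make_cell(0, rng.uniform(-10, 10, 2))
            b = make_cell(1, a.position + rng.uniform(-25, 25, 2))
            if np.allclose(a.position, b.position):
                continue
            assert np.allclose(cell_cell_potential(a, b),
                               -cell_cell_potential(b, a), atol=1e-12)

    def test_coincident_centres_deterministic_fallback(self):
        a = make_cell(0, (1.0, 1.0))
        b = make_cell(1, (1.0, 1.0))
        f = cell_cell_potential(a, b)
        assert f[0] > 0 and f[1] == 0.0


class TestFibreDirectedForces:
    P = CellFibreParams(vel_adhesion=0.6, vel_contact=0.5,
                        cell_velocity_max=10.0)

    def test_parallel_force_example(self):
        f = force_parallel(np.array([5.0, 0.0]), np.array([1.0, 0.0]), self.P)
        assert f == pytest.approx([0.3, 0.0], abs=1e-12)

    def test_parallel_vanishes_perpendicular_and_at_vmax(self):
        assert np.allclose(force_parallel(np.array([0.0, 3.0]),
                                          np.array([1.0, 0.0]), self.P), 0.0)
        assert np.allclose(force_parallel(np.array([10.0, 0.0]),
                                          np.array([1.0, 0.0]), self.P), 0.0)

    def test_parallel_clamped_above_vmax(self):
        f = force_parallel(np.array([15.0, 0.0]), np.array([1.0, 0.0]), self.P)
        assert np.allclose(f, 0.0)

    def test_perpendicular_example(self):
        f = force_perpendicular(np.array([3.0, 4.0]), np.array([1.0, 0.0]), self.P)
        assert f == pytest.approx([0.96, 1.28], abs=1e-12)

    def test_perpendicular_vanishes_along_fibre(self):
        assert np.allclose(force_perpendicular(np.array([5.0, 0.0]),
                                               np.array([1.0, 0.0]), self.P), 0.0)

    def test_perpendicular_is_full_friction_orthogonal(self):
        v = np.array([0.0, 2.0])
        f = force_perpendicular(v, np.array([1.0, 0.0]), self.P)
        assert np.allclose(f, 0.5 * v)

    def test_zero_velocity_gives_zero_forces(self):
        z = np.zeros(2)
        assert np.allclose(force_parallel(z, np.array([1.0, 0.0]), self.P), 0.0)
        assert np.allclose(force_perpendicular(z, np.array([1.0, 0.0]), self.P), 0.0)

    def test_directions_and_bound_over_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            v = rng.uniform(-12, 12, 2)
            th = rng.uniform(0, 2 * np.pi)
            f_hat = np.array([np.cos(th), np.sin(th)])
            fp = force_parallel(v, f_hat, self.P)
            fq = force_perpendicular(v, f_hat, self.P)
            assert abs(fp[0] * f_hat[1] - fp[1] * f_hat[0]) < 1e-12  # along f_hat
            assert abs(fq[0] * v[1] - fq[1] * v[0]) < 1e-9           # along v
            assert np.hypot(*fp) <= self.P.vel_adhesion + 1e-12


class TestCellFibreComposition:
    def test_far_cell_feels_nothing(self):
        c = make_cell(0, (0.0, 50.0))
        f = make_fibre(1, (0.0, 0.0), 0.0)
        assert np.allclose(add_potentials_from_fibre(c, f), 0.0)

    def test_touching_cell_at_vmax_gets_contact_terms_only(self):
        c = make_cell(0, (0.0, 12.0), vel_adhesion=0.6, vel_contact=0.5)
        c.previous_velocity = np.array([10.0, 0.0])  # |v| = v_max, v || f
        f = make_fibre(1, (0.0, 0.0), 0.0)
        out = add_potentials_from_fibre(c, f)
        d, rad_sum = 12.0, 12.0
        adh = -0.4 * (1 - d / (1.25 * rad_sum)) ** 2
        assert out == pytest.approx([0.0, adh], abs=1e-12)

    def test_sum_equals_independently_evaluated_components(self):
        c = make_cell(0, (0.0, 5.0), vel_adhesion=0.6, vel_contact=0.5)
        c.previous_velocity = np.array([2.0, 2.0])  # 45 degrees to the fibre
        f = make_fibre(1, (0.0, 0.0), 0.0)
        p = c.fibre_params
        out = add_potentials_from_fibre(c, f, p)
        d, rad_sum = 5.0, 12.0
        rep = 10.0 * (1 - d / rad_sum) ** 2
        adh = -0.4 * (1 - d / (1.25 * rad_sum)) ** 2
        expected = np.array([0.0, rep + adh]) \
            + force_parallel(c.previous_velocity, np.array([1.0, 0.0]), p) \
            - force_perpendicular(c.previous_velocity, np.array([1.0, 0.0]), p)
        assert out == pytest.approx(expected, abs=1e-12)

    def test_pull_follows_velocity_sign_along_axis(self):
        f = make_fibre(1, (0.0, 0.0), 0.0)
        for vx in (3.0, -3.0):
            c = make_cell(0, (0.0, 12.0), vel_adhesion=0.6)
            c.previous_velocity = np.array([vx, 0.0])
            out = add_potentials_from_fibre(c, f)
            assert np.sign(out[0]) == np.sign(vx)


class TestRotationPrimitives:
    def test_moment_arm_examples(self):
        assert moment_arm(np.zeros(2)) == 0.0
        assert moment_arm(np.array([3.0, 4.0])) == 5.0
        assert moment_arm(np.array([37.5, 0.0])) == 37.5

    def test_impulse_product_and_edge_cases(self):
        assert impulse(1.0, 2.0, 5.0) == 10.0
        assert impulse(0.0, 7.0, 3.0) == 0.0
        assert impulse(2.0, 3.0, 0.0) == 0.0

    def test_angular_velocity_formula_and_scaling(self):
        assert angular_velocity(0.0, 5.0) == 0.0
        assert angular_velocity(1.0, 2.0) == 0.5
        assert angular_velocity(1.0, 4.0) == pytest.approx(0.125)
        with pytest.raises(ValueError):
            angular_velocity(1.0, 0.0)

    def test_rotation_matrix_cases(self):
        o = np.array([1.0, 0.0])
        assert np.allclose(rotate_orientation(o, 0.0), o)
        assert rotate_orientation(o, np.pi / 2) == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_rotation_inverse_restores(self, rng):
        for _ in range(100):
            th, om = rng.uniform(0, 2 * np.pi), rng.uniform(-3, 3)
            o = np.array([np.cos(th), np.sin(th)])
            back = rotate_orientation(rotate_orientation(o, om), -om)
            assert np.allclose(back, o, atol=1e-12)
            assert np.hypot(*back) == pytest.approx(1.0, abs=1e-12)


class TestFibreCellInteraction:
    DOM = Domain(-200.0, 200.0, -200.0, 200.0, 30.0)

    def contact_cell(self, **kw):
        c = make_cell(0, (0.0, 8.0), **kw)
        c.velocity = np.array([1.0, 0.0])
        c.migration_speed = 1.0
        return c

    def test_tethered_fibre_is_immobile(self):
        f = make_fibre(1, (0.0, 0.0), 0.0)
        f.crosslink_points = [np.zeros(2), np.zeros(2)]
        c = self.contact_cell(fibre_pushing=True, fibre_rotation=True)
        before = (f.segment.centre.copy(), f.segment.orientation.copy())
        add_potentials_from_cell(f, c, domain=self.DOM)
        assert np.array_equal(f.segment.centre, before[0])
        assert np.array_equal(f.segment.orientation, before[1])

    def test_flags_off_leave_fibre_unchanged(self):
        f = make_fibre(1, (0.0, 0.0), 0.0)
        c = self.contact_cell()
        before = f.segment.centre.copy()
        add_potentials_from_cell(f, c, domain=self.DOM)
        assert np.array_equal(f.segment.centre, before)

    def test_pushing_translates_away_from_cell(self):
        f = make_fibre(1, (0.0, 0.0), 0.0)
        c = self.contact_cell(fibre_pushing=True)
        add_potentials_from_cell(f, c, domain=self.DOM, dt=0.1)
        assert f.segment.centre[1] < 0.0  # pushed away from the cell above
        assert f.segment.centre[0] == 0.0

    def test_pushing_rejected_at_domain_edge(self):
        # a push that would carry an endpoint outside the domain is dropped
        dom = Domain(-40.0, 40.0, -40.0, 40.0, 20.0)
        f = make_fibre(1, (0.0, -38.0), 0.0, length=78.0)
        c = make_cell(0, (0.0, -28.0), fibre_pushing=True)
        c.velocity = np.array([0.0, -1.0])
        add_potentials_from_cell(f, c, domain=dom, dt=10.0)
        assert np.array_equal(f.segment.centre, [0.0, -38.0])

    def test_endpoint_impact_rotates_faster_than_central(self):
        omegas = []
        for x_cell in (14.0, 1.0):  # near the end vs near the centre
            f = make_fibre(1, (0.0, 0.0), 0.0)
            c = make_cell(0, (x_cell, 8.0), fibre_rotation=True)
            c.velocity = np.array([0.0, -1.0])  # pressing down onto the fibre
            c.migration_speed = 1.0
            o0 = f.segment.angle
            add_potentials_from_cell(f, c, domain=self.DOM)
            omegas.append(abs(f.segment.angle - o0))
        assert omegas[0] > omegas[1] > 0.0

    def test_rotation_preserves_centre_and_length(self):
        f = make_fibre(1, (0.0, 0.0), 0.0)
        c = self.contact_cell(fibre_rotation=True)
        c.position = np.array([10.0, 8.0])
        c.velocity = np.array([0.5, -1.0])
        add_potentials_from_cell(f, c, domain=self.DOM)
        assert abs(f.segment.angle) > 0.0
        assert np.array_equal(f.segment.centre, [0.0, 0.0])
        assert f.segment.length == 30.0
        assert np.hypot(*f.segment.orientation) == pytest.approx(1.0, abs=1e-12)


class TestVelocityAssembly:
    def test_isolated_nonmotile_cell_is_still_and_stuck(self):
        c = make_cell(0, (0.0, 0.0))
        c.migration_speed = 0.0
        v = update_cell_velocity(c, [], [])
        assert np.allclose(v, 0.0)
        assert c.stuck_counter == 1
        update_cell_velocity(c, [], [])
        assert c.stuck_counter == 2

    def test_symmetric_fibres_cancel_laterally(self):
        c = make_cell(0, (0.0, 0.0))
        c.migration_speed = 0.0
        above = make_fibre(1, (0.0, 8.0), 0.0)
        below = make_fibre(2, (0.0, -8.0), 0.0)
        v = update_cell_velocity(c, [], [above, below])
        assert v == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_three_agent_sum_matches_pairwise_terms(self):
        c = make_cell(0, (0.0, 0.0), vel_adhesion=0.6, vel_contact=0.5)
        c.migration_speed = 1.0
        c.motility_vector = np.array([0.0, 1.0])
        c.previous_velocity = np.array([1.0, 1.0])
        other = make_cell(1, (15.0, 0.0))
        fib = make_fibre(2, (0.0, -9.0), 0.0)
        expected = (c.migration_speed * c.motility_vector
                    + cell_cell_potential(c, other)
                    + add_potentials_from_fibre(c, fib, c.fibre_params))
        v = update_cell_velocity(c, [other], [fib])
        assert v == pytest.approx(expected, abs=1e-12)
        assert c.stuck_counter == 0  # speed above the stuck threshold

    def test_static_fibres_without_flags_never_move(self):
        # obstacles only: no pushing, no rotation => fibre state is constant
        f = make_fibre(1, (0.0, 0.0), 0.0)
        c = self_cell = make_cell(0, (0.0, 9.0))
        self_cell.velocity = np.array([1.0, 0.0])
        before = (f.segment.centre.copy(), f.segment.orientation.copy())
        for _ in range(50):
            add_potentials_from_cell(f, c, domain=Domain(-50, 50, -50, 50, 25))
        assert np.array_equal(f.segment.centre, before[0])
        assert np.array_equal(f.segment.orientation, before[1])
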