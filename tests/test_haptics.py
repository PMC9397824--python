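"""Force laws, cycloidal guidance, contact geometry, and the simulated loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from texdisc.haptics import (
    ExplorationPolicy,
    HapticParams,
    KinematicTrace,
    ReferencePoint,
    RobotState,
    contact_test,
    cycloidal_reference,
    grating_force,
    guidance_force,
    simulate_trial_exploration,
    table_force,
    total_force,
)
from texdisc.stimuli import build_default_stimulus_set, make_triangle_trial

PARAMS = HapticParams()


def _state(x=0.0, y=0.0, z=0.0, vx=0.0, vy=0.0, vz=0.0):
    return RobotState((x, y, z), (vx, vy, vz))


@pytest.fixture(scope="module")
def passive_trace():
    sset = build_default_stimulus_set()
    trial = make_triangle_trial(
        sset.standard, sset.more_coarse[0], np.random.default_rng(3)
    )
    return simulate_trial_exploration(trial, mode="passive")


class TestGratingForce:
    def test_zero_crossing(self):
        assert grating_force(0.0, 164.0, 3.0) == 0.0

    def test_quarter_period_peak(self):
        assert grating_force(1 / (4 * 164.0), 164.0, 3.0) == pytest.approx(3.0, abs=1e-12)

    def test_periodicity(self):
        y = 0.0123
        assert grating_force(y + 1 / 164.0, 164.0, 3.0) == pytest.approx(
            grating_force(y, 164.0, 3.0), abs=1e-12
        )

    @given(
        y=st.floats(-0.1, 0.1),
        f=st.floats(50.0, 300.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_amplitude(self, y, f):
        assert abs(grating_force(y, f, 3.0)) <= 3.0 + 1e-12


class TestContact:
    def test_middle_texture_contact(self):
        in_c, tid = contact_test(_state(0.0, 0.0, 0.0005), PARAMS)
        assert in_c and tid == 1

    def test_above_table_no_contact(self):
        in_c, tid = contact_test(_state(0.0, 0.0, 0.002), PARAMS)
        assert not in_c and tid is None

    def test_gap_between_textures_no_contact(self):
        # middle texture spans x in (-0.01, 0.01); the next starts at 0.02
        in_c, _ = contact_test(_state(0.02, 0.0, 0.0), PARAMS)
        assert not in_c

    def test_side_textures(self):
        assert contact_test(_state(-0.03, 0.0, 0.0), PARAMS) == (True, 0)
        assert contact_test(_state(0.03, 0.0, 0.0), PARAMS) == (True, 2)

    def test_beyond_texture_length_no_contact(self):
        in_c, _ = contact_test(_state(0.0, 0.1, 0.0), PARAMS)
        assert not in_c


class TestTableForce:
    def test_above_table_zero(self):
        assert table_force(_state(z=0.002, vz=-1.0), PARAMS) == 0.0

    def test_static_penetration(self):
        assert table_force(_state(z=0.0, vz=0.0), PARAMS) == pytest.approx(
            1960.0 * 0.001, abs=1e-12
        )

    def test_damping_term_at_zero_penetration(self):
        eps = 1e-12
        f = table_force(_state(z=PARAMS.table_height - eps, vz=1.0), PARAMS)
        assert f == pytest.approx(-28.0, abs=1e-6)

    @given(z=st.floats(-0.002, 0.0009), vz=st.floats(-0.5, 0.0))
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_when_descending(self, z, vz):
        assert table_force(_state(z=z, vz=vz), PARAMS) >= 0.0


class TestCycloidalReference:
    def test_boundaries(self):
        a = cycloidal_reference(0.0, 0.01, 0.05, 2.0)
        b = cycloidal_reference(2.0, 0.01, 0.05, 2.0)
        assert (a.y, a.yd, a.ydd) == pytest.approx((0.01, 0.0, 0.0), abs=1e-12)
        assert (b.y, b.yd, b.ydd) == pytest.approx((0.05, 0.0, 0.0), abs=1e-12)

    def test_midpoint_and_peak_speed(self):
        mid = cycloidal_reference(1.0, 0.01, 0.05, 2.0)
        assert mid.y == pytest.approx(0.03, abs=1e-12)
        assert mid.yd == pytest.approx(2 * (0.05 - 0.01) / 2.0, abs=1e-12)

    def test_position_monotone(self):
        ts = np.linspace(0, 2.0, 500)
        ys = [cycloidal_reference(t, -0.08, 0.08, 2.0).y for t in ts]
        assert np.all(np.diff(ys) >= 0)

    def test_outside_segment_rejected(self):
        with pytest.raises(ValueError):
            cycloidal_reference(-0.1, 0.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            cycloidal_reference(2.1, 0.0, 1.0, 2.0)


class TestGuidanceForce:
    def test_perfect_tracking_zero(self):
        ref = ReferencePoint(0.02, 0.1, 0.0)
        assert guidance_force(_state(y=0.02, vy=0.1), ref, True, PARAMS) == 0.0

    def test_stiffness_term(self):
        ref = ReferencePoint(0.01, 0.0, 0.0)
        f = guidance_force(_state(y=0.0, vy=0.0), ref, True, PARAMS)
        assert f == pytest.approx(300.0 * 0.01, abs=1e-12)

    def test_gated_off_without_contact(self):
        ref = ReferencePoint(0.05, 0.1, 1.0)
        assert guidance_force(_state(), ref, False, PARAMS) == 0.0


class TestTotalForce:
    def test_active_no_contact_all_zero(self):
        fb = total_force(_state(z=0.01), None, 164.0, PARAMS, "active")
        assert fb.total == (0.0, 0.0, 0.0)

    def test_passive_contact_composition(self):
        ref = ReferencePoint(0.005, 0.0, 0.0)
        state = _state(y=0.001, z=0.0)
        fb = total_force(state, ref, 164.0, PARAMS, "passive")
        assert fb.total[1] == pytest.approx(fb.f_texture + fb.f_guidance, abs=1e-12)
        assert fb.total[2] == pytest.approx(fb.f_wall, abs=1e-12)

    def test_x_component_always_zero(self, rng):
        for _ in range(50):
            state = _state(*rng.uniform(-0.05, 0.05, 3), *rng.uniform(-0.2, 0.2, 3))
            fb = total_force(state, None, 164.0, PARAMS, "active")
            assert fb.total[0] == 0.0


class TestWallPassivity:
    def test_energy_dissipates_on_bounce(self):
        """A free mass dropped on the damped wall loses mechanical energy."""
        m, dt = 1.0, 1e-3
        z, vz = 0.003, -0.1
        E_prev, c_prev = None, False
        E0 = 0.5 * m * vz**2
        for _ in range(4000):
            fz = table_force(_state(z=z, vz=vz), PARAMS)
            contact = z < PARAMS.table_height
            vz += dt * fz / m
            z += dt * vz
            pen = max(0.0, PARAMS.table_height - z)
            E = 0.5 * m * vz**2 + 0.5 * PARAMS.wall_stiffness * pen**2
            c_new = z < PARAMS.table_height
            # energy may jump only at the contact-onset discretization boundary
            if E_prev is not None and contact == c_prev == c_new:
                assert E - E_prev <= 1e-6
            E_prev, c_prev = E, c_new
        assert E_prev < 0.5 * E0


class TestSimulatedExploration:
    def test_passive_tracking_error_bounded(self, passive_trace):
        err = np.abs(passive_trace.y_ref - passive_trace.position[:, 1])
        assert np.nanmax(err) < 0.01

    def test_tracking_error_decreases_with_stiffness(self):
        sset = build_default_stimulus_set()
        trial = make_triangle_trial(
            sset.standard, sset.less_coarse[0], np.random.default_rng(4)
        )
        errs = []
        for k_hg in (100.0, 300.0, 1000.0):
            tr = simulate_trial_exploration(
                trial, mode="passive", params=HapticParams(guidance_stiffness=k_hg)
            )
            errs.append(np.nanmax(np.abs(tr.y_ref - tr.position[:, 1])))
        assert errs[0] > errs[1] > errs[2]

    def test_zero_effort_above_table_never_contacts(self):
        sset = build_default_stimulus_set()
        trial = make_triangle_trial(
            sset.standard, sset.more_coarse[1], np.random.default_rng(5)
        )
        idle = ExplorationPolicy(
            press_force=0.0, xz_stiffness=0.0, xz_damping=0.0,
            y_stiffness=0.0, y_damping=0.0,
        )
        tr = simulate_trial_exploration(trial, mode="active", policy=idle)
        assert not tr.contact.any()
        assert np.all(tr.f_total == 0.0)

    def test_step_halving_convergence(self):
        sset = build_default_stimulus_set()
        trial = make_triangle_trial(
            sset.standard, sset.more_coarse[0], np.random.default_rng(6)
        )
        a = simulate_trial_exploration(trial, mode="passive", dt=1e-3)
        b = simulate_trial_exploration(trial, mode="passive", dt=5e-4)
        assert np.linalg.norm(a.position[-1] - b.position[-1]) < 1e-4

    def test_trace_csv_round_trip(self, passive_trace, tmp_path):
        p = tmp_path / "trace.csv"
        passive_trace.to_csv(p)
        loaded = KinematicTrace.from_csv(p)
        assert np.allclose(loaded.position, passive_trace.position)
        assert np.array_equal(loaded.texture_id, passive_trace.texture_id)

    def test_last_texture_visited(self, passive_trace):
        assert passive_trace.last_texture_visited == 2
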