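"""Unit and property tests for the intelligent-stretching velocity law."""

import pytest
from hypothesis import given, strategies as hst

from anklesim import (AnklePlant, AnkleState, ConfigurationError,
                      ControllerInput, ControllerParams, ControllerState,
                      PlantParams, SensorFaultError, controller_step,
                      run_stretch_session)

P = ControllerParams(Mp=15.0, Mn=15.0, Vmin=2.0, Vmax=20.0, C=10.0,
                     theta_p=20.0, theta_n=-40.0, theta_d=5.0,
                     hold_pos=5.0, hold_neg=0.0)


class TestVelocityLaw:
    def test_holds_at_torque_limit_until_time_elapsed(self):
        state = ControllerState(direction=1, phase="holding", hold_elapsed=2.0)
        v, new = controller_step(P, state, ControllerInput(theta=10.0, m_res=15.2))
        assert v == 0.0
        assert new.phase == "holding"
        assert new.hold_elapsed == pytest.approx(2.0 + P.dt)

    def test_reverses_at_vmax_after_hold_complete(self):
        state = ControllerState(direction=1, phase="holding", hold_elapsed=5.0)
        v, new = controller_step(P, state, ControllerInput(theta=10.0, m_res=15.2))
        assert v == -P.Vmax
        assert new.direction == -1
        assert new.phase == "moving"
        assert new.hold_elapsed == 0.0
        assert new.cycle_count == 1

    @pytest.mark.parametrize("m_res,expected_speed", [
        (0.5, 20.0),    # C/|M| = 20 exactly at the Vmax clip boundary
        (10.0, 2.0),    # C/|M| = 1 < Vmin, floored
        (0.0, 20.0),    # zero resistance treated as the Vmax case
        (2.0, 5.0),     # interior: C/|M| = 5
    ])
    def test_mid_rom_speed_is_clipped_reciprocal(self, m_res, expected_speed):
        state = ControllerState(direction=1)
        v, _ = controller_step(P, state, ControllerInput(theta=0.0, m_res=m_res))
        assert v == pytest.approx(expected_speed)

    def test_mid_rom_matches_scalar_clip_on_grid(self):
        """Brute-force check of clip(C/|M|, Vmin, Vmax) over a torque grid."""
        for k in range(1, 300):
            m = k * 0.05
            v, _ = controller_step(P, ControllerState(direction=1),
                                   ControllerInput(theta=0.0, m_res=m))
            expected = min(max(P.C / m, P.Vmin), P.Vmax)
            assert v == pytest.approx(expected)

    def test_zero_hold_reverses_immediately(self):
        p = ControllerParams(hold_pos=0.0)
        v, new = controller_step(p, ControllerState(direction=1),
                                 ControllerInput(theta=0.0, m_res=p.Mp + 1))
        assert v == -p.Vmax and new.direction == -1

    def test_position_limit_triggers_end_condition(self):
        v, new = controller_step(P, ControllerState(direction=1),
                                 ControllerInput(theta=P.theta_p + P.theta_d,
                                                 m_res=0.1))
        assert v == 0.0 and new.phase == "holding"

    def test_non_finite_input_rejected(self):
        with pytest.raises(SensorFaultError):
            controller_step(P, ControllerState(),
                            ControllerInput(theta=float("nan"), m_res=1.0))
        with pytest.raises(SensorFaultError):
            controller_step(P, ControllerState(),
                            ControllerInput(theta=0.0, m_res=float("inf")))

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            ControllerParams(Vmin=5.0, Vmax=2.0)
        with pytest.raises(ConfigurationError):
            ControllerParams(theta_p=-10.0, theta_n=10.0)
        with pytest.raises(ConfigurationError):
            ControllerParams(Mp=-1.0)
        with pytest.raises(ConfigurationError):
            ControllerParams(theta_d=-0.1)

    @given(m_res=hst.floats(-100, 100),
           theta=hst.floats(-45, 25),
           direction=hst.sampled_from([1, -1]),
           holding=hst.booleans(),
           hold_elapsed=hst.floats(0, 5))
    def test_speed_magnitude_always_in_band(self, m_res, theta, direction,
                                            holding, hold_elapsed):
        state = ControllerState(direction=direction,
                                phase="holding" if holding else "moving",
                                hold_elapsed=hold_elapsed)
        v, _ = controller_step(P, state, ControllerInput(theta=theta, m_res=m_res))
        assert v == 0.0 or P.Vmin <= abs(v) <= P.Vmax

    @given(m1=hst.floats(0.01, 50), m2=hst.floats(0.01, 50))
    def test_speed_non_increasing_in_resistance(self, m1, m2):
        lo, hi = sorted((m1, m2))
        v_lo, _ = controller_step(P, ControllerState(direction=1),
                                  ControllerInput(theta=0.0, m_res=lo))
        v_hi, _ = controller_step(P, ControllerState(direction=1),
                                  ControllerInput(theta=0.0, m_res=hi))
        if abs(v_lo) != 0 and abs(v_hi) != 0:
            assert abs(v_hi) <= abs(v_lo) + 1e-12


class TestStretchSession:
    def test_rigid_limits_give_identical_end_angles(self):
        """No creep: every dorsiflexion reversal lands on the same angle."""
        plant = AnklePlant(PlantParams(noise_sd=0.0, creep_gain=0.0))
        params = ControllerParams(hold_pos=1.0)
        log = run_stretch_session(params, plant, duration=120.0, seed=0)
        ends = log.end_range_angles(direction=1)
        assert len(ends) >= 3
        # identical up to the one-tick travel quantum of the discretization
        assert max(ends) - min(ends) <= 2 * params.Vmin * params.dt

    def test_creep_increases_dorsiflexion_end_angle(self):
        plant = AnklePlant(PlantParams(noise_sd=0.0, creep_gain=2e-3,
                                       creep_cap=5.0))
        log = run_stretch_session(ControllerParams(), plant, duration=300.0,
                                  seed=0)
        ends = log.end_range_angles(direction=1)
        assert len(ends) >= 2
        assert ends[-1] > ends[0]
        assert plant.state.rom_shift_pos > 0.0

    def test_huge_torque_limit_means_position_limited(self):
        plant = AnklePlant(PlantParams(noise_sd=0.0))
        params = ControllerParams(Mp=1e6, Mn=1e6, theta_p=6.0, theta_n=-12.0,
                                  theta_d=2.0, hold_pos=0.5, hold_neg=0.5)
        log = run_stretch_session(params, plant, duration=60.0, seed=0)
        assert len(log.cycles) >= 2
        for c in log.cycles:
            if c.direction == 1:
                assert params.theta_p <= c.end_angle <= params.theta_p \
                    + params.theta_d + params.Vmax * params.dt
            else:
                assert params.theta_n - params.theta_d \
                    - params.Vmax * params.dt <= c.end_angle <= params.theta_n

    def test_hold_durations_match_configuration(self):
        plant = AnklePlant(PlantParams(noise_sd=0.0))
        params = ControllerParams(hold_pos=3.0, hold_neg=1.0)
        log = run_stretch_session(params, plant, duration=180.0, seed=0)
        pos_holds = [c.hold_time for c in log.cycles if c.direction == 1]
        neg_holds = [c.hold_time for c in log.cycles if c.direction == -1]
        assert pos_holds and neg_holds
        assert all(abs(h - 3.0) <= 2 * params.dt for h in pos_holds)
        assert all(abs(h - 1.0) <= 2 * params.dt for h in neg_holds)

    def test_reversals_alternate_ends(self):
        plant = AnklePlant(PlantParams(noise_sd=0.0))
        params = ControllerParams(hold_pos=1.0, hold_neg=1.0)
        log = run_stretch_session(params, plant, duration=120.0, seed=0)
        dirs = [c.direction for c in log.cycles]
        assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_log_schema_and_decimation(self):
        plant = AnklePlant(PlantParams())
        log = run_stretch_session(ControllerParams(), plant, duration=5.0,
                                  seed=3, log_hz=100.0)
        assert list(log.frame.columns) == ["time_s", "theta_deg", "torque_nm",
                                           "velocity_cmd_dps", "phase",
                                           "direction"]
        assert len(log.frame) == pytest.approx(500, abs=2)

    def test_session_is_deterministic_under_seed(self):
        a = run_stretch_session(ControllerParams(), AnklePlant(PlantParams()),
                                duration=10.0, seed=7)
        b = run_stretch_session(ControllerParams(), AnklePlant(PlantParams()),
                                duration=10.0, seed=7)
        assert a.frame.equals(b.frame)

    def test_start_outside_position_limits_rejected(self):
        plant = AnklePlant(PlantParams(),
                           AnkleState(theta=50.0))
        with pytest.raises(ConfigurationError):
            run_stretch_session(ControllerParams(), plant, duration=1.0)
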