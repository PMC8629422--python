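import math

import numpy as np
import pytest

import surgecast as sc
from surgecast.controllers import (
    CastingParams,
    CastingState,
    GainTable,
    MiM2Params,
    MiM2State,
    PiecewiseGain,
    SurgeZigzagParams,
    _rd_of_turn,
    casting_command,
    mim2_command,
    mim2_gain,
    surge_zigzag_command,
    turn_number,
)


class TestGainTable:
    @pytest.mark.parametrize(
        "f,matched,channel,expected",
        [
            (0.0, True, "v", 12.9),
            (0.3, False, "v", 10.5),
            (0.7, True, "v", 5.36 * 0.7 + 12.9),  # 16.652, low branch at bp
            (1.0, True, "v", -11.4 + 24.6),
            (0.0, True, "omega", 1.40),
            (0.4, True, "omega", 0.638 * 0.4 + 1.40),
            (1.0, True, "omega", -1.22 + 2.16),
        ],
    )
    def test_table_values(self, f, matched, channel, expected):
        assert mim2_gain(f, matched, channel, MiM2Params()) == pytest.approx(expected)

    def test_gain_floored_at_zero(self):
        g = PiecewiseGain(0.0, 1.0, -10.0, 1.0, 0.5)
        assert g(2.0) == 0.0

    def test_matched_v_branches_nearly_continuous_at_breakpoint(self):
        table = sc.default_gain_table().v_matched
        low = table.a_low * table.breakpoint + table.b_low
        high = table.a_high * table.breakpoint + table.b_high
        assert abs(low - high) < 0.05

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            mim2_gain(-0.1, True, "v", MiM2Params())

    def test_printed_table_variant_moves_mismatched_breakpoint(self):
        assert sc.printed_gain_table().omega_mismatched.breakpoint == 0.4
        assert sc.default_gain_table().omega_mismatched.breakpoint == 0.2


class TestTurnNumber:
    @pytest.mark.parametrize("tau,expected", [(0.0, 0), (2.0, 2), (10.0, 3)])
    def test_reference_values(self, tau, expected):
        assert turn_number(tau) == expected

    def test_matches_cubic_floor_below_cap(self):
        for tau in np.linspace(0.0, 12.0, 241):
            cubic = 0.0116 * tau**3 - 0.199 * tau**2 + 1.1971 * tau + 0.4482
            assert turn_number(tau) == min(3, max(0, math.floor(cubic)))

    def test_saturates_at_cap(self):
        assert all(turn_number(tau) == 3 for tau in (8.0, 20.0, 100.0))

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            turn_number(-0.01)

    def test_first_turn_starts_just_after_surge(self):
        # the cubic crosses 1 right around the 0.5 s sigmoid switch
        assert turn_number(0.45) == 0
        assert turn_number(0.55) == 1


class TestMiM2Command:
    def test_fresh_detection_surges_toward_detected_side(self):
        state = MiM2State(t_d=0.0, rd0=+1, f=0.0, matched=True)
        cmd = mim2_command(state, now=0.0, params=MiM2Params())
        assert cmd.v == pytest.approx(12.9, abs=1e-6)
        assert cmd.omega == pytest.approx(0.57, abs=1e-6)

    def test_speed_vanishes_long_after_detection(self):
        state = MiM2State(t_d=0.0, rd0=+1, f=0.5, matched=True)
        assert mim2_command(state, 5.0, MiM2Params()).v < 1e-2

    def test_first_zigzag_turns_toward_detected_side(self):
        state = MiM2State(t_d=0.0, rd0=+1, f=0.4, matched=True)
        cmd = mim2_command(state, 1.0, MiM2Params())
        k_w = 0.638 * 0.4 + 1.40
        assert cmd.omega == pytest.approx(+k_w, abs=1e-6)
        assert cmd.v == pytest.approx(0.0, abs=1e-6)

    def test_sigmoid_weights_balanced_at_beta(self):
        p = MiM2Params()
        state = MiM2State(t_d=0.0, rd0=+1, f=0.0, matched=True)
        cmd = mim2_command(state, p.beta, p)
        # both logistic weights are exactly 1/2 at tau = beta
        expected_omega = 0.5 * p.omega0 + 0.5 * 1.40  # N(0.5) = 1, Rd(1) = rd0
        assert cmd.omega == pytest.approx(expected_omega, abs=1e-9)
        assert cmd.v == pytest.approx(12.9 * math.exp(-p.beta) * 0.5, abs=1e-9)

    def test_turn_alternation_sequence(self):
        assert [_rd_of_turn(+1, n) for n in range(5)] == [1, 1, -1, 1, -1]
        assert [_rd_of_turn(-1, n) for n in range(5)] == [-1, -1, 1, -1, 1]

    def test_speed_never_negative(self, rng):
        p = MiM2Params()
        for _ in range(300):
            state = MiM2State(
                t_d=0.0,
                rd0=int(rng.choice((-1, 1))),
                f=float(rng.uniform(0, 1.5)),
                matched=bool(rng.integers(2)),
            )
            assert mim2_command(state, float(rng.uniform(0, 20)), p).v >= 0.0

    def test_vision_equalizer_scales_sides_independently(self):
        state = MiM2State(t_d=0.0, rd0=+1, f=0.0, matched=True)
        cmd = mim2_command(state, 0.0, MiM2Params(), vision_gains=(1.0, 2.0))
        assert cmd.omega == pytest.approx(2 * 0.57, abs=1e-6)
        state_l = MiM2State(t_d=0.0, rd0=-1, f=0.0, matched=True)
        cmd_l = mim2_command(state_l, 0.0, MiM2Params(), vision_gains=(3.0, 1.0))
        assert cmd_l.omega == pytest.approx(-3 * 0.57, abs=1e-6)

    def test_on_detection_resets_surge(self, rng):
        from surgecast.sensing import Side

        state = MiM2State(t_d=0.0, rd0=-1, f=0.2, matched=False)
        new = sc.mim2_on_detection(state, 10.0, Side.RIGHT, 0.6, True, rng)
        assert new.t_d == 10.0 and new.rd0 == +1
        assert new.f == 0.6 and new.matched


class TestAblationEquivalence:
    def test_constant_gain_mim2_equals_surge_zigzag(self, rng):
        """With the gain table forced constant, MiM2 IS the baseline."""
        sz = SurgeZigzagParams()
        const_v = PiecewiseGain(0.0, sz.v_const, 0.0, sz.v_const, 0.7)
        const_w = PiecewiseGain(0.0, sz.omega_const, 0.0, sz.omega_const, 0.7)
        mp = MiM2Params(gains=GainTable(const_v, const_v, const_w, const_w))
        for _ in range(500):
            state = MiM2State(
                t_d=float(rng.uniform(0, 5)),
                rd0=int(rng.choice((-1, 1))),
                f=float(rng.uniform(0, 1.2)),
                matched=bool(rng.integers(2)),
            )
            now = state.t_d + float(rng.uniform(0, 10))
            a = mim2_command(state, now, mp)
            b = surge_zigzag_command(state, now, sz)
            assert a.v == pytest.approx(b.v, abs=1e-12)
            assert a.omega == pytest.approx(b.omega, abs=1e-12)

    def test_surge_zigzag_ignores_frequency_and_match(self):
        sz = SurgeZigzagParams()
        s1 = MiM2State(t_d=0.0, rd0=+1, f=0.2, matched=True)
        s2 = MiM2State(t_d=0.0, rd0=+1, f=0.8, matched=False)
        for tau in (0.0, 0.3, 1.0, 2.5):
            assert surge_zigzag_command(s1, tau, sz) == surge_zigzag_command(s2, tau, sz)

    def test_surge_phase_speed_is_constant_gain(self):
        sz = SurgeZigzagParams()
        cmd = surge_zigzag_command(MiM2State(t_d=0.0, rd0=-1), 0.0, sz)
        assert cmd.v == pytest.approx(sz.v_const, abs=1e-6)


class TestCasting:
    def setup_method(self):
        self.params = CastingParams()
        self.wind = (100.0, 0.0)  # upwind bearing = pi

    def test_tracking_offsets_upwind_by_beta(self):
        for sign, direction in ((1, -1.0), (-1, +1.0)):
            state = CastingState(mode="track", offset_sign=sign)
            # aligned heading -> no steering once on target
            target = math.pi + direction * math.radians(30.0)
            cmd = casting_command(state, target, self.wind, self.params)
            assert cmd.omega == pytest.approx(0.0, abs=1e-9)
            assert cmd.v == self.params.v_const

    def test_hold_keeps_latched_heading(self):
        state = CastingState(mode="hold", hold_heading=1.234)
        cmd = casting_command(state, 1.234, self.wind, self.params)
        assert cmd.omega == pytest.approx(0.0, abs=1e-9)

    def test_cast_targets_crosswind(self):
        for sign, target in ((1, math.pi / 2), (-1, -math.pi / 2)):
            state = CastingState(mode="cast", cast_sign=sign)
            cmd = casting_command(state, target, self.wind, self.params)
            assert cmd.omega == pytest.approx(0.0, abs=1e-9)

    def test_steering_is_saturated_proportional(self):
        state = CastingState(mode="track", offset_sign=1)
        cmd = casting_command(state, 0.0, self.wind, self.params)  # ~150 deg error
        assert abs(cmd.omega) == self.params.omega_max
        # small error: proportional, steering the heading CCW toward target
        near = math.pi - math.radians(30.0) - 0.05
        cmd2 = casting_command(CastingState(mode="track", offset_sign=1), near,
                               self.wind, self.params)
        assert cmd2.omega == pytest.approx(-self.params.steering_gain * 0.05, abs=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CastingParams(beta_offset=95.0)
        with pytest.raises(ValueError):
            CastingParams(d_lost=0.0)


class TestControllerWrappers:
    def test_make_controller_names(self):
        for name, cls in [
            ("mim2", sc.MiM2Controller),
            ("surge_zigzag", sc.SurgeZigzagController),
            ("casting", sc.CastingController),
        ]:
            assert isinstance(sc.make_controller(name), cls)
        with pytest.raises(ValueError):
            sc.make_controller("gradient_ascent")

    def test_mim2_wrapper_latches_state_between_onsets(self, rng):
        ctrl = sc.MiM2Controller()
        ctrl.reset(rng)
        wind = (100.0, 0.0)
        ctrl.command(0.0, math.pi, False, False, wind)
        ctrl.command(0.01, math.pi, True, True, wind)  # onset, matched (front)
        assert ctrl.state.t_d == 0.01
        assert ctrl.state.matched
        f_latched = ctrl.state.f
        ctrl.command(0.02, math.pi, True, True, wind)  # still on: no new onset
        assert ctrl.state.t_d == 0.01 and ctrl.state.f == f_latched

    def test_casting_wrapper_walks_through_modes(self, rng):
        ctrl = sc.CastingController()
        ctrl.reset(rng)
        wind = (100.0, 0.0)
        assert ctrl.mode == "cast"
        ctrl.command(0.0, math.pi, True, True, wind)
        assert ctrl.mode == "track"
        # lose the plume; hold until d_lost mm traveled, then cast
        t, dt = 0.0, 0.01
        while ctrl.mode in ("track", "hold") and t < 10.0:
            t += dt
            ctrl.command(t, math.pi, False, False, wind)
        dist = ctrl.params.v_const * (t - dt)  # first false tick starts the clock
        assert ctrl.mode == "cast"
        assert dist == pytest.approx(ctrl.params.d_lost, abs=2 * ctrl.params.v_const * dt)
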