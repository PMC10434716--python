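"""Unit and property tests for the field dynamics core."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import visfield as vf
from visfield.field_core import _field_kernels, _run_frame
from visfield.stimuli import StimulusFrame, TrialProtocol


def one_frame_protocol(amp, duration=360.0, center=0.0, label="object"):
    return TrialProtocol(
        frames=(StimulusFrame(duration, ((center, amp),), label),),
        experiment_id=4,
        condition="constant",
        judged_label=label,
    )


class TestSigmoid:
    def test_threshold_value_is_half(self):
        assert vf.sigmoid(0.0, beta=4.0) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert vf.sigmoid(1e3, beta=4.0) == pytest.approx(1.0)
        assert vf.sigmoid(-1e3, beta=4.0) == pytest.approx(0.0)

    @given(
        x=st.floats(-50, 50),
        beta=st.floats(0.1, 20),
    )
    @settings(deadline=None, max_examples=50)
    def test_odd_symmetry_and_monotonicity(self, x, beta):
        assert vf.sigmoid(x, beta) + vf.sigmoid(-x, beta) == pytest.approx(1.0)
        lo, hi = vf.sigmoid(x, beta), vf.sigmoid(x + 0.5, beta)
        if abs(x + 0.5) * beta < 30:  # beyond this float64 saturates
            assert hi > lo
        else:
            assert hi >= lo

    def test_rejects_nonpositive_steepness(self):
        with pytest.raises(vf.InvalidParameterError):
            vf.sigmoid(0.0, beta=0.0)


class TestGaussianKernel:
    def test_zero_amplitude_gives_zero_kernel(self, grid):
        assert not vf.gaussian_kernel(0.0, 3.0, grid).any()

    def test_symmetry(self, grid):
        k = vf.gaussian_kernel(2.0, 4.0, grid)
        assert np.allclose(k, k[::-1])
        assert k.argmax() == len(k) // 2

    def test_integral_equals_amplitude(self, grid):
        # discretized integral matches the closed-form Gaussian integral
        for amp, width in ((1.0, 3.0), (5.5, 4.0), (2.0, 10.0)):
            k = vf.gaussian_kernel(amp, width, grid)
            assert k.sum() * grid.spacing == pytest.approx(amp, abs=1e-6)

    def test_rejects_nonpositive_width(self, grid):
        with pytest.raises(vf.InvalidParameterError):
            vf.gaussian_kernel(1.0, 0.0, grid)


class TestEffectiveInput:
    def test_no_adaptation_is_identity(self, rng):
        s = rng.uniform(0, 5, 50)
        assert np.allclose(vf.effective_input(s, np.zeros(50), 0.5), s)

    def test_full_suppression_and_floor(self):
        s = np.array([3.0, 3.0])
        a = np.array([1.0, 4.0])
        out = vf.effective_input(s, a, 1.0)
        assert out[0] == 0.0
        assert out[1] == 0.0  # clipped below zero

    def test_monotone_in_adaptation(self, rng):
        s = rng.uniform(0, 5, 100)
        a = rng.uniform(0, 1, 100)
        lower = vf.effective_input(s, a, 0.5)
        higher = vf.effective_input(s, np.minimum(a + 0.2, 1.0), 0.5)
        assert np.all(higher <= lower + 1e-12)


class TestStep:
    def test_resting_fixed_point(self, quiet_params, grid):
        state = vf.FieldState.resting(grid, quiet_params)
        zero = np.zeros(grid.n_points)
        for _ in range(40 * int(quiet_params.tau_u)):
            state = vf.step(state, zero, quiet_params, grid)
        assert np.max(np.abs(state.u - quiet_params.h_u)) < 1e-6
        assert np.max(np.abs(state.v - quiet_params.h_v)) < 1e-6

    def test_weak_input_leaves_no_trace_and_relaxes_back(self, quiet_params, grid):
        state = vf.FieldState.resting(grid, quiet_params)
        weak = vf.gaussian_input(grid, [(0.0, 2.0)], quiet_params.input_width)
        for _ in range(360):
            state = vf.step(state, weak, quiet_params, grid)
        assert state.u.max() < 0  # subthreshold bump only
        assert state.m.max() == 0.0
        zero = np.zeros(grid.n_points)
        for _ in range(2000):
            state = vf.step(state, zero, quiet_params, grid)
        assert np.max(np.abs(state.u - quiet_params.h_u)) < 1e-4

    def test_strong_input_self_excites_and_leaves_trace(self, quiet_params, grid):
        state = vf.FieldState.resting(grid, quiet_params)
        amp = 5.4
        strong = vf.gaussian_input(grid, [(0.0, amp)], quiet_params.input_width)
        for _ in range(614):
            state = vf.step(state, strong, quiet_params, grid)
        # activation exceeds input-plus-resting-level: self-excitation
        assert state.u.max() > quiet_params.h_u + amp
        assert state.m.max() > 0.05
        zero = np.zeros(grid.n_points)
        for _ in range(614):
            state = vf.step(state, zero, quiet_params, grid)
        # the trace keeps activation above the bare resting level
        assert state.u.max() > quiet_params.h_u + 0.1

    def test_trace_builds_only_with_suprathreshold_activity(self, params, grid, rng):
        """m grows only on steps where something is suprathreshold, and
        stays nonnegative; purely subthreshold stimulation leaves no trace."""
        state = vf.FieldState.resting(grid, params)
        weak = vf.gaussian_input(grid, [(0.0, 3.0)], params.input_width)
        prev_m = state.m.copy()
        for _ in range(200):
            anything_above = bool((state.u > 0).any())
            state = vf.step(state, weak, params, grid, rng)
            if not anything_above:
                assert not np.any(state.m > prev_m + 1e-15)
            assert np.all(state.m >= 0)
            assert np.all(state.a >= 0) and np.all(state.a <= 1)
            prev_m = state.m.copy()

    def test_divergence_is_reported_with_field_name(self, quiet_params, grid):
        state = vf.FieldState.resting(grid, quiet_params)
        state.u[:] = np.inf
        with pytest.raises(vf.IntegrationDivergedError, match="'u'"):
            vf.step(state, np.zeros(grid.n_points), quiet_params, grid)


class TestSimulateFrames:
    def test_empty_protocol_keeps_initial_state_only(self, params):
        protocol = TrialProtocol(frames=(), experiment_id=4, condition="x")
        rec = vf.simulate_frames(protocol, params, seed=0)
        assert rec.u_trace.shape[0] == 1
        assert rec.frame_index.tolist() == [-1]

    def test_identical_seeds_are_bit_identical(self, params):
        prot = one_frame_protocol(4.7, 614.0)
        rec1 = vf.simulate_frames(prot, params, seed=42)
        rec2 = vf.simulate_frames(prot, params, seed=42)
        assert np.array_equal(rec1.u_trace, rec2.u_trace)
        assert rec1.final_state.n == rec2.final_state.n

    def test_times_strictly_increasing_and_frames_match_durations(self, params):
        prot = TrialProtocol(
            frames=(
                StimulusFrame(360.0, ((0.0, 5.0),), "object"),
                StimulusFrame(612.0, (), "blank"),
                StimulusFrame(107.0, ((0.0, 4.5),), "probe"),
            ),
            experiment_id=2,
            condition="object",
            judged_label="probe",
        )
        rec = vf.simulate_frames(prot, params, seed=1)
        assert np.all(np.diff(rec.times) > 0)
        # samples in each frame lie within its cumulative-duration window
        bounds = np.cumsum([0.0, 360.0, 612.0, 107.0])
        for f in range(3):
            t = rec.times[rec.frame_index == f]
            assert t.min() > bounds[f] and t.max() <= bounds[f + 1]

    def test_compiled_path_matches_reference_step(self, quiet_params, grid):
        """The numba integrator reproduces the numpy step() scheme exactly."""
        p = quiet_params
        s = vf.gaussian_input(grid, [(0.0, 5.0)], p.input_width)
        state_ref = vf.FieldState.resting(grid, p)
        for _ in range(50):
            state_ref = vf.step(state_ref, s, p, grid)
        state_fast = vf.FieldState.resting(grid, p)
        _run_frame(state_fast, s, 50, p, grid, _field_kernels(p, grid),
                   None, 0, 10**9)
        assert np.allclose(state_ref.u, state_fast.u, atol=1e-12)
        assert np.allclose(state_ref.v, state_fast.v, atol=1e-12)
        assert np.allclose(state_ref.m, state_fast.m, atol=1e-12)

    def test_record_export_round_trip(self, params, tmp_path):
        prot = one_frame_protocol(4.7, 100.0)
        rec = vf.simulate_frames(prot, params, seed=3)
        df = rec.to_frame()
        assert list(df.columns[:2]) == ["time_ms", "frame_index"]
        assert len(df) == len(rec.times)


class TestStationaryStates:
    def test_zero_input_is_monostable_subthreshold(self, params):
        states = vf.find_stationary_states(0.0, params)
        assert len(states) == 1
        assert states[0].u.max() < 0

    def test_scan_orders_sub_bistable_supra(self, params):
        amps = np.arange(3.8, 5.45, 0.1)
        df = vf.scan_bistability(amps, params)
        seq = df.regime.tolist()
        # collapse runs and check ordering
        collapsed = [seq[0]]
        for r in seq[1:]:
            if r != collapsed[-1]:
                collapsed.append(r)
        assert collapsed == [
            "monostable_sub", "bistable", "monostable_supra"
        ]

    def test_bistable_amp_has_two_distinct_states(self, params):
        states = vf.find_stationary_states(4.3, params)
        assert len(states) == 2
        low, high = sorted(states, key=lambda s: s.u.max())
        assert low.u.max() < 0 < high.u.max()
        # suprathreshold peak exceeds input plus resting level
        assert high.u.max() > params.h_u + 4.3
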