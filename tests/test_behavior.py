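"""Forelimb coding, state segmentation and behavioral feature rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betalock.behavior import (
    TRAINING_SPEEDS_RPM,
    WALL_CONTACT_CODES,
    apomorphine_classify,
    compute_speed,
    decode_forelimb,
    encode_forelimb,
    is_wall_contact,
    openfield_features,
    rotarod_outcome,
    rotarod_profile,
    segment_states,
    time_budget,
)
from betalock.core_io import (
    ForelimbCodeSeries,
    RotationRateSeries,
    TrackingTrace,
    ValidationError,
)


class TestForelimbCode:
    def test_worked_examples(self):
        assert encode_forelimb(True, True, False, False) == 0b1100 == 12
        assert encode_forelimb(False, False, True, True) == 0b0011 == 3
        assert encode_forelimb(False, False, False, False) == 0
        assert encode_forelimb(True, False, False, False) == 0b1000 == 8

    def test_decode_inverts_encode_for_all_16_codes(self):
        for code in range(16):
            assert encode_forelimb(*decode_forelimb(code)) == code

    def test_wall_contact_strict_rule(self):
        assert is_wall_contact(12)
        assert not is_wall_contact(3)
        assert not is_wall_contact(4)  # boundary code excluded by strict >
        assert is_wall_contact(5)
        assert WALL_CONTACT_CODES == frozenset(range(5, 16))

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValidationError):
            is_wall_contact(16)


def _series(codes, rates, dt=0.25):
    return (
        ForelimbCodeSeries(np.asarray(codes), dt=dt),
        RotationRateSeries(np.asarray(rates, dtype=float), dt=dt),
    )


class TestSegmentation:
    def test_rearing_then_inactive_hand_example(self):
        codes, rot = _series([12] * 12 + [3] * 12, [0.0] * 24)
        states = segment_states(codes, rot)
        assert states.intervals == [(0.0, 3.0, "rearing"), (3.0, 6.0, "inactive")]

    def test_all_zero_codes_single_inactive(self):
        codes, rot = _series([0] * 40, [0.0] * 40)
        states = segment_states(codes, rot)
        assert states.intervals == [(0.0, 10.0, "inactive")]

    def test_alternating_floor_codes_with_rotation_is_stepping(self):
        # 4 s of alternating single-paw floor contact at a constant 20 deg/s:
        # 80 deg cumulative > 45 deg and many floor-bit transitions
        codes, rot = _series([1, 2] * 8, [20.0] * 16)
        states = segment_states(codes, rot)
        assert states.intervals == [(0.0, 4.0, "stepping")]

    def test_rotation_without_alternation_stays_inactive(self):
        codes, rot = _series([3] * 16, [20.0] * 16)
        states = segment_states(codes, rot)
        assert states.intervals == [(0.0, 4.0, "inactive")]

    def test_alternation_without_rotation_stays_inactive(self):
        codes, rot = _series([1, 2] * 8, [0.0] * 16)
        states = segment_states(codes, rot)
        assert states.intervals == [(0.0, 4.0, "inactive")]

    def test_short_flicker_merged_into_neighbor(self):
        # one 0.25 s wall-contact frame inside a long floor-contact stretch
        codes, rot = _series([3] * 10 + [12] + [3] * 10, [0.0] * 21)
        states = segment_states(codes, rot)
        assert states.intervals == [(0.0, 21 * 0.25, "inactive")]

    def test_span_mismatch_rejected(self):
        codes = ForelimbCodeSeries(np.zeros(10, dtype=int), dt=0.25)
        rot = RotationRateSeries(np.zeros(30), dt=0.25)
        with pytest.raises(ValidationError, match="span"):
            segment_states(codes, rot)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 200))
    def test_partition_sums_to_session_length(self, seed, n):
        rng = np.random.default_rng(seed)
        codes, rot = _series(rng.integers(0, 16, n), rng.normal(0, 30, n))
        states = segment_states(codes, rot)
        assert states.start == 0.0
        assert states.end == pytest.approx(n * 0.25)
        tb = time_budget(states, (0.0, n * 0.25))
        assert sum(tb.values()) == pytest.approx(n * 0.25)


class TestTimeBudget:
    def test_hand_example_budget(self):
        codes, rot = _series([12] * 12 + [3] * 12, [0.0] * 24)
        states = segment_states(codes, rot)
        tb = time_budget(states, (0.0, 6.0))
        assert tb == {"rearing": 3.0, "stepping": 0.0, "inactive": 3.0}

    def test_window_straddling_boundary_splits_proportionally(self):
        codes, rot = _series([12] * 12 + [3] * 12, [0.0] * 24)
        states = segment_states(codes, rot)
        tb = time_budget(states, (2.0, 4.0))
        assert tb["rearing"] == pytest.approx(1.0)
        assert tb["inactive"] == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        codes, rot = _series([0] * 8, [0.0] * 8)
        states = segment_states(codes, rot)
        with pytest.raises(ValidationError):
            time_budget(states, (1.0, 1.0))


class TestSpeed:
    def test_stationary_trace_zero_speed(self):
        tr = TrackingTrace(np.full(100, 30.0), np.full(100, 30.0), fps=25.0)
        assert np.allclose(compute_speed(tr), 0.0, atol=1e-9)

    def test_straight_line_74cm_in_10s(self):
        n = 250
        x = np.linspace(0, 74, n)
        tr = TrackingTrace(x, np.full(n, 10.0), fps=25.0)
        speed = compute_speed(tr)
        assert speed.mean() == pytest.approx(7.4, abs=0.1)

    def test_circular_path_speed_is_r_omega(self):
        fps, r, omega = 25.0, 10.0, 1.0
        t = np.arange(500) / fps
        tr = TrackingTrace(37 + r * np.cos(omega * t), 37 + r * np.sin(omega * t), fps=fps)
        speed = compute_speed(tr)
        assert np.median(speed) == pytest.approx(r * omega, rel=0.05)


class TestOpenFieldFeatures:
    def test_constant_5cms_for_10s(self):
        speed = np.full(250, 5.0)
        f = openfield_features(speed, 25.0, [(0.0, 10.0, False)])
        assert f.lm_time == pytest.approx(10.0)
        assert f.immobility_time == 0.0
        assert f.distance == pytest.approx(50.0)
        assert f.avg_velocity == pytest.approx(5.0)

    def test_zero_speed_full_immobility(self):
        f = openfield_features(np.zeros(250), 25.0, [(0.0, 10.0, False)])
        assert f.immobility_time == pytest.approx(10.0)
        assert f.lm_time == 0.0
        assert f.distance == 0.0

    def test_short_fast_run_not_counted_as_large_movement(self):
        speed = np.zeros(250)
        speed[100:137] = 5.0  # 1.48 s, below the 2 s minimum
        f = openfield_features(speed, 25.0, [(0.0, 10.0, False)])
        assert f.lm_time == 0.0

    def test_threshold_monotonicity(self, rng):
        speed = np.abs(rng.normal(3.0, 3.0, 2500))
        eps = [(0.0, 100.0, False)]
        lm4 = openfield_features(speed, 25.0, eps, lm_speed=4.0).lm_time
        lm6 = openfield_features(speed, 25.0, eps, lm_speed=6.0).lm_time
        assert lm6 <= lm4
        d2 = openfield_features(speed, 25.0, eps, min_duration=2.0)
        d4 = openfield_features(speed, 25.0, eps, min_duration=4.0)
        assert d4.lm_time <= d2.lm_time
        assert d4.immobility_time <= d2.immobility_time

    def test_durations_bounded_by_episode(self, rng):
        speed = np.abs(rng.normal(2.0, 2.0, 2500))
        f = openfield_features(speed, 25.0, [(0.0, 100.0, False)])
        assert f.lm_time + f.immobility_time <= 100.0 + 1e-9


class TestApomorphine:
    def test_exactly_three_per_minute_is_lesioned(self):
        counts = np.full(30, 3)
        assert apomorphine_classify(counts) is True

    def test_89_total_rotations_is_not_lesioned(self):
        counts = np.zeros(30)
        counts[:29] = 3
        counts[29] = 2  # 89 total, mean 2.9667
        assert apomorphine_classify(counts) is False

    def test_zero_rotations_not_lesioned(self):
        assert apomorphine_classify(np.zeros(30)) is False

    def test_wrong_record_length_rejected(self):
        with pytest.raises(ValidationError, match="30"):
            apomorphine_classify(np.zeros(29))


class TestRotarod:
    def test_training_profile_speeds(self):
        prof = rotarod_profile("training")
        assert tuple(int(s) for s, _ in prof.schedule) == TRAINING_SPEEDS_RPM
        assert all(d == 60.0 for _, d in prof.schedule)

    def test_test_ramp_structure(self):
        prof = rotarod_profile("test")
        speeds = [s for s, _ in prof.schedule]
        assert len(speeds) == 59
        assert speeds == sorted(speeds)
        assert speeds[0] == 2.0 and speeds[-1] == 60.0
        assert prof.duration == pytest.approx(472.0)

    def test_outcome_at_ramp_ends(self):
        prof = rotarod_profile("test")
        assert rotarod_outcome(0.0, prof).max_speed == 2.0
        assert rotarod_outcome(472.0, prof).max_speed == 60.0

    def test_outcome_mid_ramp_step_indexing(self):
        prof = rotarod_profile("test")
        step = 472.0 / 59
        for k in (1, 10, 30):
            # fall during the k-th step (0-based k) -> speed 2 + k rpm
            assert rotarod_outcome((k + 0.5) * step, prof).max_speed == 2.0 + k

    def test_fall_beyond_profile_clamps_with_warning(self):
        prof = rotarod_profile("test")
        with pytest.warns(UserWarning, match="clamp"):
            oc = rotarod_outcome(500.0, prof)
        assert oc.max_speed == 60.0
        assert oc.time_on_rod == pytest.approx(472.0)
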