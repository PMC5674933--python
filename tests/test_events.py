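"""Onset, release and impact detection plus trial exclusion rules."""

import numpy as np
import pytest

from throwcast.events import (
    EventDetectionError,
    KeyEvents,
    NoBoardCrossingError,
    QuadraticFlightFit,
    _fit_to_impact,
    apply_exclusion_rules,
    detect_events,
    detect_onset,
    detect_release,
    extrapolate_impact,
    impact_from_fit,
)
from throwcast.preprocess import ProcessedTrial, process_trial
from throwcast.trialdata import CANONICAL_MARKERS, BoardGeometry

FS = 120.0


def _processed_stub(times, pos, vel, ball_center=None, ball_valid=None,
                    valid=None):
    """Hand-built ProcessedTrial for targeted event-detector tests."""
    n = len(times)
    if valid is None:
        valid = {m: np.ones(n, bool) for m in pos}
    if ball_center is None:
        ball_center = np.full((n, 3), np.nan)
        ball_valid = np.zeros(n, bool)
    return ProcessedTrial(
        trial_id="stub", participant_id="p", times=times, sample_rate=FS,
        pos=pos, vel=vel, acc={}, valid=valid,
        ball_center=ball_center, ball_valid=ball_valid,
        fit_residuals=np.full(n, np.nan), gap_reports={}, unfillable=[],
    )


class TestDetectOnset:
    def test_convex_profile_returns_tangent_zero_intercept(self):
        # quadratic speed v = a (t - tz)^2: strictly convex, so the profile
        # never dips below the tangent and the detector falls back to the
        # tangent's zero intercept, which for a square law sits midway
        # between tz and the 20%-threshold time
        times = np.arange(0, 2.0, 1 / FS)
        n = len(times)
        t_z, a = 1.0, 20.0
        speed = a * np.clip(times - t_z, 0.0, None) ** 2
        hand = np.zeros((n, 3))
        hand[:, 2] = (a / 3.0) * np.clip(times - t_z, 0.0, None) ** 3
        hip = np.zeros((n, 3))
        vel_hand = np.zeros((n - 1, 3))
        vel_hand[:, 2] = speed[:-1]
        proc = _processed_stub(times, {"r_hand": hand, "r_hip": hip},
                               {"r_hand": vel_hand,
                                "r_hip": np.zeros((n - 1, 3))})
        t_onset, _ = detect_onset(proc)
        t0 = t_z + (0.05 * 3.0 / a) ** (1.0 / 3.0)   # hand 5 cm above hip
        t_win_end = t0 + 0.25
        vmax = a * (t_win_end - t_z) ** 2
        t20 = t_z + np.sqrt(0.2 * vmax / a)
        expected = (t_z + t20) / 2.0
        assert abs(t_onset - expected) <= 2.5 / FS

    def test_hand_never_rising_raises(self):
        times = np.arange(0, 1.0, 1 / FS)
        n = len(times)
        flat = np.zeros((n, 3))
        proc = _processed_stub(times, {"r_hand": flat, "r_hip": flat},
                               {"r_hand": np.zeros((n - 1, 3)),
                                "r_hip": np.zeros((n - 1, 3))})
        with pytest.raises(EventDetectionError, match="never rises"):
            detect_onset(proc)

    def test_onset_recovery_on_simulated_trials(self, sim_pairs):
        errors = []
        for rec, truth in sim_pairs:
            proc = process_trial(rec)
            t_onset, _ = detect_onset(proc)
            errors.append(abs(t_onset - truth.true_onset))
        errors = np.array(errors)
        assert np.quantile(errors, 0.95) <= 0.050


class TestDetectRelease:
    def _release_stub(self, peaks):
        times = np.arange(0, 2.0, 1 / FS)
        n = len(times)
        hand = np.zeros((n, 3))
        ball = np.full((n, 3), 0.05)   # constant 5 cm from the hand
        sep = times >= 1.2
        ball[sep, 1] += 0.5            # ball leaves at 1.2 s
        speed = np.zeros(n - 1)
        for t_pk, v_pk in peaks:
            speed += v_pk * np.exp(-0.5 * ((times[:-1] - t_pk) / 0.03) ** 2)
        vel = np.zeros((n - 1, 3))
        vel[:, 1] = speed
        return _processed_stub(
            times, {"r_hand": hand}, {"r_hand": vel},
            ball_center=ball, ball_valid=np.ones(n, bool))

    def test_single_peak_found(self):
        proc = self._release_stub([(1.2, 8.0)])
        t_rel, peak = detect_release(proc)
        assert abs(t_rel - 1.2) <= 1.5 / FS
        assert peak == pytest.approx(8.0, rel=1e-3)

    def test_global_max_wins_between_two_peaks(self):
        proc = self._release_stub([(1.05, 5.0), (1.30, 9.0)])
        t_rel, _ = detect_release(proc)
        assert abs(t_rel - 1.30) <= 1.5 / FS

    def test_exact_tie_goes_to_earlier_sample(self):
        times = np.arange(0, 2.0, 1 / FS)
        n = len(times)
        hand = np.zeros((n, 3))
        ball = np.full((n, 3), 0.05)
        ball[times >= 1.2, 1] += 0.5
        vel = np.zeros((n - 1, 3))
        k1 = np.argmin(np.abs(times - 1.10))
        k2 = np.argmin(np.abs(times - 1.35))
        vel[k1, 1] = 7.0
        vel[k2, 1] = 7.0
        proc = _processed_stub(times, {"r_hand": hand}, {"r_hand": vel},
                               ball_center=ball,
                               ball_valid=np.ones(n, bool))
        t_rel, _ = detect_release(proc)
        assert np.isclose(t_rel, times[k1])

    def test_never_released_raises(self):
        times = np.arange(0, 2.0, 1 / FS)
        n = len(times)
        hand = np.zeros((n, 3))
        ball = np.full((n, 3), 0.05)
        vel = np.zeros((n - 1, 3))
        proc = _processed_stub(times, {"r_hand": hand}, {"r_hand": vel},
                               ball_center=ball,
                               ball_valid=np.ones(n, bool))
        with pytest.raises(EventDetectionError, match="never released"):
            detect_release(proc)

    def test_release_recovery_on_simulated_trials(self, sim_pairs):
        hits = 0
        for rec, truth in sim_pairs:
            proc = process_trial(rec)
            t_rel, _ = detect_release(proc)
            if abs(t_rel - truth.true_release) <= 1.0 / FS + 1e-9:
                hits += 1
        assert hits >= 0.95 * len(sim_pairs)


def _parabola_processed(p0, v0, g=9.81, t_release=1.0, t_end=1.6,
                        drop=None):
    times = np.arange(0, t_end, 1 / FS)
    n = len(times)
    tau = times - t_release
    center = np.full((n, 3), np.nan)
    flight = tau >= 0
    center[flight] = p0 + np.outer(tau[flight], v0)
    center[flight, 2] -= 0.5 * g * tau[flight] ** 2
    valid = flight.copy()
    if drop is not None:
        valid[drop] = False
    return _processed_stub(times, {}, {}, ball_center=center,
                           ball_valid=valid)


class TestExtrapolateImpact:
    def test_exact_parabola_recovered_to_micron(self):
        p0 = np.array([0.2, 0.4, 1.7])
        v0 = np.array([0.8, 11.0, 1.0])
        proc = _parabola_processed(p0, v0)
        fit = extrapolate_impact(proc, 1.0, BoardGeometry())
        t_impact, landing = impact_from_fit(fit)
        tau_true = (6.0 - p0[1]) / v0[1]
        x_true = p0[0] + v0[0] * tau_true
        z_true = p0[2] + v0[2] * tau_true - 0.5 * 9.81 * tau_true**2
        assert abs(t_impact - (1.0 + tau_true)) <= 1e-6
        assert abs(landing[0] - x_true) <= 1e-6
        assert abs(landing[1] - z_true) <= 1e-6

    def test_robust_to_25pct_dropped_fit_frames(self):
        p0 = np.array([0.2, 0.4, 1.7])
        v0 = np.array([0.8, 11.0, 1.0])
        rng = np.random.default_rng(9)
        times = np.arange(0, 1.6, 1 / FS)
        in_fit = np.flatnonzero((times - 1.0 >= 0.15) & (times - 1.0 <= 0.45))
        drop = rng.choice(in_fit, size=len(in_fit) // 4, replace=False)
        full = extrapolate_impact(_parabola_processed(p0, v0), 1.0,
                                  BoardGeometry())
        sub = extrapolate_impact(_parabola_processed(p0, v0, drop=drop), 1.0,
                                 BoardGeometry())
        _, l_full = impact_from_fit(full)
        _, l_sub = impact_from_fit(sub)
        assert abs(l_full[0] - l_sub[0]) <= 1e-6
        assert abs(l_full[1] - l_sub[1]) <= 1e-6

    def test_short_throw_raises_no_board_crossing(self):
        proc = _parabola_processed(np.array([0.0, 0.4, 1.7]),
                                   np.array([0.0, 3.0, 2.0]), t_end=1.6)
        with pytest.raises(NoBoardCrossingError):
            extrapolate_impact(proc, 1.0, BoardGeometry())

    def test_too_few_fit_samples_raise(self):
        proc = _parabola_processed(np.array([0.0, 0.4, 1.7]),
                                   np.array([0.0, 11.0, 1.0]), t_end=1.18)
        with pytest.raises(EventDetectionError, match="valid ball frames"):
            extrapolate_impact(proc, 1.0, BoardGeometry())

    def test_release_state_matches_construction(self):
        coeffs = np.array([
            [0.0, 0.8, 0.2],
            [0.0, 11.0, 0.4],
            [-0.5 * 9.81, 1.0, 1.7],
        ])
        fit = _fit_to_impact(coeffs, 1.0, BoardGeometry(), 1.0)
        state = fit.release_state()
        assert np.allclose(state[:3], [0.2, 0.4, 1.7])
        assert np.allclose(state[3:], [0.8, 11.0, 1.0])


class TestKeyEventsAndExclusion:
    def test_event_ordering_enforced(self):
        with pytest.raises(ValueError, match="onset < release < impact"):
            KeyEvents(t_onset=1.5, t_release=1.0, t_impact=2.0,
                      landing=(0.1, 1.4), hand_peak_speed=10.0)

    def test_clean_trial_not_excluded(self, sim_records):
        rec = sim_records[0]
        proc = process_trial(rec)
        events = detect_events(proc, BoardGeometry())
        rep = apply_exclusion_rules(rec, proc, events)
        assert not rep.excluded and rep.reason == "none"

    def test_flight_gaps_over_25pct_excluded(self, sim_records):
        rec = sim_records[0].copy()
        proc = process_trial(rec)
        events = detect_events(proc, BoardGeometry())
        flight = (proc.times >= events.t_release) & (proc.times <= events.t_impact)
        idx = np.flatnonzero(flight)
        kill = idx[: int(0.3 * len(idx)) + 1]
        proc.ball_valid[kill] = False
        rep = apply_exclusion_rules(rec, proc, events)
        assert rep.reason == "ball_flight_gaps_gt_25pct"

    def test_hand_lost_at_release_excluded(self, sim_records):
        rec = sim_records[0].copy()
        proc = process_trial(rec)
        events = detect_events(proc, BoardGeometry())
        k = int(np.argmin(np.abs(rec.times - events.t_release)))
        rec.valid["r_hand"][k] = False
        rep = apply_exclusion_rules(rec, proc, events)
        assert rep.reason == "hand_lost_at_release"

    def test_pre_throw_step_flag_excluded(self, sim_records):
        rec = sim_records[0].copy()
        rec.flags["pre_throw_step"] = True
        proc = process_trial(rec)
        events = detect_events(proc, BoardGeometry())
        rep = apply_exclusion_rules(rec, proc, events)
        assert rep.reason == "pre_throw_step"

    def test_unfillable_marker_is_bad_tracking(self, sim_records):
        rec = sim_records[0].copy()
        rec.valid["l_knee"][:] = False
        rec.positions["l_knee"][:] = np.nan
        proc = process_trial(rec)
        rep = apply_exclusion_rules(rec, proc, None,
                                    EventDetectionError("x"))
        assert rep.reason == "bad_joint_tracking"

    def test_no_board_crossing_failure_mapped(self, sim_records):
        rec = sim_records[0]
        proc = process_trial(rec)
        rep = apply_exclusion_rules(rec, proc, None,
                                    NoBoardCrossingError("short"))
        assert rep.reason == "no_board_crossing"

    def test_exclusions_rise_with_gap_rate(self):
        import throwcast as tc
        from throwcast.dataset import assemble_participant

        def excluded_fraction(gap_rate):
            cfg = tc.ThrowSimConfig(n_trials=15, seed=5, gap_rate=gap_rate,
                                    informative_markers=())
            records = [r for r, _ in tc.simulate_participant(cfg)]
            n_bad = 0
            for rec in records:
                proc = process_trial(rec)
                try:
                    ev = detect_events(proc, BoardGeometry())
                    rep = apply_exclusion_rules(rec, proc, ev)
                except EventDetectionError as err:
                    rep = apply_exclusion_rules(rec, proc, None, err)
                n_bad += rep.excluded
            return n_bad / len(records)

        assert excluded_fraction(0.0) <= excluded_fraction(0.10)
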