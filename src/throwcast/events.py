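"""Key-event detection: throwing onset, ball release, board impact.

Onset uses the classical tangent estimator on the hand speed profile around
the time the hand first rises 5 cm above the (ipsilateral) hip. Release is
the hand-speed maximum in a 500 ms window centered on the first frame at
which the hand-ball distance exceeds its in-hand baseline by a margin. Impact
is extrapolated by fitting each ball-center coordinate with an independent
quadratic over [150 ms, 450 ms] after release and propagating it up to 300 ms
further to the board plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ProcessedTrial
from .trialdata import CANONICAL_MARKERS, BoardGeometry, TrialRecord


class EventDetectionError(RuntimeError):
    """A key event could not be identified for this trial."""


class NoBoardCrossingError(EventDetectionError):
    """The extrapolated ball trajectory never reaches the board plane."""


@dataclass(frozen=True)
class QuadraticFlightFit:
    """Per-coordinate quadratic fit of the ball flight, tau = t - t_release."""

    t_release: float
    coeffs: np.ndarray  # (3, 3): rows x,y,z; columns [c2, c1, c0]

    def position_at(self, tau: float) -> np.ndarray:
        return np.array([np.polyval(c, tau) for c in self.coeffs])

    def velocity_at(self, tau: float) -> np.ndarray:
        return np.array([np.polyval(np.polyder(c), tau) for c in self.coeffs])

    def release_state(self) -> np.ndarray:
        """Six predictors: ball position and velocity at release."""
        return np.concatenate([self.position_at(0.0), self.velocity_at(0.0)])


@dataclass
class KeyEvents:
    t_onset: float
    t_release: float
    t_impact: float
    landing: tuple[float, float]
    hand_peak_speed: float
    flight_fit: QuadraticFlightFit | None = None
    qc: set = field(default_factory=set)

    def __post_init__(self):
        if not self.t_onset < self.t_release < self.t_impact:
            raise ValueError("events must satisfy onset < release < impact")


EXCLUSION_REASONS = (
    "bad_joint_tracking",
    "hand_lost_at_release",
    "ball_flight_gaps_gt_25pct",
    "pre_throw_step",
    "no_board_crossing",
    "none",
)


@dataclass(frozen=True)
class ExclusionReport:
    trial_id: str
    excluded: bool
    reason: str

    def __post_init__(self):
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")
        if self.excluded != (self.reason != "none"):
            raise ValueError("excluded flag inconsistent with reason")


def detect_onset(processed: ProcessedTrial, rise_height: float = 0.05,
                 window: float = 0.5, fraction: float = 0.2,
                 hand: str = "r_hand", hip: str = "r_hip"):
    """Tangent-method onset of the throwing hand's initial rise.

    Returns ``(t_onset, qc_flags)``. Steps: (1) find the first time the hand
    is ``rise_height`` above the hip; (2) in a ``window`` centered there,
    find the first time hand speed reaches ``fraction`` of the window
    maximum; (3) walk back to the latest sample where the speed profile
    crosses the tangent taken at that point, falling back to the tangent's
    zero-speed intercept (clamped to the window start) when the profile never
    dips below the tangent.
    """
    qc: set = set()
    both = processed.valid[hand] & processed.valid[hip]
    zdiff = processed.pos[hand][:, 2] - processed.pos[hip][:, 2]
    above = both & (zdiff >= rise_height)
    if not np.any(above):
        raise EventDetectionError("hand never rises above the hip threshold")
    t0 = processed.times[np.argmax(above)]

    tv = processed.vel_times
    speed = processed.speed(hand)
    in_win = (tv >= t0 - window / 2) & (tv <= t0 + window / 2) & np.isfinite(speed)
    if not np.any(in_win):
        raise EventDetectionError("no valid hand speed around the rise event")
    wi = np.flatnonzero(in_win)
    ts_w = tv[wi]
    sp_w = speed[wi]
    vmax = sp_w.max()
    v_thr = fraction * vmax
    k20 = int(np.argmax(sp_w >= v_thr))
    t20, v20 = ts_w[k20], sp_w[k20]

    # tangent slope from a central difference on the filtered speed
    lo, hi = max(k20 - 1, 0), min(k20 + 1, len(sp_w) - 1)
    slope = (sp_w[hi] - sp_w[lo]) / (ts_w[hi] - ts_w[lo]) if hi > lo else 0.0

    tangent = v20 + slope * (ts_w - t20)
    resid = sp_w - tangent
    t_onset = None
    for k in range(k20 - 1, 0, -1):
        if resid[k] * resid[k - 1] < 0 or resid[k] == 0.0:
            t_onset = ts_w[k]
            break
    if t_onset is None:
        if slope > 0:
            t_onset = t20 - v20 / slope
        else:
            t_onset = ts_w[0]
            qc.add("onset_no_tangent_slope")
        if t_onset < ts_w[0]:
            t_onset = ts_w[0]
            qc.add("onset_clamped_to_window_start")
    return float(t_onset), qc


def detect_release(processed: ProcessedTrial, window: float = 0.5,
                   hold_margin: float = 0.03, baseline_s: float = 0.2,
                   hand: str = "r_hand"):
    """Hand-speed maximum around the first supra-threshold hand-ball distance.

    The threshold is the median in-hand hand-ball distance over the first
    ``baseline_s`` of the trial plus ``hold_margin``. Returns
    ``(t_release, hand_peak_speed)``. Ties on the speed maximum go to the
    earlier sample.
    """
    ok = processed.valid[hand] & processed.ball_valid
    dist = np.where(
        ok, np.linalg.norm(processed.pos[hand] - processed.ball_center, axis=1),
        np.nan,
    )
    t_start = processed.times[0]
    base = dist[(processed.times <= t_start + baseline_s)]
    base = base[np.isfinite(base)]
    if len(base) == 0:
        raise EventDetectionError("no valid hand-ball distance at trial start")
    threshold = float(np.median(base)) + hold_margin
    over = np.isfinite(dist) & (dist > threshold)
    if not np.any(over):
        raise EventDetectionError("hand-ball distance never exceeds threshold; "
                                  "ball apparently never released")
    t_d = processed.times[np.argmax(over)]

    tv = processed.vel_times
    speed = processed.speed(hand)
    in_win = (tv >= t_d - window / 2) & (tv <= t_d + window / 2) & np.isfinite(speed)
    if not np.any(in_win):
        raise EventDetectionError("no valid hand speed in the release window")
    wi = np.flatnonzero(in_win)
    k = wi[int(np.argmax(speed[wi]))]
    return float(tv[k]), float(speed[k])


def extrapolate_impact(processed: ProcessedTrial, t_release: float,
                       board: BoardGeometry,
                       fit_window: tuple[float, float] = (0.150, 0.450),
                       horizon: float = 0.300,
                       min_samples: int = 6) -> QuadraticFlightFit:
    """Quadratic fit of the ball flight after release (valid frames only).

    Raises :class:`NoBoardCrossingError` if the extrapolated forward
    coordinate does not reach the board plane within
    ``fit_window[1] + horizon`` after release.
    """
    tau = processed.times - t_release
    sel = processed.ball_valid & (tau >= fit_window[0]) & (tau <= fit_window[1])
    if sel.sum() < min_samples:
        raise EventDetectionError(
            f"only {int(sel.sum())} valid ball frames inside the fit window")
    t_fit = tau[sel]
    coeffs = np.stack([
        np.polyfit(t_fit, processed.ball_center[sel, j], 2) for j in range(3)
    ])
    return _fit_to_impact(coeffs, t_release, board, fit_window[1] + horizon)


def _fit_to_impact(coeffs: np.ndarray, t_release: float, board: BoardGeometry,
                   tau_max: float) -> QuadraticFlightFit:
    fit = QuadraticFlightFit(t_release=t_release, coeffs=coeffs)
    c2, c1, c0 = coeffs[1]
    crossing = None
    if abs(c2) > 1e-9:
        roots = np.roots([c2, c1, c0 - board.distance_m])
        real = sorted(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0)
        crossing = real[0] if real else None
    elif abs(c1) > 1e-12:
        r = (board.distance_m - c0) / c1
        crossing = r if r > 0 else None
    if crossing is None or crossing > tau_max:
        raise NoBoardCrossingError(
            "extrapolated trajectory does not reach the board within horizon")
    landing = fit.position_at(crossing)
    object.__setattr__(fit, "_impact_tau", float(crossing))
    object.__setattr__(fit, "_landing", (float(landing[0]), float(landing[2])))
    return fit


def impact_from_fit(fit: QuadraticFlightFit):
    return fit.t_release + fit._impact_tau, fit._landing


def detect_events(processed: ProcessedTrial, board: BoardGeometry,
                  onset_rise_m: float = 0.05, onset_window_s: float = 0.5,
                  onset_fraction: float = 0.2, release_window_s: float = 0.5,
                  release_margin_m: float = 0.03,
                  fit_window_s: tuple[float, float] = (0.150, 0.450),
                  horizon_s: float = 0.300) -> KeyEvents:
    """Run the full onset/release/impact detection for one processed trial."""
    t_onset, qc = detect_onset(processed, onset_rise_m, onset_window_s,
                               onset_fraction)
    t_release, peak = detect_release(processed, release_window_s,
                                     release_margin_m)
    fit = extrapolate_impact(processed, t_release, board, fit_window_s,
                             horizon_s)
    t_impact, landing = impact_from_fit(fit)
    return KeyEvents(
        t_onset=t_onset,
        t_release=t_release,
        t_impact=t_impact,
        landing=landing,
        hand_peak_speed=peak,
        flight_fit=fit,
        qc=qc,
    )


def apply_exclusion_rules(record: TrialRecord, processed: ProcessedTrial,
                          events: KeyEvents | None,
                          failure: EventDetectionError | None = None,
                          max_speed_m_s: float = 30.0) -> ExclusionReport:
    """Trial exclusion: bad joint tracking, hand lost at release, >25% missing
    ball-flight frames, or a flagged pre-throw step. The first matching
    reason (in that order) is reported; detection failures map onto the bad
    tracking / no-board-crossing categories."""

    def report(reason):
        return ExclusionReport(record.trial_id, reason != "none", reason)

    # rule 1: impossible values or unfillable gaps on any canonical marker
    if processed.unfillable:
        return report("bad_joint_tracking")
    for m in CANONICAL_MARKERS:
        sp = processed.speed(m)
        if np.any(sp[np.isfinite(sp)] > max_speed_m_s):
            return report("bad_joint_tracking")

    if events is None:
        if isinstance(failure, NoBoardCrossingError):
            return report("no_board_crossing")
        return report("bad_joint_tracking")

    # rule 2: raw right-hand tracking lost at the release frame
    k_rel = int(np.argmin(np.abs(record.times - events.t_release)))
    if not record.valid["r_hand"][k_rel]:
        return report("hand_lost_at_release")

    # rule 3: >25% missing ball frames between release and impact
    in_flight = (record.times >= events.t_release) & (record.times <= events.t_impact)
    if in_flight.sum() > 0:
        missing = 1.0 - processed.ball_valid[in_flight].mean()
        if missing > 0.25:
            return report("ball_flight_gaps_gt_25pct")

    # rule 4: manually flagged pre-throw step
    if record.flags.get("pre_throw_step"):
        return report("pre_throw_step")

    return report("none")
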