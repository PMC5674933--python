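"""Synthetic overarm-throw generator with exact ground truth.

Each simulated trial reproduces the structure of a recorded throw: a quiescent
standing posture, an elevation phase raising the throwing hand (an initial
brisk lift followed by a reach-back, both minimum-jerk segments), a short
forward-projection segment whose hand speed peaks exactly at ball release, and
a drag-free ballistic ball flight toward a board 6 m ahead. The ball is rigidly
attached to the hand until release and carries five asymmetrically placed
surface markers spinning smoothly around a per-trial axis.

Class structure: the side (Right/Left) on which the ball lands is driven by a
lateral release-velocity component modeled as a wrist/finger "snap" that is
*not* expressed in the coarse joint markers. Side information enters the
tracked body kinematics only through the configured ``informative_markers``,
whose lateral (x) coordinate diverges by class, ramping linearly from a chosen
time decile of the action up to release. This makes the generator a controlled
instrument: markers without injected divergence are exactly uninformative, so
downstream classifiers can be validated against chance, and parameter-recovery
tests have an unambiguous target.

Measurement noise has two components, emulating optical motion capture: slow
low-pass-correlated drift (reconstruction/soft-tissue error) and white
instrumental jitter. Recording gaps are injected as random short runs of
invalidated frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .trialdata import (
    BALL_MARKERS,
    BALL_RADIUS_M,
    CANONICAL_MARKERS,
    BoardGeometry,
    TrialRecord,
)

# Quiet-standing marker positions (m) in the lab frame (x right, y forward,
# z up, origin at the starting floor mark).
REST_POSTURE: dict[str, tuple[float, float, float]] = {
    "l_foot": (-0.12, 0.05, 0.04), "r_foot": (0.12, 0.05, 0.04),
    "l_ankle": (-0.12, 0.00, 0.09), "r_ankle": (0.12, 0.00, 0.09),
    "l_knee": (-0.12, 0.02, 0.50), "r_knee": (0.12, 0.02, 0.50),
    "l_hip": (-0.13, 0.00, 0.95), "r_hip": (0.13, 0.00, 0.95),
    "l_shoulder": (-0.19, 0.00, 1.45), "r_shoulder": (0.19, 0.00, 1.45),
    "l_elbow": (-0.22, 0.00, 1.17), "r_elbow": (0.22, 0.00, 1.17),
    "l_wrist": (-0.21, 0.02, 0.93), "r_wrist": (0.21, 0.02, 0.93),
    "l_hand": (-0.20, 0.03, 0.83), "r_hand": (0.20, 0.03, 0.83),
    "cv7": (0.00, -0.03, 1.52), "head": (0.00, 0.05, 1.65),
}

# Whole-body weight-shift displacement (m) applied over the throwing action
# (an "on-place" thrower leaning into the throw; feet stay planted).
_WEIGHT_SHIFT: dict[str, tuple[float, float, float]] = {
    "l_hip": (0.0, 0.16, -0.03), "r_hip": (0.0, 0.16, -0.03),
    "l_shoulder": (0.0, 0.20, -0.02), "r_shoulder": (0.0, 0.18, -0.02),
    "cv7": (0.0, 0.20, -0.02), "head": (0.0, 0.22, -0.02),
    "l_knee": (0.0, 0.07, -0.01), "r_knee": (0.0, 0.07, -0.01),
    "l_ankle": (0.0, 0.02, 0.0), "r_ankle": (0.0, 0.02, 0.0),
    "l_foot": (0.0, 0.0, 0.0), "r_foot": (0.0, 0.0, 0.0),
    # counter-swinging contralateral arm
    "l_elbow": (0.0, -0.10, 0.03), "l_wrist": (0.0, -0.14, 0.06),
    "l_hand": (0.0, -0.16, 0.08),
}

# Arm-chain markers follow the hand trajectory with attenuated amplitude.
_HAND_FOLLOW = {"r_wrist": 0.85, "r_elbow": 0.55, "r_shoulder": 0.12}

#: Five asymmetric unit directions for the ball surface markers (their
#: centroid is deliberately offset from the sphere center).
BALL_MARKER_LAYOUT = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.577350269, 0.577350269, 0.577350269],
        [-0.666666667, 0.666666667, 0.333333333],
    ]
)

_BALL_HOLD_OFFSET = np.array([0.02, 0.06, 0.01])  # ball center relative to hand


@dataclass(frozen=True)
class InformativeMarker:
    """Class-dependent lateral divergence injected into one joint marker.

    The marker's x coordinate is offset by ``side_sign * amplitude_m * ramp``
    where the ramp rises linearly from the start of ``onset_decile`` (1..10,
    fractions of the onset-to-release action) to 1 at ball release.
    """

    marker: str
    onset_decile: int
    amplitude_m: float

    def __post_init__(self):
        if self.marker not in CANONICAL_MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if not 1 <= self.onset_decile <= 10:
            raise ValueError("onset_decile must be in [1, 10]")
        if self.amplitude_m < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class ThrowSimConfig:
    """Study conditions for one simulated participant."""

    n_trials: int = 100
    p_right: float = 0.5
    duration_range_s: tuple[float, float] = (0.8, 1.8)
    release_speed_range: tuple[float, float] = (9.0, 14.0)
    lateral_speed_range: tuple[float, float] = (0.5, 1.2)
    landing_z_range: tuple[float, float] = (0.9, 2.1)
    informative_markers: tuple[InformativeMarker, ...] = (
        InformativeMarker("l_ankle", 6, 0.08),
        InformativeMarker("r_wrist", 9, 0.04),
    )
    noise_sigma: float = 0.002          # slow drift on body markers, m
    noise_cutoff_hz: float = 1.0        # drift correlation band
    jitter_sigma: float = 0.0005        # white instrumental jitter, m
    ball_noise_sigma: float = 0.0005    # white jitter on ball markers, m
    gap_rate: float = 0.002             # per-frame gap-start probability
    max_gap_run: int = 6
    ball_occlusion_rate: float = 0.0
    ball_spin_hz: float = 1.5
    board: BoardGeometry = field(default_factory=BoardGeometry)
    gravity: float = 9.81
    sample_rate: float = 120.0
    quiescence_s: float = 0.6
    projection_s: float = 0.2           # forward-projection segment duration
    participant_id: str = "sim"
    seed: int | None = 0

    def __post_init__(self):
        if not 0.0 <= self.p_right <= 1.0:
            raise ValueError("p_right must be in [0, 1]")
        if self.quiescence_s < 0.5:
            raise ValueError("need at least 0.5 s of quiescent standing")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        if self.duration_range_s[0] < 2 * self.projection_s:
            raise ValueError("throw duration must exceed the projection segment")


@dataclass(frozen=True)
class GroundTruth:
    """Simulation bookkeeping: true events, class and landing for one trial."""

    trial_id: str
    true_onset: float
    true_release: float
    true_impact: float
    true_side: str                     # "Right" | "Left"
    true_landing: tuple[float, float]  # (x, z) on the board plane
    release_pos: np.ndarray
    release_vel: np.ndarray
    informative_markers: tuple[InformativeMarker, ...]

    def __post_init__(self):
        if not self.true_onset < self.true_release < self.true_impact:
            raise ValueError("events must be ordered onset < release < impact")


def minimum_jerk(t: np.ndarray, t0: float, t1: float,
                 p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Minimum-jerk point-to-point trajectory, clamped outside [t0, t1]."""
    tau = np.clip((np.asarray(t, float) - t0) / (t1 - t0), 0.0, 1.0)
    s = tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    return np.asarray(p0) + np.outer(s, np.asarray(p1) - np.asarray(p0))


def simulate_ball_flight(release_pos, release_vel, gravity: float,
                         board: BoardGeometry, sample_rate: float = 120.0):
    """Drag-free parabolic flight from release until board crossing.

    Returns ``(times, trajectory, t_impact, landing)`` with times relative to
    release, trajectory sampled at ``sample_rate`` on [0, t_impact], and
    landing the (x, z) point where y first reaches the board plane.
    """
    p = np.asarray(release_pos, float)
    v = np.asarray(release_vel, float)
    if v[1] <= 0:
        raise ValueError("forward (y) release velocity must be positive")
    t_impact = (board.distance_m - p[1]) / v[1]
    if t_impact <= 0:
        raise ValueError("release position already past the board")
    z_at_board = p[2] + v[2] * t_impact - 0.5 * gravity * t_impact**2
    if z_at_board <= 0:
        raise ValueError("ball hits the floor before crossing the board plane")
    ts = np.arange(0.0, t_impact, 1.0 / sample_rate)
    traj = p + np.outer(ts, v)
    traj[:, 2] -= 0.5 * gravity * ts**2
    landing = (p[0] + v[0] * t_impact, z_at_board)
    return ts, traj, t_impact, landing


def ball_marker_cloud(center_series: np.ndarray, times: np.ndarray,
                      radius: float = BALL_RADIUS_M,
                      layout: np.ndarray = BALL_MARKER_LAYOUT,
                      occlusion_rate: float = 0.0,
                      spin_axis=(0.26726124, 0.53452248, 0.80178373),
                      spin_hz: float = 1.5,
                      rng: np.random.Generator | None = None):
    """Five ball-surface marker series around a rotating rigid ball.

    ``marker_i(t) = center(t) + radius * R(t) @ layout_i`` with R(t) a smooth
    rotation about ``spin_axis``. Per-marker frames are dropped independently
    with probability ``occlusion_rate``.
    """
    if radius <= 0:
        raise ValueError("ball radius must be positive")
    layout = np.asarray(layout, float)
    if layout.shape != (5, 3):
        raise ValueError("layout must give 5 unit directions")
    center = np.asarray(center_series, float)
    axis = np.asarray(spin_axis, float)
    axis = axis / np.linalg.norm(axis)
    angles = 2.0 * np.pi * spin_hz * np.asarray(times, float)
    rots = Rotation.from_rotvec(np.outer(angles, axis))
    n = len(center)
    positions, valid = {}, {}
    if rng is None:
        rng = np.random.default_rng()
    for i, name in enumerate(BALL_MARKERS):
        offs = rots.apply(radius * layout[i])
        positions[name] = center + offs
        keep = np.ones(n, dtype=bool)
        if occlusion_rate > 0:
            keep = rng.random(n) >= occlusion_rate
        valid[name] = keep
    return positions, valid


def inject_gaps(valid: np.ndarray, gap_rate: float, max_run: int,
                rng: np.random.Generator) -> np.ndarray:
    """Clear random runs (length <= max_run) of a validity mask."""
    if not 0.0 <= gap_rate < 1.0:
        raise ValueError("gap_rate must be in [0, 1)")
    mask = np.asarray(valid, bool).copy()
    n = len(mask)
    starts = np.flatnonzero(rng.random(n) < gap_rate)
    for s in starts:
        run = int(rng.integers(1, max_run + 1))
        mask[s:s + run] = False
    return mask


def _correlated_noise(n: int, sigma: float, cutoff_hz: float, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Low-pass-correlated Gaussian drift scaled to std ``sigma``."""
    if sigma == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n + 256)          # pad to settle the filter
    b, a = signal.butter(2, cutoff_hz / (fs / 2))
    smooth = signal.filtfilt(b, a, white)[128:128 + n]
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(n)
    return sigma / sd * smooth


def _measurement_noise(n: int, cfg: ThrowSimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    drift = np.column_stack(
        [_correlated_noise(n, cfg.noise_sigma, cfg.noise_cutoff_hz,
                           cfg.sample_rate, rng) for _ in range(3)]
    )
    if cfg.jitter_sigma > 0:
        drift = drift + cfg.jitter_sigma * rng.standard_normal((n, 3))
    return drift


def _sample_release_velocity(cfg: ThrowSimConfig, side_sign: float,
                             release_pos: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Ball release velocity with given speed, lateral snap and landing height."""
    speed = rng.uniform(*cfg.release_speed_range)
    vx = side_sign * rng.uniform(*cfg.lateral_speed_range)
    z_land = rng.uniform(*cfg.landing_z_range)
    dy = cfg.board.distance_m - release_pos[1]
    vy = np.sqrt(max(speed**2 - vx**2, 1e-9))
    vz = 0.0
    for _ in range(4):
        tf = dy / vy
        vz = (z_land - release_pos[2] + 0.5 * cfg.gravity * tf**2) / tf
        rest = speed**2 - vx**2 - vz**2
        if rest <= 1.0:
            raise ValueError("release speed too low to reach the board")
        vy = np.sqrt(rest)
    return np.array([vx, vy, vz])


def simulate_trial(cfg: ThrowSimConfig, trial_id: str,
                   rng: np.random.Generator) -> tuple[TrialRecord, GroundTruth]:
    """Generate one labeled trial; see module docstring for the model."""
    fs = cfg.sample_rate
    dt = 1.0 / fs
    t_onset = cfg.quiescence_s
    duration = rng.uniform(*cfg.duration_range_s)
    t_release = t_onset + duration
    side_sign = 1.0 if rng.random() < cfg.p_right else -1.0
    side = "Right" if side_sign > 0 else "Left"

    posture_jitter = np.array([rng.normal(0, 0.015), rng.normal(0, 0.015), 0.0])
    rest = {m: np.asarray(p) + posture_jitter for m, p in REST_POSTURE.items()}

    # hand path: lift -> reach-back -> forward projection (release at the
    # projection midpoint, where minimum-jerk speed peaks)
    t_proj0 = t_release - cfg.projection_s / 2
    t_proj1 = t_release + cfg.projection_s / 2
    t_elev = t_proj0 - t_onset
    t_lift = min(0.4, 0.5 * t_elev)

    p_release = (np.array([0.25, 0.35, 1.72]) + posture_jitter
                 + rng.normal(0, 0.01, 3))
    v_ball = _sample_release_velocity(cfg, side_sign, p_release, rng)
    # hand moves in the sagittal plane; the lateral component is a snap
    v_hand = np.array([0.0, v_ball[1], v_ball[2]])
    hand_speed = np.linalg.norm(v_hand)
    path_len = hand_speed * cfg.projection_s / 1.875
    vhat = v_hand / hand_speed
    p_back = p_release - 0.5 * path_len * vhat
    p_follow = p_release + 0.5 * path_len * vhat

    ts_rel, _, tau_f, landing = simulate_ball_flight(
        p_release + _BALL_HOLD_OFFSET, v_ball, cfg.gravity, cfg.board, fs
    )
    t_impact = t_release + tau_f
    t_end = t_impact + 2 * dt
    times = np.arange(0.0, t_end, dt)
    n = len(times)

    rest_hand = rest["r_hand"]
    p_lift = rest_hand + np.array([0.0, 0.05, 0.30])
    hand = np.where(
        (times < t_onset + t_lift)[:, None],
        minimum_jerk(times, t_onset, t_onset + t_lift, rest_hand, p_lift),
        minimum_jerk(times, t_onset + t_lift, t_proj0, p_lift, p_back),
    )
    in_proj = times >= t_proj0
    hand[in_proj] = minimum_jerk(times[in_proj], t_proj0, t_proj1,
                                 p_back, p_follow)
    hand_excursion = hand - rest_hand

    mj_shift = minimum_jerk(times, t_onset, t_proj1,
                            np.zeros(3), np.ones(3))[:, 0]

    positions: dict[str, np.ndarray] = {}
    for m in CANONICAL_MARKERS:
        if m == "r_hand":
            traj = hand.copy()
        else:
            traj = np.broadcast_to(rest[m], (n, 3)).copy()
            shift = _WEIGHT_SHIFT.get(m)
            if shift is not None:
                traj = traj + np.outer(mj_shift, np.asarray(shift))
            follow = _HAND_FOLLOW.get(m)
            if follow is not None:
                traj = traj + follow * hand_excursion
        positions[m] = traj

    # class-dependent lateral divergence on the informative markers
    for info in cfg.informative_markers:
        t_start = t_onset + (info.onset_decile - 1) / 10.0 * duration
        ramp = np.clip((times - t_start) / (t_release - t_start), 0.0, 1.0)
        positions[info.marker] = positions[info.marker].copy()
        positions[info.marker][:, 0] += side_sign * info.amplitude_m * ramp

    # ball: rigidly attached to the hand until release, ballistic afterwards
    ball_center = hand + _BALL_HOLD_OFFSET
    flight = times >= t_release
    tau = times[flight] - t_release
    p0 = p_release + _BALL_HOLD_OFFSET
    ball_center[flight] = p0 + np.outer(tau, v_ball)
    ball_center[flight, 2] -= 0.5 * cfg.gravity * tau**2

    ball_positions, ball_valid = ball_marker_cloud(
        ball_center, times, occlusion_rate=cfg.ball_occlusion_rate,
        spin_hz=cfg.ball_spin_hz, rng=rng,
    )

    valid = {}
    for m in CANONICAL_MARKERS:
        positions[m] = positions[m] + _measurement_noise(n, cfg, rng)
        valid[m] = inject_gaps(np.ones(n, bool), cfg.gap_rate,
                               cfg.max_gap_run, rng)
        positions[m][~valid[m]] = np.nan
    for m in BALL_MARKERS:
        # the ball is a rigid body with hard-mounted markers: no soft-tissue
        # drift, only instrumental jitter
        ball_positions[m] = (ball_positions[m]
                             + cfg.ball_noise_sigma * rng.standard_normal((n, 3)))
        ball_valid[m] &= inject_gaps(np.ones(n, bool), cfg.gap_rate,
                                     cfg.max_gap_run, rng)
        ball_positions[m][~ball_valid[m]] = np.nan

    record = TrialRecord(
        participant_id=cfg.participant_id,
        trial_id=trial_id,
        times=times,
        positions=positions,
        valid=valid,
        ball_positions=ball_positions,
        ball_valid=ball_valid,
        sample_rate=fs,
    )
    truth = GroundTruth(
        trial_id=trial_id,
        true_onset=t_onset,
        true_release=t_release,
        true_impact=t_impact,
        true_side=side,
        true_landing=(float(landing[0]), float(landing[1])),
        release_pos=p0,
        release_vel=v_ball,
        informative_markers=cfg.informative_markers,
    )
    return record, truth


def simulate_participant(cfg: ThrowSimConfig,
                         rng: np.random.Generator | None = None
                         ) -> list[tuple[TrialRecord, GroundTruth]]:
    """Generate ``cfg.n_trials`` labeled trials for one synthetic thrower."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = []
    for k in range(cfg.n_trials):
        out.append(simulate_trial(cfg, f"{cfg.participant_id}_t{k:03d}", rng))
    return out


def null_config(**overrides) -> ThrowSimConfig:
    """Config with no informative markers: body kinematics carry no side info."""
    base = ThrowSimConfig(informative_markers=())
    return replace(base, **overrides) if overrides else base
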