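"""Trajectory preprocessing: gap filling, zero-lag low-pass filtering,
numerical differentiation and ball-center estimation.

The fixed pipeline order is fill -> filter -> differentiate. Positions are
low-pass filtered with a forward-backward (zero phase) Butterworth filter of
order 5 and 15 Hz cutoff; velocities and accelerations are forward first
differences of the filtered series. The ball center is recovered per frame by
fitting the available ball-surface markers onto a sphere of known radius
(45 mm), warm-started from the previous frame's center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .trialdata import BALL_MARKERS, BALL_RADIUS_M, TrialRecord


def fill_gaps_spline(values: np.ndarray, valid: np.ndarray,
                     times: np.ndarray | None = None):
    """Fill interior gaps of a series by cubic-spline interpolation.

    Valid samples pass through unchanged; leading/trailing gaps are left
    invalid and reported. Returns ``(filled, span_valid, (n_lead, n_trail))``
    where ``span_valid`` marks the contiguous filled span.
    """
    values = np.asarray(values, float)
    valid = np.asarray(valid, bool)
    n = len(valid)
    idx = np.flatnonzero(valid)
    if len(idx) < 4:
        raise ValueError("need at least 4 valid samples to fill gaps")
    if times is None:
        times = np.arange(n, dtype=float)
    first, last = idx[0], idx[-1]
    filled = values.copy()
    span = np.zeros(n, bool)
    span[first:last + 1] = True
    interior_bad = span & ~valid
    if np.any(interior_bad):
        spline = CubicSpline(times[idx], values[idx], axis=0)
        filled[interior_bad] = spline(times[interior_bad])
    filled[~span] = np.nan
    return filled, span, (int(first), int(n - 1 - last))


from functools import lru_cache


@lru_cache(maxsize=16)
def _butter_coeffs(order: int, cutoff_hz: float, fs: float):
    return signal.butter(order, cutoff_hz / (fs / 2))


def lowpass_zero_lag(values: np.ndarray, fs: float,
                     order: int = 5, cutoff_hz: float = 15.0) -> np.ndarray:
    """Forward-backward Butterworth low-pass; zero phase shift.

    Edge handling: reflective padding of 3x the filter order on both ends.
    """
    values = np.asarray(values, float)
    if fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    if not np.all(np.isfinite(values)):
        raise ValueError("series must be fully valid over its span")
    padlen = 3 * order
    if values.shape[0] <= padlen:
        raise ValueError("span shorter than the required filter padding")
    b, a = _butter_coeffs(order, cutoff_hz, fs)
    return signal.filtfilt(b, a, values, axis=0, padtype="even", padlen=padlen)


def differentiate(values: np.ndarray, fs: float) -> np.ndarray:
    """Forward first difference scaled by the sample interval.

    Output has length n-1, timestamped at the leading sample of each pair.
    """
    values = np.asarray(values, float)
    if values.shape[0] < 2:
        raise ValueError("need at least two samples to differentiate")
    return np.diff(values, axis=0) * fs


def _circumcenter(p: np.ndarray):
    a, b, c = p
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = np.dot(n, n)
    if nn < 1e-16:
        return None, None
    o = a + (np.cross(np.dot(ab, ab) * ac - np.dot(ac, ac) * ab,
                      np.cross(ab, ac))) / (2.0 * nn)
    return o, n / np.sqrt(nn)


def _gauss_newton_center(points: np.ndarray, radius: float,
                         init: np.ndarray) -> np.ndarray:
    c = init.astype(float).copy()
    for _ in range(30):
        diff = c - points
        d = np.linalg.norm(diff, axis=1)
        d = np.maximum(d, 1e-12)
        r = d - radius
        J = diff / d[:, None]
        JtJ = J.T @ J
        g = J.T @ r
        try:
            step = np.linalg.solve(JtJ + 1e-12 * np.eye(3), -g)
        except np.linalg.LinAlgError:
            break
        c = c + step
        if np.linalg.norm(step) < 1e-12:
            break
    return c


def _fit_centers_batch(points: np.ndarray, radius: float):
    """Vectorized known-radius sphere fit for many frames at once.

    ``points`` is (n_frames, k, 3) with k >= 4 markers all valid; Gauss-Newton
    from the per-frame centroid, identical to :func:`fit_ball_center`.
    Returns ``(centers, rms)``.
    """
    pts = np.asarray(points, float)
    nf, k, _ = pts.shape
    centroid = pts.mean(axis=1)
    local = pts - centroid[:, None, :]
    c = np.zeros((nf, 3))
    eye = 1e-12 * np.eye(3)
    for _ in range(30):
        diff = c[:, None, :] - local
        d = np.maximum(np.linalg.norm(diff, axis=2), 1e-12)
        r = d - radius
        J = diff / d[:, :, None]
        JtJ = np.einsum("fki,fkj->fij", J, J) + eye
        g = np.einsum("fki,fk->fi", J, r)
        step = np.linalg.solve(JtJ, -g[..., None])[..., 0]
        c = c + step
        if np.max(np.abs(step)) < 1e-12:
            break
    centers = c + centroid
    d = np.linalg.norm(pts - centers[:, None, :], axis=2)
    rms = np.sqrt(np.mean((d - radius) ** 2, axis=1))
    return centers, rms


def fit_ball_center(points: np.ndarray, radius: float = BALL_RADIUS_M,
                    prev_center: np.ndarray | None = None):
    """Least-squares center of a sphere of known radius through ``points``.

    Minimizes sum((|p_i - c| - r)^2). With exactly three points the two
    mirror solutions are disambiguated by proximity to ``prev_center`` (or a
    deterministic upward choice when none is given). Returns
    ``(center, rms_residual)``. A misfit (markers not on a radius-r sphere)
    is reported through the residual, not raised.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 3:
        raise ValueError("need at least 3 three-dimensional points")
    centroid = points.mean(axis=0)
    local = points - centroid
    prev_local = None if prev_center is None else np.asarray(prev_center) - centroid

    if points.shape[0] == 3:
        o, nhat = _circumcenter(local)
        if o is None:
            if prev_local is None:
                raise ValueError("collinear points and no previous center")
            c = _gauss_newton_center(local, radius, prev_local)
        else:
            h2 = radius**2 - np.dot(local[0] - o, local[0] - o)
            if h2 <= 0:
                # markers wider than the sphere allows: best fit is in-plane
                c = _gauss_newton_center(
                    local, radius, o if prev_local is None else prev_local)
            else:
                h = np.sqrt(h2)
                cands = [o + h * nhat, o - h * nhat]
                if prev_local is not None:
                    c = min(cands, key=lambda x: np.linalg.norm(x - prev_local))
                else:
                    c = max(cands, key=lambda x: (x[2], x[0], x[1]))
    else:
        init = prev_local if prev_local is not None else np.zeros(3)
        c = _gauss_newton_center(local, radius, init)

    d = np.linalg.norm(points - (c + centroid), axis=1)
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    return c + centroid, rms


@dataclass
class ProcessedTrial:
    """Filtered positions, derivatives and the estimated ball center.

    Velocities/accelerations are aligned to the position time base minus the
    differentiation trim (length n-1 / n-2, timestamped at leading samples).
    ``valid`` marks the filled span per marker; ``ball_valid`` marks frames
    where the sphere fit had >= 3 raw-tracked ball markers.
    """

    trial_id: str
    participant_id: str
    times: np.ndarray
    sample_rate: float
    pos: dict[str, np.ndarray]
    vel: dict[str, np.ndarray]
    acc: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    ball_center: np.ndarray
    ball_valid: np.ndarray
    fit_residuals: np.ndarray
    gap_reports: dict[str, tuple[int, int]]
    unfillable: list[str]
    flags: dict = field(default_factory=dict)

    @property
    def vel_times(self) -> np.ndarray:
        return self.times[:-1]

    def speed(self, marker: str) -> np.ndarray:
        return np.linalg.norm(self.vel[marker], axis=1)

    def position_at(self, marker: str, t) -> np.ndarray:
        out = np.empty(3)
        for j in range(3):
            out[j] = np.interp(t, self.times, self.pos[marker][:, j])
        return out


def process_trial(record: TrialRecord, order: int = 5,
                  cutoff_hz: float = 15.0,
                  ball_radius: float = BALL_RADIUS_M) -> ProcessedTrial:
    """Run fill -> filter -> differentiate on all series of one trial and
    estimate the per-frame ball center from the ball-surface markers."""
    fs = record.sample_rate
    n = record.n_frames
    pos, vel, acc, valid, reports = {}, {}, {}, {}, {}
    unfillable = []

    for name, raw in record.positions.items():
        mask = record.valid[name]
        try:
            filled, span, (lead, trail) = fill_gaps_spline(
                raw, mask, record.times)
        except ValueError:
            unfillable.append(name)
            pos[name] = np.full((n, 3), np.nan)
            vel[name] = np.full((n - 1, 3), np.nan)
            acc[name] = np.full((max(n - 2, 0), 3), np.nan)
            valid[name] = np.zeros(n, bool)
            reports[name] = (n, 0)
            continue
        lo = lead
        hi = n - trail
        smooth = np.full((n, 3), np.nan)
        try:
            smooth[lo:hi] = lowpass_zero_lag(filled[lo:hi], fs, order, cutoff_hz)
        except ValueError:
            unfillable.append(name)
            valid[name] = np.zeros(n, bool)
            pos[name] = smooth
            vel[name] = np.full((n - 1, 3), np.nan)
            acc[name] = np.full((max(n - 2, 0), 3), np.nan)
            reports[name] = (lead, trail)
            continue
        pos[name] = smooth
        vel[name] = differentiate(smooth, fs)
        acc[name] = differentiate(vel[name], fs)
        valid[name] = span
        reports[name] = (lead, trail)

    # ball markers: fill+filter for smoothness, but only frames with raw
    # tracking count as available for the sphere fit
    ball_smooth, ball_avail = {}, {}
    for name in BALL_MARKERS:
        if name not in record.ball_positions:
            continue
        raw = record.ball_positions[name]
        mask = record.ball_valid[name]
        try:
            filled, span, (lead, trail) = fill_gaps_spline(
                raw, mask, record.times)
            lo, hi = lead, n - trail
            smooth = np.full((n, 3), np.nan)
            smooth[lo:hi] = lowpass_zero_lag(filled[lo:hi], fs, order, cutoff_hz)
        except ValueError:
            continue
        ball_smooth[name] = smooth
        ball_avail[name] = mask & span

    ball_center = np.full((n, 3), np.nan)
    ball_valid = np.zeros(n, bool)
    residuals = np.full(n, np.nan)
    names = list(ball_smooth)
    if names:
        avail = np.column_stack([ball_avail[m] for m in names])
        stacks = np.stack([ball_smooth[m] for m in names], axis=1)
        full = avail.all(axis=1)
        if full.any():
            centers, rms = _fit_centers_batch(stacks[full], ball_radius)
            ball_center[full] = centers
            residuals[full] = rms
            ball_valid[full] = True
        # frames with partial marker visibility: sequential fit, warm-started
        # from the nearest already-solved frame (disambiguates 3-point fits)
        for i in np.flatnonzero(~full):
            sel = avail[i]
            if sel.sum() < 3:
                continue
            prev = None
            if i > 0 and ball_valid[i - 1]:
                prev = ball_center[i - 1]
            elif i + 1 < n and ball_valid[i + 1]:
                prev = ball_center[i + 1]
            try:
                c, rms = fit_ball_center(stacks[i][sel], ball_radius, prev)
            except ValueError:
                continue
            ball_center[i] = c
            residuals[i] = rms
            ball_valid[i] = True

    return ProcessedTrial(
        trial_id=record.trial_id,
        participant_id=record.participant_id,
        times=record.times,
        sample_rate=fs,
        pos=pos,
        vel=vel,
        acc=acc,
        valid=valid,
        ball_center=ball_center,
        ball_valid=ball_valid,
        fit_residuals=residuals,
        gap_reports=reports,
        unfillable=unfillable,
        flags=dict(record.flags),
    )
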