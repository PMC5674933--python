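"""Release-aligned resampling, predictor spaces, and spatiotemporal PCA.

Every trial of a participant is represented on a common window of length W
(the participant's mean throwing duration) ending at ball release, resampled
to 100 time points. A predictor space selects a set of joint markers (a
single marker or a body segment) and a time interval (one decile of 10
samples, or "through" = everything from onset to the end of a decile). The
stacked feature vector per trial is

    q = [S_j(t_i), v_j(t_i)]  for all selected markers j and samples t_i,

of dimension N_F = 3 coords x 2 kinds x N_J x N_T. Spatiotemporal PCA
(PCA on these stacked vectors, so temporal structure lives inside the
components) compresses q to the leading components reaching a target
variance-accounted-for (VAF), 98% by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .preprocess import ProcessedTrial
from .trialdata import CANONICAL_MARKERS, SEGMENTS, segment_markers

N_RESAMPLE = 100
KINDS = ("pos", "vel")
COORDS = ("x", "y", "z")


def mean_throw_duration(durations_or_events) -> float:
    """Mean onset-to-release duration over a participant's good trials."""
    vals = []
    for item in durations_or_events:
        if hasattr(item, "t_release"):
            vals.append(item.t_release - item.t_onset)
        else:
            vals.append(float(item))
    if not vals:
        raise ValueError("no trials with valid onset and release")
    return float(np.mean(vals))


@dataclass
class AlignedTrial:
    """One trial resampled on ``n`` points ending at ball release.

    ``data`` has shape (18, 6, n): canonical markers x channels x time, with
    channels ordered [pos_x, pos_y, pos_z, vel_x, vel_y, vel_z].
    """

    trial_id: str
    data: np.ndarray
    window_s: float
    t_release: float

    def __post_init__(self):
        if self.data.shape[:2] != (len(CANONICAL_MARKERS), 6):
            raise ValueError("aligned data must be (18, 6, n)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def align_and_resample(processed: ProcessedTrial, t_release: float,
                       window_s: float, n: int = N_RESAMPLE) -> AlignedTrial:
    """Cubic resampling of positions and velocities on the release-anchored
    window [t_release - W, t_release].

    Velocities are resampled from the differentiated series, not
    re-differentiated. The window may include pre-onset quiescence; it must
    not extend before the recording (or a marker's valid span).
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    grid = np.linspace(t_release - window_s, t_release, n)
    if grid[0] < processed.times[0] - 1e-9:
        raise ValueError("window extends before the start of the recording")
    data = np.empty((len(CANONICAL_MARKERS), 6, n))
    tv = processed.vel_times
    for mi, marker in enumerate(CANONICAL_MARKERS):
        span = processed.valid[marker]
        if not span.any():
            raise ValueError(f"marker {marker!r} has no valid span")
        idx = np.flatnonzero(span)
        lo, hi = idx[0], idx[-1]
        t_span = processed.times[lo:hi + 1]
        if grid[0] < t_span[0] - 1e-9 or grid[-1] > t_span[-1] + 1e-9:
            raise ValueError(
                f"marker {marker!r} valid span does not cover the window")
        pos_spline = CubicSpline(t_span, processed.pos[marker][lo:hi + 1])
        data[mi, :3] = pos_spline(grid).T
        vt = tv[lo:hi]
        if grid[-1] > vt[-1] + 1e-9:
            raise ValueError(
                f"marker {marker!r} velocity span does not cover the window")
        vel_spline = CubicSpline(vt, processed.vel[marker][lo:hi])
        data[mi, 3:] = vel_spline(grid).T
    return AlignedTrial(processed.trial_id, data, window_s, t_release)


@dataclass(frozen=True)
class PredictorSpec:
    """A spatial unit (single marker or body segment) x a time interval."""

    scope: str                  # marker or segment name
    markers: tuple[str, ...]
    mode: str                   # "decile" | "through"
    decile: int

    def __post_init__(self):
        if self.mode not in ("decile", "through"):
            raise ValueError("mode must be 'decile' or 'through'")
        if not 1 <= self.decile <= 10:
            raise ValueError("decile must be in [1, 10]")
        unknown = [m for m in self.markers if m not in CANONICAL_MARKERS]
        if unknown:
            raise ValueError(f"unknown markers in spec: {unknown}")

    @classmethod
    def for_marker(cls, marker: str, mode: str, decile: int) -> "PredictorSpec":
        return cls(marker, (marker,), mode, decile)

    @classmethod
    def for_segment(cls, segment: str, mode: str, decile: int) -> "PredictorSpec":
        return cls(segment, segment_markers(segment), mode, decile)

    def time_slice(self, n: int = N_RESAMPLE) -> slice:
        per = n // 10
        if self.mode == "decile":
            return slice(per * (self.decile - 1), per * self.decile)
        return slice(0, per * self.decile)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class FeatureMatrix:
    """Stacked spatiotemporal features, one column per trial.

    Rows are ordered marker-major, then kinematic kind (position before
    velocity), then coordinate (x, y, z), then time sample.
    """

    X: np.ndarray               # (N_F, N_Trials)
    rows: list[tuple[str, str, str, int]]
    n_j: int
    n_t: int

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_trials(self) -> int:
        return self.X.shape[1]


def build_features(aligned: list[AlignedTrial],
                   spec: PredictorSpec) -> FeatureMatrix:
    """Assemble the N_F x N_Trials matrix for one predictor space."""
    if not aligned:
        raise ValueError("no aligned trials")
    n = aligned[0].n_samples
    if any(tr.n_samples != n for tr in aligned):
        raise ValueError("all trials must share the resampling length")
    tsl = spec.time_slice(n)
    midx = [CANONICAL_MARKERS.index(m) for m in spec.markers]
    stack = np.stack([tr.data for tr in aligned])        # (K, 18, 6, n)
    sub = stack[:, midx, :, tsl]                         # (K, N_J, 6, N_T)
    n_t = sub.shape[3]
    X = sub.transpose(1, 2, 3, 0).reshape(-1, len(aligned))
    rows = [
        (m, kind, coord, t)
        for m in spec.markers
        for kind in KINDS
        for coord in COORDS
        for t in range(tsl.start, tsl.stop)
    ]
    assert X.shape[0] == 6 * spec.n_markers * n_t == len(rows)
    return FeatureMatrix(X=X, rows=rows, n_j=spec.n_markers, n_t=n_t)


class SpatiotemporalPCA(BaseEstimator, TransformerMixin):
    """PCA on stacked spatiotemporal feature vectors with VAF truncation.

    Follows scikit-learn conventions: ``fit`` takes (n_trials, n_features)
    and exposes ``mean_``, orthonormal ``components_`` (the retained
    spatiotemporal components), the full ``explained_variance_ratio_`` (VAF
    spectrum over all components) and ``n_components_``, the smallest count
    whose cumulative VAF reaches ``vaf``. Component signs are fixed so each
    component's largest-magnitude loading is positive. Features are centered
    but not rescaled (positions and velocities enter in their native units);
    set ``zscore=True`` to standardize for sensitivity analyses.
    """

    def __init__(self, vaf: float = 0.98, zscore: bool = False):
        self.vaf = vaf
        self.zscore = zscore

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 trials for stPCA")
        self.scale_ = None
        if self.zscore:
            sd = X.std(axis=0, ddof=1)
            self.scale_ = np.where(sd > 0, sd, 1.0)
            X = X / self.scale_
        total_var = np.var(X, axis=0, ddof=1).sum()
        if total_var <= 0:
            raise ValueError("zero total variance")
        pca = PCA(svd_solver="full")
        scores = pca.fit_transform(X)
        self.mean_ = pca.mean_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        cum = np.cumsum(self.explained_variance_ratio_)
        self.n_components_ = int(np.searchsorted(cum, self.vaf - 1e-12) + 1)
        self.n_components_ = min(self.n_components_, len(cum))
        comps = pca.components_[: self.n_components_].copy()
        sc = scores[:, : self.n_components_].copy()
        flip = np.sign(comps[np.arange(len(comps)),
                             np.abs(comps).argmax(axis=1)])
        flip[flip == 0] = 1.0
        comps *= flip[:, None]
        sc *= flip[None, :]
        self.components_ = comps
        self.scores_ = sc
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        if self.scale_ is not None:
            X = X / self.scale_
        return (X - self.mean_) @ self.components_.T

    @property
    def cumulative_vaf_(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio_)


def fit_stpca(X: np.ndarray, vaf_threshold: float = 0.98) -> SpatiotemporalPCA:
    """Fit stPCA on an (N_F, N_Trials) feature matrix (trials as columns)."""
    return SpatiotemporalPCA(vaf=vaf_threshold).fit(np.asarray(X).T)


def project(model: SpatiotemporalPCA, X: np.ndarray) -> np.ndarray:
    """Scores (N_PC, N_Trials) of feature columns under a fitted model."""
    return model.transform(np.asarray(X).T).T
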