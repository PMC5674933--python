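"""Alignment/resampling, predictor spaces and spatiotemporal PCA."""

import numpy as np
import pytest

from throwcast.events import KeyEvents
from throwcast.features import (
    N_RESAMPLE,
    AlignedTrial,
    PredictorSpec,
    SpatiotemporalPCA,
    align_and_resample,
    build_features,
    fit_stpca,
    mean_throw_duration,
    project,
)
from throwcast.preprocess import ProcessedTrial
from throwcast.trialdata import CANONICAL_MARKERS

FS = 120.0


class TestMeanThrowDuration:
    def test_mean_of_durations(self):
        assert mean_throw_duration([1.0, 1.2]) == pytest.approx(1.1)

    def test_single_trial(self):
        assert mean_throw_duration([0.9]) == pytest.approx(0.9)

    def test_accepts_event_objects(self):
        ev = KeyEvents(1.0, 2.2, 2.7, (0.1, 1.4), 10.0)
        assert mean_throw_duration([ev, 1.0]) == pytest.approx(1.1)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_throw_duration([])

    def test_simulated_window_in_configured_support(self, participant,
                                                    sim_cfg):
        lo, hi = sim_cfg.duration_range_s
        assert lo <= participant.window_s <= hi


def _linear_processed(n=400, slope=None):
    """All markers move on exact straight lines (constant velocity)."""
    times = np.arange(n) / FS
    rng = np.random.default_rng(8)
    pos, vel, valid = {}, {}, {}
    slopes = {}
    for m in CANONICAL_MARKERS:
        s = slope if slope is not None else rng.normal(0, 1.0, 3)
        p0 = rng.normal(0, 1.0, 3)
        pos[m] = p0 + np.outer(times, s)
        vel[m] = np.tile(s, (n - 1, 1))
        valid[m] = np.ones(n, bool)
        slopes[m] = (p0, s)
    proc = ProcessedTrial(
        trial_id="lin", participant_id="p", times=times, sample_rate=FS,
        pos=pos, vel=vel, acc={}, valid=valid,
        ball_center=np.full((n, 3), np.nan),
        ball_valid=np.zeros(n, bool),
        fit_residuals=np.full(n, np.nan), gap_reports={}, unfillable=[])
    return proc, slopes


class TestAlignAndResample:
    def test_exactly_n_samples_for_any_window(self):
        proc, _ = _linear_processed()
        for w in (0.5, 1.1, 2.0):
            tr = align_and_resample(proc, 2.5, w)
            assert tr.n_samples == N_RESAMPLE
        tr = align_and_resample(proc, 2.5, 1.0, n=50)
        assert tr.n_samples == 50

    def test_linear_trajectories_resampled_exactly(self):
        proc, slopes = _linear_processed()
        tr = align_and_resample(proc, 2.5, 1.2)
        grid = np.linspace(2.5 - 1.2, 2.5, N_RESAMPLE)
        for mi, m in enumerate(CANONICAL_MARKERS):
            p0, s = slopes[m]
            expect_pos = p0[:, None] + np.outer(s, grid)
            assert np.allclose(tr.data[mi, :3], expect_pos, atol=1e-9)
            assert np.allclose(tr.data[mi, 3:], s[:, None], atol=1e-9)

    def test_window_before_recording_raises(self):
        proc, _ = _linear_processed()
        with pytest.raises(ValueError, match="before the start"):
            align_and_resample(proc, 0.5, 1.0)

    def test_window_may_cover_quiescence(self):
        proc, _ = _linear_processed()
        tr = align_and_resample(proc, 3.0, 2.9)   # nearly the whole record
        assert tr.n_samples == N_RESAMPLE

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="18, 6"):
            AlignedTrial("t", np.zeros((5, 6, 100)), 1.0, 2.0)


class TestPredictorSpec:
    def test_decile_slice_holds_10_samples(self):
        for d in range(1, 11):
            sl = PredictorSpec.for_marker("r_hand", "decile", d).time_slice()
            assert sl.stop - sl.start == 10
            assert sl.start == 10 * (d - 1)

    def test_through_slice_grows_from_start(self):
        for d in range(1, 11):
            sl = PredictorSpec.for_marker("r_hand", "through", d).time_slice()
            assert sl.start == 0 and sl.stop == 10 * d

    def test_segment_scope_markers(self):
        spec = PredictorSpec.for_segment("trunk", "decile", 3)
        assert set(spec.markers) == {"l_shoulder", "r_shoulder",
                                     "l_hip", "r_hip"}

    def test_validation(self):
        with pytest.raises(ValueError):
            PredictorSpec.for_marker("r_hand", "window", 3)
        with pytest.raises(ValueError):
            PredictorSpec.for_marker("r_hand", "decile", 11)
        with pytest.raises(ValueError):
            PredictorSpec("x", ("nose",), "decile", 1)


class TestBuildFeatures:
    def test_trunk_through_full_window_has_2400_features(self,
                                                         aligned_factory):
        aligned = aligned_factory(4)
        spec = PredictorSpec.for_segment("trunk", "through", 10)
        fm = build_features(aligned, spec)
        assert fm.n_features == 3 * 2 * 4 * 100 == 2400
        assert fm.n_trials == 4

    def test_single_marker_decile_has_60_features(self, aligned_factory):
        aligned = aligned_factory(4)
        fm = build_features(
            aligned, PredictorSpec.for_marker("r_hand", "decile", 5))
        assert fm.n_features == 60
        assert len(fm.rows) == 60

    def test_through_d1_equals_decile_d1(self, aligned_factory):
        aligned = aligned_factory(5)
        a = build_features(aligned,
                           PredictorSpec.for_marker("l_ankle", "through", 1))
        b = build_features(aligned,
                           PredictorSpec.for_marker("l_ankle", "decile", 1))
        np.testing.assert_array_equal(a.X, b.X)

    def test_rows_match_values(self, aligned_factory):
        aligned = aligned_factory(3)
        spec = PredictorSpec.for_marker("r_wrist", "decile", 2)
        fm = build_features(aligned, spec)
        mi = CANONICAL_MARKERS.index("r_wrist")
        for r, (marker, kind, coord, t) in enumerate(fm.rows):
            ch = {"pos": 0, "vel": 3}[kind] + "xyz".index(coord)
            for k, tr in enumerate(aligned):
                assert fm.X[r, k] == tr.data[mi, ch, t]

    def test_mismatched_lengths_raise(self, aligned_factory):
        bad = aligned_factory(2) + aligned_factory(1, n=50)
        with pytest.raises(ValueError, match="resampling length"):
            build_features(bad, PredictorSpec.for_marker("r_hand", "decile", 1))


class TestSpatiotemporalPCA:
    def _rank3_matrix(self, n_trials=40, n_feat=120, seed=0, noise=1e-4):
        rng = np.random.default_rng(seed)
        basis = np.linalg.qr(rng.normal(0, 1, (n_feat, 3)))[0]
        scores = rng.normal(0, [5.0, 3.0, 2.0], (n_trials, 3))
        return scores @ basis.T + noise * rng.normal(0, 1, (n_trials, n_feat))

    def test_rank3_spectrum_keeps_3_components(self):
        X = self._rank3_matrix()
        model = SpatiotemporalPCA(vaf=0.98).fit(X)
        assert model.n_components_ == 3

    def test_reconstruction_residual_within_vaf_budget(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 80)) * rng.gamma(2, 1, 80)
        model = SpatiotemporalPCA(vaf=0.98).fit(X)
        recon = model.mean_ + model.scores_ @ model.components_
        resid_var = np.var(X - recon, axis=0, ddof=1).sum()
        total_var = np.var(X, axis=0, ddof=1).sum()
        assert resid_var / total_var <= 0.02

    def test_vaf_spectrum_monotone_and_complete(self):
        X = self._rank3_matrix(noise=0.1)
        model = SpatiotemporalPCA().fit(X)
        vaf = model.explained_variance_ratio_
        assert np.all(np.diff(vaf) <= 1e-12)
        assert model.cumulative_vaf_[-1] == pytest.approx(1.0)

    def test_transform_reproduces_training_scores(self):
        X = self._rank3_matrix()
        model = SpatiotemporalPCA().fit(X)
        assert np.allclose(model.transform(X), model.scores_, atol=1e-9)

    def test_mean_vector_maps_to_zero_scores(self):
        X = self._rank3_matrix()
        model = SpatiotemporalPCA().fit(X)
        assert np.allclose(model.transform(model.mean_[None, :]), 0.0,
                           atol=1e-9)

    def test_training_score_covariance_diagonal(self):
        X = self._rank3_matrix(noise=0.1)
        model = SpatiotemporalPCA().fit(X)
        cov = np.cov(model.scores_.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() <= 1e-6 * np.diag(cov).max()

    def test_duplicating_trials_preserves_components_and_vaf(self):
        X = self._rank3_matrix(noise=0.05)
        a = SpatiotemporalPCA().fit(X)
        b = SpatiotemporalPCA().fit(np.vstack([X, X]))
        assert np.allclose(a.explained_variance_ratio_[:5],
                           b.explained_variance_ratio_[:5], atol=1e-9)
        k = min(a.n_components_, b.n_components_)
        assert np.allclose(a.components_[:k], b.components_[:k], atol=1e-7)

    def test_sign_convention_largest_loading_positive(self):
        X = self._rank3_matrix()
        model = SpatiotemporalPCA().fit(X)
        for comp in model.components_:
            assert comp[np.abs(comp).argmax()] > 0

    def test_orthonormal_components(self):
        X = self._rank3_matrix(noise=0.1)
        model = SpatiotemporalPCA().fit(X)
        gram = model.components_ @ model.components_.T
        assert np.allclose(gram, np.eye(model.n_components_), atol=1e-9)

    def test_error_cases(self):
        with pytest.raises(ValueError, match="2 trials"):
            SpatiotemporalPCA().fit(np.zeros((1, 10)))
        with pytest.raises(ValueError, match="variance"):
            SpatiotemporalPCA().fit(np.ones((5, 10)))
        model = SpatiotemporalPCA().fit(self._rank3_matrix())
        with pytest.raises(ValueError, match="dimension"):
            model.transform(np.zeros((2, 7)))

    def test_column_wrappers_match_row_api(self):
        X = self._rank3_matrix().T      # (N_F, N_Trials)
        model = fit_stpca(X)
        scores = project(model, X)
        assert scores.shape == (model.n_components_, X.shape[1])
        assert np.allclose(scores, model.scores_.T, atol=1e-9)
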