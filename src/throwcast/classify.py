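"""Two-class LDA with leave-one-out cross-validation and the
misclassification index.

The discriminant is the classical closed form w = S^-1 (mu_1 - mu_0) on the
pooled within-class covariance S (with a small ridge for near-singular
cases) and a threshold from the class means and log-prior ratio. Results are
reported as the misclassification error ME (fraction of LOOCV-misclassified
trials) and, to factor out the intrinsic class-separation quality of a
participant, as the misclassification index

    MI_BK = (ME_BodyKin - ME_Ball) / (1 - ME_Ball),

where ME_Ball is the LOOCV error using the ball's position and velocity at
release as the six predictors (an intrinsically perfect code for the landing
point of a drag-free flight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class ShrinkageLDA(BaseEstimator, ClassifierMixin):
    """Two-class linear discriminant with ridge-regularized pooled covariance.

    Priors are the empirical class proportions. Decision-boundary ties are
    broken deterministically toward ``classes_[1]`` (with Right/Left labels,
    "Right"; labels sort alphabetically).
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y), dtype=float)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError("ShrinkageLDA is strictly two-class")
        masks = [y == c for c in self.classes_]
        counts = np.array([m.sum() for m in masks])
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 trials")
        self.priors_ = counts / counts.sum()
        self.means_ = np.stack([X[m].mean(axis=0) for m in masks])
        d = X.shape[1]
        pooled = np.zeros((d, d))
        for m, mu in zip(masks, self.means_):
            dev = X[m] - mu
            pooled += dev.T @ dev
        pooled /= (counts.sum() - 2)
        self.covariance_ = pooled
        reg = pooled + self.ridge * np.eye(d)
        self.coef_ = np.linalg.solve(reg, self.means_[1] - self.means_[0])
        self.threshold_ = (
            self.coef_ @ (self.means_[0] + self.means_[1]) / 2.0
            - np.log(self.priors_[1] / self.priors_[0])
        )
        self.n_features_in_ = d
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ - self.threshold_

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores >= 0, self.classes_[1], self.classes_[0])


def fit_lda(scores: np.ndarray, labels, ridge: float = 1e-8) -> ShrinkageLDA:
    """Fit LDA on an (n_trials, n_features) score matrix."""
    return ShrinkageLDA(ridge=ridge).fit(scores, labels)


@dataclass(frozen=True)
class ClassificationOutcome:
    me: float                   # misclassification fraction in [0, 1]
    predicted: np.ndarray
    n_used: int

    def __post_init__(self):
        wrong = round(self.me * self.n_used)
        if not np.isclose(self.me, wrong / self.n_used, atol=1e-9):
            raise ValueError("ME must equal misclassified / n_used")

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (1.0 - self.me)


def loocv_me(scores: np.ndarray, labels, ridge: float = 1e-8,
             nested_pca: bool = False, feature_matrix: np.ndarray | None = None,
             vaf: float = 0.98) -> ClassificationOutcome:
    """Leave-one-out misclassification error of LDA.

    Each trial is classified by an LDA refit on the remaining n-1. With
    ``nested_pca=True`` the spatiotemporal PCA is also refit inside every
    fold from ``feature_matrix`` (N_F x N_Trials), the stricter variant that
    guards against the mild optimism of compressing with all trials.
    """
    from .features import SpatiotemporalPCA  # local import to avoid a cycle

    labels = np.asarray(labels)
    if nested_pca:
        if feature_matrix is None:
            raise ValueError("nested_pca requires the raw feature matrix")
        base = np.asarray(feature_matrix, float).T   # (n_trials, N_F)
        n = base.shape[0]
    else:
        scores = check_array(scores, dtype=float)
        n = scores.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 trials")
    if labels.shape[0] != n:
        raise ValueError("labels do not match the trials")

    if nested_pca:
        predicted = np.empty(n, dtype=labels.dtype)
        for k in range(n):
            keep = np.ones(n, bool)
            keep[k] = False
            y_tr = labels[keep]
            if len(np.unique(y_tr)) < 2:
                raise ValueError("a LOOCV fold has a single-class training set")
            pca = SpatiotemporalPCA(vaf=vaf).fit(base[keep])
            model = ShrinkageLDA(ridge=ridge).fit(pca.scores_, y_tr)
            predicted[k] = model.predict(pca.transform(base[k:k + 1]))[0]
    else:
        predicted = _loocv_predict_vectorized(scores, labels, ridge)
    me = float(np.mean(predicted != labels))
    return ClassificationOutcome(me=me, predicted=predicted, n_used=n)


def _loocv_predict_vectorized(X: np.ndarray, labels: np.ndarray,
                              ridge: float) -> np.ndarray:
    """All leave-one-out LDA folds at once.

    Exact leave-one-out downdates of the per-class sums reproduce the
    per-fold refit (same math as :class:`ShrinkageLDA` on each n-1 subset,
    batched over folds).
    """
    classes = unique_labels(labels)
    if len(classes) != 2:
        raise ValueError("LOOCV LDA is strictly two-class")
    n, d = X.shape
    yb = (labels == classes[1]).astype(int)        # 0 -> classes[0]
    counts = np.array([(yb == 0).sum(), (yb == 1).sum()])
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 trials")
    if counts.min() == 2:
        raise ValueError("a LOOCV fold has a class with a single trial")

    sums = np.stack([X[yb == c].sum(axis=0) for c in (0, 1)])
    sqs = np.stack([X[yb == c].T @ X[yb == c] for c in (0, 1)])
    outer = np.einsum("ni,nj->nij", X, X)

    # per-fold class means (held-out trial removed from its own class)
    n_own = counts[yb] - 1
    mu_own = (sums[yb] - X) / n_own[:, None]
    mu_other = sums[1 - yb] / counts[1 - yb][:, None]
    mu0 = np.where((yb == 0)[:, None], mu_own, mu_other)
    mu1 = np.where((yb == 1)[:, None], mu_own, mu_other)

    # per-fold pooled within-class scatter
    scatter_own = (sqs[yb] - outer
                   - n_own[:, None, None] * np.einsum("ni,nj->nij",
                                                      mu_own, mu_own))
    mu_oth_full = sums / counts[:, None]
    scatter_other_all = sqs - counts[:, None, None] * np.einsum(
        "ci,cj->cij", mu_oth_full, mu_oth_full)
    pooled = (scatter_own + scatter_other_all[1 - yb]) / (n - 3)
    pooled = pooled + ridge * np.eye(d)

    w = np.linalg.solve(pooled, (mu1 - mu0)[..., None])[..., 0]
    pri1 = np.where(yb == 1, counts[1] - 1, counts[1]) / (n - 1)
    thr = (np.einsum("ni,ni->n", w, mu0 + mu1) / 2.0
           - np.log(pri1 / (1.0 - pri1)))
    score = np.einsum("ni,ni->n", w, X) - thr
    return np.where(score >= 0, classes[1], classes[0])


def ball_baseline_me(release_states: np.ndarray, labels,
                     ridge: float = 1e-8) -> ClassificationOutcome:
    """LOOCV LDA on the six raw ball release-state predictors (no PCA).

    ``release_states`` is (n_trials, 6): position and velocity of the ball
    at release.
    """
    release_states = check_array(release_states, dtype=float)
    if release_states.shape[1] != 6:
        raise ValueError("expected 6 release-state features "
                         "(3 position + 3 velocity)")
    return loocv_me(release_states, labels, ridge=ridge)


def misclassification_index(me_bodykin: float, me_ball: float) -> float:
    """MI_BK = (ME_BodyKin - ME_Ball) / (1 - ME_Ball).

    Equal to ME_BodyKin when the ball baseline is error-free, and to 0 when
    body kinematics are exactly as informative as the ball at release.
    Reported externally as a percentage (x100).
    """
    for v in (me_bodykin, me_ball):
        if not 0.0 <= v <= 1.0:
            raise ValueError("misclassification errors must be in [0, 1]")
    if me_ball >= 1.0:
        raise ValueError("MI undefined for a ball baseline with ME = 1")
    return (me_bodykin - me_ball) / (1.0 - me_ball)
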