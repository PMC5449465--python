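"""PCA + multiclass-LDA stimulus decoder with winner-take-all thresholding.

The decoder pipeline: center the trial x feature matrix and project it onto
its first ``k`` principal components, fit a multiclass linear discriminant
(shared covariance, shrinkage-regularized) on the scores, and read out a
posterior probability over the four stimulation patterns for each test
trial.  When the largest posterior exceeds a threshold ``p_thr`` the
posterior vector is replaced by a one-hot (winner-take-all); otherwise the
soft posterior is kept.  The decoded force is the posterior-weighted sum of
the four workspace force vectors, so a one-hot posterior snaps the force to
a single field while an uncertain posterior blends them.

Cross-validated decoding is leave-one-out: each trial is predicted by a
model (PCA included) fit on the remaining M - 1 trials.  Because PCA is
label-independent, the per-fold projections can be computed once and reused
across label permutations; :class:`LeaveOneOutCache` exposes exactly that,
which makes the shuffle-based bias correction in :mod:`statebmi.evaluation`
tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .binning import Signal, StateActivityDataset, Variant

__all__ = [
    "N_CLASSES",
    "DecoderModel",
    "fit_decoder",
    "predict_posteriors",
    "apply_wta",
    "decode_force",
    "LeaveOneOutCache",
    "loo_decode",
]

logger = logging.getLogger(__name__)

N_CLASSES = 4

#: singular values below this fraction of the largest are treated as rank 0
_RANK_RTOL = 1e-10


def _make_lda() -> LinearDiscriminantAnalysis:
    # lsqr + Ledoit-Wolf shrinkage keeps the pooled covariance invertible
    # even when trials are few relative to the retained components
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def _ledoit_wolf_cov(z: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf-shrunk covariance of centered data (direct evaluation)."""
    n, p = z.shape
    emp = z.T @ z / n
    x2 = z**2
    trace_terms = x2.sum(axis=0) / n
    mu = trace_terms.sum() / p
    delta_ = float((emp**2).sum())
    beta_ = float((x2.T @ x2).sum())
    beta_ = (beta_ / n - delta_) / (p * n)
    delta = (delta_ - 2.0 * mu * trace_terms.sum() + p * mu**2) / p
    beta = min(beta_, delta)
    shrinkage = 0.0 if beta == 0 else beta / delta
    shrunk = (1.0 - shrinkage) * emp
    shrunk.flat[:: p + 1] += shrinkage * mu
    return shrunk


def _shrunk_class_cov(x: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf-shrunk covariance of one class's scores.

    Matches the reference discriminant implementation: standardize, shrink
    toward the identity with the Ledoit-Wolf coefficient, rescale.
    """
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    cov = _ledoit_wolf_cov(z)
    return sd[:, None] * cov * sd[None, :]


def _lda_fold_posterior(
    h_train: np.ndarray, y: np.ndarray, h_test: np.ndarray
) -> np.ndarray:
    """Posterior over the 4 stimuli from a pooled-covariance discriminant.

    A direct (loop-free) evaluation of the same model the public decoder
    fits: per-class means, priors from class frequencies, pooled
    shrinkage-regularized covariance, softmax over the linear discriminant
    scores.  Exists so that leave-one-out and shuffle loops do not pay
    estimator-object overhead per fold; equivalence with the estimator path
    is asserted in the test suite.
    """
    n = h_train.shape[0]
    means = np.empty((N_CLASSES, h_train.shape[1]))
    priors = np.empty(N_CLASSES)
    cov = np.zeros((h_train.shape[1], h_train.shape[1]))
    for c in range(N_CLASSES):
        xc = h_train[y == c + 1]
        means[c] = xc.mean(axis=0)
        priors[c] = xc.shape[0] / n
        cov += priors[c] * _shrunk_class_cov(xc)
    coef = np.linalg.solve(cov, means.T).T
    intercept = -0.5 * np.einsum("ij,ij->i", means, coef) + np.log(priors)
    scores = h_test @ coef.T + intercept
    scores -= scores.max()
    p = np.exp(scores)
    return p / p.sum()


def _effective_rank(s: np.ndarray) -> int:
    if s.size == 0 or s[0] <= 0:
        return 0
    return int(np.sum(s > _RANK_RTOL * s[0]))


@dataclass
class DecoderModel:
    """A fitted stimulus decoder.

    ``pca_center`` and ``pca_loadings`` (k x F, orthonormal rows) define the
    dimensionality reduction; ``lda`` holds the discriminant fitted on the
    scores; ``p_thr`` is the winner-take-all threshold.  ``variant`` and
    ``signal`` tag which feature construction the model expects.
    """

    pca_center: np.ndarray
    pca_loadings: np.ndarray
    k: int
    lda: LinearDiscriminantAnalysis
    p_thr: float
    variant: Variant | None = None
    signal: Signal | None = None

    @property
    def n_features(self) -> int:
        return self.pca_center.size

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Project feature vectors onto the retained components."""
        features = np.atleast_2d(features)
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {features.shape[1]}"
            )
        return (features - self.pca_center) @ self.pca_loadings.T


def fit_decoder(
    matrix: np.ndarray,
    labels: np.ndarray,
    k: int | None,
    p_thr: float,
    *,
    variant: Variant | str | None = None,
    signal: Signal | str | None = None,
) -> DecoderModel:
    """Fit PCA + LDA on a training activity matrix.

    Parameters
    ----------
    matrix:
        Training trials x features.
    labels:
        Stimulus labels in ``1..4``; every class must be represented.
    k:
        Retained principal components; ``None`` keeps the full numerical
        rank of the centered training matrix.
    p_thr:
        Winner-take-all threshold stored on the model, in ``[0, 1]``.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (trials x features)")
    if matrix.shape[0] != labels.size:
        raise ValueError("matrix rows and labels must align")
    if not 0.0 <= p_thr <= 1.0:
        raise ValueError("p_thr must be in [0, 1]")
    present = np.unique(labels)
    if not np.all(np.isin(np.arange(1, N_CLASSES + 1), present)):
        raise ValueError("every stimulus class 1..4 must appear in training")
    counts = np.bincount(labels, minlength=N_CLASSES + 1)[1:]
    if np.any(counts < 2):
        raise ValueError("need at least 2 training trials per class")

    pca = PCA(n_components=None, svd_solver="full").fit(matrix)
    rank = _effective_rank(pca.singular_values_)
    if k is None:
        k = max(rank, 1)
    if not 1 <= k <= max(rank, 1):
        raise ValueError(f"k must be in 1..rank ({rank}), got {k}")
    loadings = pca.components_[:k]
    scores = (matrix - pca.mean_) @ loadings.T

    lda = _make_lda().fit(scores, labels)
    return DecoderModel(
        pca_center=pca.mean_,
        pca_loadings=loadings,
        k=k,
        lda=lda,
        p_thr=p_thr,
        variant=Variant(variant) if variant is not None else None,
        signal=Signal(signal) if signal is not None else None,
    )


def predict_posteriors(model: DecoderModel, features: np.ndarray) -> np.ndarray:
    """Raw posterior P(s_d | a) over the four stimuli for each trial.

    Accepts a single feature vector or a (trials x features) matrix; returns
    a ``(4,)`` vector or ``(trials, 4)`` matrix whose rows sum to one.
    """
    single = np.asarray(features).ndim == 1
    scores = model.transform(features)
    proba = model.lda.predict_proba(scores)
    out = np.zeros((scores.shape[0], N_CLASSES))
    out[:, np.asarray(model.lda.classes_, dtype=int) - 1] = proba
    return out[0] if single else out


def apply_wta(posteriors: np.ndarray, p_thr: float) -> np.ndarray:
    """Winner-take-all thresholding of posterior vectors.

    Rows whose maximum exceeds ``p_thr`` become one-hot at the argmax (ties
    broken toward the lowest stimulus index); other rows pass unchanged.
    """
    p = np.atleast_2d(np.asarray(posteriors, dtype=float))
    out = p.copy()
    winners = p.argmax(axis=1)  # first occurrence = lowest index on ties
    take = p.max(axis=1) > p_thr
    out[take] = 0.0
    out[take, winners[take]] = 1.0
    return out[0] if np.asarray(posteriors).ndim == 1 else out


def decode_force(p_tilde: np.ndarray, forces: np.ndarray) -> np.ndarray:
    """Posterior-weighted sum of the four force vectors.

    ``forces`` is (4, 2); the result lies in their convex hull because the
    weights are a probability vector.
    """
    p_tilde = np.asarray(p_tilde, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if forces.shape != (N_CLASSES, 2):
        raise ValueError("forces must have shape (4, 2)")
    return p_tilde @ forces


class LeaveOneOutCache:
    """Per-fold PCA projections for repeated leave-one-out decoding.

    Fitting PCA inside every fold avoids train/test leakage, but the
    projections depend only on the features -- not the labels -- so they are
    computed once here and reused for every labeling (the true one and each
    shuffle of the bias correction).
    """

    def __init__(self, matrix: np.ndarray, k: int | None):
        matrix = np.asarray(matrix, dtype=float)
        m = matrix.shape[0]
        if m < 12:
            raise ValueError("leave-one-out decoding needs at least 12 trials")
        self.n_trials = m
        self.folds: list[tuple[np.ndarray, np.ndarray]] = []
        for i in range(m):
            train = np.delete(matrix, i, axis=0)
            pca = PCA(n_components=None, svd_solver="full").fit(train)
            rank = _effective_rank(pca.singular_values_)
            kf = max(rank, 1) if k is None else min(k, max(rank, 1))
            loadings = pca.components_[:kf]
            h_train = (train - pca.mean_) @ loadings.T
            h_test = (matrix[i] - pca.mean_) @ loadings.T
            self.folds.append((h_train, h_test))

    def decode(self, labels: np.ndarray, p_thr: float) -> np.ndarray:
        """Thresholded posterior matrix P-tilde (M x 4) for a labeling."""
        labels = np.asarray(labels, dtype=int)
        if labels.size != self.n_trials:
            raise ValueError("labels length must match the cached trials")
        raw = np.empty((self.n_trials, N_CLASSES))
        for i, (h_train, h_test) in enumerate(self.folds):
            y = np.delete(labels, i)
            classes = np.unique(y)
            if classes.size < N_CLASSES:
                # degenerate fold: fall back to the training priors
                logger.warning(
                    "fold %d is missing a class; returning training priors", i
                )
                raw[i] = np.bincount(y, minlength=N_CLASSES + 1)[1:] / y.size
                continue
            raw[i] = _lda_fold_posterior(h_train, y, h_test)
        return apply_wta(raw, p_thr)


def loo_decode(
    dataset: StateActivityDataset,
    k: int | None,
    p_thr: float,
    *,
    cache: LeaveOneOutCache | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out decoding of a whole dataset.

    Each trial is predicted by a PCA + LDA model fit on the other M - 1
    trials, then thresholded.  Returns ``(p_tilde, predicted_labels)`` where
    ``p_tilde`` is (M x 4) and predictions are ``argmax + 1``.
    """
    if cache is None:
        cache = LeaveOneOutCache(dataset.matrix, k)
    p_tilde = cache.decode(dataset.labels, p_thr)
    predicted = p_tilde.argmax(axis=1) + 1
    return p_tilde, predicted
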