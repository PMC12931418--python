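"""Baseline outlier detectors and cross-validation runners.

Three comparison methods: reconstruction by PCA projection alone (rank chosen
by the optimal hard threshold), per-protein Z-scores of the preprocessed
intensities with Gaussian tail probabilities, and per-protein isolation-forest
anomaly scores (on raw intensities or on autoencoder residuals).  The
cross-validation runners score each sample with a model whose training set
excluded it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import IsolationForest

from .autoencoder import ConditionalAutoencoder
from .dimension import grid_search_dimension, oht_rank
from .preprocessing import impute_for_input
from .stats import (
    ResidualSet,
    adjust_tail_probs_samplewise,
    compute_residuals,
    fit_t_two_pass,
    gaussian_tail_probs,
    t_tail_probs,
)

__all__ = [
    "BaselineResult",
    "pca_oht_fit",
    "zscore_outliers",
    "isolation_scores",
    "per_protein_isolation",
    "cross_validate",
    "PCAOutlierDetector",
    "ZScoreOutlierDetector",
]


@dataclass
class BaselineResult:
    method: str
    scores: np.ndarray  # NaN on missing cells
    tail_probs: np.ndarray | None = None
    adjusted: np.ndarray | None = None


def pca_oht_fit(X: np.ndarray, M: np.ndarray, q: int | None = None) -> np.ndarray:
    """Rank-q PCA reconstruction of the imputed, protein-centered matrix.

    The rank defaults to the optimal hard threshold.  Algebraically identical
    to the SVD-initialized linear autoencoder before any training.
    """
    Ximp = impute_for_input(X, M)
    if q is None:
        q = oht_rank(Ximp)
    mu = Ximp.mean(axis=0)
    Xc = Ximp - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:q].T
    return (Xc @ V) @ V.T + mu


def zscore_outliers(X: np.ndarray, M: np.ndarray, method: str = "by") -> BaselineResult:
    """Protein-wise Z-scores of the preprocessed intensities, Gaussian tails.

    Equivalent to scoring residuals of the trivial model x_hat = protein mean;
    no latent structure or covariates are used.
    """
    Xobs = np.where(M > 0, X, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_j = np.nanmean(Xobs, axis=0)
        sd_j = np.nanstd(Xobs, axis=0, ddof=1)
    res = ResidualSet(e=Xobs - mean_j, mean_j=np.zeros_like(mean_j), sd_j=sd_j)
    P = gaussian_tail_probs(res)
    adjusted = adjust_tail_probs_samplewise(P, M, method=method)
    return BaselineResult(method="zscore", scores=P, tail_probs=P, adjusted=adjusted)


def isolation_scores(values: np.ndarray, seed=0, n_estimators: int = 100) -> np.ndarray:
    """Isolation-forest anomaly scores for one protein's values (higher = more isolated)."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    if np.ptp(values) == 0:
        warnings.warn("constant vector: all isolation scores equal", UserWarning)
        return np.zeros(len(values))
    forest = IsolationForest(
        n_estimators=n_estimators, max_samples=len(values), random_state=seed
    ).fit(values)
    return -forest.score_samples(values)


def per_protein_isolation(
    values_matrix: np.ndarray, M: np.ndarray, mode: str = "raw", seed: int = 0
) -> BaselineResult:
    """Run an isolation forest independently on every protein.

    ``values_matrix`` holds raw preprocessed intensities (mode='raw') or
    autoencoder residuals (mode='residual'); scores replace tail probabilities
    for ranking, so no adjustment is produced.
    """
    if mode not in ("raw", "residual"):
        raise ValueError("mode must be 'raw' or 'residual'")
    scores = np.full(values_matrix.shape, np.nan)
    for j in range(values_matrix.shape[1]):
        sel = M[:, j] > 0
        if sel.sum() < 10:
            warnings.warn(f"protein column {j} has < 10 observed values; skipped", UserWarning)
            continue
        scores[sel, j] = isolation_scores(values_matrix[sel, j], seed=seed + j)
    return BaselineResult(method=f"isolation_{mode}", scores=scores)


class PCAOutlierDetector(BaseEstimator):
    """PCA-reconstruction detector with OHT rank and t-distributed tails."""

    def __init__(self, q: int | None = None, distribution: str = "t",
                 adjustment: str = "by", cutoff: float = 0.1):
        self.q = q
        self.distribution = distribution
        self.adjustment = adjustment
        self.cutoff = cutoff

    def fit(self, X, mask=None):
        X = np.asarray(X, dtype=float)
        M = (~np.isnan(X)).astype(float) if mask is None else np.asarray(mask, dtype=float)
        self.X_hat_ = pca_oht_fit(X, M, q=self.q)
        self.q_ = self.q if self.q is not None else oht_rank(impute_for_input(X, M))
        res = compute_residuals(np.where(M > 0, X, np.nan), self.X_hat_, M)
        self.residuals_ = res
        if self.distribution == "t":
            self.tdist_ = fit_t_two_pass(res)
            self.tail_probs_ = t_tail_probs(res, self.tdist_)
        else:
            self.tail_probs_ = gaussian_tail_probs(res)
        self.adjusted_ = adjust_tail_probs_samplewise(self.tail_probs_, M, self.adjustment)
        return self


class ZScoreOutlierDetector(BaseEstimator):
    """Per-protein Z-score detector (no confounder correction)."""

    def __init__(self, adjustment: str = "by", cutoff: float = 0.1):
        self.adjustment = adjustment
        self.cutoff = cutoff

    def fit(self, X, mask=None):
        X = np.asarray(X, dtype=float)
        M = (~np.isnan(X)).astype(float) if mask is None else np.asarray(mask, dtype=float)
        result = zscore_outliers(X, M, method=self.adjustment)
        self.tail_probs_ = result.tail_probs
        self.adjusted_ = result.adjusted
        return self


def cross_validate(
    X: np.ndarray,
    M: np.ndarray,
    C: np.ndarray | None = None,
    scheme: str = "loo",
    dim_method: str = "oht",
    fixed_q: int | None = None,
    seed: int = 0,
    **model_config,
):
    """Held-out tail probabilities via leave-one-out or 5-fold cross-validation.

    Per fold the encoding dimension is selected on training samples only, the
    autoencoder is trained with early stopping on a 20% validation split, the
    Student's-t model is fitted on training residuals, and the held-out
    samples are scored with those training-derived parameters.

    Returns (tail_prob_matrix, fold_assignment).
    """
    n = X.shape[0]
    if n < 10:
        raise ValueError("cross-validation needs at least 10 samples")
    rng = np.random.default_rng(seed)
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "kfold5":
        perm = rng.permutation(n)
        folds = [perm[k::5] for k in range(5)]
    else:
        raise ValueError("scheme must be 'loo' or 'kfold5'")

    P = np.full(X.shape, np.nan)
    fold_of = np.empty(n, dtype=int)
    for k, test_idx in enumerate(folds):
        fold_of[test_idx] = k
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr, Mtr = X[train_idx], M[train_idx]
        Ctr = None if C is None else C[train_idx]
        if fixed_q is not None:
            q = fixed_q
        elif dim_method == "oht":
            q = oht_rank(impute_for_input(np.where(Mtr > 0, Xtr, np.nan), Mtr))
        else:
            q = grid_search_dimension(Xtr, Mtr, Ctr, model_config, seed=seed).best_q
        q = int(min(q, len(train_idx) - 2, X.shape[1]))
        config = dict(model_config)
        config.update(q=max(q, 1), validation_fraction=0.2, seed=seed)
        model = ConditionalAutoencoder(**config).fit(
            np.where(Mtr > 0, Xtr, np.nan), mask=Mtr, covariates=Ctr
        )
        res_tr = compute_residuals(Xtr, model.X_hat_, Mtr)
        tfit = fit_t_two_pass(res_tr)

        # impute held-out samples with training protein means
        col_means = np.nansum(np.where(Mtr > 0, Xtr, 0.0), axis=0) / np.maximum(
            Mtr.sum(axis=0), 1
        )
        Xte = np.where(M[test_idx] > 0, X[test_idx], col_means[None, :])
        Cte = None if C is None else C[test_idx]
        X_hat_te, _ = model.reconstruct(Xte, mask=M[test_idx], covariates=Cte)
        res_te = compute_residuals(X[test_idx], X_hat_te, M[test_idx])
        P[test_idx] = t_tail_probs(res_te, tfit)
    return P, fold_of
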