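"""Encoding-dimension selection.

Two strategies are provided: the optimal hard threshold (OHT) on singular
values of the protein-centered matrix (analytic, for linear unconditioned
models), and a grid search that injects artificial outliers, refits the model
for each candidate bottleneck width, and keeps the candidate that best
recovers the injected cells by area under the precision-recall curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

__all__ = [
    "GridSearchResult",
    "oht_rank",
    "candidate_grid",
    "auprc",
    "grid_search_dimension",
]


@dataclass
class GridSearchResult:
    candidates: np.ndarray
    auprc_per_candidate: np.ndarray
    best_q: int


def _omega(beta: float) -> float:
    # cubic approximation to the optimal hard threshold coefficient
    # (unknown-noise variant, relative to the median singular value)
    return 0.56 * beta**3 - 0.95 * beta**2 + 1.82 * beta + 1.43


def oht_rank(X: np.ndarray, M: np.ndarray | None = None) -> int:
    """Number of singular values above the optimal hard threshold.

    The matrix is imputed (protein means) if a mask is given, protein-centered,
    and decomposed; singular values exceeding omega(beta) times the median
    singular value are counted, where beta is the matrix aspect ratio.
    Returns at least 1.
    """
    from .preprocessing import impute_for_input

    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("matrix must be at least 2 x 2")
    if M is not None:
        X = impute_for_input(X, M)
    elif np.isnan(X).any():
        X = impute_for_input(X, (~np.isnan(X)).astype(float))
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    beta = min(n, p) / max(n, p)
    thresh = _omega(beta) * np.median(s)
    return max(int((s > thresh).sum()), 1)


def candidate_grid(n_samples: int) -> np.ndarray:
    """Log-spaced candidate bottleneck widths in [4, n_samples // 2].

    At most 25 candidates, or half the sample size if smaller; duplicates
    created by rounding the geometric progression are bumped to the nearest
    unused integer so the count is preserved whenever the range allows.
    """
    half = n_samples // 2
    if half < 4:
        warnings.warn(
            "sample size too small for the standard grid; using a single candidate",
            UserWarning,
        )
        return np.array([min(4, n_samples - 2)])
    k = min(25, half)
    available = half - 4 + 1
    if available < k:
        warnings.warn(
            f"range [4, {half}] holds only {available} integers (< {k}); using all of them",
            UserWarning,
        )
        return np.arange(4, half + 1)
    targets = np.geomspace(4, half, k)
    used: set[int] = set()
    out = []
    for t in targets:
        c = int(round(t))
        if c in used:
            # bump to the nearest unused integer within range (ties upward)
            for delta in range(1, half):
                if c + delta <= half and c + delta not in used:
                    c = c + delta
                    break
                if c - delta >= 4 and c - delta not in used:
                    c = c - delta
                    break
        used.add(c)
        out.append(c)
    return np.array(sorted(out))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision for recovering positives, ranking scores ascending.

    ``scores`` follow the tail-probability convention: smaller means more
    outlying, so positives should sit at the low end.
    """
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("need at least one positive label")
    return float(average_precision_score(labels, -np.asarray(scores, dtype=float)))


def grid_search_dimension(
    X: np.ndarray,
    M: np.ndarray,
    C=None,
    base_config: dict | None = None,
    seed: int = 0,
    candidates: np.ndarray | None = None,
    injection_freq: float = 1e-3,
    injection_log_mean: float = 3.0,
    injection_log_sd: float = 1.6,
) -> GridSearchResult:
    """Select the bottleneck width by recovery of injected artificial outliers.

    For each candidate q the original matrix is corrupted with artificial
    outliers (protein standard deviations taken from the uncorrupted matrix),
    the autoencoder is refit on the corrupted copy, Student's-t tail
    probabilities are computed, and the AUPRC of recovering the injected cells
    is recorded.  The best candidate (ties to the smallest q) is returned;
    the final model must then be refit on the uncorrupted data by the caller.
    """
    from .autoencoder import ConditionalAutoencoder
    from .simulation import inject_outliers
    from .stats import compute_residuals, fit_t_two_pass, t_tail_probs

    base_config = dict(base_config or {})
    n = X.shape[0]
    if candidates is None:
        candidates = candidate_grid(n)
    candidates = np.asarray(
        [q for q in candidates if q <= min(n - 1, X.shape[1])], dtype=int
    )

    injection = inject_outliers(
        X, M, freq=injection_freq, log_mean=injection_log_mean,
        log_sd=injection_log_sd, seed=seed,
    )
    labels_flat = injection.labels[M > 0]
    if labels_flat.sum() < 1:
        # tiny matrices may draw no outliers at 1/1000; force at least a few
        injection = inject_outliers(
            X, M, freq=max(injection_freq, 5.0 / max(M.sum(), 1)),
            log_mean=injection_log_mean, log_sd=injection_log_sd, seed=seed,
        )
        labels_flat = injection.labels[M > 0]

    scores = []
    kept = []
    for q in candidates:
        config = dict(base_config)
        config["q"] = int(q)
        config.setdefault("seed", seed)
        try:
            model = ConditionalAutoencoder(**config).fit(
                np.where(M > 0, injection.X_corrupted, np.nan), mask=M, covariates=C
            )
            res = compute_residuals(injection.X_corrupted, model.X_hat_, M)
            tfit = fit_t_two_pass(res, M)
            P = t_tail_probs(res, tfit)
            score = auprc(P[M > 0], injection.labels[M > 0])
        except (FloatingPointError, np.linalg.LinAlgError) as err:
            warnings.warn(f"candidate q={q} skipped: {err}", UserWarning)
            continue
        kept.append(int(q))
        scores.append(score)
    if not kept:
        raise RuntimeError("every candidate fit failed during grid search")
    scores = np.asarray(scores)
    best_q = kept[int(np.argmax(scores))]  # argmax returns the first (smallest q) max
    return GridSearchResult(
        candidates=np.asarray(kept), auprc_per_candidate=scores, best_q=best_q
    )
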