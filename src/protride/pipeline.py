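"""End-to-end orchestration.

``Protrider`` is the top-level estimator: preprocessed log intensities in,
outlier table out.  ``run`` wires file reading, preprocessing, dimension
selection, model fitting, tail-probability statistics, sample-wise adjustment,
and diagnostics into a single seeded, reproducible pass, and is what the
command-line interface calls.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from .autoencoder import ConditionalAutoencoder, DesignMatrix, encode_covariates
from .baselines import PCAOutlierDetector, ZScoreOutlierDetector, per_protein_isolation
from .dimension import grid_search_dimension, oht_rank
from .preprocessing import PreprocessedData, impute_for_input, preprocess, read_intensity_table
from .stats import (
    adjust_tail_probs_samplewise,
    assemble_results,
    call_outliers,
    compute_residuals,
    fit_t_two_pass,
    gaussian_tail_probs,
    t_tail_probs,
)

__all__ = ["RunConfig", "Diagnostics", "Protrider", "run", "diagnostics_report", "stage_seeds"]

_MODES = ("protrider", "lite", "pca", "zscore", "isolation")


def stage_seeds(seed: int, stages=("injection", "autoencoder", "simulation")) -> dict:
    """Deterministic per-stage child seeds (< 2**31) from one user seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(stages))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(stages, children)
    }


@dataclass
class RunConfig:
    intensities: str | None = None
    annotation: str | None = None
    out_dir: str | None = None
    covariates: list[str] = field(default_factory=list)
    max_missing_frac: float = 0.3
    mode: str = "protrider"
    dim_method: str = "grid"  # 'oht' or 'grid'
    q: int | None = None  # overrides dim_method when set
    distribution: str = "t"  # 't' or 'gaussian'
    adjustment: str = "by"
    cutoff: float = 0.1
    lambda_weight: float = 1.0
    n_layers: int = 1
    epochs: int = 400
    learning_rate: float | None = None
    seed: int = 0
    force: bool = False

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        if self.mode == "lite" and (self.covariates or self.dim_method == "grid"):
            # the lite model sees neither covariates nor the missingness mask
            # and selects its dimension analytically
            self.covariates = []
            self.dim_method = "oht"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class Diagnostics:
    corr_before: np.ndarray
    corr_after: np.ndarray
    tail_prob_hist: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)
    qq: np.ndarray  # columns: theoretical, observed (-log10 scale)
    outliers_per_sample: np.ndarray


class Protrider(BaseEstimator):
    """Aberrant protein abundance detector.

    Fits a (conditional) autoencoder to a sample x protein log-intensity
    matrix, models residuals with a shared-df Student's-t distribution, and
    flags cells whose sample-wise adjusted two-sided tail probability falls
    at or below ``cutoff``.

    Parameters mirror the pipeline configuration; ``mode='lite'`` disables
    covariates and missingness modeling and selects the bottleneck width with
    the optimal hard threshold.

    Attributes after ``fit``: ``q_``, ``autoencoder_``, ``residuals_``,
    ``tdist_`` (t mode), ``tail_probs_``, ``adjusted_``, ``outlier_mask_``,
    ``results_`` (tidy per-cell table).
    """

    def __init__(
        self,
        mode: str = "protrider",
        q: int | None = None,
        dim_method: str = "grid",
        distribution: str = "t",
        adjustment: str = "by",
        cutoff: float = 0.1,
        lambda_weight: float = 1.0,
        n_layers: int = 1,
        epochs: int = 400,
        learning_rate: float | None = None,
        seed: int = 0,
    ):
        self.mode = mode
        self.q = q
        self.dim_method = dim_method
        self.distribution = distribution
        self.adjustment = adjustment
        self.cutoff = cutoff
        self.lambda_weight = lambda_weight
        self.n_layers = n_layers
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    def _model_config(self, use_mask: bool) -> dict:
        return dict(
            n_layers=self.n_layers,
            lambda_weight=self.lambda_weight if use_mask else 0.0,
            use_mask_input=use_mask,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
        )

    def fit(self, X, mask=None, covariates=None, sample_ids=None, protein_ids=None):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        X = np.asarray(X, dtype=float)
        M = (~np.isnan(X)).astype(float) if mask is None else np.asarray(mask, dtype=float)
        Xobs = np.where(M > 0, X, np.nan)
        lite = self.mode == "lite"
        if lite and covariates is not None:
            raise ValueError("lite mode does not accept covariates")
        C = covariates.C if isinstance(covariates, DesignMatrix) else covariates
        seeds = stage_seeds(self.seed)
        use_mask = not lite and self.mode == "protrider"

        dim_method = "oht" if lite else self.dim_method
        if self.q is not None:
            self.q_ = int(self.q)
        elif dim_method == "oht":
            self.q_ = oht_rank(impute_for_input(Xobs, M))
        else:
            config = self._model_config(use_mask)
            config["seed"] = seeds["autoencoder"]
            gs = grid_search_dimension(
                np.where(M > 0, X, 0.0), M, C, config, seed=seeds["injection"]
            )
            self.q_ = gs.best_q
            self.grid_search_ = gs
        self.q_ = int(min(self.q_, X.shape[0] - 1, X.shape[1]))

        if self.mode in ("protrider", "lite"):
            config = self._model_config(use_mask)
            config.update(q=self.q_, seed=seeds["autoencoder"])
            model = ConditionalAutoencoder(**config).fit(Xobs, mask=M, covariates=C)
            self.autoencoder_ = model
            self.X_hat_ = model.X_hat_
        elif self.mode == "pca":
            det = PCAOutlierDetector(q=self.q_, distribution=self.distribution,
                                     adjustment=self.adjustment, cutoff=self.cutoff)
            det.fit(Xobs, mask=M)
            self.X_hat_ = det.X_hat_
        elif self.mode == "zscore":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                self.X_hat_ = np.broadcast_to(
                    np.nanmean(Xobs, axis=0), X.shape
                ).copy()
        else:  # isolation: anomaly scores on raw intensities replace tail probs
            result = per_protein_isolation(Xobs, M, mode="raw", seed=seeds["autoencoder"])
            self.scores_ = result.scores
            self.X_hat_ = np.broadcast_to(np.nanmean(Xobs, axis=0), X.shape).copy()

        res = compute_residuals(Xobs, self.X_hat_, M)
        self.residuals_ = res
        # the Z-score baseline is defined with Gaussian tails
        distribution = "gaussian" if self.mode == "zscore" else self.distribution
        if distribution == "t":
            self.tdist_ = fit_t_two_pass(res)
            self.tail_probs_ = t_tail_probs(res, self.tdist_)
        else:
            self.tail_probs_ = gaussian_tail_probs(res)
        self.adjusted_ = adjust_tail_probs_samplewise(self.tail_probs_, M, self.adjustment)
        self.outlier_mask_ = call_outliers(self.adjusted_, self.cutoff) * (M > 0)
        self.results_ = assemble_results(
            Xobs, self.X_hat_, M, res, self.tail_probs_, self.adjusted_,
            cutoff=self.cutoff, sample_ids=sample_ids, protein_ids=protein_ids,
        )
        self.mask_ = M
        return self

    def fit_predict(self, X, mask=None, covariates=None):
        """Fit and return the binary outlier matrix (1 = outlier)."""
        self.fit(X, mask=mask, covariates=covariates)
        return self.outlier_mask_


def diagnostics_report(
    data: PreprocessedData | None,
    X: np.ndarray,
    residuals: np.ndarray,
    tail_probs: np.ndarray,
    calls: np.ndarray,
) -> Diagnostics:
    """Sample-correlation, calibration, and call-count diagnostics.

    Sample-sample Spearman correlations are computed on protein-centered
    matrices (pairwise over shared observed proteins), before and after the
    model correction; tail probabilities are summarized as histogram counts
    and as QQ pairs of observed vs uniform -log10 quantiles.
    """
    def _corr(mat):
        centered = mat - np.nanmean(mat, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearmanr(centered.T, nan_policy="omit").statistic
        rho = np.atleast_2d(rho)
        np.fill_diagonal(rho, 1.0)
        return rho

    corr_before = _corr(X)
    if np.all(np.nanstd(residuals, axis=0) == 0):
        warnings.warn("residuals have zero variance; correlation undefined", UserWarning)
        corr_after = np.full_like(corr_before, np.nan)
        np.fill_diagonal(corr_after, 1.0)
    else:
        corr_after = _corr(residuals)

    p = tail_probs[~np.isnan(tail_probs)]
    counts, edges = np.histogram(p, bins=20, range=(0.0, 1.0))
    p_sorted = np.sort(p)
    theo = (np.arange(1, len(p_sorted) + 1) - 0.5) / len(p_sorted)
    qq = np.column_stack([-np.log10(theo), -np.log10(p_sorted)])
    per_sample = np.sort(np.nansum(calls, axis=1))[::-1]
    return Diagnostics(
        corr_before=corr_before,
        corr_after=corr_after,
        tail_prob_hist=(counts, edges),
        qq=qq,
        outliers_per_sample=per_sample,
    )


def run(config: RunConfig):
    """Execute the full pipeline from files to an output directory.

    Returns (results table, Diagnostics).  Outputs: ``outliers.tsv``,
    ``run_log.json``, ``diagnostics_*.tsv``, and grid-search diagnostics when
    applicable.  Refuses to overwrite an existing output directory unless
    ``config.force`` is set.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        if out_dir.exists() and any(out_dir.iterdir()) and not config.force:
            raise FileExistsError(f"{out_dir} exists; pass force=True to overwrite")
        out_dir.mkdir(parents=True, exist_ok=True)

    raw = read_intensity_table(config.intensities)
    data = preprocess(raw, max_missing_frac=config.max_missing_frac)
    C = None
    if config.covariates:
        if config.annotation is None:
            raise ValueError("covariates requested but no annotation table given")
        sep = "," if str(config.annotation).endswith(".csv") else "\t"
        annotation = pd.read_csv(config.annotation, sep=sep, index_col=0)
        annotation = annotation.loc[list(data.sample_ids)]
        C = encode_covariates(annotation, config.covariates)

    detector = Protrider(
        mode=config.mode,
        q=config.q,
        dim_method=config.dim_method,
        distribution=config.distribution,
        adjustment=config.adjustment,
        cutoff=config.cutoff,
        lambda_weight=config.lambda_weight,
        n_layers=config.n_layers,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    detector.fit(
        data.X,
        mask=data.M,
        covariates=C if config.mode in ("protrider",) else None,
        sample_ids=data.sample_ids,
        protein_ids=data.protein_ids,
    )
    diag = diagnostics_report(
        data, data.X, detector.residuals_.e, detector.tail_probs_, detector.outlier_mask_
    )

    if out_dir is not None:
        results = detector.results_.copy()
        results.insert(0, "method", config.mode)
        results.to_csv(out_dir / "outliers.tsv", sep="\t", index=False, float_format="%.6g")
        log = {
            "config": dataclasses.asdict(config),
            "n_samples": int(data.n_samples),
            "n_proteins_kept": int(data.n_proteins),
            "selected_q": int(detector.q_),
            "nu0": float(detector.tdist_.nu0) if hasattr(detector, "tdist_") else None,
            "calls_per_sample": {
                str(s): int(c)
                for s, c in zip(data.sample_ids, np.nansum(detector.outlier_mask_, axis=1))
            },
        }
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
        pd.DataFrame(
            diag.corr_before, index=data.sample_ids, columns=data.sample_ids
        ).to_csv(out_dir / "diagnostics_corr_before.tsv", sep="\t")
        pd.DataFrame(
            diag.corr_after, index=data.sample_ids, columns=data.sample_ids
        ).to_csv(out_dir / "diagnostics_corr_after.tsv", sep="\t")
        pd.DataFrame(diag.qq, columns=["theoretical", "observed"]).to_csv(
            out_dir / "diagnostics_qq.tsv", sep="\t", index=False
        )
        if hasattr(detector, "grid_search_"):
            pd.DataFrame(
                {
                    "q": detector.grid_search_.candidates,
                    "auprc": detector.grid_search_.auprc_per_candidate,
                }
            ).to_csv(out_dir / "grid_search.tsv", sep="\t", index=False)
    return detector.results_, diag
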