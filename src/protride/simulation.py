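"""Simulation utilities: outlier injection, negative controls, fixtures.

Three generators live here.  The injector corrupts observed log intensities by
adding a signed multiple of the protein's standard deviation, with amplitudes
drawn from a log-normal distribution (log-mean 3, log-sd 1.6 by default) and a
fair sign coin — the scheme used during grid search over the encoding
dimension.  The negative-control generator resamples residuals from a fitted
Student's-t model, adds them to the autoencoder predictions, and reverses the
preprocessing, producing raw datasets that contain no true outliers so that
every downstream call is a false positive.  Finally, a from-scratch synthetic
dataset generator emulates the structure of TMT-style proteomics: low-rank
covariation, per-batch additive offsets, heavy-tailed residuals, and
missingness that is either completely at random or enriched at low abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import RawIntensityTable

__all__ = [
    "InjectionResult",
    "SyntheticDataset",
    "draw_injection_amplitudes",
    "inject_outliers",
    "simulate_negative_control",
    "empirical_false_positive_proportion",
    "generate_synthetic_dataset",
]


@dataclass
class InjectionResult:
    X_corrupted: np.ndarray
    labels: np.ndarray  # binary, 1 = injected (always a subset of observed cells)
    z_values: dict = field(default_factory=dict)  # (i, j) -> signed z


def draw_injection_amplitudes(
    n: int, log_mean: float = 3.0, log_sd: float = 1.6, rng=None
) -> np.ndarray:
    """Absolute injection amplitudes |z| ~ LogNormal(log_mean, log_sd)."""
    rng = np.random.default_rng(rng)
    return rng.lognormal(mean=log_mean, sigma=log_sd, size=n)


def inject_outliers(
    X: np.ndarray,
    M: np.ndarray,
    freq: float = 1e-3,
    log_mean: float = 3.0,
    log_sd: float = 1.6,
    seed=None,
) -> InjectionResult:
    """Corrupt observed cells with artificial outliers x + z * s_j.

    Each observed cell is independently selected with probability ``freq``;
    the signed amplitude z has |z| log-normal and a fair random sign.  Protein
    standard deviations s_j are computed on the uncorrupted matrix.
    """
    if not 0.0 <= freq <= 0.1:
        raise ValueError("freq must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    M = np.asarray(M)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s_j = np.nanstd(np.where(M > 0, X, np.nan), axis=0, ddof=1)
    zero_sd = ~(s_j > 0)
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} protein(s) with zero sd are never injected", UserWarning
        )

    eligible = (M > 0) & ~zero_sd[None, :]
    pick = eligible & (rng.random(X.shape) < freq)
    idx = np.argwhere(pick)
    amplitudes = draw_injection_amplitudes(len(idx), log_mean, log_sd, rng)
    signs = rng.choice([-1.0, 1.0], size=len(idx))
    z = signs * amplitudes

    X_corrupted = X.copy()
    z_values = {}
    for (i, j), zij in zip(idx, z):
        X_corrupted[i, j] = X[i, j] + zij * s_j[j]
        z_values[(int(i), int(j))] = float(zij)
    return InjectionResult(
        X_corrupted=X_corrupted, labels=pick.astype(int), z_values=z_values
    )


def simulate_negative_control(
    X_hat: np.ndarray,
    tfit,
    size_factors: np.ndarray,
    M: np.ndarray,
    sample_ids=None,
    protein_ids=None,
    log_base: float = 2.0,
    seed=None,
) -> RawIntensityTable:
    """Raw-scale dataset with residuals resampled from the fitted t model.

    Residuals e* ~ t(nu0, mu_j, tau_j) are drawn i.i.d. per cell and added to
    the model predictions; the preprocessing (log transform, size-factor
    scaling) is reversed and the anchor's missingness pattern is copied.  By
    construction the output contains no true outliers.
    """
    if tfit is None or not np.all(np.isfinite(tfit.tau_j)):
        raise ValueError("t-distribution fit with finite parameters required")
    rng = np.random.default_rng(seed)
    n, p = X_hat.shape
    e_star = tfit.mu_j[None, :] + tfit.tau_j[None, :] * rng.standard_t(tfit.nu0, size=(n, p))
    log_matrix = X_hat + e_star
    raw = np.power(log_base, log_matrix) * np.asarray(size_factors)[:, None]
    raw = np.where(M > 0, raw, np.nan).T  # back to protein x sample
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if protein_ids is None:
        protein_ids = [f"P{j}" for j in range(p)]
    return RawIntensityTable(values=raw, protein_ids=protein_ids, sample_ids=sample_ids)


def empirical_false_positive_proportion(calls) -> float:
    """Mean per-sample-run false-positive proportion.

    ``calls`` is an iterable of (n_calls, n_false) pairs, one per sample and
    run; a sample-run with no positive call contributes a proportion of 0.
    """
    props = []
    for n_calls, n_false in calls:
        props.append(0.0 if n_calls == 0 else n_false / n_calls)
    return float(np.mean(props)) if props else 0.0


def negative_control_study(
    n_datasets: int = 20,
    n_samples: int = 50,
    n_proteins: int = 500,
    adjustment: str = "by",
    cutoff: float = 0.1,
    seed: int = 0,
    mode: str = "lite",
    anchor=None,
):
    """Empirical false-positive calibration on model-generated null data.

    An anchor dataset is fitted with the full pipeline; its predictions and
    fitted Student's-t parameters then seed ``n_datasets`` negative-control
    datasets (residuals resampled from the t model, preprocessing reversed).
    Each simulated dataset is refit from scratch — all parameters including
    the shared degrees of freedom are re-estimated — and outliers are called
    at the stated cutoff.  Every call is a false positive by construction.

    Returns a dict with the mean per-sample-run false-positive proportion,
    total calls per run, and the per-sample-run (n_calls, n_false) pairs.
    """
    from .pipeline import Protrider, stage_seeds
    from .preprocessing import preprocess

    rng_seed = stage_seeds(seed)["simulation"]
    rng = np.random.default_rng(rng_seed)

    if anchor is None:
        anchor = generate_synthetic_dataset(
            n_samples=n_samples, n_proteins=n_proteins, seed=int(rng.integers(2**31))
        )
    data = preprocess(anchor.raw)
    base = Protrider(mode=mode, seed=int(rng.integers(2**31)))
    base.fit(data.X, mask=data.M)

    calls = []
    totals_per_run = []
    for _ in range(n_datasets):
        sim_raw = simulate_negative_control(
            base.X_hat_,
            base.tdist_,
            data.size_factors,
            data.M,
            sample_ids=data.sample_ids,
            protein_ids=data.protein_ids,
            seed=int(rng.integers(2**31)),
        )
        sim_data = preprocess(sim_raw)
        det = Protrider(
            mode=mode, adjustment=adjustment, cutoff=cutoff,
            seed=int(rng.integers(2**31)),
        )
        det.fit(sim_data.X, mask=sim_data.M)
        per_sample = np.nansum(det.outlier_mask_, axis=1).astype(int)
        calls.extend((int(c), int(c)) for c in per_sample)
        totals_per_run.append(int(per_sample.sum()))
    return {
        "mean_false_positive_proportion": empirical_false_positive_proportion(calls),
        "total_calls_per_run": totals_per_run,
        "calls": calls,
        "n_datasets": n_datasets,
    }


@dataclass
class SyntheticDataset:
    raw: RawIntensityTable
    annotation: pd.DataFrame
    truth: dict


def generate_synthetic_dataset(
    n_samples: int = 50,
    n_proteins: int = 500,
    latent_dim: int = 6,
    nu: float = 5.0,
    batch_count: int = 5,
    batch_sd: float = 2.0,
    loading_sd: float = 0.4,
    noise_scale: float = 0.3,
    mcar_rate: float = 0.05,
    intensity_dropout: bool = True,
    seed=None,
) -> SyntheticDataset:
    """Generate a raw-scale fixture dataset with known structure.

    Log2 intensities follow protein mean + latent factors x loadings +
    per-batch additive offsets + t(nu)-distributed noise with per-protein
    scales; the matrix is exponentiated and multiplied by per-sample size
    factors to reach the raw intensity scale.  Missingness combines a
    completely-at-random component with (optionally) a logistic dropout that
    preferentially removes low-abundance values, emulating the low-intensity
    dropout of data-dependent acquisition.  All generative parameters are
    recorded in ``truth``.
    """
    if latent_dim >= n_samples / 2:
        raise ValueError("latent_dim must be below half the sample count")
    if batch_count < 1 or not 0 <= mcar_rate < 1:
        raise ValueError("invalid parameter combination")
    rng = np.random.default_rng(seed)

    protein_mean = rng.normal(20.0, 2.0, size=n_proteins)
    loadings = rng.normal(0.0, loading_sd, size=(latent_dim, n_proteins))
    factors = rng.normal(0.0, 1.0, size=(n_samples, latent_dim))
    batch = rng.integers(0, batch_count, size=n_samples)
    batch_offsets = rng.normal(0.0, batch_sd, size=(batch_count, n_proteins))
    sex = rng.choice(["F", "M"], size=n_samples)
    sex_effect = rng.normal(0.0, 0.2, size=n_proteins)
    tau_j = np.exp(rng.normal(np.log(noise_scale), 0.3, size=n_proteins))
    noise = tau_j[None, :] * rng.standard_t(nu, size=(n_samples, n_proteins))

    log_intensity = (
        protein_mean[None, :]
        + factors @ loadings
        + batch_offsets[batch]
        + (sex == "M").astype(float)[:, None] * sex_effect[None, :]
        + noise
    )
    size_factors = rng.lognormal(0.0, 0.2, size=n_samples)
    raw = np.power(2.0, log_intensity) * size_factors[:, None]

    missing = rng.random(raw.shape) < mcar_rate
    if intensity_dropout:
        low = np.quantile(log_intensity, 0.02)
        p_drop = 1.0 / (1.0 + np.exp(log_intensity - low))
        missing |= rng.random(raw.shape) < p_drop
    # keep every protein observable in at least half the samples on average;
    # the preprocessing filter handles the tail
    raw = np.where(missing, np.nan, raw).T  # protein x sample

    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    protein_ids = [f"P{j:04d}" for j in range(n_proteins)]
    annotation = pd.DataFrame(
        {"batch": [f"B{b}" for b in batch], "sex": sex}, index=sample_ids
    )
    truth = {
        "latent_dim": latent_dim,
        "nu": nu,
        "batch_assignment": batch,
        "batch_sd": batch_sd,
        "protein_mean": protein_mean,
        "tau_j": tau_j,
        "size_factors": size_factors,
        "log_intensity": log_intensity,
        "injected_outliers": {},
    }
    return SyntheticDataset(
        raw=RawIntensityTable(values=raw, protein_ids=protein_ids, sample_ids=sample_ids),
        annotation=annotation,
        truth=truth,
    )
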