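"""Intensity-matrix preprocessing.

Raw protein intensities (proteins x samples, positive reals, missing allowed)
are normalized for overall sample intensity with median-of-ratios size factors,
log2-transformed, and filtered for proteins with too many missing values.  The
result is the sample x protein log-intensity matrix ``X`` together with the
binary presence mask ``M`` (1 = observed) that downstream modeling consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawIntensityTable",
    "PreprocessedData",
    "read_intensity_table",
    "compute_size_factors",
    "preprocess",
    "impute_for_input",
]

#: Strings accepted as missing in intensity files, besides empty cells.
_NA_VALUES = ["", "NA", "NaN", "nan"]


@dataclass
class RawIntensityTable:
    """Raw intensity matrix, proteins as rows and samples as columns.

    ``values`` holds positive intensities with ``NaN`` marking missing
    measurements.  Protein and sample identifiers must be unique.
    """

    values: np.ndarray  # (n_proteins, n_samples), NaN = missing
    protein_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n_prot, n_samp = self.values.shape
        if n_prot < 2 or n_samp < 2:
            raise ValueError("need at least 2 proteins and 2 samples")
        if len(set(self.protein_ids)) != n_prot:
            raise ValueError("protein_ids are not unique")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("sample_ids are not unique")
        observed = self.values[~np.isnan(self.values)]
        if np.any(observed <= 0):
            bad = np.argwhere(np.nan_to_num(self.values, nan=1.0) <= 0)
            i, j = bad[0]
            raise ValueError(
                f"non-positive intensity at protein {self.protein_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)


@dataclass
class PreprocessedData:
    """Normalized log2 intensities in sample x protein orientation.

    ``X`` carries NaN where a value was missing; ``M`` is the matching binary
    presence mask.  ``kept_proteins`` indexes into the raw table's protein
    axis for the proteins that survived the missingness filter.
    """

    X: np.ndarray  # (n_samples, n_proteins), NaN where M == 0
    M: np.ndarray  # binary, same shape
    size_factors: np.ndarray  # (n_samples,), positive
    kept_proteins: np.ndarray  # indices into the raw protein axis
    protein_ids: np.ndarray
    sample_ids: np.ndarray
    log_base: float = 2.0
    max_missing_frac: float = field(default=0.3)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.X.shape[1]


def read_intensity_table(path) -> RawIntensityTable:
    """Read a TSV/CSV intensity file (first column protein ID, header = sample IDs)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=True)
    return RawIntensityTable(
        values=df.to_numpy(dtype=float),
        protein_ids=df.index.to_numpy(),
        sample_ids=df.columns.to_numpy(),
    )


def compute_size_factors(raw: RawIntensityTable) -> np.ndarray:
    """Median-of-ratios size factors on the raw intensity scale.

    The per-protein reference is the geometric mean of its intensities across
    samples, computed over proteins observed in every sample; each sample's
    factor is the median ratio of its intensities to the reference.  When no
    protein is fully observed, pairwise-complete geometric means are used
    instead (with a warning).
    """
    V = raw.values
    all_missing = np.all(np.isnan(V), axis=0)
    if np.any(all_missing):
        sid = raw.sample_ids[np.argmax(all_missing)]
        raise ValueError(f"sample {sid!r} has no observed intensities")

    fully_observed = ~np.isnan(V).any(axis=1)
    if fully_observed.any():
        ref_rows = V[fully_observed]
        reference = np.exp(np.mean(np.log(ref_rows), axis=1))
        ratios = ref_rows / reference[:, None]
    else:
        warnings.warn(
            "no protein observed in all samples; size factors computed from "
            "pairwise-complete geometric means",
            UserWarning,
        )
        with np.errstate(invalid="ignore"):
            reference = np.exp(np.nanmean(np.log(V), axis=1))
        ratios = V / reference[:, None]
    factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("size factor computation produced non-positive factors")
    return factors


def preprocess(raw: RawIntensityTable, max_missing_frac: float = 0.3) -> PreprocessedData:
    """Filter, normalize, and log2-transform a raw intensity table.

    Proteins whose missing fraction is strictly greater than
    ``max_missing_frac`` are removed; remaining intensities are divided by the
    sample's size factor and log2-transformed.  Output is sample x protein.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    size_factors = compute_size_factors(raw)

    missing_frac = np.isnan(raw.values).mean(axis=1)
    keep = missing_frac <= max_missing_frac
    if not keep.any():
        raise ValueError("no protein passes the missingness filter")
    kept = np.flatnonzero(keep)

    V = raw.values[kept]  # proteins x samples
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.log2(V / size_factors[None, :]).T  # samples x proteins
    M = (~np.isnan(V.T)).astype(float)
    return PreprocessedData(
        X=X,
        M=M,
        size_factors=size_factors,
        kept_proteins=kept,
        protein_ids=raw.protein_ids[kept],
        sample_ids=raw.sample_ids,
        log_base=2.0,
        max_missing_frac=max_missing_frac,
    )


def impute_for_input(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Replace missing cells by the protein-wise mean of observed values.

    Used only to build the autoencoder's input; imputed cells never enter the
    reconstruction loss.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M)
    if X.shape != M.shape:
        raise ValueError("X and M shapes differ")
    n_obs = M.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmax(n_obs == 0))
        raise ValueError(f"protein at column {j} has no observed values")
    with np.errstate(invalid="ignore"):
        col_means = np.nansum(np.where(M > 0, X, 0.0), axis=0) / n_obs
    out = np.where(M > 0, X, col_means[None, :])
    return out
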