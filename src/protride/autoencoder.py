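"""Conditional autoencoder for log-intensity matrices.

The model reconstructs log2 protein intensities while (optionally) predicting
the probability that each intensity was observed, and can condition on known
sample covariates by concatenating them to the encoder input and to the latent
code.  The training objective is a composite loss

    L = MSE(X, X_hat) + lambda * BCE(M, M_hat)

where the mean squared error runs over observed cells only and the binary
cross-entropy over all cells.  One-layer encoders/decoders are linear and are
initialized from a truncated SVD of the protein-centered input, so that at
epoch 0 the model coincides with a rank-q PCA reconstruction.  Optimization is
full-batch Adam.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

__all__ = [
    "DesignMatrix",
    "ConditionalAutoencoder",
    "encode_covariates",
    "masked_mse",
    "missingness_bce",
    "total_loss",
    "init_from_svd",
    "fit_autoencoder",
]

_CLIP = 1e-7  # sigmoid clipping bound for BCE stability


@dataclass
class DesignMatrix:
    """Encoded sample covariates: one-hot categoricals, standardized numerics."""

    C: np.ndarray  # (n_samples, n_encoded)
    column_names: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.C.shape[1]


def encode_covariates(annotation: pd.DataFrame, covariate_spec: list[str]) -> DesignMatrix:
    """Build a design matrix from a sample annotation table.

    Categorical covariates are expanded to a full one-hot encoding; numeric
    covariates are standardized to zero mean and unit variance.  Columns that
    are constant across samples are dropped with a warning.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariate_spec:
        if cov not in annotation.columns:
            raise ValueError(f"covariate {cov!r} not present in the annotation table")
        series = annotation[cov]
        if series.isna().any():
            sample = annotation.index[series.isna()][0]
            raise ValueError(f"missing value for covariate {cov!r} in sample {sample!r}")
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            vals = series.to_numpy(dtype=float)
            sd = vals.std(ddof=0)
            if sd == 0:
                warnings.warn(f"covariate {cov!r} is constant; dropped", UserWarning)
                continue
            cols.append((vals - vals.mean()) / sd)
            names.append(cov)
        else:
            levels = pd.unique(series.astype(str))
            if len(levels) < 2:
                warnings.warn(f"covariate {cov!r} is constant; dropped", UserWarning)
                continue
            for level in levels:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}={level}")
    C = np.column_stack(cols) if cols else np.zeros((len(annotation), 0))
    return DesignMatrix(C=C, column_names=names)


# ---------------------------------------------------------------------------
# loss components


def masked_mse(X: np.ndarray, X_hat: np.ndarray, M: np.ndarray) -> float:
    """Mean squared reconstruction error over observed cells only."""
    if X.shape != X_hat.shape or X.shape != M.shape:
        raise ValueError("shape mismatch between X, X_hat, M")
    total = M.sum()
    if total == 0:
        raise ValueError("mask has no observed cells")
    diff = np.where(M > 0, X - X_hat, 0.0)
    return float((M * diff**2).sum() / total)


def missingness_bce(M: np.ndarray, M_hat: np.ndarray) -> float:
    """Binary cross-entropy between the presence mask and predicted presence
    probabilities, averaged over all cells (observed and missing)."""
    if M.shape != M_hat.shape:
        raise ValueError("shape mismatch between M and M_hat")
    P = np.clip(M_hat, _CLIP, 1.0 - _CLIP)
    n_cells = M.size
    return float(-(M * np.log(P) + (1.0 - M) * np.log(1.0 - P)).sum() / n_cells)


def total_loss(
    X: np.ndarray,
    X_hat: np.ndarray,
    M: np.ndarray,
    M_hat: np.ndarray | None,
    lambda_weight: float,
) -> float:
    """Composite loss: masked MSE plus lambda times the missingness BCE."""
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be non-negative")
    loss = masked_mse(X, X_hat, M)
    if M_hat is not None and lambda_weight > 0:
        loss += lambda_weight * missingness_bce(M, M_hat)
    return loss


# ---------------------------------------------------------------------------
# parameter containers


def _geometric_widths(d_in: int, d_out: int, n_layers: int) -> list[int]:
    """Hidden widths interpolated geometrically between input and output."""
    widths = np.geomspace(max(d_in, 1), max(d_out, 1), n_layers + 1)
    widths = [int(round(w)) for w in widths]
    widths[0], widths[-1] = d_in, d_out
    return widths


class _MLP:
    """Minimal fully connected stack with ReLU between layers and manual backprop."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray]):
        self.W = weights
        self.b = biases

    @classmethod
    def glorot(cls, widths: list[int], rng: np.random.Generator) -> "_MLP":
        W, b = [], []
        for d0, d1 in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(6.0 / (d0 + d1))
            W.append(rng.uniform(-scale, scale, size=(d0, d1)))
            b.append(np.zeros(d1))
        return cls(W, b)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        cache = [x]
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = np.maximum(h, 0.0)
            cache.append(h)
        return h, cache

    def backward(self, grad_out: np.ndarray, cache: list[np.ndarray]):
        """Return (grad wrt input, [grad W...], [grad b...])."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            if i < last:  # undo ReLU of this layer's output
                g = g * (cache[i + 1] > 0)
            gW[i] = cache[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return g, gW, gb

    def params(self):
        return self.W + self.b

    def grads_from(self, gW, gb):
        return gW + gb


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# SVD initialization (1-layer models)


def init_from_svd(
    X_imputed: np.ndarray,
    M: np.ndarray,
    q: int,
    C: np.ndarray | None = None,
    use_mask_input: bool = False,
) -> dict:
    """Initial weights for the linear (1-layer) model from a truncated SVD.

    The encoder projects protein-centered intensities onto the top-q right
    singular vectors; the decoder is the transpose with protein means as
    output biases.  With covariates, the decoder's covariate block is first
    set by per-protein least squares of the centered intensities on the
    design matrix, and the SVD is taken on the covariate-adjusted matrix, so
    the latent space starts out devoted to hidden (unmodeled) structure.
    Rows attached to mask inputs and the mask head start at zero, except the
    mask-head bias, which is the logit of each protein's observed presence
    rate.
    """
    n, p = X_imputed.shape
    if q > min(n - 1, p):
        raise ValueError(f"q={q} exceeds the usable rank min(n-1, p)={min(n - 1, p)}")
    n_covariates = 0 if C is None else C.shape[1]
    mu = X_imputed.mean(axis=0)
    Xc = X_imputed - mu
    if n_covariates > 0:
        Cc = C - C.mean(axis=0)  # centered so the protein means stay in the bias
        B, *_ = np.linalg.lstsq(Cc, Xc, rcond=None)
        Xc = Xc - Cc @ B
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:q].T  # (p, q)

    d_in = p + (p if use_mask_input else 0) + n_covariates
    W_enc = np.zeros((d_in, q))
    W_enc[:p] = V
    b_enc = -mu @ V  # encoder centers the intensities

    d_lat = q + n_covariates
    W_dec = np.zeros((d_lat, p))
    W_dec[:q] = V.T
    b_dec = mu.copy()
    if n_covariates > 0:
        W_dec[q:] = B
        b_dec = b_dec - C.mean(axis=0) @ B

    params = {
        "enc": _MLP([W_enc], [b_enc]),
        "dec_x": _MLP([W_dec], [b_dec]),
        "dec_m": None,
    }
    if use_mask_input:
        rate = np.clip(M.mean(axis=0), _CLIP, 1 - _CLIP)
        params["dec_m"] = _MLP([np.zeros((d_lat, p))], [logit(rate)])
    return params


# ---------------------------------------------------------------------------
# estimator


class ConditionalAutoencoder(BaseEstimator):
    """Autoencoder correcting known and hidden confounders in log intensities.

    Parameters
    ----------
    q : int
        Bottleneck (latent space) dimension.
    n_layers : int
        Layers per encoder/decoder (1-3); 1 gives a linear model initialized
        from a truncated SVD, deeper stacks use ReLU activations and random
        initialization.
    lambda_weight : float
        Weight of the missingness BCE term in the composite loss.
    use_mask_input : bool
        Feed the presence mask alongside the intensities and predict presence
        probabilities with a dedicated sigmoid head.
    learning_rate : float or None
        Adam step size; defaults to 1e-4 for 1-layer and 5e-4 for deeper models.
    epochs : int
        Number of full-batch epochs.
    validation_fraction : float
        If > 0, hold out this fraction of samples and stop early when the
        validation loss has not improved for ``patience`` epochs.
    seed : int
        Seed for weight initialization and the validation split.

    Attributes
    ----------
    X_hat_ : ndarray of shape (n_samples, n_proteins)
        Predicted log intensities on the training data.
    M_hat_ : ndarray or None
        Predicted presence probabilities (None without mask modeling).
    loss_trace_ : ndarray
        Composite training loss per epoch (index 0 = loss at initialization).
    """

    def __init__(
        self,
        q: int = 10,
        n_layers: int = 1,
        lambda_weight: float = 1.0,
        use_mask_input: bool = True,
        learning_rate: float | None = None,
        epochs: int = 400,
        validation_fraction: float = 0.0,
        patience: int = 10,
        seed: int = 0,
    ):
        self.q = q
        self.n_layers = n_layers
        self.lambda_weight = lambda_weight
        self.use_mask_input = use_mask_input
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.seed = seed

    # -- construction -------------------------------------------------------

    def _effective_lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-4 if self.n_layers == 1 else 5e-4

    def _build(self, X: np.ndarray, M: np.ndarray, C: np.ndarray | None, rng: np.random.Generator):
        n_cov = 0 if C is None else C.shape[1]
        n, p = X.shape
        if not 1 <= self.q <= min(n - 1, p):
            raise ValueError(f"q={self.q} outside [1, min(n-1, p)] for n={n}, p={p}")
        if self.n_layers not in (1, 2, 3):
            raise ValueError("n_layers must be 1, 2 or 3")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be non-negative")
        if self.n_layers == 1:
            return init_from_svd(X, M, self.q, C, self.use_mask_input)
        d_in = p + (p if self.use_mask_input else 0) + n_cov
        d_lat = self.q + n_cov
        enc = _MLP.glorot(_geometric_widths(d_in, self.q, self.n_layers), rng)
        dec_x = _MLP.glorot(_geometric_widths(d_lat, p, self.n_layers), rng)
        dec_m = None
        if self.use_mask_input:
            dec_m = _MLP.glorot(_geometric_widths(d_lat, p, self.n_layers), rng)
        return {"enc": enc, "dec_x": dec_x, "dec_m": dec_m}

    # -- forward / backward --------------------------------------------------

    def _encoder_input(self, Xin, M, C):
        parts = [Xin]
        if self.use_mask_input:
            parts.append(M)
        if C is not None and C.shape[1] > 0:
            parts.append(C)
        return np.concatenate(parts, axis=1)

    def _forward(self, params, Xin, M, C):
        F = self._encoder_input(Xin, M, C)
        Z, enc_cache = params["enc"].forward(F)
        D = Z if C is None or C.shape[1] == 0 else np.concatenate([Z, C], axis=1)
        X_hat, decx_cache = params["dec_x"].forward(D)
        M_hat = None
        decm_cache = None
        logits = None
        if params["dec_m"] is not None:
            logits, decm_cache = params["dec_m"].forward(D)
            M_hat = expit(logits)
        return {
            "X_hat": X_hat,
            "M_hat": M_hat,
            "logits": logits,
            "enc_cache": enc_cache,
            "decx_cache": decx_cache,
            "decm_cache": decm_cache,
        }

    def _loss_and_grads(self, params, Xin, X, M, C):
        fwd = self._forward(params, Xin, M, C)
        X_hat, M_hat = fwd["X_hat"], fwd["M_hat"]
        loss = total_loss(X, X_hat, M, M_hat, self.lambda_weight if M_hat is not None else 0.0)

        n_obs = M.sum()
        gX_hat = 2.0 * M * np.where(M > 0, X_hat - X, 0.0) / n_obs
        gD_x, gW_dx, gb_dx = params["dec_x"].backward(gX_hat, fwd["decx_cache"])
        gD = gD_x
        grads = {"dec_x": (gW_dx, gb_dx)}
        if M_hat is not None and self.lambda_weight > 0:
            glogits = self.lambda_weight * (M_hat - M) / M.size
            gD_m, gW_dm, gb_dm = params["dec_m"].backward(glogits, fwd["decm_cache"])
            gD = gD + gD_m
            grads["dec_m"] = (gW_dm, gb_dm)
        gZ = gD[:, : self.q]  # covariate columns carry no parameters upstream
        _, gW_e, gb_e = params["enc"].backward(gZ, fwd["enc_cache"])
        grads["enc"] = (gW_e, gb_e)
        return loss, grads, fwd

    @staticmethod
    def _flatten(params, grads=None):
        plist, glist = [], []
        for key in ("enc", "dec_x", "dec_m"):
            mlp = params[key]
            if mlp is None:
                continue
            plist += mlp.params()
            if grads is not None:
                gW, gb = grads[key]
                glist += gW + gb
        return (plist, glist) if grads is not None else plist

    # -- fitting -------------------------------------------------------------

    def fit(self, X, mask=None, covariates=None):
        """Fit on a sample x protein log-intensity matrix.

        ``X`` may contain NaN at missing cells; the presence mask is derived
        from it when ``mask`` is not given.  ``covariates`` is an encoded
        design matrix (``DesignMatrix`` or ndarray) aligned with the rows of X.
        """
        from .preprocessing import impute_for_input

        X = np.asarray(X, dtype=float)
        M = (~np.isnan(X)).astype(float) if mask is None else np.asarray(mask, dtype=float)
        C = covariates.C if isinstance(covariates, DesignMatrix) else covariates
        if C is not None:
            C = np.asarray(C, dtype=float)
            if C.shape[0] != X.shape[0]:
                raise ValueError("covariate rows do not match samples")
        Xin = impute_for_input(X, M)
        Xtarget = np.where(M > 0, X, 0.0)

        rng = np.random.default_rng(self.seed)
        n_cov = 0 if C is None else C.shape[1]
        params = self._build(Xin, M, C, rng)
        opt = _Adam(self._flatten(params), lr=self._effective_lr())

        train_idx = np.arange(X.shape[0])
        val_idx = None
        if self.validation_fraction > 0:
            perm = rng.permutation(X.shape[0])
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            val_idx, train_idx = perm[:n_val], perm[n_val:]

        def subset(idx):
            return (
                Xin[idx],
                Xtarget[idx],
                M[idx],
                None if C is None else C[idx],
            )

        tr = subset(train_idx)
        trace = []
        best_val = np.inf
        best_params = None
        stale = 0
        for epoch in range(self.epochs):
            loss, grads, _ = self._loss_and_grads(params, *tr)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            trace.append(loss)
            plist, glist = self._flatten(params, grads)
            opt.step(plist, glist)
            if val_idx is not None:
                vXin, vXt, vM, vC = subset(val_idx)
                vfwd = self._forward(params, vXin, vM, vC)
                vloss = total_loss(
                    vXt, vfwd["X_hat"], vM, vfwd["M_hat"],
                    self.lambda_weight if vfwd["M_hat"] is not None else 0.0,
                )
                if vloss < best_val - 1e-9:
                    best_val = vloss
                    best_params = self._copy_params(params)
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_params is not None:
            params = best_params

        fwd = self._forward(params, Xin, M, C)
        self.params_ = params
        self.n_covariates_ = n_cov
        self.X_hat_ = fwd["X_hat"]
        self.M_hat_ = (
            None if fwd["M_hat"] is None else np.clip(fwd["M_hat"], _CLIP, 1 - _CLIP)
        )
        self.loss_trace_ = np.asarray(trace)
        self.final_loss_ = total_loss(
            Xtarget, self.X_hat_, M, fwd["M_hat"],
            self.lambda_weight if fwd["M_hat"] is not None else 0.0,
        )
        return self

    @staticmethod
    def _copy_params(params):
        out = {}
        for key, mlp in params.items():
            out[key] = None if mlp is None else _MLP(
                [w.copy() for w in mlp.W], [b.copy() for b in mlp.b]
            )
        return out

    def reconstruct(self, X, mask=None, covariates=None):
        """Predict (X_hat, M_hat) for new samples with the fitted weights."""
        from .preprocessing import impute_for_input

        X = np.asarray(X, dtype=float)
        M = (~np.isnan(X)).astype(float) if mask is None else np.asarray(mask, dtype=float)
        C = covariates.C if isinstance(covariates, DesignMatrix) else covariates
        # callers may pre-impute (e.g. with training-set protein means)
        Xin = X if not np.isnan(X).any() else impute_for_input(X, M)
        fwd = self._forward(self.params_, Xin, M, C)
        M_hat = None if fwd["M_hat"] is None else np.clip(fwd["M_hat"], _CLIP, 1 - _CLIP)
        return fwd["X_hat"], M_hat

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Serialize weights + config to a single .npz checkpoint."""
        arrays = {}
        for key in ("enc", "dec_x", "dec_m"):
            mlp = self.params_.get(key)
            if mlp is None:
                continue
            for i, (W, b) in enumerate(zip(mlp.W, mlp.b)):
                arrays[f"{key}_W{i}"] = W
                arrays[f"{key}_b{i}"] = b
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ConditionalAutoencoder":
        data = np.load(path)
        config = json.loads(bytes(data["config_json"]).decode())
        model = cls(**config)
        params = {"enc": None, "dec_x": None, "dec_m": None}
        for key in ("enc", "dec_x", "dec_m"):
            W, b, i = [], [], 0
            while f"{key}_W{i}" in data:
                W.append(data[f"{key}_W{i}"])
                b.append(data[f"{key}_b{i}"])
                i += 1
            if W:
                params[key] = _MLP(W, b)
        model.params_ = params
        return model


def fit_autoencoder(X, M, C=None, **config) -> ConditionalAutoencoder:
    """Functional wrapper: fit a :class:`ConditionalAutoencoder` and return it."""
    model = ConditionalAutoencoder(**config)
    return model.fit(X, mask=M, covariates=C)
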