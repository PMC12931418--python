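import numpy as np
import pandas as pd
import pytest

from protride import (
    ConditionalAutoencoder,
    encode_covariates,
    impute_for_input,
    masked_mse,
    missingness_bce,
    total_loss,
)


class TestCovariateEncoding:
    def test_categorical_one_hot_rows_sum_to_one(self):
        ann = pd.DataFrame({"sex": ["F", "M", "F"]}, index=["a", "b", "c"])
        design = encode_covariates(ann, ["sex"])
        assert design.C.shape == (3, 2)
        np.testing.assert_allclose(design.C.sum(axis=1), 1.0)

    def test_numeric_standardized(self):
        ann = pd.DataFrame({"age": [10.0, 20.0, 30.0]}, index=list("abc"))
        design = encode_covariates(ann, ["age"])
        assert design.C[:, 0].mean() == pytest.approx(0.0)
        assert design.C[:, 0].std() == pytest.approx(1.0)

    def test_constant_covariate_dropped_with_warning(self):
        ann = pd.DataFrame({"lab": ["x", "x", "x"]}, index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            design = encode_covariates(ann, ["lab"])
        assert design.C.shape[1] == 0

    def test_missing_value_names_sample_and_covariate(self):
        ann = pd.DataFrame({"sex": ["F", None, "M"]}, index=list("abc"))
        with pytest.raises(ValueError, match="sex.*b"):
            encode_covariates(ann, ["sex"])


class TestLosses:
    def test_masked_mse_examples(self):
        X = np.array([[1.0, -1.0, 5.0]])
        X_hat = np.array([[0.0, 0.0, 0.0]])
        M = np.array([[1.0, 1.0, 0.0]])
        assert masked_mse(X, X, M) == 0.0
        assert masked_mse(X, X_hat, M) == pytest.approx(1.0)
        # homogeneity: doubling residuals quadruples the loss
        assert masked_mse(2 * X, 2 * X_hat, M) == pytest.approx(4.0)
        with pytest.raises(ValueError, match="no observed"):
            masked_mse(X, X_hat, np.zeros_like(M))

    def test_bce_closed_forms(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert missingness_bce(M, M) <= 1e-6
        assert missingness_bce(M, np.full_like(M, 0.5)) == pytest.approx(np.log(2), abs=1e-9)
        one = np.array([[1.0]])
        assert missingness_bce(one, np.array([[0.25]])) == pytest.approx(-np.log(0.25))
        with pytest.raises(ValueError, match="shape"):
            missingness_bce(M, M[:1])

    def test_total_loss_composition(self):
        X = np.array([[1.0, -1.0]])
        X_hat = np.zeros_like(X)
        M = np.ones_like(X)
        mse = masked_mse(X, X_hat, M)
        M_hat = np.full_like(M, 0.5)
        bce = missingness_bce(M, M_hat)
        assert total_loss(X, X_hat, M, None, 0.0) == pytest.approx(mse)
        assert total_loss(X, X_hat, M, M_hat, 2.0) == pytest.approx(mse + 2.0 * bce)
        with pytest.raises(ValueError, match="non-negative"):
            total_loss(X, X_hat, M, M_hat, -1.0)

    def test_masked_cells_do_not_enter_mse(self, rng):
        X = rng.normal(size=(5, 4))
        X_hat = rng.normal(size=(5, 4))
        M = np.ones_like(X)
        M[2, 1] = 0
        before = masked_mse(X, X_hat, M)
        X2 = X.copy()
        X2[2, 1] = 99.0  # perturb a masked (imputed) cell
        assert masked_mse(X2, X_hat, M) == before


def _lowrank(rng, n=30, p=80, rank=3, noise=0.0):
    X = rng.normal(size=(n, rank)) @ rng.normal(size=(rank, p))
    X += rng.normal(0, noise, size=(n, p))
    return X + 5.0


class TestSVDInit:
    def test_epoch_zero_equals_truncated_svd(self, rng):
        X = _lowrank(rng, noise=1.0)
        model = ConditionalAutoencoder(
            q=4, use_mask_input=False, lambda_weight=0.0, epochs=0
        ).fit(X)
        mu = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - mu, full_matrices=False)
        expected = ((X - mu) @ Vt[:4].T) @ Vt[:4] + mu
        assert np.max(np.abs(model.X_hat_ - expected)) < 1e-6

    def test_full_rank_reconstruction_is_identity(self, rng):
        X = rng.normal(size=(10, 6))
        model = ConditionalAutoencoder(
            q=6, use_mask_input=False, lambda_weight=0.0, epochs=0
        ).fit(X)
        assert np.max(np.abs(model.X_hat_ - X)) < 1e-6

    def test_mask_bias_reproduces_presence_rate(self, rng):
        X = rng.normal(size=(20, 15))
        M = (rng.random((20, 15)) > 0.2).astype(float)
        X = np.where(M > 0, X, np.nan)
        model = ConditionalAutoencoder(q=3, use_mask_input=True, epochs=0).fit(X)
        np.testing.assert_allclose(model.M_hat_, M.mean(axis=0)[None, :].repeat(20, 0), atol=1e-9)

    def test_q_above_rank_rejected(self, rng):
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError, match="q="):
            ConditionalAutoencoder(q=5, epochs=0).fit(X)


class TestFitting:
    def test_noiseless_lowrank_recovery(self, rng):
        X = _lowrank(rng, rank=3, noise=0.0)
        model = ConditionalAutoencoder(
            q=3, use_mask_input=False, lambda_weight=0.0, epochs=10
        ).fit(X)
        assert masked_mse(X, model.X_hat_, np.ones_like(X)) < 1e-4

    def test_deterministic_given_seed(self, rng):
        X = _lowrank(rng, noise=0.5)
        kw = dict(q=3, epochs=30, seed=7)
        a = ConditionalAutoencoder(**kw).fit(X)
        b = ConditionalAutoencoder(**kw).fit(X)
        np.testing.assert_array_equal(a.loss_trace_, b.loss_trace_)

    def test_loss_never_increases_over_window(self, rng):
        X = _lowrank(rng, noise=0.5)
        M = (rng.random(X.shape) > 0.1).astype(float)
        model = ConditionalAutoencoder(q=3, epochs=120, seed=0).fit(
            np.where(M > 0, X, np.nan), mask=M
        )
        trace = model.loss_trace_
        window = 50
        for k in range(len(trace) - window):
            assert trace[k + window] <= trace[k] + 1e-8

    def test_batch_covariate_removes_confounding(self):
        from scipy.stats import spearmanr

        from protride import generate_synthetic_dataset, preprocess

        ds = generate_synthetic_dataset(
            n_samples=40, n_proteins=300, latent_dim=2, loading_sd=0.1,
            batch_count=4, batch_sd=2.0, seed=5,
        )
        data = preprocess(ds.raw)
        ann = ds.annotation.loc[list(data.sample_ids)]
        design = encode_covariates(ann, ["batch"])
        model = ConditionalAutoencoder(q=3, seed=0).fit(
            data.X, mask=data.M, covariates=design
        )
        batch = ds.truth["batch_assignment"]

        def median_within_batch(mat):
            centered = mat - np.nanmean(mat, axis=0)
            rho = spearmanr(centered.T, nan_policy="omit").statistic
            vals = [
                rho[i, k]
                for i in range(len(batch))
                for k in range(i + 1, len(batch))
                if batch[i] == batch[k]
            ]
            return np.median(vals)

        raw_corr = median_within_batch(data.X)
        resid = np.where(data.M > 0, data.X - model.X_hat_, np.nan)
        resid_corr = median_within_batch(resid)
        assert raw_corr > 0.6
        assert resid_corr < 0.2

    def test_multilayer_fits_and_one_layer_is_linear(self, rng):
        X = _lowrank(rng, noise=0.5)
        deep = ConditionalAutoencoder(q=3, n_layers=2, epochs=20, seed=0).fit(X)
        assert np.all(np.isfinite(deep.loss_trace_))
        assert deep.X_hat_.shape == X.shape
        # a 1-layer model has exactly one weight matrix per stack: no hidden ReLU
        shallow = ConditionalAutoencoder(q=3, n_layers=1, epochs=0).fit(X)
        assert len(shallow.params_["enc"].W) == 1
        assert len(shallow.params_["dec_x"].W) == 1

    def test_save_load_round_trip(self, rng, tmp_path):
        X = _lowrank(rng, noise=0.5)
        M = (rng.random(X.shape) > 0.1).astype(float)
        Xn = np.where(M > 0, X, np.nan)
        model = ConditionalAutoencoder(q=3, epochs=15, seed=1).fit(Xn, mask=M)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ConditionalAutoencoder.load(path)
        X_hat, M_hat = loaded.reconstruct(impute_for_input(Xn, M), mask=M)
        np.testing.assert_array_equal(X_hat, model.X_hat_)
        np.testing.assert_array_equal(M_hat, model.M_hat_)
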