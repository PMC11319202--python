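"""Embedding machinery: VAE mechanics, baselines, latent alignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regle.representation import (
    PCABaseline,
    TrainedVAE,
    VAEConfig,
    align_latents,
    decode,
    decoder_sweep,
    encode,
    encode_table,
    pca_baseline,
    reconstruction_mse,
    spline_baseline,
    train_vae,
)


def _toy_curves(rng, n=120, L=64):
    """Two-parameter family: scaled, time-warped saturating curves."""
    t = np.linspace(0, 1, L)
    a = rng.uniform(1, 3, n)
    b = rng.uniform(2, 10, n)
    return a[:, None] * (1 - np.exp(-b[:, None] * t))


TOY_CFG = VAEConfig(input_length=64, input_channels=1, latent_dim=2,
                    conv_channels=(4, 8, 8), fc_widths=(32, 16, 8),
                    epochs=8, batch_size=64, learning_rate=3e-3, seed=0)


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of the full VAE loss agree with central
        differences for parameters in every layer type."""
        from regle.nn import ConvVAE, vae_loss_and_grads

        rng = np.random.default_rng(0)
        net = ConvVAE(input_length=40, input_channels=2, latent_dim=3,
                      n_injected=5, conv_channels=(4, 6, 8),
                      fc_widths=(16, 12, 8), seed=1)
        x = rng.standard_normal((6, 40, 2)).astype(np.float32)
        e = rng.standard_normal((6, 5)).astype(np.float32)

        def loss():
            val, *_ = vae_loss_and_grads(net, x, e, 0.01,
                                         np.random.default_rng(42))
            return val

        _, _, _, grads = vae_loss_and_grads(net, x, e, 0.01,
                                            np.random.default_rng(42))
        for name in ("e_conv2_W", "e_fc1_W", "e_mu_W", "e_lv_b",
                     "d_fc2_W", "d_proj_W", "d_conv3_W"):
            P = net.params[name]
            idx = np.unravel_index(np.argmax(np.abs(grads[name])), P.shape)
            h = 1e-3
            orig = P[idx]
            P[idx] = orig + h
            up = loss()
            P[idx] = orig - h
            down = loss()
            P[idx] = orig
            numeric = (up - down) / (2 * h)
            analytic = float(grads[name][idx])
            assert analytic == pytest.approx(numeric, rel=0.02, abs=1e-4), name


class TestTrainVAE:
    def test_loss_decreases_over_training(self, rng):
        m = train_vae(_toy_curves(rng), config=TOY_CFG)
        hist = m.history
        assert len(hist) == TOY_CFG.epochs
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_constant_dataset_collapses(self, rng):
        # degenerate target: reconstruction error vanishes relative to the
        # unit signal and the posterior collapses toward the prior
        curves = np.ones((100, 64))
        cfg = VAEConfig(**{**TOY_CFG.__dict__, "epochs": 100, "kl_weight": 1e-2})
        m = train_vae(curves, config=cfg)
        assert m.history["train_recon"].iloc[-1] < 0.01
        assert m.history["train_kl"].iloc[-1] < 0.5

    def test_edfs_required_iff_injected(self, rng):
        curves = _toy_curves(rng)
        with pytest.raises(ValueError):
            train_vae(curves, edfs=np.ones((120, 5)), config=TOY_CFG)
        cfg = VAEConfig(**{**TOY_CFG.__dict__, "n_injected": 5})
        with pytest.raises(ValueError):
            train_vae(curves, config=cfg)

    def test_training_deterministic_given_seed(self, rng):
        curves = _toy_curves(rng)
        a = train_vae(curves, config=TOY_CFG)
        b = train_vae(curves, config=TOY_CFG)
        assert np.array_equal(encode(a, curves), encode(b, curves))


class TestEncodeDecode:
    @pytest.fixture(scope="class")
    def model_and_data(self):
        rng = np.random.default_rng(7)
        curves = _toy_curves(rng)
        cfg = VAEConfig(**{**TOY_CFG.__dict__, "epochs": 150, "batch_size": 32})
        return train_vae(curves, config=cfg), curves

    def test_encode_deterministic(self, model_and_data):
        m, curves = model_and_data
        assert np.array_equal(encode(m, curves), encode(m, curves))

    def test_encodings_finite_posterior_means(self, model_and_data):
        m, curves = model_and_data
        z = encode(m, curves)
        assert z.shape == (len(curves), 2)
        assert np.all(np.isfinite(z))

    def test_decode_shape_matches_config(self, model_and_data):
        m, _ = model_and_data
        out = decode(m, np.zeros((3, 2)))
        assert out.shape == (3, 64, 1)

    def test_decoder_locally_lipschitz(self, model_and_data):
        m, _ = model_and_data
        base = decode(m, np.zeros((1, 2)))
        bumped = decode(m, np.array([[1e-6, 0.0]]))
        rms = np.sqrt(np.mean((bumped - base) ** 2))
        assert rms < 1e-3

    def test_reconstruction_beats_mean_predictor(self, model_and_data):
        # decode(encode(x)) should do better than predicting the dataset
        # mean curve for the bulk of the data
        m, curves = model_and_data
        per = reconstruction_mse(m, curves)["per_curve"]
        mean_mse = np.mean((curves - curves.mean(axis=0)) ** 2, axis=1)
        assert np.mean(per < mean_mse) >= 0.9

    def test_ppg_shaped_encoder_round_trip(self):
        # 100-point single-channel pulses: odd lengths exercise the
        # ceil-pooling / crop path of the decoder
        from regle.synthgen import PPGParams, ppg_from_params

        rng = np.random.default_rng(5)
        pulses = np.stack([
            ppg_from_params(PPGParams(systolic_pos=p)).values
            + rng.normal(0, 0.01, 100)
            for p in rng.uniform(0.15, 0.3, 80)
        ])
        cfg = VAEConfig(input_length=100, input_channels=1, latent_dim=2,
                        conv_channels=(4, 8, 8), fc_widths=(32, 16, 8),
                        epochs=5, batch_size=40, learning_rate=3e-3, seed=0)
        m = train_vae(pulses, config=cfg)
        out = decode(m, encode(m, pulses))
        assert out.shape == (80, 100, 1)
        assert m.history["train_loss"].iloc[-1] < m.history["train_loss"].iloc[0]


class TestReconstructionMSE:
    def test_identical_reconstruction_zero(self):
        class Identity:
            def transform(self, x):
                return x

            def inverse_transform(self, x):
                return x

        curves = np.random.default_rng(0).standard_normal((5, 10))
        assert reconstruction_mse(Identity(), curves)["mean"] == 0.0

    def test_zero_reconstruction_of_unit_curves(self):
        class Zero:
            def transform(self, x):
                return x

            def inverse_transform(self, x):
                return np.zeros_like(x)

        curves = np.random.default_rng(1).standard_normal((8, 12))
        out = reconstruction_mse(Zero(), curves)
        assert out["mean"] == pytest.approx(np.mean(curves**2))

    def test_matches_two_loop_oracle(self, rng):
        curves = rng.standard_normal((10, 6))
        recon = rng.standard_normal((10, 6))

        class Fixed:
            def transform(self, x):
                return x

            def inverse_transform(self, x):
                return recon

        out = reconstruction_mse(Fixed(), curves)["per_curve"]
        for i in range(10):
            acc = 0.0
            for t in range(6):
                acc += (recon[i, t] - curves[i, t]) ** 2
            assert out[i] == pytest.approx(acc / 6)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            reconstruction_mse(PCABaseline(1), np.zeros((0, 4)))


class TestDecoderSweep:
    @pytest.fixture(scope="class")
    def residual_model(self):
        rng = np.random.default_rng(3)
        curves = _toy_curves(rng)
        edfs = rng.standard_normal((len(curves), 5))
        cfg = VAEConfig(**{**TOY_CFG.__dict__, "n_injected": 5})
        return train_vae(curves, edfs, config=cfg), edfs

    def test_zero_value_reproduces_zero_latent_decode(self, residual_model):
        m, edfs = residual_model
        fam = decoder_sweep(m, edfs[0], 0, [0.0])
        direct = decode(m, np.zeros((1, 2)), edfs[:1])
        assert np.allclose(fam, direct)

    def test_output_count_matches_values(self, residual_model):
        m, edfs = residual_model
        fam = decoder_sweep(m, edfs[0], 1, [-1.0, 0.0, 1.0])
        assert fam.shape[0] == 3

    def test_out_of_range_coordinate(self, residual_model):
        m, edfs = residual_model
        with pytest.raises(ValueError):
            decoder_sweep(m, edfs[0], 5, [0.0])

    def test_plain_model_rejected(self, rng):
        m = train_vae(_toy_curves(rng), config=TOY_CFG)
        with pytest.raises(ValueError):
            decoder_sweep(m, np.zeros(5), 0, [0.0])


class TestAlignLatents:
    def test_exact_recovery_of_signed_permutation(self, rng):
        A = pd.DataFrame(rng.standard_normal((100, 4)),
                         index=[f"i{k}" for k in range(100)])
        perm_true = [2, 0, 3, 1]
        signs_true = [1, -1, 1, -1]
        B = A.iloc[:, perm_true] * signs_true
        B.columns = range(4)
        perm, signs, matched = align_latents(A, B)
        assert np.allclose(matched, 1.0)
        # A's column k must pair with the B column built from it, sign intact
        for k in range(4):
            assert np.allclose(
                np.abs(np.corrcoef(A.values[:, k], B.values[:, perm[k]])[0, 1]), 1.0
            )
            assert np.corrcoef(A.values[:, k], signs[k] * B.values[:, perm[k]])[0, 1] > 0.99

    def test_independent_noise_matches_nothing(self, rng):
        ids = [f"i{k}" for k in range(1000)]
        A = pd.DataFrame(rng.standard_normal((1000, 3)), index=ids)
        B = pd.DataFrame(rng.standard_normal((1000, 3)), index=ids)
        _, _, matched = align_latents(A, B)
        assert matched.mean() < 0.1

    def test_matches_exhaustive_signed_permutation_search(self, rng):
        # oracle: brute force over all 2^4 * 4! signed permutations
        ids = [f"i{k}" for k in range(60)]
        A = pd.DataFrame(rng.standard_normal((60, 4)), index=ids)
        B = pd.DataFrame(rng.standard_normal((60, 4)), index=ids)
        perm, signs, matched = align_latents(A, B)
        r = np.array([[np.corrcoef(A.values[:, i], B.values[:, j])[0, 1]
                       for j in range(4)] for i in range(4)])
        best = -np.inf
        for p in itertools.permutations(range(4)):
            total = sum(abs(r[i, p[i]]) for i in range(4))
            best = max(best, total)
        assert matched.sum() == pytest.approx(best, abs=1e-12)

    def test_too_few_shared_individuals(self, rng):
        A = pd.DataFrame(rng.standard_normal((2, 2)), index=["a", "b"])
        with pytest.raises(ValueError):
            align_latents(A, A)


class TestPCABaseline:
    def test_full_rank_exact_reconstruction(self, rng):
        curves = rng.standard_normal((30, 12))
        model = pca_baseline(curves, 12)
        out = reconstruction_mse(model, curves)
        assert out["mean"] < 1e-10

    def test_components_orthonormal(self, rng):
        model = pca_baseline(rng.standard_normal((50, 20)), 5)
        gram = model.components_ @ model.components_.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_matches_svd_truncation_oracle(self, rng):
        curves = rng.standard_normal((40, 15))
        k = 4
        model = pca_baseline(curves, k)
        recon = model.inverse_transform(model.transform(curves))
        centered = curves - curves.mean(axis=0)
        U, S, Vt = np.linalg.svd(centered, full_matrices=False)
        truncated = U[:, :k] @ np.diag(S[:k]) @ Vt[:k] + curves.mean(axis=0)
        assert np.allclose(recon, truncated, atol=1e-8)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            PCABaseline(0)


class TestSplineBaseline:
    def test_five_coefficients(self, rng):
        assert spline_baseline(rng.standard_normal(1000)).shape == (5,)

    def test_cubic_polynomial_reproduced(self):
        t = np.linspace(0, 1, 500)
        v = 1.0 - 2.0 * t + 0.5 * t**2 + 3.0 * t**3
        coef = spline_baseline(v)
        basis = np.column_stack(
            [np.ones_like(t), t, t**2, t**3, np.clip(t - 0.2, 0, None) ** 3]
        )
        assert np.max(np.abs(basis @ coef - v)) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        v = rng.standard_normal(300)
        t = np.linspace(0, 1, 300)
        basis = np.column_stack(
            [np.ones_like(t), t, t**2, t**3, np.clip(t - 0.2, 0, None) ** 3]
        )
        oracle = np.linalg.solve(basis.T @ basis, basis.T @ v)
        assert np.allclose(spline_baseline(v), oracle, atol=1e-8)

    def test_constant_curve_flat_fit(self):
        coef = spline_baseline(np.full(100, 2.5))
        t = np.linspace(0, 1, 100)
        basis = np.column_stack(
            [np.ones_like(t), t, t**2, t**3, np.clip(t - 0.2, 0, None) ** 3]
        )
        assert np.allclose(basis @ coef, 2.5, atol=1e-8)


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        curves = _toy_curves(rng)
        m = train_vae(curves, config=TOY_CFG)
        m.save(tmp_path / "model")
        loaded = TrainedVAE.load(tmp_path / "model")
        assert np.array_equal(encode(m, curves), encode(loaded, curves))
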