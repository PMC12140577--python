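"""VAE training, encoding/decoding, gradients, and the dimension scan."""

import numpy as np
import pytest
from scipy import stats as sps

from latentgec.io import BoldTimeSeries, build_pattern_set
from latentgec.vae import (
    TrainConfig,
    TrainedVae,
    VaeSpec,
    _init_params,
    _loss_and_grads,
    decode,
    encode,
    reconstruction_mse,
    scan_latent_dims,
    train_vae,
    vae_loss_terms,
)


def _pca_floor(X, k):
    """Best linear reconstruction MSE with k components (the PCA oracle)."""
    Xc = X - X.mean(axis=0)
    _, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return np.sum(s[k:] ** 2) / Xc.size


class TestTraining:
    def test_reconstruction_near_pca_floor_on_linear_subspace(
            self, rank3_patterns, rank3_vae):
        test = rank3_patterns.test
        err = reconstruction_mse(rank3_vae, test)
        floor = _pca_floor(rank3_patterns.train, 3)
        # data variance is ~1 per region; the floor here is ~0 so compare
        # against a practical ceiling of 1.5x the floor plus small slack
        assert err <= max(1.5 * floor, 0.1 * test.var())

    def test_epochs_zero_returns_untrained(self, rank3_patterns):
        spec = VaeSpec(input_dim=20, latent_dim=3)
        vae = train_vae(rank3_patterns, spec, TrainConfig(epochs=0, seed=1))
        fresh = _init_params(spec, np.random.default_rng(1))
        assert vae.loss_history == []
        for k in fresh:
            assert np.array_equal(vae.params[k], fresh[k])

    def test_kl_weight_zero_loss_is_pure_reconstruction(self, rank3_patterns):
        spec = VaeSpec(input_dim=20, latent_dim=3, kl_weight=0.0)
        rng = np.random.default_rng(0)
        p = _init_params(spec, rng)
        x = rank3_patterns.train[:32]
        eps = rng.standard_normal((32, 3))
        loss, recon, kl, _ = _loss_and_grads(p, spec, x, eps, spec.kl_weight)
        assert loss == pytest.approx(recon, abs=1e-12)

    def test_kl_term_nonnegative(self, rank3_vae, rank3_patterns):
        _, kl = vae_loss_terms(rank3_vae, rank3_patterns.train[:200])
        assert kl >= 0

    def test_training_is_seed_repeatable(self, rank3_patterns):
        spec = VaeSpec(input_dim=20, latent_dim=3)
        cfg = TrainConfig(epochs=3, seed=9)
        a = train_vae(rank3_patterns, spec, cfg)
        b = train_vae(rank3_patterns, spec, cfg)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_analytic_gradients_match_finite_differences(self):
        # oracle: central finite differences on a tiny network
        spec = VaeSpec(input_dim=6, latent_dim=2, hidden_dims=[5, 4])
        rng = np.random.default_rng(0)
        p = _init_params(spec, rng)
        x = rng.standard_normal((7, 6))
        eps = rng.standard_normal((7, 2))
        _, _, _, g = _loss_and_grads(p, spec, x, eps, 1.0)
        h = 1e-6
        for key in ["We0", "bmu", "Wlv", "Wd1", "bout", "Wmu"]:
            flat = p[key].ravel()
            idx = rng.integers(0, flat.size, size=3)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + h
                lp, *_ = _loss_and_grads(p, spec, x, eps, 1.0)
                flat[i] = orig - h
                lm, *_ = _loss_and_grads(p, spec, x, eps, 1.0)
                flat[i] = orig
                fd = (lp - lm) / (2 * h)
                assert g[key].ravel()[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestEncodeDecode:
    def test_empty_input(self, rank3_vae):
        assert encode(rank3_vae, np.empty((0, 20))).shape == (0, 3)
        assert decode(rank3_vae, np.empty((0, 3))).shape == (0, 20)

    def test_encode_deterministic(self, rank3_vae, rank3_patterns):
        x = rank3_patterns.test[:50]
        assert np.array_equal(encode(rank3_vae, x), encode(rank3_vae, x))

    def test_latent_geometry_preserved(self, rank3_vae, rank3_patterns):
        x = rank3_patterns.test[:80]
        z = encode(rank3_vae, x)
        from scipy.spatial.distance import pdist

        rho = sps.spearmanr(pdist(x), pdist(z)).statistic
        assert rho > 0.8

    def test_roundtrip_error_matches_reported(self, rank3_vae, rank3_patterns):
        x = rank3_patterns.train
        xhat = decode(rank3_vae, encode(rank3_vae, x))
        direct = np.mean((xhat - x) ** 2)
        assert reconstruction_mse(rank3_vae, x) == pytest.approx(direct, abs=1e-8)

    def test_roundtrip_relative_error_small_on_subspace(
            self, rank3_vae, rank3_patterns):
        x = rank3_patterns.test
        xhat = decode(rank3_vae, encode(rank3_vae, x))
        rel = np.linalg.norm(xhat - x) / np.linalg.norm(x)
        assert rel < 0.15

    def test_zero_latent_decodes_finite(self, rank3_vae):
        out = decode(rank3_vae, np.zeros((1, 3)))
        assert np.isfinite(out).all()

    def test_shape_mismatch(self, rank3_vae):
        with pytest.raises(ValueError):
            encode(rank3_vae, np.zeros((5, 7)))
        with pytest.raises(ValueError):
            decode(rank3_vae, np.zeros((5, 7)))

    def test_test_error_invariant_to_row_order(self, rank3_vae, rank3_patterns):
        x = rank3_patterns.test
        shuffled = x[np.random.default_rng(0).permutation(len(x))]
        assert reconstruction_mse(rank3_vae, x) == pytest.approx(
            reconstruction_mse(rank3_vae, shuffled), abs=1e-12)


class TestSaveLoad:
    def test_checkpoint_roundtrip(self, rank3_vae, rank3_patterns, tmp_path):
        p = tmp_path / "vae.npz"
        rank3_vae.save(p)
        back = TrainedVae.load(p)
        x = rank3_patterns.test[:10]
        assert np.allclose(encode(back, x), encode(rank3_vae, x), atol=1e-12)


class TestDimScan:
    def test_single_dim_scan(self, rank3_patterns):
        res = scan_latent_dims(rank3_patterns, [3], TrainConfig(epochs=2, seed=0))
        assert res.derivative == []
        assert res.elbow == 3

    def test_rank6_elbow(self):
        # patterns of true rank 6 in N=20; elbow should land near 6.
        # Uses the documented scan settings: a small KL weight so the
        # bottleneck is capacity-limited rather than regularization-limited,
        # enough epochs to reach the noiseless-data floor, and restarts so a
        # single bad training run cannot fake a plateau in the error curve.
        rng = np.random.default_rng(11)
        W = rng.standard_normal((20, 6))
        series = [
            BoldTimeSeries(data=rng.standard_normal((200, 6)) @ W.T,
                           tr_seconds=0.72, subject_id=f"s{i}")
            for i in range(8)
        ]
        ps = build_pattern_set(series, train_frac=0.875, seed=0)
        res = scan_latent_dims(ps, list(range(2, 11)),
                               TrainConfig(epochs=600, seed=0),
                               kl_weight=0.01, n_restarts=3)
        assert res.elbow in {5, 6, 7}
        # errors should not systematically increase with dimension
        assert res.errors[-1] <= res.errors[0]
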