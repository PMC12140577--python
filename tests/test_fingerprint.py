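"""Noise-probe mode decoding and reference-network association."""

import numpy as np
import pytest

from latentgec.fingerprint import (
    ModePattern,
    RsnMembership,
    associate_rsn,
    mode_patterns,
    probe_mode,
)
from latentgec.vae import TrainedVae, VaeSpec


def _linear_decoder_vae(W: np.ndarray) -> TrainedVae:
    """A VAE whose decoder is exactly the linear map z -> z @ W.T.

    Hidden ReLU layers are bypassed by splitting the map into positive and
    negative parts routed through separate always-active units.
    """
    M = W.shape[1]
    N = W.shape[0]
    h = 2 * M
    spec = VaeSpec(input_dim=N, latent_dim=M, hidden_dims=[h + 1, h])
    rng = np.random.default_rng(0)
    from latentgec.vae import _init_params

    p = _init_params(spec, rng)
    big = 1e6
    # decoder layer 0: latent -> h units: [z+big, -z+big] (all positive)
    Wd0 = np.zeros((M, h))
    Wd0[:, :M] = np.eye(M)
    Wd0[:, M:] = -np.eye(M)
    p["Wd0"] = Wd0
    p["bd0"] = np.full(h, big)
    # decoder layer 1: pass-through to h+1 units
    Wd1 = np.zeros((h, h + 1))
    Wd1[:, :h] = np.eye(h)
    p["Wd1"] = Wd1
    p["bd1"] = np.zeros(h + 1)
    # output: W @ (pos - neg) with the big offsets cancelled in the bias
    Wout = np.zeros((h + 1, N))
    Wout[:M, :] = 0.5 * W.T
    Wout[M:h, :] = -0.5 * W.T
    p["Wout"] = Wout
    p["bout"] = -(np.full(h, big) @ Wout[:h])
    return TrainedVae(spec=spec, params=p)


@pytest.fixture(scope="module")
def linear_vae():
    rng = np.random.default_rng(9)
    W = rng.standard_normal((12, 3))
    return W, _linear_decoder_vae(W)


class TestProbe:
    def test_linear_decoder_exact(self, linear_vae):
        W, vae = linear_vae
        from latentgec.vae import decode

        z = np.random.default_rng(1).standard_normal((20, 3))
        assert np.allclose(decode(vae, z), z @ W.T, atol=1e-6)

    def test_zero_noise_constant_output(self, linear_vae):
        _, vae = linear_vae
        decoded, injected = probe_mode(vae, 0, frames=100, noise_sd=0.0)
        assert np.allclose(decoded.var(axis=0), 0.0, atol=1e-20)
        assert np.all(injected == 0)

    def test_variance_through_linear_map(self, linear_vae):
        W, vae = linear_vae
        sd = 1.5
        decoded, injected = probe_mode(vae, 1, frames=5000, noise_sd=sd,
                                       seed=4)
        expected = injected.var() * W[:, 1] ** 2
        assert np.allclose(decoded.var(axis=0), expected, rtol=1e-6)

    def test_seeded_repeatability(self, linear_vae):
        _, vae = linear_vae
        a = probe_mode(vae, 2, frames=50, seed=8)
        b = probe_mode(vae, 2, frames=50, seed=8)
        assert np.array_equal(a[0], b[0])

    def test_out_of_range_index(self, linear_vae):
        _, vae = linear_vae
        with pytest.raises(IndexError):
            probe_mode(vae, 3)


class TestModePatterns:
    def test_shapes(self, linear_vae):
        _, vae = linear_vae
        mp = mode_patterns(vae, frames=200, seed=0)
        assert mp.variance_map.shape == (3, 12)
        assert mp.signed_map.shape == (3, 12)
        assert (mp.variance_map >= 0).all()

    def test_signed_map_matches_decoder_columns(self, linear_vae):
        W, vae = linear_vae
        mp = mode_patterns(vae, frames=2000, seed=1)
        for k in range(3):
            # each region is an exact scalar multiple of the injected series,
            # so the correlation map is +/-1 with the decoder column's signs
            assert np.array_equal(np.sign(mp.signed_map[k]), np.sign(W[:, k]))
            assert np.allclose(np.abs(mp.signed_map[k]), 1.0, atol=1e-9)

    def test_variance_scales_quadratically_with_noise(self, linear_vae):
        _, vae = linear_vae
        m1 = mode_patterns(vae, frames=2000, noise_sd=1.0, seed=2)
        m2 = mode_patterns(vae, frames=2000, noise_sd=2.0, seed=2)
        ratio = m2.variance_map / m1.variance_map
        assert np.allclose(ratio, 4.0, rtol=0.05)


class TestRsnAssociation:
    def _patterns(self, maps):
        return ModePattern(variance_map=np.abs(maps), signed_map=maps,
                           probe_config={})

    def test_proportional_membership_perfect_correlation(self):
        rng = np.random.default_rng(0)
        pattern = rng.standard_normal(30)
        memb = 50 + 20 * (pattern - pattern.min()) / np.ptp(pattern)
        rsn = RsnMembership(values=memb[:, None], network_names=["DMN"])
        assoc = associate_rsn(self._patterns(pattern[None, :]), rsn)
        assert assoc.r[0, 0] == pytest.approx(1.0)
        assert assoc.significant[0, 0]

    def test_orthogonalized_membership_zero_correlation(self):
        rng = np.random.default_rng(1)
        pattern = rng.standard_normal(62)
        raw = rng.uniform(0, 100, 62)
        pc = pattern - pattern.mean()
        resid = raw - raw.mean() - (raw - raw.mean()) @ pc / (pc @ pc) * pc
        memb = 100 * (resid - resid.min()) / np.ptp(resid)  # percentages
        rsn = RsnMembership(values=memb[:, None], network_names=["VIS"])
        assoc = associate_rsn(self._patterns(pattern[None, :]), rsn)
        assert abs(assoc.r[0, 0]) < 1e-10

    def test_bh_stepup_oracle(self):
        # hand-listed p-values; BH at 0.05 flags exactly ranks <= k*
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.011, 0.021, 0.031, 0.041, 0.051, 0.061,
                      0.071, 0.081, 0.091])
        # step-up by hand: largest k with p_(k) <= 0.05 * k / 10
        thresholds = 0.05 * np.arange(1, 11) / 10
        ks = np.flatnonzero(np.sort(p) <= thresholds)
        k_star = ks.max() + 1 if ks.size else 0
        expected = np.zeros(10, dtype=bool)
        expected[np.argsort(p)[:k_star]] = True
        rej, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(rej, expected)
        assert k_star == 1  # only p=0.001 survives this ladder

    def test_bh_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((4, 30))
        memb = rng.uniform(0, 100, (30, 5))
        rsn = RsnMembership(values=memb,
                            network_names=[f"n{i}" for i in range(5)])
        lo = associate_rsn(self._patterns(maps), rsn, alpha=0.01)
        hi = associate_rsn(self._patterns(maps), rsn, alpha=0.05)
        assert np.all(hi.significant | ~lo.significant)

    def test_constant_membership_column_raises(self):
        maps = np.random.default_rng(0).standard_normal((2, 10))
        memb = np.column_stack([np.full(10, 50.0),
                                np.random.default_rng(1).uniform(0, 100, 10)])
        rsn = RsnMembership(values=memb, network_names=["a", "b"])
        with pytest.raises(ValueError, match="constant"):
            associate_rsn(self._patterns(maps), rsn)

    def test_variance_invariant_to_noise_sign(self, linear_vae):
        _, vae = linear_vae
        decoded, injected = probe_mode(vae, 0, frames=500, seed=5)
        # decoding the negated series gives the same per-region variance
        from latentgec.vae import decode

        latent = np.zeros((500, 3))
        latent[:, 0] = -injected
        flipped = decode(vae, latent)
        assert np.allclose(decoded.var(axis=0), flipped.var(axis=0),
                           rtol=1e-9)
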