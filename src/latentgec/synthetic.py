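"""Ground-truth latent Hopf systems and synthetic multi-subject datasets.

The generator realises the pipeline's own generative assumption: a small
number ``M`` of latent Stuart-Landau modes with a known directed coupling
``C*`` are mixed linearly into ``N >> M`` regions and observed with
additive Gaussian noise.  Because the mixing is linear and known, every
downstream stage has a closed-form oracle: the pseudo-inverse of the mixing
is an exact "oracle encoder", the source covariance is ``W Cov(x) W^T``,
and recovery of ``C*`` by the inference loop is directly scoreable.

Defaults mirror the modelling conditions used throughout the package:
``a = -0.02`` (subcritical, noise-driven), intrinsic frequencies drawn in
0.01-0.07 Hz (inside the 0.008-0.08 Hz analysis band), noise SD 0.01, and
coupling magnitudes U(0.05, 0.2) on a sparse directed support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hopf import HopfSystem, SimConfig, simulate_hopf_ensemble
from .io import BoldTimeSeries
from .observables import offdiag


@dataclass
class GroundTruth:
    """A known latent system plus its source-space observation model."""

    C_star: np.ndarray
    system: HopfSystem
    mixing: np.ndarray          # N x M, full column rank
    obs_noise_sd: float = 0.0
    condition_label: str = "SYN"

    @property
    def n_modes(self) -> int:
        return self.C_star.shape[0]

    @property
    def n_regions(self) -> int:
        return self.mixing.shape[0]

    def oracle_encode(self, ts: BoldTimeSeries | np.ndarray) -> np.ndarray:
        """Map source signals back to latent space with pinv(mixing)."""
        data = ts.data if isinstance(ts, BoldTimeSeries) else np.asarray(ts)
        return data @ np.linalg.pinv(self.mixing).T


@dataclass
class RecoveryReport:
    """Agreement between an inferred coupling and the known truth."""

    pearson_offdiag: float
    sign_agreement: float
    frobenius_rel_error: float


def make_ground_truth(
    M: int = 6,
    N: int = 20,
    density: float = 0.2,
    asymmetry: float = 1.0,
    seed: int = 0,
    a: float = -0.02,
    sigma: float = 0.01,
    obs_noise_sd: float = 0.0,
    freq_range_hz: tuple[float, float] = (0.01, 0.07),
    condition_label: str = "SYN",
) -> GroundTruth:
    """Draw a sparse directed coupling and its latent Hopf system.

    ``asymmetry`` in [0, 1] interpolates between a symmetric support (every
    edge reciprocated with equal weight) and a fully directed one; edge
    magnitudes are U(0.05, 0.2).  The mixing matrix has random orthonormal
    columns scaled by U(0.5, 1.5).
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    if M >= N:
        raise ValueError(f"need M < N, got M={M}, N={N}")
    if not 0 <= asymmetry <= 1:
        raise ValueError(f"asymmetry must be in [0, 1], got {asymmetry}")
    rng = np.random.default_rng(seed)

    n_slots = M * (M - 1)
    n_edges = max(1, int(round(density * n_slots)))

    def _draw_directed() -> np.ndarray:
        C = np.zeros((M, M))
        idx = np.argwhere(~np.eye(M, dtype=bool))
        chosen = idx[rng.choice(len(idx), n_edges, replace=False)]
        for i, j in chosen:
            C[i, j] = rng.uniform(0.05, 0.2)
        return C

    def _draw_symmetric() -> np.ndarray:
        C = np.zeros((M, M))
        pairs = np.argwhere(np.triu(np.ones((M, M), dtype=bool), 1))
        n_pairs = max(1, n_edges // 2)
        chosen = pairs[rng.choice(len(pairs), min(n_pairs, len(pairs)),
                                  replace=False)]
        for i, j in chosen:
            w = rng.uniform(0.05, 0.2)
            C[i, j] = C[j, i] = w
        return C

    C_star = (1.0 - asymmetry) * _draw_symmetric() + asymmetry * _draw_directed()

    omega = 2 * np.pi * rng.uniform(*freq_range_hz, size=M)
    system = HopfSystem(a=np.full(M, a), omega=omega, sigma=sigma, C=C_star)

    # random orthonormal columns, scaled
    G = rng.standard_normal((N, M))
    Q, _ = np.linalg.qr(G)
    mixing = Q[:, :M] * rng.uniform(0.5, 1.5, size=M)

    return GroundTruth(
        C_star=C_star, system=system, mixing=mixing,
        obs_noise_sd=obs_noise_sd, condition_label=condition_label,
    )


def generate_latents(
    gt: GroundTruth,
    n_subjects: int,
    frames: int,
    tr_seconds: float = 0.72,
    seed: int = 0,
    dt: float = 0.1,
    transient_s: float = 60.0,
) -> np.ndarray:
    """Latent trajectories only, shape ``(n_subjects, frames, M)``."""
    if n_subjects == 0:
        return np.empty((0, frames, gt.n_modes))
    cfg = SimConfig(t_sample=tr_seconds, n_samples=frames, dt=dt,
                    transient_s=transient_s, seed=seed)
    rng = np.random.default_rng(seed)
    return simulate_hopf_ensemble(gt.system, cfg, n_realizations=n_subjects,
                                  rng=rng)


def generate_dataset(
    gt: GroundTruth,
    n_subjects: int,
    frames: int,
    tr_seconds: float = 0.72,
    seed: int = 0,
    dt: float = 0.1,
    transient_s: float = 60.0,
    saturation: bool = False,
) -> list[BoldTimeSeries]:
    """Simulate subjects, mix to source space, add observation noise.

    With ``saturation`` a tanh is applied after mixing to stress the
    nonlinear encoding path (off by default, which keeps the closed-form
    covariance oracle exact).
    """
    if frames < 200:
        raise ValueError(f"frames must be >= 200, got {frames}")
    xs = generate_latents(gt, n_subjects, frames, tr_seconds, seed, dt,
                          transient_s)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    out = []
    for s in range(n_subjects):
        y = xs[s] @ gt.mixing.T
        if saturation:
            scale = np.abs(y).mean() or 1.0
            y = scale * np.tanh(y / scale)
        if gt.obs_noise_sd > 0:
            y = y + rng.normal(0.0, gt.obs_noise_sd, size=y.shape)
        out.append(BoldTimeSeries(
            data=y, tr_seconds=tr_seconds,
            subject_id=f"sub-{s:03d}", condition=gt.condition_label,
        ))
    return out


def recovery_report(C_star: np.ndarray, C_hat: np.ndarray,
                    sign_threshold: float = 1e-3) -> RecoveryReport:
    """Score an inferred coupling against the truth (off-diagonal entries).

    ``sign_agreement`` counts matching signs among truth entries with
    ``|C*| > sign_threshold``; the relative Frobenius error is
    ``||C_hat - C*||_F / ||C*||_F``.
    """
    C_star = np.asarray(C_star, dtype=float)
    C_hat = np.asarray(C_hat, dtype=float)
    if C_star.shape != C_hat.shape:
        raise ValueError(f"shape mismatch: {C_star.shape} vs {C_hat.shape}")
    vs, vh = offdiag(C_star), offdiag(C_hat)
    pearson = float(np.corrcoef(vs, vh)[0, 1])
    big = np.abs(vs) > sign_threshold
    sign_agree = (
        float(np.mean(np.sign(vs[big]) == np.sign(vh[big]))) if big.any() else 1.0
    )
    denom = np.linalg.norm(vs)
    rel = float(np.linalg.norm(vh - vs) / denom) if denom > 0 else float("inf")
    return RecoveryReport(
        pearson_offdiag=pearson, sign_agreement=sign_agree,
        frobenius_rel_error=rel,
    )
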