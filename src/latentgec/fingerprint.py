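"""Source-space fingerprints of latent modes via noise-probe decoding.

To see which regions a latent mode drives, standard Gaussian noise is
injected into that single latent dimension (all others held at zero) and
decoded to source space.  The temporal variance of each decoded regional
series gives the unsigned spatial pattern of the mode; the Pearson
correlation between each decoded series and the injected noise gives a
signed pattern separating regions that activate with the mode from those
that deactivate.  Patterns are then associated with reference functional
networks (e.g. the seven canonical resting-state networks) by correlating
them with per-region network membership percentages, with
Benjamini-Hochberg FDR correction across all mode-network tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .vae import TrainedVae, decode


@dataclass
class ModePattern:
    """Per-mode source-space patterns (``M x N``) and the probe settings."""

    variance_map: np.ndarray
    signed_map: np.ndarray
    probe_config: dict


@dataclass
class RsnMembership:
    """``N x R`` matrix of per-region network participation percentages."""

    values: np.ndarray
    network_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("membership must be an N x R matrix")
        if (self.values < 0).any() or (self.values > 100).any():
            raise ValueError("membership entries must be percentages in [0, 100]")
        if len(self.network_names) != self.values.shape[1]:
            raise ValueError("one name per network column required")


@dataclass
class RsnAssociation:
    """Mode-network correlations with FDR-corrected significance flags."""

    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    network_names: list[str]


def probe_mode(
    vae: TrainedVae,
    k: int,
    frames: int = 2000,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Decode noise injected into latent dimension ``k`` (0-based).

    Returns ``(decoded T x N, injected T-vector)``.
    """
    M = vae.spec.latent_dim
    if not 0 <= k < M:
        raise IndexError(f"mode index {k} out of range [0, {M})")
    rng = np.random.default_rng(seed)
    injected = rng.normal(0.0, noise_sd, size=frames) if noise_sd > 0 \
        else np.zeros(frames)
    latent = np.zeros((frames, M))
    latent[:, k] = injected
    decoded = decode(vae, latent)
    return decoded, injected


def mode_patterns(
    vae: TrainedVae,
    frames: int = 2000,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ModePattern:
    """Probe every latent dimension; stack variance and signed maps.

    ``variance_map[k, j]`` is the temporal variance of region *j* under the
    mode-*k* probe; ``signed_map[k, j]`` the correlation of region *j* with
    the injected series (zero where the decoded series is constant).
    """
    M, N = vae.spec.latent_dim, vae.spec.input_dim
    var_map = np.zeros((M, N))
    signed = np.zeros((M, N))
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=M)
    for k in range(M):
        decoded, injected = probe_mode(vae, k, frames, noise_sd, int(seeds[k]))
        var_map[k] = decoded.var(axis=0)
        dsd = decoded.std(axis=0)
        isd = injected.std()
        if isd > 0:
            dc = decoded - decoded.mean(axis=0)
            ic = injected - injected.mean()
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (ic @ dc) / (frames * dsd * isd)
            signed[k] = np.where(dsd > 0, r, 0.0)
    return ModePattern(
        variance_map=var_map, signed_map=signed,
        probe_config={"frames": frames, "noise_sd": noise_sd, "seed": seed},
    )


def associate_rsn(
    patterns: ModePattern,
    membership: RsnMembership,
    alpha: float = 0.05,
) -> RsnAssociation:
    """Correlate each signed mode pattern with each network's membership.

    Two-sided p-values; Benjamini-Hochberg step-up across the full
    ``M x R`` family at level ``alpha``.
    """
    maps = patterns.signed_map
    memb = membership.values
    if maps.shape[1] != memb.shape[0]:
        raise ValueError(
            f"pattern width {maps.shape[1]} != membership rows {memb.shape[0]}"
        )
    if (memb.std(axis=0) == 0).any():
        bad = np.flatnonzero(memb.std(axis=0) == 0)
        raise ValueError(f"constant membership column(s) {bad.tolist()}")
    M, R = maps.shape[0], memb.shape[1]
    r = np.zeros((M, R))
    p = np.ones((M, R))
    for k in range(M):
        for j in range(R):
            res = _stats.pearsonr(maps[k], memb[:, j])
            r[k, j], p[k, j] = res.statistic, res.pvalue
    rej, _, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return RsnAssociation(
        r=r, p=p, significant=rej.reshape(M, R),
        network_names=list(membership.network_names),
    )


def association_table(assoc: RsnAssociation) -> str:
    """TSV report of r, p and significance stars per mode and network."""
    lines = ["mode\tnetwork\tr\tp\tsig"]
    for k in range(assoc.r.shape[0]):
        for j, name in enumerate(assoc.network_names):
            star = "*" if assoc.significant[k, j] else ""
            lines.append(
                f"N{k + 1}\t{name}\t{assoc.r[k, j]:.4f}\t{assoc.p[k, j]:.3e}\t{star}"
            )
    return "\n".join(lines)
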