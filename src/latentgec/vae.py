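"""Variational autoencoder for time-by-time spatial patterns.

The encoder is a funnel of two dense ReLU layers ending in a Gaussian
variational layer (mean and log-variance heads); the decoder mirrors the
encoder.  Training minimises

    loss = E_batch[ sum_features (x_hat - x)^2 ]  +  kl_weight * E_batch[ KL ]

with ``KL = 0.5 * sum_m (mu_m^2 + var_m - log var_m - 1)`` the analytic
divergence between the per-sample posterior and a standard Gaussian, using
the reparameterization trick and an Adam optimiser (batches of 128, 50
epochs by default).  Everything is plain numpy with hand-written
backpropagation — the networks involved are tiny (tens of units), so no
deep-learning framework is needed — and fully seeded, so training is
bit-repeatable.

Downstream dynamical modelling uses the *posterior mean* as the latent
trajectory (deterministic encoding); stochastic encoding is available via
``sample=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import PatternSet


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class VaeSpec:
    """Architecture: input width, latent width, encoder hidden funnel.

    ``hidden_dims`` defaults to ``[input_dim // 2, input_dim // 4]``
    (strictly decreasing toward the latent layer); the decoder mirrors it.
    """

    input_dim: int
    latent_dim: int
    hidden_dims: list[int] | None = None
    kl_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.latent_dim >= self.input_dim:
            raise ValueError("latent_dim must be < input_dim")
        if self.hidden_dims is None:
            h1 = max(self.input_dim // 2, self.latent_dim + 2)
            h2 = max(self.input_dim // 4, self.latent_dim + 1)
            if h2 >= h1:
                h2 = max(self.latent_dim + 1, h1 - 1)
            self.hidden_dims = [h1, h2]
        dims = [self.input_dim, *self.hidden_dims, self.latent_dim]
        if any(b >= a for a, b in zip(dims, dims[1:])):
            raise ValueError(
                f"hidden_dims must decrease strictly toward the latent layer: {dims}"
            )


@dataclass
class TrainConfig:
    """Optimisation settings (defaults: Adam 1e-3, batch 128, 50 epochs)."""

    batch_size: int = 128
    epochs: int = 50
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def _init_params(spec: VaeSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He initialisation for ReLU layers, small Gaussian for linear heads."""
    dims = [spec.input_dim, *spec.hidden_dims]
    p: dict[str, np.ndarray] = {}
    for i, (din, dout) in enumerate(zip(dims, dims[1:])):
        p[f"We{i}"] = rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)
        p[f"be{i}"] = np.zeros(dout)
    h_last = spec.hidden_dims[-1]
    for head in ("mu", "lv"):
        p[f"W{head}"] = rng.standard_normal((h_last, spec.latent_dim)) * np.sqrt(1.0 / h_last)
        p[f"b{head}"] = np.zeros(spec.latent_dim)
    ddims = [spec.latent_dim, *reversed(spec.hidden_dims)]
    for i, (din, dout) in enumerate(zip(ddims, ddims[1:])):
        p[f"Wd{i}"] = rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)
        p[f"bd{i}"] = np.zeros(dout)
    p["Wout"] = rng.standard_normal((spec.hidden_dims[0], spec.input_dim)) * np.sqrt(
        1.0 / spec.hidden_dims[0]
    )
    p["bout"] = np.zeros(spec.input_dim)
    return p


@dataclass
class TrainedVae:
    """Trained parameters plus the normalization of the training patterns."""

    spec: VaeSpec
    params: dict[str, np.ndarray]
    loss_history: list[tuple[float, float]] = field(default_factory=list)
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    @property
    def n_hidden_layers(self) -> int:
        return len(self.spec.hidden_dims)

    def save(self, path) -> None:
        np.savez(
            path,
            input_dim=self.spec.input_dim,
            latent_dim=self.spec.latent_dim,
            hidden_dims=np.array(self.spec.hidden_dims),
            kl_weight=self.spec.kl_weight,
            loss_history=np.array(self.loss_history).reshape(-1, 2),
            mean=self.mean if self.mean is not None else np.array([]),
            sd=self.sd if self.sd is not None else np.array([]),
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "TrainedVae":
        z = np.load(path, allow_pickle=False)
        spec = VaeSpec(
            input_dim=int(z["input_dim"]), latent_dim=int(z["latent_dim"]),
            hidden_dims=[int(d) for d in z["hidden_dims"]],
            kl_weight=float(z["kl_weight"]),
        )
        params = {k[6:]: z[k] for k in z.files if k.startswith("param_")}
        mean = z["mean"] if z["mean"].size else None
        sd = z["sd"] if z["sd"].size else None
        return cls(spec=spec, params=params,
                   loss_history=[tuple(r) for r in z["loss_history"]],
                   mean=mean, sd=sd)


def _encode_forward(p: dict, spec: VaeSpec, x: np.ndarray):
    hs = [x]
    h = x
    for i in range(len(spec.hidden_dims)):
        h = np.maximum(h @ p[f"We{i}"] + p[f"be{i}"], 0.0)
        hs.append(h)
    mu = h @ p["Wmu"] + p["bmu"]
    lv = h @ p["Wlv"] + p["blv"]
    return hs, mu, lv


def _decode_forward(p: dict, spec: VaeSpec, z: np.ndarray):
    hs = [z]
    h = z
    for i in range(len(spec.hidden_dims)):
        h = np.maximum(h @ p[f"Wd{i}"] + p[f"bd{i}"], 0.0)
        hs.append(h)
    xhat = h @ p["Wout"] + p["bout"]
    return hs, xhat


def vae_loss_terms(vae: TrainedVae, x: np.ndarray,
                   eps: np.ndarray | None = None) -> tuple[float, float]:
    """(reconstruction, KL) for a batch; deterministic when ``eps`` is None."""
    p, spec = vae.params, vae.spec
    _, mu, lv = _encode_forward(p, spec, x)
    z = mu if eps is None else mu + np.exp(0.5 * lv) * eps
    _, xhat = _decode_forward(p, spec, z)
    recon = float(np.mean(np.sum((xhat - x) ** 2, axis=1)))
    kl = float(np.mean(0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=1)))
    return recon, kl


def _loss_and_grads(p: dict, spec: VaeSpec, x: np.ndarray, eps: np.ndarray,
                    kl_weight: float):
    """Forward + analytic backward pass for one batch."""
    B = x.shape[0]
    ehs, mu, lv = _encode_forward(p, spec, x)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    dhs, xhat = _decode_forward(p, spec, z)

    recon = np.mean(np.sum((xhat - x) ** 2, axis=1))
    kl = np.mean(0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=1))
    loss = recon + kl_weight * kl

    g: dict[str, np.ndarray] = {}
    nH = len(spec.hidden_dims)

    # decoder backward
    dxhat = 2.0 * (xhat - x) / B
    g["Wout"] = dhs[-1].T @ dxhat
    g["bout"] = dxhat.sum(axis=0)
    dh = dxhat @ p["Wout"].T
    for i in range(nH - 1, -1, -1):
        dh = dh * (dhs[i + 1] > 0)
        g[f"Wd{i}"] = dhs[i].T @ dh
        g[f"bd{i}"] = dh.sum(axis=0)
        dh = dh @ p[f"Wd{i}"].T
    dz = dh

    # through reparameterization + KL
    dmu = dz + kl_weight * mu / B
    dlv = dz * eps * std * 0.5 + kl_weight * 0.5 * (np.exp(lv) - 1.0) / B

    g["Wmu"] = ehs[-1].T @ dmu
    g["bmu"] = dmu.sum(axis=0)
    g["Wlv"] = ehs[-1].T @ dlv
    g["blv"] = dlv.sum(axis=0)
    dh = dmu @ p["Wmu"].T + dlv @ p["Wlv"].T
    for i in range(nH - 1, -1, -1):
        dh = dh * (ehs[i + 1] > 0)
        g[f"We{i}"] = ehs[i].T @ dh
        g[f"be{i}"] = dh.sum(axis=0)
        dh = dh @ p[f"We{i}"].T

    return loss, float(recon), float(kl), g


def train_vae(patterns: PatternSet | np.ndarray, spec: VaeSpec,
              cfg: TrainConfig | None = None) -> TrainedVae:
    """Train on the pattern set's training rows; returns the trained model.

    With ``epochs = 0`` the model is returned with freshly initialised,
    un-updated weights and an empty loss history.
    """
    cfg = cfg or TrainConfig()
    if isinstance(patterns, PatternSet):
        X = patterns.train
        mean, sd = patterns.mean, patterns.sd
    else:
        X = np.asarray(patterns, dtype=float)
        mean = sd = None
    if X.shape[1] != spec.input_dim:
        raise ValueError(
            f"patterns have {X.shape[1]} regions, spec expects {spec.input_dim}"
        )
    rng = np.random.default_rng(cfg.seed)
    p = _init_params(spec, rng)
    vae = TrainedVae(spec=spec, params=p, mean=mean, sd=sd)
    if cfg.epochs == 0:
        return vae

    # Adam state
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(v_) for k, v_ in p.items()}
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    t = 0
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_recon = ep_kl = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            xb = X[order[start:start + cfg.batch_size]]
            eps = rng.standard_normal((xb.shape[0], spec.latent_dim))
            loss, recon, kl, g = _loss_and_grads(p, spec, xb, eps,
                                                 spec.kl_weight)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            t += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - b2**t) / (1 - b1**t)
            for k in p:
                m[k] = b1 * m[k] + (1 - b1) * g[k]
                v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
                p[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps_adam)
            ep_recon += recon
            ep_kl += kl
            n_batches += 1
        vae.loss_history.append((ep_recon / n_batches, ep_kl / n_batches))
    return vae


def encode(vae: TrainedVae, patterns: np.ndarray, sample: bool = False,
           seed: int = 0) -> np.ndarray:
    """Latent codes (posterior means mu) of ``K x N`` patterns.

    ``sample=True`` draws one reparameterized sample per row instead of
    returning the mean.
    """
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2 or x.shape[1] != vae.spec.input_dim:
        raise ValueError(
            f"patterns must be K x {vae.spec.input_dim}, got {x.shape}"
        )
    if x.shape[0] == 0:
        return np.empty((0, vae.spec.latent_dim))
    _, mu, lv = _encode_forward(vae.params, vae.spec, x)
    if not sample:
        return mu
    rng = np.random.default_rng(seed)
    return mu + np.exp(0.5 * lv) * rng.standard_normal(mu.shape)


def decode(vae: TrainedVae, latent: np.ndarray,
           unnormalize: bool = False) -> np.ndarray:
    """Reconstructed patterns for ``K x M`` latent codes.

    Output lives in the (normalized) training space unless ``unnormalize``
    maps it back through the stored per-region mean/SD.
    """
    z = np.asarray(latent, dtype=float)
    if z.ndim != 2 or z.shape[1] != vae.spec.latent_dim:
        raise ValueError(
            f"latent must be K x {vae.spec.latent_dim}, got {z.shape}"
        )
    if z.shape[0] == 0:
        return np.empty((0, vae.spec.input_dim))
    _, xhat = _decode_forward(vae.params, vae.spec, z)
    if unnormalize and vae.mean is not None:
        xhat = xhat * vae.sd + vae.mean
    return xhat


def reconstruction_mse(vae: TrainedVae, x: np.ndarray) -> float:
    """Per-entry mean squared deterministic reconstruction error."""
    x = np.asarray(x, dtype=float)
    xhat = decode(vae, encode(vae, x))
    return float(np.mean((xhat - x) ** 2))


@dataclass
class DimScanResult:
    """Reconstruction error across latent dimensions and the chosen elbow."""

    dims: list[int]
    errors: list[float]
    derivative: list[float]
    elbow: int
    failures: list = field(default_factory=list)


def scan_latent_dims(
    patterns: PatternSet,
    dims: list[int] | None = None,
    cfg: TrainConfig | None = None,
    kl_weight: float = 1.0,
    elbow_fraction: float = 0.1,
    n_restarts: int = 1,
) -> DimScanResult:
    """Train one VAE per latent dimension and locate the error elbow.

    The elbow is the smallest dimension whose outgoing error decrement has
    magnitude below ``elbow_fraction`` of the initial decrement; if none
    qualifies, the largest scanned dimension is returned.  Per-dimension
    failures are recorded and skipped.

    Two safeguards address the nonconvexity of VAE training, whose
    seed-to-seed error variance can otherwise swamp the decrement signal:
    ``n_restarts`` trains each dimension from several seeds and keeps the
    best held-out error, and the elbow is computed on the running-minimum
    envelope of the error curve, since the true attainable reconstruction
    error cannot increase with dimension (any observed increase is
    training noise).
    """
    dims = sorted(dims) if dims else list(range(5, 13))
    if not dims:
        raise ValueError("dims must be nonempty")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    cfg = cfg or TrainConfig()
    errors: list[float] = []
    ok_dims: list[int] = []
    failures = []
    test = patterns.test if isinstance(patterns, PatternSet) else None
    for d in dims:
        best = np.inf
        err_msgs = []
        for restart in range(n_restarts):
            try:
                r_cfg = replace(cfg, seed=cfg.seed + 9973 * restart)
                vae = train_vae(patterns, VaeSpec(
                    input_dim=patterns.n_regions, latent_dim=d,
                    kl_weight=kl_weight), r_cfg)
                eval_x = (test if test is not None and len(test)
                          else patterns.train)
                best = min(best, reconstruction_mse(vae, eval_x))
            except Exception as exc:  # noqa: BLE001 - partial result contract
                err_msgs.append(repr(exc))
        if np.isfinite(best):
            errors.append(best)
            ok_dims.append(d)
        else:
            failures.append((d, "; ".join(err_msgs)))
    if not ok_dims:
        raise TrainingError(f"all dimensions failed: {failures}")

    envelope = np.minimum.accumulate(errors)
    deriv = list(np.diff(envelope))
    if not deriv:
        elbow = ok_dims[0]
    else:
        initial = abs(deriv[0])
        elbow = ok_dims[-1]
        for i, d in enumerate(deriv):
            if abs(d) <= elbow_fraction * initial:
                elbow = ok_dims[i]
                break
    return DimScanResult(dims=ok_dims, errors=errors, derivative=deriv,
                         elbow=elbow, failures=failures)
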