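"""Coupled Stuart-Landau (Hopf normal form) dynamics in latent space.

Each latent mode *j* follows the normal form of a supercritical Hopf
bifurcation, diffusively coupled to the other modes through a directed
matrix ``C``::

    dz_j/dt = (a_j + i w_j - |z_j|^2) z_j + sum_k C[j, k] (z_k - z_j) + eta_j

``z_j = x_j + i y_j`` is the complex state, ``a_j`` the bifurcation
parameter (self-sustained oscillation for ``a > 0``, damped fixed point for
``a < 0``), ``w_j`` the intrinsic angular frequency, and ``eta_j`` additive
complex Gaussian noise of standard deviation ``sigma`` per component.
``C[j, k]`` is the influence of mode *k* on mode *j*; its diagonal is zero
(self-influence lives in ``a_j``).

Integration is Euler-Maruyama with a fixed step ``dt``; the observable is
``x = Re(z)`` sampled every ``t_sample`` seconds after a discarded
transient.  The integrator core is numba-compiled and consumes noise drawn
beforehand from a seeded generator, so trajectories are exactly reproducible per
backend; a pure-numpy path (``backend="numpy"``) computes the same scheme
(identical up to floating-point association order) and serves as a
cross-check.

Euler discretization note: the explicit step amplifies the rotation
(|1 + i w dt| > 1), which biases the limit-cycle radius by ~``dt w^2 / 2``
in the effective bifurcation parameter.  This is immaterial when generator
and fitted model share the same ``dt``, but quantitative amplitude checks
should use a small step (``dt <= 0.01`` keeps the radius within 1%% for the
0.008-0.08 Hz band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal as _signal


class IntegrationError(RuntimeError):
    """Raised when the trajectory blows up (suggests a smaller dt)."""


@dataclass
class HopfSystem:
    """Parameters of the coupled Stuart-Landau system.

    ``a``/``omega`` are per-mode vectors (``omega`` in rad/s), ``sigma`` the
    per-component noise SD, ``C`` the ``M x M`` directed coupling matrix
    with zero diagonal (``C[j, k]`` = influence of k on j).
    """

    a: np.ndarray
    omega: np.ndarray
    sigma: float = 0.01
    C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.a.shape != self.omega.shape:
            raise ValueError("a and omega must have the same length")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        M = self.a.shape[0]
        if self.C is None:
            self.C = np.zeros((M, M))
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (M, M):
            raise ValueError(f"C must be {M}x{M}, got {self.C.shape}")
        self.C = self.C.copy()
        np.fill_diagonal(self.C, 0.0)

    @property
    def n_modes(self) -> int:
        return self.a.shape[0]

    def with_coupling(self, C: np.ndarray) -> "HopfSystem":
        return HopfSystem(a=self.a, omega=self.omega, sigma=self.sigma, C=C)


@dataclass
class SimConfig:
    """Integration / sampling configuration.

    ``dt`` is the Euler-Maruyama step (s), ``t_sample`` the observation
    period (normally the TR), ``n_samples`` the number of output frames and
    ``transient_s`` the discarded warm-up.
    """

    t_sample: float
    n_samples: int
    dt: float = 0.1
    transient_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_sample <= 0:
            raise ValueError("dt and t_sample must be positive")
        if self.dt > self.t_sample:
            raise ValueError(f"dt={self.dt} must not exceed t_sample={self.t_sample}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.transient_s < 0:
            raise ValueError("transient_s must be >= 0")


@dataclass
class SimulatedTrajectory:
    """Sampled real parts ``x`` (``T x M``) and the final complex state."""

    x: np.ndarray
    z_final: np.ndarray
    t_sample: float = 0.0


@njit(cache=True)
def _em_core(zr, zi, a, om, C, noise, dt, keep_idx, out):  # pragma: no cover
    """Euler-Maruyama over `steps`; records Re(z) at keep_idx steps.

    zr/zi: (R, M) initial state, modified in place.
    noise: (steps, R, M, 2) pre-scaled increments.
    out:   (R, n_keep, M).
    Returns 1 on blow-up (|z| > 1e6), else 0.
    """
    R, M = zr.shape
    steps = noise.shape[0]
    ki = 0
    fr_buf = np.empty(M)
    fi_buf = np.empty(M)
    for s in range(steps):
        for r in range(R):
            # derivatives from the pre-step state for every mode
            for j in range(M):
                cr = 0.0
                ci = 0.0
                for k in range(M):
                    cjk = C[j, k]
                    if cjk != 0.0:
                        cr += cjk * (zr[r, k] - zr[r, j])
                        ci += cjk * (zi[r, k] - zi[r, j])
                x = zr[r, j]
                y = zi[r, j]
                r2 = x * x + y * y
                fr_buf[j] = (a[j] - r2) * x - om[j] * y + cr
                fi_buf[j] = (a[j] - r2) * y + om[j] * x + ci
            for j in range(M):
                zr[r, j] += dt * fr_buf[j] + noise[s, r, j, 0]
                zi[r, j] += dt * fi_buf[j] + noise[s, r, j, 1]
                if abs(zr[r, j]) > 1e6 or abs(zi[r, j]) > 1e6:
                    return 1
        if ki < keep_idx.shape[0] and s == keep_idx[ki]:
            for r in range(R):
                for j in range(M):
                    out[r, ki, j] = zr[r, j]
            ki += 1
    return 0


def _em_core_numpy(zr, zi, a, om, C, noise, dt, keep_idx, out):
    """Pure-numpy twin of :func:`_em_core` (same discretization; trajectories
    agree up to floating-point association order)."""
    steps = noise.shape[0]
    ki = 0
    row_strength = C.sum(axis=1)
    for s in range(steps):
        cr = zr @ C.T - zr * row_strength
        ci = zi @ C.T - zi * row_strength
        r2 = zr * zr + zi * zi
        fr = (a - r2) * zr - om * zi + cr
        fi = (a - r2) * zi + om * zr + ci
        zr += dt * fr + noise[s, :, :, 0]
        zi += dt * fi + noise[s, :, :, 1]
        if np.abs(zr).max() > 1e6 or np.abs(zi).max() > 1e6:
            return 1
        if ki < keep_idx.shape[0] and s == keep_idx[ki]:
            out[:, ki, :] = zr
            ki += 1
    return 0


def simulate_hopf_ensemble(
    system: HopfSystem,
    cfg: SimConfig,
    n_realizations: int = 1,
    rng: np.random.Generator | None = None,
    z0: np.ndarray | None = None,
    backend: str = "numba",
    return_final: bool = False,
):
    """Integrate ``n_realizations`` independent trajectories in one pass.

    Returns the sampled real parts with shape ``(R, n_samples, M)``; with
    ``return_final`` also the final complex states ``(R, M)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    M = system.n_modes
    R = n_realizations
    n_tr = int(round(cfg.transient_s / cfg.dt))
    keep_idx = n_tr + np.round(
        np.arange(cfg.n_samples) * cfg.t_sample / cfg.dt
    ).astype(np.int64)
    steps = int(keep_idx[-1]) + 1

    noise = rng.standard_normal((steps, R, M, 2))
    noise *= system.sigma * np.sqrt(cfg.dt)
    if z0 is None:
        z = rng.standard_normal((R, M, 2)) * 0.1
        zr, zi = np.ascontiguousarray(z[:, :, 0]), np.ascontiguousarray(z[:, :, 1])
    else:
        z0 = np.asarray(z0, dtype=complex)
        zr = np.broadcast_to(z0.real, (R, M)).astype(float).copy()
        zi = np.broadcast_to(z0.imag, (R, M)).astype(float).copy()

    out = np.empty((R, cfg.n_samples, M))
    core = _em_core if backend == "numba" else _em_core_numpy
    status = core(zr, zi, system.a, system.omega, system.C, noise,
                  cfg.dt, keep_idx, out)
    if status:
        raise IntegrationError(
            "trajectory exceeded |z| = 1e6; try a smaller dt or weaker coupling"
        )
    if return_final:
        return out, zr + 1j * zi
    return out


def simulate_hopf(
    system: HopfSystem,
    cfg: SimConfig,
    z0: np.ndarray | None = None,
    backend: str = "numba",
) -> SimulatedTrajectory:
    """Integrate one trajectory; see module docstring for the model."""
    x, z_final = simulate_hopf_ensemble(system, cfg, 1, z0=z0,
                                        backend=backend, return_final=True)
    return SimulatedTrajectory(x=x[0], z_final=z_final[0],
                               t_sample=cfg.t_sample)


def estimate_intrinsic_frequencies(
    latents: list[np.ndarray],
    tr_seconds: float,
    band: tuple[float, float] = (0.008, 0.08),
) -> np.ndarray:
    """Per-mode intrinsic frequency (Hz): subject-averaged spectral peak.

    For each recording and mode the periodogram peak within ``band`` is
    located; the estimates are averaged across recordings.  Signals are
    assumed already band-limited; a short recording (under two cycles of the
    band's low edge) triggers a resolution warning.
    """
    import warnings

    latents = [np.asarray(x, dtype=float) for x in latents]
    if not latents:
        raise ValueError("no trajectories given")
    M = latents[0].shape[1]
    for x in latents:
        if x.shape[1] != M:
            raise ValueError("trajectories disagree on the number of modes")

    fs = 1.0 / tr_seconds
    peaks = np.zeros((len(latents), M))
    for s, x in enumerate(latents):
        T = x.shape[0]
        if T * tr_seconds < 2.0 / band[0]:
            warnings.warn(
                f"recording {s} shorter than two cycles of {band[0]} Hz; "
                "spectral resolution is coarse", stacklevel=2,
            )
        freqs, pxx = _signal.periodogram(x, fs=fs, axis=0, detrend="constant")
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        if not in_band.any():
            in_band = freqs > 0
        fb = freqs[in_band]
        peaks[s] = fb[np.argmax(pxx[in_band], axis=0)]
    return peaks.mean(axis=0)
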