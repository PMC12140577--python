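"""Connectivity observables: zero-lag FC, forward-shifted FCf(tau), and helpers.

FC is the matrix of pairwise Pearson correlations between signals; FCf(tau)
correlates each signal with every signal shifted *forward* by tau frames.
The orientation convention is fixed throughout the package: the row index of
FCf is the earlier signal, the column the later one, i.e.
``FCf[i, j] = corr(x_i[0:T-tau], x_j[tau:T])``.  A large ``FCf[i, j]``
therefore means mode *i* leads mode *j*.  Asymmetry of FCf is the signature
of temporal irreversibility (broken detailed balance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConstantSignalError(ValueError):
    """Raised when a Pearson correlation is undefined due to zero variance."""


def _as_array(m) -> np.ndarray:
    """Accept plain arrays or Fc/Fcf wrapper objects."""
    return np.asarray(getattr(m, "values", m), dtype=float)


@dataclass
class FcMatrix:
    """Symmetric zero-lag Pearson correlation matrix with provenance tags."""

    values: np.ndarray
    space_tag: str = "latent"     # latent | source
    source_tag: str = "empirical"  # empirical | model


@dataclass
class FcfMatrix:
    """Forward-shifted correlation matrix; row = earlier, column = later."""

    values: np.ndarray
    tau: int = 3
    space_tag: str = "latent"
    source_tag: str = "empirical"


def _check_columns(x: np.ndarray) -> None:
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ConstantSignalError(
            f"constant column(s) {bad.tolist()}: correlation undefined"
        )


def compute_fc(x: np.ndarray, space_tag: str = "latent",
               source_tag: str = "empirical") -> FcMatrix:
    """Pairwise Pearson correlation between columns of a ``T x M`` matrix."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError(f"need a T x M matrix with T >= 3, got shape {x.shape}")
    _check_columns(x)
    fc = np.corrcoef(x, rowvar=False)
    fc = np.atleast_2d(fc)
    np.fill_diagonal(fc, 1.0)
    return FcMatrix(values=fc, space_tag=space_tag, source_tag=source_tag)


def compute_fcf(x: np.ndarray, tau: int = 3, space_tag: str = "latent",
                source_tag: str = "empirical") -> FcfMatrix:
    """Forward-shifted correlation: ``FCf[i, j] = corr(x_i[:-tau], x_j[tau:])``.

    With ``tau = 0`` this reduces entrywise to :func:`compute_fc`.
    """
    x = np.asarray(x, dtype=float)
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    T = x.shape[0]
    if T <= tau + 2:
        raise ValueError(f"need T > tau + 2, got T={T}, tau={tau}")
    a = x[: T - tau] if tau else x
    b = x[tau:]
    _check_columns(a)
    _check_columns(b)
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    num = am.T @ bm
    den = np.outer(
        np.sqrt((am ** 2).sum(axis=0)), np.sqrt((bm ** 2).sum(axis=0))
    )
    vals = num / den
    return FcfMatrix(values=vals, tau=tau, space_tag=space_tag,
                     source_tag=source_tag)


def offdiag(m) -> np.ndarray:
    """Flatten the off-diagonal entries of a square matrix (row-major)."""
    a = _as_array(m)
    mask = ~np.eye(a.shape[0], dtype=bool)
    return a[mask]


def matrix_similarity(A, B) -> float:
    """Pearson correlation between the off-diagonal entries of two matrices.

    The unit diagonal of correlation matrices is excluded so it cannot
    inflate the similarity.
    """
    a, b = _as_array(A), _as_array(B)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"need same-shape square matrices, got {a.shape}, {b.shape}")
    va, vb = offdiag(a), offdiag(b)
    if va.std() == 0 or vb.std() == 0:
        raise ConstantSignalError("constant off-diagonal entries: similarity undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def group_average(mats: list, group_size: int, seed: int = 0) -> list[np.ndarray]:
    """Average random disjoint subgroups of matrices (remainder dropped).

    Subject-level observables are pooled into subgroup means before model
    fitting; the subgroup assignment is a seeded shuffle without replacement.
    """
    if not mats:
        raise ValueError("no matrices given")
    if group_size < 1 or len(mats) < group_size:
        raise ValueError(
            f"group_size {group_size} invalid for {len(mats)} matrices"
        )
    arrs = [_as_array(m) for m in mats]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(arrs))
    n_groups = len(arrs) // group_size
    out = []
    for g in range(n_groups):
        idx = order[g * group_size: (g + 1) * group_size]
        out.append(np.mean([arrs[i] for i in idx], axis=0))
    return out


def asymmetry_index(C, eps: float = 1e-12) -> float:
    """Normalised asymmetry ``||C - C^T||_F / (||C + C^T||_F + eps)``.

    Zero for symmetric matrices; large (>= 1e6 order) for purely
    antisymmetric ones.  Used to quantify how far a coupling matrix departs
    from detailed balance.
    """
    a = _as_array(C)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"need a square matrix, got shape {a.shape}")
    num = np.linalg.norm(a - a.T)
    den = np.linalg.norm(a + a.T) + eps
    return float(num / den)
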