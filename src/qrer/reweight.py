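"""Simplex weights and weighted balance statistics.

A weight vector carries one flat-Dirichlet-style simplex per arm: W1 over the
N1 treated units and W0 over the N0 controls, each summing to one.  The
weighted covariate mean difference

    Delta(W) = sum_i W_i T_i X_i - sum_i W_i (1 - T_i) X_i

generalizes the arm mean difference (uniform weights recover it), and the
weighted Mahalanobis distance plugs weighted mean/covariance estimators into
the rerandomization distance so that uniform weights reproduce D(X, T)
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CovariateMatrix

SIMPLEX_TOL = 1e-10


@dataclass
class WeightVector:
    """Per-arm simplex weights aligned to the canonical unit ordering."""

    w1: np.ndarray
    w0: np.ndarray

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w0 = np.asarray(self.w0, dtype=float)
        for name, w in (("w1", self.w1), ("w0", self.w0)):
            if w.ndim != 1 or w.size < 1:
                raise ValueError(f"{name} must be a nonempty 1-D array")
            if np.any(w < 0):
                raise ValueError(f"{name} has negative entries")
            if abs(w.sum() - 1.0) > SIMPLEX_TOL:
                raise ValueError(f"{name} sums to {w.sum():.12g}, not 1")

    @property
    def full(self) -> np.ndarray:
        """Concatenated (W1, W0) in canonical order."""
        return np.concatenate([self.w1, self.w0])

    @classmethod
    def uniform(cls, N1: int, N0: int) -> "WeightVector":
        return cls(np.full(N1, 1.0 / N1), np.full(N0, 1.0 / N0))

    @classmethod
    def renormalized(cls, w1, w0) -> "WeightVector":
        """Build from nonnegative raw weights, rescaling each arm to sum 1.

        Renormalization is deliberately opt-in: weights that should already
        be on the simplex are validated strictly so bugs surface.
        """
        w1 = np.asarray(w1, dtype=float)
        w0 = np.asarray(w0, dtype=float)
        if w1.sum() <= 0 or w0.sum() <= 0:
            raise ValueError("arm weights must have positive sums")
        return cls(w1 / w1.sum(), w0 / w0.sum())


@dataclass
class WeightedBalance:
    """Weighted mean difference, reweighted vector W*, and distance."""

    delta: np.ndarray
    D_w: float
    wstar: np.ndarray


def sample_dirichlet_weights(N1: int, N0: int,
                             rng: np.random.Generator) -> WeightVector:
    """One draw of independent flat Dirichlet weights for the two arms."""
    if N1 < 1 or N0 < 1:
        raise ValueError("N1 and N0 must be >= 1")
    w1, w0 = sample_dirichlet_batch(1, N1, N0, rng)
    return WeightVector(w1[0], w0[0])


def sample_dirichlet_batch(n: int, N1: int, N0: int, rng: np.random.Generator,
                           dtype=np.float64):
    """n independent draws per arm; returns arrays (n, N1) and (n, N0).

    Flat Dirichlet via normalized standard exponentials.
    """
    e1 = rng.standard_exponential((n, N1), dtype=dtype)
    e0 = rng.standard_exponential((n, N0), dtype=dtype)
    e1 /= e1.sum(axis=1, keepdims=True)
    e0 /= e0.sum(axis=1, keepdims=True)
    return e1, e0


def weighted_mean_difference(cov: CovariateMatrix, W: WeightVector) -> np.ndarray:
    """Delta(W): weighted treated mean minus weighted control mean."""
    if W.w1.size != cov.N1 or W.w0.size != cov.N0:
        raise ValueError("weight vector does not match the group sizes")
    return W.w1 @ cov.X1 - W.w0 @ cov.X0


def delta_batch(cov: CovariateMatrix, w1: np.ndarray, w0: np.ndarray) -> np.ndarray:
    """Delta(W) for stacked weights: (n, N1) and (n, N0) -> (n, d)."""
    return w1 @ cov.X1 - w0 @ cov.X0


def reweighted_vector(cov: CovariateMatrix, W: WeightVector) -> np.ndarray:
    """W*_i = {N1 T_i + N0 (1 - T_i)} W_i / N; sums to one overall."""
    return np.concatenate([cov.N1 * W.w1, cov.N0 * W.w0]) / cov.N


def weighted_mahalanobis(cov: CovariateMatrix, W: WeightVector) -> WeightedBalance:
    """Weighted Mahalanobis distance D(X, W).

    Uses the weighted covariance
    ``cov_W(X) = sum_i W*_i (X_i - Xbar_W)(X_i - Xbar_W)' / (1 - sum_i W*_i^2)``
    with ``Xbar_W = sum_i W*_i X_i``; uniform weights give back the sample
    covariance (N-1 denominator) and the unweighted distance exactly.
    """
    delta = weighted_mean_difference(cov, W)
    wstar = reweighted_vector(cov, W)
    denom = 1.0 - wstar @ wstar
    if denom <= 0:
        raise ValueError("degenerate weights: sum of squared W* reaches 1")
    xbar = wstar @ cov.X
    Xc = cov.X - xbar
    S = (Xc.T * wstar) @ Xc / denom
    try:
        sol = np.linalg.solve(S, delta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("weighted covariance is singular") from exc
    D_w = float(cov.N1 * cov.N0 / cov.N * delta @ sol)
    return WeightedBalance(delta=delta, D_w=D_w, wstar=wstar)


def weighted_mahalanobis_batch(cov: CovariateMatrix, w1: np.ndarray,
                               w0: np.ndarray) -> np.ndarray:
    """D(X, W) for stacked weight batches -> (n,) distances."""
    n = w1.shape[0]
    deltas = delta_batch(cov, w1, w0)                       # (n, d)
    wstar = np.concatenate([cov.N1 * w1, cov.N0 * w0], axis=1) / cov.N
    denom = 1.0 - np.einsum("ni,ni->n", wstar, wstar)
    if np.any(denom <= 0):
        raise ValueError("degenerate weights in batch")
    xbar = wstar @ cov.X                                    # (n, d)
    # sum_i W*_i X_i X_i' - xbar xbar'
    M2 = np.einsum("ni,ij,ik->njk", wstar, cov.X, cov.X, optimize=True)
    S = (M2 - xbar[:, :, None] * xbar[:, None, :]) / denom[:, None, None]
    sol = np.linalg.solve(S, deltas[:, :, None])[:, :, 0]   # (n, d)
    return cov.N1 * cov.N0 / cov.N * np.einsum("nd,nd->n", deltas, sol)
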