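"""Rerandomization: constrained allocation sampling and Mahalanobis screening.

Complete randomization (CR) draws a binary allocation with the treated group
size fixed at N1.  Rerandomization (ReR) keeps only those CR draws whose
Mahalanobis distance between arm covariate means,

    D(X, T) = (N1 N0 / N) * Delta' cov(X)^{-1} Delta,   Delta = X1bar - X0bar,

falls below a threshold ``a`` chosen so that a fraction ``p_a`` of CR draws
is accepted.  D is asymptotically chi-squared with d degrees of freedom, so
``a`` is the ``p_a`` quantile of chi2_d; ``p_a = 1`` recovers CR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import stats

from .data import CovariateMatrix

# accept/reject sampling guard: if fewer than ACCEPT_FLOOR of the first
# PROBE_DRAWS raw draws pass, rerandomization is declared infeasible
ACCEPT_FLOOR = 1e-4
PROBE_DRAWS = 50_000
_CHUNK = 4096


@dataclass
class Allocation:
    """A candidate allocation with its Mahalanobis distance."""

    T_tilde: np.ndarray
    D: float
    accepted: Optional[bool] = None


@dataclass
class RerandSpec:
    """Acceptance probability, derived threshold, and pool size."""

    p_a: float
    B: int = 1000
    a: float = field(default=None)

    def __post_init__(self):
        if not (0 < self.p_a <= 1):
            raise ValueError("p_a must lie in (0, 1]")
        if self.B < 1:
            raise ValueError("pool size B must be positive")

    def threshold(self, d: int) -> float:
        if self.a is None:
            self.a = chi2_threshold(d, self.p_a)
        return self.a


def chi2_threshold(d: int, p_a: float) -> float:
    """Threshold ``a`` solving P(chi2_d <= a) = p_a; +inf when p_a = 1."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if not (0 < p_a <= 1):
        raise ValueError("p_a must lie in (0, 1]")
    if p_a == 1:
        return np.inf
    return float(stats.chi2.ppf(p_a, df=d))


def _delta(cov: CovariateMatrix, T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    xbar1 = T @ cov.X / cov.N1
    xbar0 = (1.0 - T) @ cov.X / cov.N0
    return xbar1 - xbar0


def mahalanobis_distance(cov: CovariateMatrix, T: np.ndarray) -> float:
    """Mahalanobis distance of the arm mean difference under allocation T."""
    T = np.asarray(T)
    if int(np.sum(T)) != cov.N1:
        raise ValueError(f"allocation must have exactly N1={cov.N1} ones")
    delta = _delta(cov, T)
    return float(cov.N1 * cov.N0 / cov.N * delta @ cov.cov_solve(delta))


def _mahalanobis_batch(cov: CovariateMatrix, A: np.ndarray) -> np.ndarray:
    """Distances for a stack of allocations, rows of A (n, N)."""
    S1 = A @ cov.X                      # (n, d) treated sums
    colsum = cov.X.sum(axis=0)
    deltas = S1 / cov.N1 - (colsum - S1) / cov.N0
    sol = cov.cov_solve(deltas.T)       # (d, n)
    return cov.N1 * cov.N0 / cov.N * np.einsum("nd,dn->n", deltas, sol)


def sample_cr_allocation(cov: CovariateMatrix, rng: np.random.Generator) -> Allocation:
    """One uniform draw over the C(N, N1) constrained allocations."""
    if not (1 <= cov.N1 <= cov.N - 1):
        raise ValueError("N1 must lie in [1, N-1]")
    T = rng.permutation(cov.T_obs)
    return Allocation(T_tilde=T, D=mahalanobis_distance(cov, T))


def rerandomize_pool(cov: CovariateMatrix, spec: RerandSpec,
                     rng: np.random.Generator) -> List[Allocation]:
    """Accept/reject sample ``spec.B`` allocations with D <= a."""
    A1, D = rerandomize_pool_arrays(cov, spec, rng)
    return [Allocation(T_tilde=A1[i], D=float(D[i]), accepted=True)
            for i in range(spec.B)]


def rerandomize_pool_arrays(cov: CovariateMatrix, spec: RerandSpec,
                            rng: np.random.Generator):
    """Vectorized pool sampler returning (allocations (B, N) int8, D (B,))."""
    a = spec.threshold(cov.d)
    template = cov.T_obs.astype(np.int8)
    # expected raw draws ~ B / p_a; cap the per-round batch
    chunk_size = int(min(_CHUNK, max(64, np.ceil(1.5 * spec.B / spec.p_a))))
    keep_T, keep_D = [], []
    n_raw = n_acc = 0
    while n_acc < spec.B:
        chunk = np.tile(template, (chunk_size, 1))
        chunk = rng.permuted(chunk, axis=1)
        D = _mahalanobis_batch(cov, chunk)
        mask = D <= a
        keep_T.append(chunk[mask])
        keep_D.append(D[mask])
        n_raw += chunk_size
        n_acc += int(mask.sum())
        if n_raw >= PROBE_DRAWS and n_acc / n_raw < ACCEPT_FLOOR:
            raise RuntimeError(
                f"acceptance rate {n_acc / n_raw:.2e} below {ACCEPT_FLOOR:g} "
                f"after {n_raw} draws; increase p_a"
            )
    T_all = np.concatenate(keep_T)[: spec.B]
    D_all = np.concatenate(keep_D)[: spec.B]
    return T_all, D_all
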