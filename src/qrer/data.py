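"""Covariate data container used throughout the package.

The container keeps the covariate matrix together with the observed binary
treatment allocation and the group sizes, and fixes the *canonical ordering*
convention used internally everywhere: treated units come first, controls
second.  The permutation mapping the user's row order to the canonical order
is stored so results can be reported in the original order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve


class SingularCovarianceError(np.linalg.LinAlgError):
    """Sample covariance of the covariates is not invertible."""


@dataclass
class CovariateMatrix:
    """N x d covariate matrix with a fixed observed allocation.

    Parameters
    ----------
    X : ndarray of shape (N, d)
        Covariates in canonical order (treated rows first).
    N1, N0 : int
        Treated / control group sizes, ``N1 + N0 == N``.
    permutation : ndarray of shape (N,)
        ``permutation[i]`` is the original row index of canonical row ``i``.
    ridge : float, default 0.0
        Optional ridge ``ridge * I`` added to the sample covariance before
        factorization.  Zero by default: a singular covariance is an error,
        never a silent pseudo-inverse.
    """

    X: np.ndarray
    N1: int
    N0: int
    permutation: np.ndarray
    ridge: float = 0.0
    _chol: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        if self.N1 + self.N0 != self.N:
            raise ValueError("N1 + N0 must equal the number of rows of X")
        if self.N1 < 2 or self.N0 < 2:
            raise ValueError("need at least two units per arm (N1, N0 >= 2)")

    # -- construction ----------------------------------------------------

    @classmethod
    def from_arrays(cls, X, T, ridge: float = 0.0) -> "CovariateMatrix":
        """Build from covariates and a binary allocation in any row order."""
        X = np.asarray(X, dtype=float)
        T = np.asarray(T)
        if set(np.unique(T)) - {0, 1}:
            raise ValueError("treatment vector must be binary {0,1}")
        T = T.astype(int)
        if T.shape[0] != X.shape[0]:
            raise ValueError("X and T have different lengths")
        perm = np.concatenate([np.flatnonzero(T == 1), np.flatnonzero(T == 0)])
        return cls(X=X[perm], N1=int(T.sum()), N0=int((1 - T).sum()),
                   permutation=perm, ridge=ridge)

    # -- basic views ------------------------------------------------------

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def T_obs(self) -> np.ndarray:
        """Observed allocation in canonical order: (1,...,1,0,...,0)."""
        return np.concatenate([np.ones(self.N1, dtype=int),
                               np.zeros(self.N0, dtype=int)])

    @property
    def X1(self) -> np.ndarray:
        """Treated rows (canonical order)."""
        return self.X[: self.N1]

    @property
    def X0(self) -> np.ndarray:
        """Control rows (canonical order)."""
        return self.X[self.N1:]

    @property
    def pooled_mean(self) -> np.ndarray:
        return self.X.mean(axis=0)

    def to_original_order(self, values: np.ndarray) -> np.ndarray:
        """Re-order a per-unit vector from canonical back to input order."""
        out = np.empty_like(np.asarray(values))
        out[self.permutation] = values
        return out

    # -- covariance -------------------------------------------------------

    def sample_cov(self) -> np.ndarray:
        """Sample covariance of X with the N-1 denominator."""
        return np.cov(self.X, rowvar=False, ddof=1).reshape(self.d, self.d)

    def cov_factor(self):
        """Cached Cholesky factor of the (optionally ridged) covariance."""
        if self._chol is None:
            S = self.sample_cov()
            if self.ridge > 0:
                S = S + self.ridge * np.eye(self.d)
            try:
                object.__setattr__(self, "_chol", cho_factor(S, lower=True))
            except np.linalg.LinAlgError as exc:
                rank = np.linalg.matrix_rank(S)
                raise SingularCovarianceError(
                    f"sample covariance is singular (rank {rank} < d={self.d}); "
                    "remove collinear columns or set ridge > 0"
                ) from exc
        return self._chol

    def cov_solve(self, B: np.ndarray) -> np.ndarray:
        """Solve cov(X) @ Z = B using the cached factorization."""
        return cho_solve(self.cov_factor(), B)
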