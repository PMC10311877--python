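"""Weighted treatment-effect estimators and PATE inference.

The basic estimator is the weighted mean difference of observed outcomes,

    tau_hat(W, Y) = sum_i W_i T_i Y_i - sum_i W_i (1 - T_i) Y_i,

whose ensemble over M generated weight vectors equals, by linearity, the
same estimator applied to the averaged weight vector.  PATE inference fits a
weighted linear model of the outcome on the treatment indicator with case
weights proportional to the per-arm simplex weights (treated arm scaled by
N1, control by N0, so uniform weights reduce to ordinary least squares); the
point estimate reproduces the weighted mean difference exactly and the
standard error comes from a heteroskedasticity-robust sandwich.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm

from .data import CovariateMatrix
from .rerand import RerandSpec, rerandomize_pool_arrays
from .reweight import WeightVector


@dataclass
class EstimationResult:
    tau_hat: float
    estimator: str
    M: int = 1
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    level: float = 0.95

    def to_dict(self):
        return {"estimator": self.estimator, "tau_hat": self.tau_hat,
                "se": self.se, "ci": [self.ci_low, self.ci_high],
                "level": self.level, "M": self.M}


def _check_lengths(W: WeightVector, T_obs, Y_obs):
    T = np.asarray(T_obs)
    Y = np.asarray(Y_obs, dtype=float)
    if Y.shape[0] != T.shape[0]:
        raise ValueError("outcome and allocation lengths differ")
    if W.w1.size != int(T.sum()) or W.w0.size != int((1 - T).sum()):
        raise ValueError("weights do not match the allocation group sizes")
    return T, Y


def tau_hat(W: WeightVector, T_obs, Y_obs) -> float:
    """Weighted mean difference of observed outcomes under allocation T."""
    T, Y = _check_lengths(W, T_obs, Y_obs)
    return float(W.w1 @ Y[T == 1] - W.w0 @ Y[T == 0])


def average_weights(weight_list: Sequence[WeightVector]) -> WeightVector:
    """Elementwise mean of M weight vectors (still on the simplices)."""
    if len(weight_list) == 0:
        raise ValueError("empty weight list")
    w1 = np.mean([w.w1 for w in weight_list], axis=0)
    w0 = np.mean([w.w0 for w in weight_list], axis=0)
    return WeightVector(w1, w0)


def tau_ensemble(weight_list: Sequence[WeightVector], T_obs, Y_obs) -> float:
    """Mean of tau_hat over M weight vectors (= tau_hat of the mean vector)."""
    if len(weight_list) == 0:
        raise ValueError("empty weight list")
    return float(np.mean([tau_hat(w, T_obs, Y_obs) for w in weight_list]))


def pate_inference(W: WeightVector, T_obs, Y_obs, level: float = 0.95,
                   cov_type: str = "HC1") -> EstimationResult:
    """Weighted linear model inference for the population effect.

    Case weights are ``{N1 T_i + N0 (1 - T_i)} W_i`` so the point estimate
    equals ``tau_hat(W)`` and uniform weights give plain OLS.  ``cov_type``
    selects the sandwich flavor (HC0-HC3); the confidence interval uses
    normal quantiles.
    """
    T, Y = _check_lengths(W, T_obs, Y_obs)
    N1, N0 = W.w1.size, W.w0.size
    w = np.empty(T.shape[0], dtype=float)
    w[T == 1] = N1 * W.w1
    w[T == 0] = N0 * W.w0
    if (w[T == 1] > 0).sum() < 2 or (w[T == 0] > 0).sum() < 2:
        raise ValueError("need positive weight on >= 2 units per arm")
    exog = sm.add_constant(T.astype(float))
    fit = sm.WLS(Y, exog, weights=w).fit(cov_type=cov_type)
    est, se = float(fit.params[1]), float(fit.bse[1])
    z = stats.norm.ppf(0.5 + level / 2)
    return EstimationResult(tau_hat=est, estimator="PATE_WLS", se=se,
                            ci_low=est - z * se, ci_high=est + z * se,
                            level=level)


def rer_estimate(cov: CovariateMatrix, spec: RerandSpec,
                 Y_generator: Callable[[np.ndarray, np.random.Generator], np.ndarray],
                 rng: np.random.Generator) -> EstimationResult:
    """Rerandomization estimate: one accepted allocation, raw mean difference.

    ``Y_generator(T_tilde, rng)`` returns the responses observed under the
    accepted allocation (in canonical unit order); in simulation mode it
    regenerates outcomes from the potential-outcome model.
    """
    one = RerandSpec(p_a=spec.p_a, B=1, a=spec.a)
    allocs, _ = rerandomize_pool_arrays(cov, one, rng)
    T = allocs[0].astype(int)
    Y = np.asarray(Y_generator(T, rng), dtype=float)
    est = float(Y[T == 1].mean() - Y[T == 0].mean())
    return EstimationResult(tau_hat=est, estimator="ReR")
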