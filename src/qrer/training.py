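"""QReR training: the MMD + regularizer objective and the fitting loop.

The generator is trained so that the weighted covariate mean differences
Delta(W~) of transformed Dirichlet weights match, in distribution, the mean
differences Delta(T~) of accepted rerandomized allocations.  The objective is

    L(theta) = L_MMD + lambda1 * R1 + lambda2 * R2

with L_MMD the square root of the biased (V-statistic) maximum mean
discrepancy under an RBF kernel exp(-gamma ||x - y||^2), R1 penalizing the
departure of each weighted arm mean from the pooled covariate mean, and R2
penalizing departure of the weights from uniform.  The kernel bandwidth gamma
is updated adversarially: after each descent step on theta, one ascent step
on L_MMD with respect to log(gamma) on the same batch.

Early stopping monitors the two-sample Kolmogorov-Smirnov statistic between
the weighted Mahalanobis distances of transformed weights and the distances
of accepted allocations, on fixed held-out pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .data import CovariateMatrix
from .network import (Adam, GeneratorModel, build_generator,
                      initialize_identity)
from .rerand import RerandSpec, rerandomize_pool_arrays
from .reweight import (delta_batch, sample_dirichlet_batch,
                       weighted_mahalanobis_batch)


@dataclass
class TrainingConfig:
    """Hyper-parameters of the fitting procedure.

    Defaults are the reference settings used throughout the simulation
    study: batch sizes (B, B_init, B_stop, B_loss) = (512, 1000, 1000,
    10000), iteration counts (N_init, N_train, N_stop) = (500, 5000, 15),
    both regularization coefficients equal to 1, and Adam with default
    parameters.  ``eval_every`` sets the cadence (in iterations) of the
    early-stopping evaluation; the patience N_stop counts consecutive
    non-improving evaluations.
    """

    p_a: float = 0.1
    B: int = 512
    B_init: int = 1000
    B_stop: int = 1000
    B_loss: int = 10000
    N_init: int = 500
    N_train: int = 5000
    N_stop: int = 15
    lambda1: float = 1.0
    lambda2: float = 1.0
    eval_every: int = 100
    min_delta: float = 1e-4
    lr: float = 1e-3
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.p_a <= 1):
            raise ValueError("p_a must lie in (0, 1]")
        for name in ("B", "B_init", "B_stop", "B_loss",
                     "N_init", "N_train", "N_stop", "eval_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")

    def to_dict(self):
        return asdict(self)


@dataclass
class TrainingTrace:
    """Per-iteration loss components and the early-stopping trajectory."""

    iterations: List[int] = field(default_factory=list)
    mmd: List[float] = field(default_factory=list)
    r1: List[float] = field(default_factory=list)
    r2: List[float] = field(default_factory=list)
    gamma: List[float] = field(default_factory=list)
    eval_iterations: List[int] = field(default_factory=list)
    ks_metric: List[float] = field(default_factory=list)
    best_iteration: int = 0
    best_metric: float = np.inf
    initial_metric: float = np.inf

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({"iteration": self.iterations, "mmd": self.mmd,
                           "r1": self.r1, "r2": self.r2, "gamma": self.gamma})
        ks = pd.DataFrame({"iteration": self.eval_iterations,
                           "ks_metric": self.ks_metric})
        return df.merge(ks, on="iteration", how="left")


# ---------------------------------------------------------------------------
# loss components (float64 implementations; used directly by tests and by
# the float32 training loop below through the same formulas)
# ---------------------------------------------------------------------------

def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """exp(-gamma ||x - y||^2) for two vectors."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    diff = x - y
    return float(np.exp(-gamma * (diff @ diff)))


def _mmd_terms(deltas_W: np.ndarray, deltas_T: np.ndarray, gamma: float):
    Dww = cdist(deltas_W, deltas_W, "sqeuclidean")
    Dtt = cdist(deltas_T, deltas_T, "sqeuclidean")
    Dwt = cdist(deltas_W, deltas_T, "sqeuclidean")
    Kww = np.exp(-gamma * Dww)
    Ktt = np.exp(-gamma * Dtt)
    Kwt = np.exp(-gamma * Dwt)
    return (Dww, Dtt, Dwt), (Kww, Ktt, Kwt)


def mmd_loss(deltas_W: np.ndarray, deltas_T: np.ndarray, gamma: float) -> float:
    """Square-root V-statistic MMD between two samples of mean differences.

    All B^2 kernel terms (diagonals included) enter each double sum; the
    squared statistic is clamped at zero before the root.
    """
    deltas_W = np.atleast_2d(np.asarray(deltas_W, dtype=float))
    deltas_T = np.atleast_2d(np.asarray(deltas_T, dtype=float))
    if deltas_W.shape != deltas_T.shape:
        raise ValueError("the two delta samples must have the same shape")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    B = deltas_W.shape[0]
    _, (Kww, Ktt, Kwt) = _mmd_terms(deltas_W, deltas_T, gamma)
    sq = (Kww.sum() + Ktt.sum() - 2.0 * Kwt.sum()) / B**2
    return float(np.sqrt(max(sq, 0.0)))


def regularizer_balance(cov: CovariateMatrix, w1: np.ndarray,
                        w0: np.ndarray) -> float:
    """R1: batch-mean squared distance of each weighted arm mean from Xbar."""
    xbar = cov.pooled_mean
    m1 = w1 @ cov.X1 - xbar
    m0 = w0 @ cov.X0 - xbar
    B = np.atleast_2d(m1).shape[0]
    return float((np.sum(m1 * m1) + np.sum(m0 * m0)) / B)


def regularizer_dispersion(w1: np.ndarray, w0: np.ndarray) -> float:
    """R2: batch-mean squared distance of the weights from uniform."""
    w1 = np.atleast_2d(w1)
    w0 = np.atleast_2d(w0)
    B = w1.shape[0]
    d1 = w1 - 1.0 / w1.shape[1]
    d0 = w0 - 1.0 / w0.shape[1]
    return float((np.sum(d1 * d1) + np.sum(d0 * d0)) / B)


def total_loss(cov: CovariateMatrix, w1: np.ndarray, w0: np.ndarray,
               deltas_T: np.ndarray, gamma: float,
               lambda1: float = 1.0, lambda2: float = 1.0) -> float:
    """L_MMD + lambda1 R1 + lambda2 R2 for a batch of transformed weights."""
    deltas_W = delta_batch(cov, np.atleast_2d(w1), np.atleast_2d(w0))
    return (mmd_loss(deltas_W, deltas_T, gamma)
            + lambda1 * regularizer_balance(cov, w1, w0)
            + lambda2 * regularizer_dispersion(w1, w0))


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_t |F_a(t) - F_b(t)|."""
    sample_a = np.asarray(sample_a, dtype=float).ravel()
    sample_b = np.asarray(sample_b, dtype=float).ravel()
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("samples must be nonempty")
    return float(stats.ks_2samp(sample_a, sample_b).statistic)


def median_heuristic_gamma(deltas: np.ndarray) -> float:
    """gamma_0 = 1 / median(||x_i - x_j||^2) over distinct sample pairs."""
    D = cdist(deltas, deltas, "sqeuclidean")
    off = D[np.triu_indices_from(D, k=1)]
    med = np.median(off)
    return float(1.0 / med) if med > 0 else 1.0


# ---------------------------------------------------------------------------
# gradient pieces for the float32 loop
# ---------------------------------------------------------------------------

_MMD_EPS = 1e-12


def _sqdist(A, B):
    """Pairwise squared Euclidean distances via the Gram expansion."""
    aa = np.einsum("ij,ij->i", A, A)
    bb = np.einsum("ij,ij->i", B, B)
    D = aa[:, None] + bb[None, :] - 2.0 * (A @ B.T)
    np.maximum(D, 0.0, out=D)
    return D


def _mmd_value_and_grads(deltas_W, deltas_T, gamma):
    """L_MMD, dL/d deltas_W, and dL/d gamma (V-statistic, RBF kernel).

    Accepts float32 or float64 batches; all O(B^2) work stays in the input
    dtype.
    """
    B = deltas_W.shape[0]
    Dww = _sqdist(deltas_W, deltas_W)
    Dtt = _sqdist(deltas_T, deltas_T)
    Dwt = _sqdist(deltas_W, deltas_T)
    g = np.asarray(-gamma, dtype=deltas_W.dtype)
    Kww = np.exp(g * Dww)
    Ktt = np.exp(g * Dtt)
    Kwt = np.exp(g * Dwt)
    sq = float(Kww.sum()) + float(Ktt.sum()) - 2.0 * float(Kwt.sum())
    L = np.sqrt(max(sq / B**2, 0.0))
    if L < _MMD_EPS:
        return L, np.zeros_like(deltas_W), 0.0
    # dS/dW_i = (-4 gamma / B^2) [sum_j Kww_ij (W_i - W_j)
    #                             - sum_j Kwt_ij (W_i - T_j)]
    term_w = Kww.sum(axis=1)[:, None] * deltas_W - Kww @ deltas_W
    term_t = Kwt.sum(axis=1)[:, None] * deltas_W - Kwt @ deltas_T
    dS_dW = (-4.0 * gamma / B**2) * (term_w - term_t)
    dS_dgamma = (-float((Kww * Dww).sum()) - float((Ktt * Dtt).sum())
                 + 2.0 * float((Kwt * Dwt).sum())) / B**2
    return L, dS_dW / (2.0 * L), dS_dgamma / (2.0 * L)


def _gamma_ascent(log_gamma: float, opt: Adam, grad_log_gamma: float) -> float:
    """Apply one Adam ascent step to log(gamma); skip nonfinite gradients."""
    if not np.isfinite(grad_log_gamma):
        return log_gamma
    holder = np.array([log_gamma], dtype=np.float32)
    opt.step([holder], [np.array([-grad_log_gamma], dtype=np.float32)])
    return float(holder[0])


def update_bandwidth(log_gamma: float, opt: Adam, deltas_W: np.ndarray,
                     deltas_T: np.ndarray) -> float:
    """One ascent step on L_MMD w.r.t. gamma (log-parameterized).

    The network parameters are held fixed; the step uses the same batch as
    the preceding descent step on theta.  Returns the new log(gamma);
    nonfinite gradients leave it unchanged.
    """
    gamma = float(np.exp(log_gamma))
    _, _, dL_dgamma = _mmd_value_and_grads(deltas_W, deltas_T, gamma)
    return _gamma_ascent(log_gamma, opt, dL_dgamma * gamma)


def stopping_metric(model: GeneratorModel, cov: CovariateMatrix,
                    stop_w1: np.ndarray, stop_w0: np.ndarray,
                    stop_D_alloc: np.ndarray,
                    dropout_seed: Optional[int] = None) -> float:
    """KS statistic between weighted and allocation Mahalanobis distances.

    The transformed weights are produced the same way generation produces
    them -- with dropout sampling -- since that is the distribution being
    matched.  Passing a fixed ``dropout_seed`` reuses identical masks at
    every evaluation, so the metric is deterministic given the model and
    the fixed stopping pools and comparable across evaluations;
    ``dropout_seed=None`` disables dropout for a deterministic-map check.
    """
    if dropout_seed is None:
        w1, w0, _ = model.forward(np.concatenate([stop_w1, stop_w0], axis=1))
    else:
        w1, w0, _ = model.forward(np.concatenate([stop_w1, stop_w0], axis=1),
                                  train=True,
                                  rng=np.random.default_rng(dropout_seed))
    D_w = weighted_mahalanobis_batch(cov, w1.astype(float), w0.astype(float))
    return ks_statistic(D_w, stop_D_alloc)


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def train_qrer(cov: CovariateMatrix, config: TrainingConfig,
               rng: Optional[np.random.Generator] = None):
    """Fit the QReR generator on a covariate matrix.

    Pre-generates the three pools (initialization weights, loss allocations,
    stopping pair), pre-trains the network toward the identity map, then
    alternates Adam descent on theta with bandwidth ascent on gamma, stopping
    early once the KS metric has not improved for ``N_stop`` consecutive
    evaluations.  Returns ``(model, trace)`` with the parameters that
    achieved the best stopping metric.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N1, N0 = cov.N1, cov.N0
    X1 = cov.X1.astype(np.float32)
    X0 = cov.X0.astype(np.float32)
    xbar = cov.pooled_mean.astype(np.float32)

    # (i) pools
    spec = RerandSpec(p_a=config.p_a, B=config.B_loss + config.B_stop)
    allocs, D_pool = rerandomize_pool_arrays(cov, spec, rng)
    deltas_all = (allocs @ cov.X) / N1 - ((1 - allocs) @ cov.X) / N0
    loss_deltas = deltas_all[: config.B_loss].astype(np.float32)
    stop_D_alloc = D_pool[config.B_loss:]
    init_w1, init_w0 = sample_dirichlet_batch(config.B_init, N1, N0, rng)
    stop_w1, stop_w0 = sample_dirichlet_batch(config.B_stop, N1, N0, rng)
    stop_w1 = stop_w1.astype(np.float32)
    stop_w0 = stop_w0.astype(np.float32)

    # (ii) identity initialization
    model = build_generator(N1, N0, rng)
    initialize_identity(model, init_w1, init_w0, config.N_init, rng,
                        lr=config.lr)

    trace = TrainingTrace()
    eval_seed = int(rng.integers(2**31))
    metric0 = stopping_metric(model, cov, stop_w1, stop_w0, stop_D_alloc,
                              dropout_seed=eval_seed)
    trace.initial_metric = metric0
    trace.eval_iterations.append(0)
    trace.ks_metric.append(metric0)
    trace.best_metric = metric0
    trace.best_iteration = 0
    best_params = [p.copy() for p in model.params]

    log_gamma = float(np.log(median_heuristic_gamma(
        loss_deltas[: config.B].astype(float))))
    opt_theta = Adam(model.param_shapes(), lr=config.lr)
    opt_gamma = Adam([(1,)], lr=config.lr)

    lam1, lam2 = config.lambda1, config.lambda2
    bad_evals = 0
    for it in range(1, config.N_train + 1):
        idx = rng.integers(0, config.B_loss, size=config.B)
        batch_T = loss_deltas[idx]
        d1, d0 = sample_dirichlet_batch(config.B, N1, N0, rng,
                                        dtype=np.float32)
        w1, w0, cache = model.forward(
            np.concatenate([d1, d0], axis=1), train=True, rng=rng)

        deltas_W = w1 @ X1 - w0 @ X0
        gamma = float(np.exp(log_gamma))
        L_mmd, dL_dW, dL_dgamma = _mmd_value_and_grads(deltas_W, batch_T, gamma)

        B = config.B
        m1 = w1 @ X1 - xbar
        m0 = w0 @ X0 - xbar
        r1 = float((np.sum(m1 * m1) + np.sum(m0 * m0)) / B)
        e1 = w1 - np.float32(1.0 / N1)
        e0 = w0 - np.float32(1.0 / N0)
        r2 = float((np.sum(e1 * e1) + np.sum(e0 * e0)) / B)
        loss = L_mmd + lam1 * r1 + lam2 * r2
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"nonfinite training loss at iteration {it}")

        dW = dL_dW
        dw1 = dW @ X1.T + lam1 * (2.0 / B) * (m1 @ X1.T) + lam2 * (2.0 / B) * e1
        dw0 = -dW @ X0.T + lam1 * (2.0 / B) * (m0 @ X0.T) + lam2 * (2.0 / B) * e0
        grads = model.backward(cache, dw1, dw0)
        opt_theta.step(model.params, grads)

        # gamma ascent on the same batch (theta frozen)
        log_gamma = _gamma_ascent(log_gamma, opt_gamma, dL_dgamma * gamma)

        trace.iterations.append(it)
        trace.mmd.append(L_mmd)
        trace.r1.append(r1)
        trace.r2.append(r2)
        trace.gamma.append(gamma)

        if it % config.eval_every == 0:
            metric = stopping_metric(model, cov, stop_w1, stop_w0,
                                     stop_D_alloc, dropout_seed=eval_seed)
            trace.eval_iterations.append(it)
            trace.ks_metric.append(metric)
            if metric < trace.best_metric - config.min_delta:
                trace.best_metric = metric
                trace.best_iteration = it
                best_params = [p.copy() for p in model.params]
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= config.N_stop:
                    break

    model.params = best_params
    model.gamma = float(np.exp(log_gamma))
    model.train_state = {"iterations": trace.iterations[-1] if trace.iterations else 0,
                         "best_iteration": trace.best_iteration,
                         "best_metric": trace.best_metric,
                         "initial_metric": trace.initial_metric}
    return model, trace
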