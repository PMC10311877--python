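"""Synthetic benchmark: data generation and the simulation evaluation harness.

The generator emulates a confounded two-arm observational study with eight
covariates.  Four are Gaussian: treated units draw from N(mu, Sigma) and
controls from N(0, I4), with three (mu, Sigma) scenarios covering mean
shift only, heterogeneous variances, and within-treated correlation.  Four
are Bernoulli with treatment-dependent success probabilities.  The rates are
chosen so the true standardized mean difference of every covariate is 0.2 or
0.5 -- a meaningful imbalance.  Group sizes are N1 = 250 treated and
N0 = r * 250 controls, r in {1, 2}, and the r = 1 dataset is nested inside
the r = 2 dataset drawn from the same seed.

Outcomes follow Y = g(X) + tau * T + eps with tau = 1, eps ~ N(0, 1), and
three response surfaces of increasing nonlinearity (linear, interaction,
polynomial), all computed from the raw (pre-standardization) covariates.
Covariates are standardized to zero mean / unit variance afterwards for the
balancing methods; the Mahalanobis distance is affine-invariant, so this
changes nothing for rerandomization but fixes the scale the network sees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CovariateMatrix
from .estimate import tau_ensemble, tau_hat
from .network import generate_weights
from .rerand import RerandSpec, rerandomize_pool_arrays
from .reweight import WeightVector, delta_batch
from .training import TrainingConfig, train_qrer

N1_DESIGN = 250
N0_POOL = 500          # full control pool; r=1 takes the first 250 rows
TAU_TRUE = 1.0
SURFACES = ("linear", "interaction", "polynomial")

_SCENARIO_MU = {
    1: np.array([0.2, 0.2, 0.5, 0.5]),
    2: np.sqrt(1.5) * np.array([0.2, 0.2, 0.5, 0.5]),
    3: np.sqrt(1.5) * np.array([0.2, 0.2, 0.5, 0.5]),
}
_SCENARIO_SIGMA = {
    1: np.eye(4),
    2: 2.0 * np.eye(4),
    3: 1.5 * np.eye(4) + 0.5 * np.ones((4, 4)),
}
# Bernoulli success probabilities (control, treated)
_BERN = {5: (0.1, 0.168), 6: (0.1, 0.168), 7: (0.4, 0.642), 8: (0.4, 0.642)}


@dataclass
class SimulationDataset:
    """One synthetic study: raw/standardized covariates and three outcomes."""

    X_raw: np.ndarray
    T_obs: np.ndarray
    scenario: int
    r: int
    seed: Optional[int] = None
    X_std: Optional[np.ndarray] = None
    Y: Dict[str, np.ndarray] = field(default_factory=dict)
    g: Dict[str, np.ndarray] = field(default_factory=dict)
    tau_true: float = TAU_TRUE

    @property
    def N(self) -> int:
        return self.X_raw.shape[0]

    @property
    def N1(self) -> int:
        return int(self.T_obs.sum())

    @property
    def N0(self) -> int:
        return self.N - self.N1

    def covariates(self, standardized: bool = True) -> CovariateMatrix:
        X = self.X_std if standardized else self.X_raw
        if X is None:
            raise ValueError("dataset not standardized yet")
        return CovariateMatrix.from_arrays(X, self.T_obs)

    def response_under(self, surface: str, T: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
        """Regenerate outcomes under a new allocation with fresh noise."""
        return (self.g[surface] + self.tau_true * np.asarray(T, dtype=float)
                + rng.standard_normal(self.N))


def true_smd_bernoulli(p_control: float, p_treated: float) -> float:
    """Design standardized mean difference of a Bernoulli covariate."""
    pooled = (p_treated * (1 - p_treated) + p_control * (1 - p_control)) / 2
    return (p_treated - p_control) / np.sqrt(pooled)


def true_smd_gaussian(mu_t: float, mu_c: float, var_t: float,
                      var_c: float) -> float:
    return (mu_t - mu_c) / np.sqrt((var_t + var_c) / 2)


def generate_covariates(scenario: int, r: int,
                        rng: np.random.Generator) -> SimulationDataset:
    """Covariates and allocation for one study.

    The full control pool of 500 units is always drawn so that, for a fixed
    generator state, the r = 1 dataset consists of the first 500 rows of the
    r = 2 dataset (treated block plus first 250 controls).
    """
    if scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")
    if r not in (1, 2):
        raise ValueError("r must be 1 or 2")
    mu, Sigma = _SCENARIO_MU[scenario], _SCENARIO_SIGMA[scenario]
    L = np.linalg.cholesky(Sigma)

    def block(n, treated):
        X = np.empty((n, 8))
        if treated:
            X[:, :4] = rng.standard_normal((n, 4)) @ L.T + mu
        else:
            X[:, :4] = rng.standard_normal((n, 4))
        for j, (p0, p1) in _BERN.items():
            X[:, j - 1] = rng.random(n) < (p1 if treated else p0)
        return X

    X_t = block(N1_DESIGN, treated=True)
    X_c = block(N0_POOL, treated=False)[: r * N1_DESIGN]
    X = np.vstack([X_t, X_c])
    T = np.concatenate([np.ones(N1_DESIGN, dtype=int),
                        np.zeros(r * N1_DESIGN, dtype=int)])
    return SimulationDataset(X_raw=X, T_obs=T, scenario=scenario, r=r)


def _surface_values(X: np.ndarray) -> Dict[str, np.ndarray]:
    x1, x3, x5, x7 = X[:, 0], X[:, 2], X[:, 4], X[:, 6]
    g_lin = 3.5 * x1 + 4.5 * x3 + 1.5 * x5 + 2.5 * x7
    g_int = g_lin + 2.5 * np.sign(x1) * np.sqrt(np.abs(x1)) + 2.5 * x3 * x7
    g_pol = g_int + 5.5 * x3**2 - 4.5 * x1 * x3**3
    return {"linear": g_lin, "interaction": g_int, "polynomial": g_pol}


def generate_responses(ds: SimulationDataset,
                       rng: np.random.Generator) -> SimulationDataset:
    """Attach the three outcome vectors, sharing one eps draw per unit."""
    ds.g = _surface_values(ds.X_raw)
    eps = rng.standard_normal(ds.N)
    t = ds.T_obs.astype(float)
    for s in SURFACES:
        ds.Y[s] = ds.g[s] + ds.tau_true * t + eps
    return ds


def standardize(ds: SimulationDataset) -> SimulationDataset:
    """Column-standardize covariates (mean 0, unit N-1 variance)."""
    sd = ds.X_raw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"covariate column {j} is constant")
    ds.X_std = (ds.X_raw - ds.X_raw.mean(axis=0)) / sd
    return ds


def make_dataset(scenario: int, r: int, seed) -> SimulationDataset:
    """Generate, attach responses, and standardize one study.

    With the same ``seed``, the r = 1 dataset's rows (covariates and
    outcomes) are bit-identical to the first 500 rows of the r = 2 dataset.
    """
    rng = np.random.default_rng(seed)
    ds = generate_covariates(scenario, r, rng)
    ds.seed = seed if isinstance(seed, int) else None
    generate_responses(ds, rng)
    return standardize(ds)


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Aggregated simulation metrics, one row per grid cell and method."""

    table: pd.DataFrame

    def cell(self, **kwargs) -> pd.Series:
        mask = np.ones(len(self.table), dtype=bool)
        for k, v in kwargs.items():
            mask &= self.table[k] == v
        sub = self.table[mask]
        if len(sub) != 1:
            raise KeyError(f"query {kwargs} matched {len(sub)} rows")
        return sub.iloc[0]


def mcse_bias(estimates: np.ndarray) -> float:
    if len(estimates) < 2:
        return float("nan")
    return float(np.std(estimates, ddof=1) / np.sqrt(len(estimates)))


def mcse_rmse(estimates: np.ndarray, tau: float) -> float:
    if len(estimates) < 2:
        return float("nan")
    sq = (np.asarray(estimates) - tau) ** 2
    rmse = np.sqrt(sq.mean())
    if rmse == 0:
        return 0.0
    return float(np.sqrt(np.var(sq, ddof=1) / (4 * len(sq) * rmse**2)))


def _aggregate(rows, estimates, tau, cell, method):
    est = np.asarray(estimates)
    err = est - tau
    rows.append({**cell, "method": method, "n_reps": len(est),
                 "bias": float(err.mean()),
                 "rmse": float(np.sqrt((err**2).mean())),
                 "mcse_bias": mcse_bias(est),
                 "mcse_rmse": mcse_rmse(est, tau)})


def scaled_down_config(p_a: float) -> TrainingConfig:
    """Reduced-size training configuration used by the bundled benchmark.

    Keeps the reference batch size B = 512 and the early-stopping patience
    of 15 evaluations, shrinks the pre-generated pools, caps training at
    2000 iterations, and evaluates the stopping metric every 50 iterations
    (a 750-iteration patience window, proportionally the same share of the
    iteration budget as the reference cadence).  On the B_stop = 500
    stopping pool the KS statistic moves on a 2e-3 grid, so an
    "improvement" must clear min_delta = 5e-3 to count.
    """
    return TrainingConfig(p_a=p_a, N_train=2000, N_init=150, B_init=384,
                          B_loss=3000, B_stop=500, eval_every=50,
                          min_delta=5e-3)


def run_benchmark(scenarios: Iterable[int] = (1,), ratios: Iterable[int] = (1,),
                  surfaces: Sequence[str] = SURFACES,
                  p_as: Iterable[float] = (0.1,), n_reps: int = 200,
                  methods: Sequence[str] = ("rer",), seed: int = 0,
                  train_config_factory=scaled_down_config,
                  M: int = 1000, collect=None, checkpoint=None) -> EvalReport:
    """Monte-Carlo evaluation of ReR and/or QReR over a simulation grid.

    For each replicate dataset: rerandomization draws one accepted
    allocation and regenerates outcomes under it, estimating the effect by
    the raw mean difference; QReR trains the generator once per replicate
    and acceptance probability (covariates only), then estimates the effect
    on the *observed* outcomes with a single weight vector (QReR_S) and with
    the M-vector ensemble (QReR_M).  ``collect``, if given, is called with a
    dict of per-replicate artifacts (used to audit training traces).

    ``checkpoint`` names a CSV file of per-replicate estimates, appended to
    as replicates finish; on restart, finished replicates are loaded from it
    instead of recomputed (replicate seeding is deterministic, so skipping
    is exact).
    """
    done = {}
    ckpt_file = None
    if checkpoint is not None:
        import csv
        from pathlib import Path
        path = Path(checkpoint)
        if path.exists():
            for rec in pd.read_csv(path).itertuples(index=False):
                key = (rec.scenario, rec.r, rec.p_a, rec.rep)
                done.setdefault(key, {})[(rec.method, rec.surface)] = rec.estimate
        path.parent.mkdir(parents=True, exist_ok=True)
        new_file = not path.exists()
        ckpt_file = open(path, "a", newline="")
        ckpt_writer = csv.writer(ckpt_file)
        if new_file:
            ckpt_writer.writerow(["scenario", "r", "p_a", "rep", "method",
                                  "surface", "estimate"])

    def record(scenario, r, p_a, rep, method, surface, value):
        ests[(method, surface)].append(value)
        if ckpt_file is not None:
            ckpt_writer.writerow([scenario, r, p_a, rep, method, surface,
                                  repr(value)])
            ckpt_file.flush()

    rows = []
    for scenario, r, p_a in itertools.product(scenarios, ratios, p_as):
        ests = {(m, s): [] for m in ("ReR", "QReR_S", "QReR_M")
                for s in surfaces}
        method_names = ({"ReR"} if "rer" in methods else set()) | \
            ({"QReR_S", "QReR_M"} if "qrer" in methods else set())
        for rep in range(n_reps):
            prior = done.get((scenario, r, p_a, rep), {})
            if {m for m, _ in prior} >= method_names and \
                    all((m, s) in prior for m in method_names for s in surfaces):
                for m in method_names:
                    for s in surfaces:
                        ests[(m, s)].append(prior[(m, s)])
                continue
            ds_seed = np.random.SeedSequence([seed, scenario, rep])
            ds = make_dataset(scenario, r, ds_seed)
            cov = ds.covariates()
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, scenario, r, rep, 10**6 + int(p_a * 1000)]))
            if "rer" in methods:
                spec = RerandSpec(p_a=p_a, B=1)
                allocs, _ = rerandomize_pool_arrays(cov, spec, rng)
                T = allocs[0].astype(int)
                for s in surfaces:
                    Y = ds.response_under(s, T, rng)
                    record(scenario, r, p_a, rep, "ReR", s,
                           float(Y[T == 1].mean() - Y[T == 0].mean()))
            if "qrer" in methods:
                config = train_config_factory(p_a)
                model, trace = train_qrer(cov, config, rng)
                weights = generate_weights(model, M, rng)
                for s in surfaces:
                    record(scenario, r, p_a, rep, "QReR_S", s,
                           tau_hat(weights[0], cov.T_obs, ds.Y[s]))
                    record(scenario, r, p_a, rep, "QReR_M", s,
                           tau_ensemble(weights, cov.T_obs, ds.Y[s]))
                if collect is not None:
                    collect({"scenario": scenario, "r": r, "p_a": p_a,
                             "rep": rep, "trace": trace, "model": model,
                             "dataset": ds})
        for s in surfaces:
            cell = {"scenario": scenario, "r": r, "surface": s, "p_a": p_a}
            if "rer" in methods:
                _aggregate(rows, ests[("ReR", s)], TAU_TRUE, cell, "ReR")
            if "qrer" in methods:
                _aggregate(rows, ests[("QReR_S", s)], TAU_TRUE, cell, "QReR_S")
                _aggregate(rows, ests[("QReR_M", s)], TAU_TRUE, cell, "QReR_M")
    if ckpt_file is not None:
        ckpt_file.close()
    return EvalReport(table=pd.DataFrame(rows))


def balance_comparison(model, cov: CovariateMatrix, spec: RerandSpec,
                       rng: np.random.Generator, n_vectors: int = 1000):
    """Per-covariate KS comparison of weighted vs rerandomized differences.

    Generates ``n_vectors`` transformed weight vectors and the same number
    of accepted allocations, computes the covariate mean differences of
    both, and returns the per-covariate two-sample KS statistics and
    asymptotic p-values together with their averages.
    """
    weights = generate_weights(model, n_vectors, rng)
    w1 = np.stack([w.w1 for w in weights])
    w0 = np.stack([w.w0 for w in weights])
    deltas_W = delta_batch(cov, w1, w0)
    pool_spec = RerandSpec(p_a=spec.p_a, B=n_vectors, a=spec.a)
    allocs, _ = rerandomize_pool_arrays(cov, pool_spec, rng)
    deltas_T = ((allocs @ cov.X) / cov.N1
                - ((1 - allocs) @ cov.X) / cov.N0)
    ks = np.empty(cov.d)
    pvals = np.empty(cov.d)
    for j in range(cov.d):
        res = stats.ks_2samp(deltas_W[:, j], deltas_T[:, j], method="asymp")
        ks[j], pvals[j] = res.statistic, res.pvalue
    return {"ks": ks, "p_values": pvals,
            "mean_ks": float(ks.mean()), "mean_p_value": float(pvals.mean())}
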