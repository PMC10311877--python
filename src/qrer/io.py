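"""CSV/JSON round-tripping and reproducible seed management.

CSV dialect everywhere: comma-separated, header row, UTF-8, '.' decimal, no
index column.  One master seed fans out into named child streams so each
component (data, rerandomization, Dirichlet draws, network init, training,
generation) can be re-run independently with identical results.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CovariateMatrix
from .reweight import WeightVector


def seed_sequence(master: int, *keys) -> np.random.SeedSequence:
    """Deterministic child seed sequence for a named stream."""
    entropy = [int(master)]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) if isinstance(k, str)
                       else int(k))
    return np.random.SeedSequence(entropy)


def seed_stream(master: int, *keys) -> np.random.Generator:
    """Generator for the named child stream of a master seed."""
    return np.random.default_rng(seed_sequence(master, *keys))


# -- covariates / treatment / outcomes --------------------------------------

def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty covariate table")
    return df


def read_treatment_csv(path, column: str = "treated") -> np.ndarray:
    df = pd.read_csv(path)
    col = df[column] if column in df.columns else df.iloc[:, 0]
    vals = col.to_numpy()
    if set(np.unique(vals)) - {0, 1}:
        raise ValueError(f"{path}: treatment column must contain only 0/1")
    return vals.astype(int)


def covariate_matrix_from_csv(cov_path, treat_path,
                              ridge: float = 0.0) -> CovariateMatrix:
    X = read_covariates_csv(cov_path)
    T = read_treatment_csv(treat_path)
    return CovariateMatrix.from_arrays(X.to_numpy(dtype=float), T, ridge=ridge)


# -- allocation pools ---------------------------------------------------------

def write_pool_csv(path, allocations, distances) -> None:
    """Pool export: one row per allocation, columns alloc_id, D, T_1..T_N."""
    A = np.asarray(allocations)
    cols = {"alloc_id": np.arange(len(A)), "D": np.asarray(distances)}
    for i in range(A.shape[1]):
        cols[f"T_{i + 1}"] = A[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_pool_csv(path):
    df = pd.read_csv(path)
    tcols = [c for c in df.columns if c.startswith("T_")]
    return df[tcols].to_numpy(dtype=np.int8), df["D"].to_numpy()


# -- weights -----------------------------------------------------------------

def write_weights_csv(path, W: WeightVector, cov: CovariateMatrix) -> None:
    """Serialize a weight vector in the user's original unit order."""
    treated = cov.to_original_order(cov.T_obs)
    weights = cov.to_original_order(W.full)
    pd.DataFrame({"unit_id": np.arange(cov.N), "treated": treated,
                  "weight": weights}).to_csv(path, index=False)


def read_weights_csv(path) -> WeightVector:
    df = pd.read_csv(path)
    t = df["treated"].to_numpy(dtype=int)
    w = df["weight"].to_numpy(dtype=float)
    return WeightVector(w[t == 1], w[t == 0])


# -- simulation dataset bundles ----------------------------------------------

def write_dataset_bundle(ds, outdir) -> None:
    """Write a simulation dataset as CSVs plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"x{j + 1}" for j in range(ds.X_raw.shape[1])]
    pd.DataFrame(ds.X_raw, columns=cols).to_csv(
        outdir / "covariates_raw.csv", index=False)
    if ds.X_std is not None:
        pd.DataFrame(ds.X_std, columns=cols).to_csv(
            outdir / "covariates_std.csv", index=False)
    pd.DataFrame({"treated": ds.T_obs}).to_csv(outdir / "treatment.csv",
                                               index=False)
    pd.DataFrame(ds.Y).to_csv(outdir / "responses.csv", index=False)
    write_json(outdir / "manifest.json",
               {"scenario": ds.scenario, "r": ds.r, "seed": ds.seed,
                "tau_true": ds.tau_true, "N": ds.N, "N1": ds.N1})


def read_dataset_bundle(outdir):
    """Load a dataset bundle written by :func:`write_dataset_bundle`."""
    from .simbench import SimulationDataset
    outdir = Path(outdir)
    manifest = read_json(outdir / "manifest.json")
    ds = SimulationDataset(
        X_raw=pd.read_csv(outdir / "covariates_raw.csv").to_numpy(),
        T_obs=pd.read_csv(outdir / "treatment.csv")["treated"].to_numpy(),
        scenario=manifest["scenario"], r=manifest["r"],
        seed=manifest["seed"], tau_true=manifest["tau_true"])
    std = outdir / "covariates_std.csv"
    if std.exists():
        ds.X_std = pd.read_csv(std).to_numpy()
    resp = pd.read_csv(outdir / "responses.csv")
    ds.Y = {c: resp[c].to_numpy() for c in resp.columns}
    return ds


# -- config / results --------------------------------------------------------

def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")


def read_json(path):
    return json.loads(Path(path).read_text())
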