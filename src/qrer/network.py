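"""The weight-transformation network G(W | X, theta) and its optimizer.

Architecture: a length-N simplex weight vector passes through two fully
connected hidden layers of 512 ReLU units, each followed by dropout at rate
0.5 during training, into two linear heads of sizes N1 and N0 whose outputs
go through separate softmax maps.  The output is therefore a valid pair of
per-arm simplex vectors for any input.  The covariates do not enter the
network itself; they enter only through the training losses, which depend on
the weighted mean differences of a fixed covariate matrix.

Everything is plain numpy: the forward pass caches what the hand-written
backward pass needs, and ``Adam`` implements the standard optimizer.  Batch
math runs in float32; weights handed back to callers are float64 simplex
vectors (renormalized, so per-arm sums are exact to float64 rounding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .reweight import WeightVector, sample_dirichlet_batch

HIDDEN = 512
DROPOUT_RATE = 0.5
LOG_FLOOR = 1e-12


class Adam:
    """Standard Adam (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.v = [np.zeros(s, dtype=np.float32) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        # equivalent reformulation folding both bias corrections into the
        # step size: p -= lr*sqrt(b2t)/b1t * m / (sqrt(v) + eps*sqrt(b2t))
        lr_t = np.float32(self.lr * np.sqrt(b2t) / b1t)
        eps_t = np.float32(self.eps * np.sqrt(b2t))
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + eps_t)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=1, keepdims=True)
    return z


@dataclass
class GeneratorModel:
    """Parameters of G plus the trained kernel bandwidth and train state."""

    N1: int
    N0: int
    params: List[np.ndarray]
    dropout_rate: float = DROPOUT_RATE
    gamma: Optional[float] = None
    train_state: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.N1 + self.N0

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    # -- forward / backward ----------------------------------------------

    def forward(self, W: np.ndarray, *, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Forward pass on a (B, N) batch.

        Returns ``(w1, w0, cache)`` with ``w1`` (B, N1) and ``w0`` (B, N0) on
        their simplices.  With ``train=True`` dropout masks are drawn from
        ``rng`` and the cache holds everything ``backward`` needs.
        """
        V1, b1, V2, b2, U1, c1, U0, c0 = self.params
        Wf = np.asarray(W, dtype=np.float32)
        H1 = Wf @ V1 + b1
        np.maximum(H1, 0, out=H1)
        M1 = M2 = None
        if train:
            keep = 1.0 - self.dropout_rate
            M1 = (rng.random(H1.shape, dtype=np.float32) < keep) / np.float32(keep)
            H1 *= M1
        H2 = H1 @ V2 + b2
        np.maximum(H2, 0, out=H2)
        if train:
            M2 = (rng.random(H2.shape, dtype=np.float32) < keep) / np.float32(keep)
            H2 *= M2
        w1 = _softmax(H2 @ U1 + c1)
        w0 = _softmax(H2 @ U0 + c0)
        cache = (Wf, H1, H2, M1, M2, w1, w0) if train else None
        return w1, w0, cache

    def backward(self, cache, dw1: np.ndarray, dw0: np.ndarray):
        """Gradients of a scalar loss w.r.t. params, given dL/d(w1, w0)."""
        V1, b1, V2, b2, U1, c1, U0, c0 = self.params
        Wf, H1, H2, M1, M2, w1, w0 = cache
        dw1 = dw1.astype(np.float32, copy=False)
        dw0 = dw0.astype(np.float32, copy=False)
        # softmax jacobian: dz = y * (dy - sum(dy * y))
        dz1 = dw1 * w1
        dz1 -= w1 * dz1.sum(axis=1, keepdims=True)
        dz0 = dw0 * w0
        dz0 -= w0 * dz0.sum(axis=1, keepdims=True)
        dU1 = H2.T @ dz1
        dc1 = dz1.sum(axis=0)
        dU0 = H2.T @ dz0
        dc0 = dz0.sum(axis=0)
        dH2 = dz1 @ U1.T + dz0 @ U0.T
        # cached H(1,2) are post-ReLU, post-dropout: an entry is positive iff
        # the unit survived both, and every kept inverted-mask entry is the
        # constant 1/keep -- so one fused where() applies ReLU and dropout
        inv_keep = np.float32(1.0 / (1.0 - self.dropout_rate))
        if M2 is not None:
            dH2 *= np.where(H2 > 0, inv_keep, np.float32(0.0))
        else:
            dH2[H2 <= 0] = 0.0
        dV2 = H1.T @ dH2
        db2 = dH2.sum(axis=0)
        dH1 = dH2 @ V2.T
        if M1 is not None:
            dH1 *= np.where(H1 > 0, inv_keep, np.float32(0.0))
        else:
            dH1[H1 <= 0] = 0.0
        dV1 = Wf.T @ dH1
        db1 = dH1.sum(axis=0)
        return [dV1, db1, dV2, db2, dU1, dc1, dU0, dc0]

    def param_shapes(self):
        return [p.shape for p in self.params]

    # -- persistence -------------------------------------------------------

    def save(self, path):
        """Write an .npz checkpoint plus a JSON sidecar next to it."""
        path = Path(path)
        names = ["V1", "b1", "V2", "b2", "U1", "c1", "U0", "c0"]
        np.savez(path, **dict(zip(names, self.params)))
        sidecar = {
            "N1": self.N1, "N0": self.N0, "dropout_rate": self.dropout_rate,
            "gamma": self.gamma, "train_state": self.train_state,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "GeneratorModel":
        path = Path(path)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            params = [z[k] for k in ["V1", "b1", "V2", "b2", "U1", "c1", "U0", "c0"]]
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        return cls(N1=meta["N1"], N0=meta["N0"], params=params,
                   dropout_rate=meta["dropout_rate"], gamma=meta["gamma"],
                   train_state=meta["train_state"])


def build_generator(N1: int, N0: int, rng: np.random.Generator,
                    hidden: int = HIDDEN,
                    dropout_rate: float = DROPOUT_RATE) -> GeneratorModel:
    """Fresh generator with uniform fan-in initialization of each layer."""
    if N1 < 2 or N0 < 2:
        raise ValueError("N1 and N0 must be >= 2")
    N = N1 + N0

    def layer(fan_in, fan_out):
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)
        b = rng.uniform(-bound, bound, size=fan_out).astype(np.float32)
        return W, b

    V1, b1 = layer(N, hidden)
    V2, b2 = layer(hidden, hidden)
    U1, c1 = layer(hidden, N1)
    U0, c0 = layer(hidden, N0)
    return GeneratorModel(N1=N1, N0=N0,
                          params=[V1, b1, V2, b2, U1, c1, U0, c0],
                          dropout_rate=dropout_rate)


def identity_init_loss(model: GeneratorModel, w1_in, w0_in, *,
                       train=False, rng=None):
    """Mean squared error between log inputs and log outputs of G."""
    w1, w0, cache = model.forward(np.concatenate([w1_in, w0_in], axis=1),
                                  train=train, rng=rng)
    B = w1.shape[0]
    l1 = np.log(np.maximum(w1, LOG_FLOOR)) - np.log(np.maximum(w1_in, LOG_FLOOR))
    l0 = np.log(np.maximum(w0, LOG_FLOOR)) - np.log(np.maximum(w0_in, LOG_FLOOR))
    loss = (np.sum(l1 * l1) + np.sum(l0 * l0)) / B
    return float(loss), (cache, w1, w0, l1, l0, B)


def initialize_identity(model: GeneratorModel, w1_init: np.ndarray,
                        w0_init: np.ndarray, n_steps: int,
                        rng: np.random.Generator, lr: float = 1e-3,
                        dropout: bool = True):
    """Pre-train G toward the identity map on a fixed batch of draws.

    Minimizes the batch-mean squared error between elementwise log inputs and
    log outputs for ``n_steps`` full-batch Adam steps.  Returns the per-step
    loss history.
    """
    w1_init = np.asarray(w1_init, dtype=np.float32)
    w0_init = np.asarray(w0_init, dtype=np.float32)
    opt = Adam(model.param_shapes(), lr=lr)
    history = []
    for _ in range(n_steps):
        loss, (cache, w1, w0, l1, l0, B) = identity_init_loss(
            model, w1_init, w0_init, train=dropout, rng=rng)
        if not np.isfinite(loss):
            raise FloatingPointError("nonfinite identity-initialization loss")
        dw1 = (2.0 / B) * l1 / np.maximum(w1, LOG_FLOOR)
        dw0 = (2.0 / B) * l0 / np.maximum(w0, LOG_FLOOR)
        grads = model.backward(cache, dw1, dw0)
        opt.step(model.params, grads)
        history.append(loss)
    return history


def generate_weight_arrays(model: GeneratorModel, M: int,
                           rng: np.random.Generator, *,
                           dropout_active: bool = True):
    """M Dirichlet draws pushed through G; returns (w1 (M,N1), w0 (M,N0)).

    Dropout stays active by default: the generator is trained with dropout
    sampling, so the distribution of transformed weights it matches to the
    rerandomized template includes the dropout noise.  Monte-Carlo dropout
    at generation reproduces that distribution (and gives each generated
    vector the single-allocation-like diversity the ensemble averages
    over); deterministic generation would collapse it.  Output is still a
    deterministic function of ``rng``.
    """
    d1, d0 = sample_dirichlet_batch(M, model.N1, model.N0, rng)
    w1, w0, _ = model.forward(
        np.concatenate([d1, d0], axis=1),
        train=dropout_active, rng=rng if dropout_active else None)
    w1 = w1.astype(np.float64)
    w0 = w0.astype(np.float64)
    w1 /= w1.sum(axis=1, keepdims=True)
    w0 /= w0.sum(axis=1, keepdims=True)
    return w1, w0


def generate_weights(model: GeneratorModel, M: int, rng: np.random.Generator,
                     *, dropout_active: bool = True) -> List[WeightVector]:
    """M transformed weight vectors (Monte-Carlo dropout by default)."""
    w1, w0 = generate_weight_arrays(model, M, rng, dropout_active=dropout_active)
    return [WeightVector(w1[m], w0[m]) for m in range(M)]
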