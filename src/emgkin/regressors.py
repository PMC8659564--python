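"""Sequence regressors: a stacked LSTM and an MLP baseline, in NumPy.

The LSTM cell follows the standard gate equations

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
    C_t = f_t * C_{t-1} + i_t * tanh(W_c [h_{t-1}, x_t] + b_c)
    h_t = o_t * tanh(C_t)

with elementwise products throughout.  Layers are stacked: layer l consumes
layer l-1's hidden sequence, with inverted dropout on the inter-layer
sequences in training mode only; a linear head maps the top hidden state to
the two joint angles at every time step.  Training minimizes mean-squared
error on normalized targets with Adam, over per-cycle sequences (state is
reset at cycle boundaries).  Gradients are exact backpropagation through
time, verified against numerical differentiation in the test suite.

The published architecture (10 recurrent layers of 200 units, <= 200
epochs) is available via :meth:`ModelConfig.paper_scale`; the shipped
default is a reduced profile (2 layers of 32 units, 30 epochs) sized for a
single CPU.  ``seq_stride`` optionally subsamples the per-cycle sequences
before training and prediction; both joints' targets are band-limited well
below the working rate, so a moderate stride changes the effective sampling
interval but not the information content of a sequence.

The MLP baseline is a stateless per-time-point map
``linear(5 -> 160) -> tanh -> linear(160 -> 2)`` trained full-batch with a
conjugate-gradient optimizer (SciPy's nonlinear Polak-Ribiere CG standing
in for the scaled-conjugate-gradient family) or, optionally, Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ModelConfig",
    "LSTMLayerParams",
    "LSTMState",
    "LSTMModel",
    "MLPParams",
    "MLPModel",
    "DivergenceError",
    "lstm_cell_step",
    "lstm_forward",
    "train_lstm",
    "mlp_forward",
    "train_mlp",
    "to_sequences",
    "from_sequences",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters shared by both regressors.

    The defaults are the desk-scale profile; :meth:`paper_scale` restores
    the published architecture (10 x 200 LSTM, 200 epochs, full-rate
    sequences).
    """

    arch: str = "lstm"  # "lstm" | "mlp"
    n_layers: int = 2
    hidden: int = 32
    dropout_p: float = 0.2
    lr: float = 0.005
    max_epochs: int = 30
    optimizer: str = "adam"  # for the MLP: "cg" | "adam"
    output_dim: int = 2
    input_dim: int = 5
    batch_size: int = 8
    betas: tuple[float, float] = (0.9, 0.999)
    mlp_hidden: int = 160
    seq_len: int = 1000
    seq_stride: int = 1
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.seq_stride < 1:
            raise ValueError("seq_stride must be >= 1")

    @classmethod
    def paper_scale(cls, **overrides) -> "ModelConfig":
        base = cls(
            n_layers=10, hidden=200, max_epochs=200, seq_stride=1, dtype="float32"
        )
        return replace(base, **overrides)

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        return replace(cls(), **overrides)


@dataclass
class LSTMLayerParams:
    """One recurrent layer's gate weights over the concatenated [h, x]."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    def __post_init__(self) -> None:
        h = self.W_f.shape[0]
        for name in ("W_f", "W_i", "W_o", "W_c"):
            w = getattr(self, name)
            if w.shape != self.W_f.shape:
                raise ValueError(f"{name} shape {w.shape} != {self.W_f.shape}")
        for name in ("b_f", "b_i", "b_o", "b_c"):
            b = getattr(self, name)
            if b.shape != (h,):
                raise ValueError(f"{name} must have shape ({h},)")

    def packed(self) -> tuple[np.ndarray, np.ndarray]:
        """Gate-stacked (4H, H+I) weight and (4H,) bias for the fast path."""
        return (
            np.vstack([self.W_f, self.W_i, self.W_o, self.W_c]),
            np.concatenate([self.b_f, self.b_i, self.b_o, self.b_c]),
        )


@dataclass
class LSTMState:
    """Hidden and cell vectors of one layer at one time step."""

    h: np.ndarray
    C: np.ndarray


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_cell_step(
    x_t: np.ndarray, state_prev: LSTMState, p: LSTMLayerParams
) -> LSTMState:
    """One LSTM cell update for a single time step (reference path)."""
    x_t = np.asarray(x_t, dtype=float)
    concat = np.concatenate([state_prev.h, x_t])
    if concat.shape[0] != p.W_f.shape[1]:
        raise ValueError(
            f"[h, x] length {concat.shape[0]} != weight columns {p.W_f.shape[1]}"
        )
    f = _sigmoid(p.W_f @ concat + p.b_f)
    i = _sigmoid(p.W_i @ concat + p.b_i)
    o = _sigmoid(p.W_o @ concat + p.b_o)
    g = np.tanh(p.W_c @ concat + p.b_c)
    C = f * state_prev.C + i * g
    h = o * np.tanh(C)
    return LSTMState(h=h, C=C)


def _init_layer(
    rng: np.random.Generator, input_size: int, hidden: int, dtype
) -> LSTMLayerParams:
    """Scaled-uniform init; forget-gate bias starts at 1 (standard practice)."""
    bound = 1.0 / np.sqrt(hidden + input_size)

    def w():
        return rng.uniform(-bound, bound, size=(hidden, hidden + input_size)).astype(
            dtype
        )

    return LSTMLayerParams(
        W_f=w(),
        W_i=w(),
        W_o=w(),
        W_c=w(),
        b_f=np.ones(hidden, dtype=dtype),
        b_i=np.zeros(hidden, dtype=dtype),
        b_o=np.zeros(hidden, dtype=dtype),
        b_c=np.zeros(hidden, dtype=dtype),
    )


class LSTMModel:
    """Stacked LSTM with a per-step linear head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self.layers: list[LSTMLayerParams] = []
        in_size = cfg.input_dim
        for _ in range(cfg.n_layers):
            self.layers.append(_init_layer(rng, in_size, cfg.hidden, dtype))
            in_size = cfg.hidden
        bound = 1.0 / np.sqrt(cfg.hidden)
        self.head_W = rng.uniform(
            -bound, bound, size=(cfg.output_dim, cfg.hidden)
        ).astype(dtype)
        self.head_b = np.zeros(cfg.output_dim, dtype=dtype)

    # ---- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for p in self.layers:
            out.extend([p.W_f, p.W_i, p.W_o, p.W_c, p.b_f, p.b_i, p.b_o, p.b_c])
        out.extend([self.head_W, self.head_b])
        return out

    # ---- forward ------------------------------------------------------------
    def _forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        cache: bool = False,
    ):
        """Run the stack over a (B, L, input_dim) batch of sequences."""
        B, L, _ = X.shape
        H = self.cfg.hidden
        dtype = X.dtype
        caches = []
        seq = X
        drop_masks: list[np.ndarray | None] = []
        for li, layer in enumerate(self.layers):
            W, b = layer.packed()
            Wt = W.T.astype(dtype, copy=False)
            h = np.zeros((B, H), dtype=dtype)
            c = np.zeros((B, H), dtype=dtype)
            hs = np.empty((L, B, H), dtype=dtype)
            if cache:
                st = {
                    "f": np.empty((L, B, H), dtype=dtype),
                    "i": np.empty((L, B, H), dtype=dtype),
                    "o": np.empty((L, B, H), dtype=dtype),
                    "g": np.empty((L, B, H), dtype=dtype),
                    "tc": np.empty((L, B, H), dtype=dtype),
                    "c_prev": np.empty((L, B, H), dtype=dtype),
                    "h_prev": np.empty((L, B, H), dtype=dtype),
                    "x": seq,
                }
            for t in range(L):
                concat = np.concatenate([h, seq[:, t, :]], axis=1)
                z = concat @ Wt + b
                f = _sigmoid(z[:, :H])
                i = _sigmoid(z[:, H : 2 * H])
                o = _sigmoid(z[:, 2 * H : 3 * H])
                g = np.tanh(z[:, 3 * H :])
                if cache:
                    st["c_prev"][t] = c
                    st["h_prev"][t] = h
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                hs[t] = h
                if cache:
                    st["f"][t] = f
                    st["i"][t] = i
                    st["o"][t] = o
                    st["g"][t] = g
                    st["tc"][t] = tc
            out_seq = np.transpose(hs, (1, 0, 2))
            mask = None
            if train and self.cfg.dropout_p > 0 and li < len(self.layers) - 1:
                if rng is None:
                    raise ValueError("training-mode forward requires an rng")
                keep = 1.0 - self.cfg.dropout_p
                mask = (rng.random(out_seq.shape) < keep).astype(dtype) / keep
                out_seq = out_seq * mask
            drop_masks.append(mask)
            if cache:
                st["hs"] = hs
                caches.append(st)
            seq = out_seq
        Y = seq @ self.head_W.T.astype(dtype, copy=False) + self.head_b
        if cache:
            return Y, {"layer": caches, "masks": drop_masks, "top": seq}
        return Y

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode forward over (B, L, input_dim)."""
        return self._forward(np.asarray(X), train=False)

    def predict_matrix(self, features: np.ndarray) -> np.ndarray:
        """Predict a (5, M) matrix cycle-by-cycle; output is (2, M')."""
        X = to_sequences(
            np.asarray(features), self.cfg.seq_len, self.cfg.seq_stride
        ).astype(np.dtype(self.cfg.dtype))
        return from_sequences(self.predict(X)).astype(float)

    # ---- backward -----------------------------------------------------------
    def loss_and_grads(
        self,
        X: np.ndarray,
        T: np.ndarray,
        rng: np.random.Generator | None = None,
        train: bool = True,
    ) -> tuple[float, list[np.ndarray]]:
        """MSE loss and exact BPTT gradients in :meth:`parameters` order."""
        Y, cache = self._forward(X, train=train, rng=rng, cache=True)
        diff = Y - T
        loss = float(np.mean(diff * diff))
        dY = (2.0 / diff.size) * diff
        B, L, _ = X.shape
        H = self.cfg.hidden
        top = cache["top"]  # (B, L, H)
        dHW = np.einsum("blo,blh->oh", dY, top)
        dHb = dY.sum(axis=(0, 1))
        dseq = dY @ self.head_W.astype(X.dtype, copy=False)  # (B, L, H)
        grads_layers: list[list[np.ndarray]] = []
        for li in range(len(self.layers) - 1, -1, -1):
            mask = cache["masks"][li]
            if mask is not None:
                dseq = dseq * mask
            st = cache["layer"][li]
            layer = self.layers[li]
            W, _ = layer.packed()
            W = W.astype(X.dtype, copy=False)
            I = layer.input_size
            dW = np.zeros_like(W)
            db = np.zeros(4 * H, dtype=X.dtype)
            dh_next = np.zeros((B, H), dtype=X.dtype)
            dc_next = np.zeros((B, H), dtype=X.dtype)
            dX = np.empty((B, L, I), dtype=X.dtype)
            for t in range(L - 1, -1, -1):
                f, i, o, g, tc = st["f"][t], st["i"][t], st["o"][t], st["g"][t], st["tc"][t]
                dh = dseq[:, t, :] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc * tc)
                df = dc * st["c_prev"][t]
                di = dc * g
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [
                        df * f * (1.0 - f),
                        di * i * (1.0 - i),
                        do * o * (1.0 - o),
                        dg * (1.0 - g * g),
                    ],
                    axis=1,
                )
                concat = np.concatenate([st["h_prev"][t], st["x"][:, t, :]], axis=1)
                dW += dz.T @ concat
                db += dz.sum(axis=0)
                dconcat = dz @ W
                dh_next = dconcat[:, :H]
                dX[:, t, :] = dconcat[:, H:]
            grads_layers.append(
                [
                    dW[:H],
                    dW[H : 2 * H],
                    dW[2 * H : 3 * H],
                    dW[3 * H :],
                    db[:H],
                    db[H : 2 * H],
                    db[2 * H : 3 * H],
                    db[3 * H :],
                ]
            )
            dseq = dX
        grads: list[np.ndarray] = []
        for layer_grads in reversed(grads_layers):
            grads.extend(layer_grads)
        grads.extend([dHW, dHb])
        return loss, grads


def lstm_forward(
    sequence: np.ndarray,
    layers: Sequence[LSTMLayerParams],
    head_W: np.ndarray,
    head_b: np.ndarray,
    dropout_p: float = 0.0,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Functional forward pass over one (input_dim, L) sequence.

    Initial hidden and cell states are zero; layer l consumes layer l-1's
    hidden sequence; dropout applies between layers in ``train`` mode only;
    the linear head runs at every time step.  Eval mode is deterministic.
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    if mode == "train" and dropout_p > 0 and rng is None:
        raise ValueError("train mode with dropout requires an rng")
    seq = np.asarray(sequence, dtype=float).T  # (L, input_dim)
    L = seq.shape[0]
    for li, p in enumerate(layers):
        state = LSTMState(
            h=np.zeros(p.hidden_size), C=np.zeros(p.hidden_size)
        )
        hs = np.empty((L, p.hidden_size))
        for t in range(L):
            state = lstm_cell_step(seq[t], state, p)
            hs[t] = state.h
        if mode == "train" and dropout_p > 0 and li < len(layers) - 1:
            keep = 1.0 - dropout_p
            hs = hs * ((rng.random(hs.shape) < keep) / keep)
        seq = hs
    return (seq @ np.asarray(head_W).T + np.asarray(head_b)).T  # (output_dim, L)


class _Adam:
    """Adam with bias correction over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def to_sequences(matrix: np.ndarray, seq_len: int, stride: int = 1) -> np.ndarray:
    """Reshape a (channels, M) matrix into (n_cycles, L', channels) sequences."""
    C, M = matrix.shape
    if M % seq_len != 0:
        raise ValueError(f"column count {M} is not a multiple of seq_len {seq_len}")
    seqs = matrix.T.reshape(M // seq_len, seq_len, C)
    return seqs[:, ::stride, :]


def from_sequences(seqs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_sequences` up to the stride: (channels, n*L')."""
    n, L, C = seqs.shape
    return seqs.reshape(n * L, C).T


def train_lstm(
    features: np.ndarray, targets: np.ndarray, cfg: ModelConfig
) -> tuple[LSTMModel, list[float]]:
    """Fit the stacked LSTM on normalized (5 x M, 2 x M) matrices.

    Sequences are the per-cycle chunks (``cfg.seq_len`` points, subsampled
    by ``cfg.seq_stride``); minibatches are reshuffled each epoch from
    ``cfg.seed``.  Returns the model and the per-epoch mean training loss.
    """
    features = np.asarray(features)
    targets = np.asarray(targets)
    if features.shape[1] != targets.shape[1]:
        raise ValueError("features and targets must be column-aligned")
    if not (np.all(np.isfinite(features)) and np.all(np.isfinite(targets))):
        raise ValueError("non-finite values in training data")
    dtype = np.dtype(cfg.dtype)
    X = to_sequences(features, cfg.seq_len, cfg.seq_stride).astype(dtype)
    T = to_sequences(targets, cfg.seq_len, cfg.seq_stride).astype(dtype)
    model = LSTMModel(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas)
    n = X.shape[0]
    trace: list[float] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = model.loss_and_grads(X[idx], T[idx], rng=rng, train=True)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.step(grads)
            losses.append(loss * len(idx))
        trace.append(float(np.sum(losses) / n))
    return model, trace


# ---- MLP baseline ----------------------------------------------------------


@dataclass
class MLPParams:
    """Weights of the 5 -> hidden -> 2 tanh network."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray


def mlp_forward(x: np.ndarray, params: MLPParams) -> np.ndarray:
    """Per-time-point map linear -> tanh -> linear over a (5, N) batch."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != params.W1.shape[1]:
        raise ValueError(
            f"input width {x.shape[0]} != expected {params.W1.shape[1]}"
        )
    hidden = np.tanh(params.W1 @ x + params.b1[:, None])
    return params.W2 @ hidden + params.b2[:, None]


class MLPModel:
    """Trained MLP wrapper with the same matrix in / matrix out surface."""

    def __init__(self, params: MLPParams, cfg: ModelConfig):
        self.params = params
        self.cfg = cfg

    def predict_matrix(self, features: np.ndarray) -> np.ndarray:
        return mlp_forward(np.asarray(features, dtype=float), self.params)


def _mlp_pack(p: MLPParams) -> np.ndarray:
    return np.concatenate([p.W1.ravel(), p.b1, p.W2.ravel(), p.b2])


def _mlp_unpack(theta: np.ndarray, n_in: int, n_h: int, n_out: int) -> MLPParams:
    a = n_h * n_in
    b = a + n_h
    c = b + n_out * n_h
    return MLPParams(
        W1=theta[:a].reshape(n_h, n_in),
        b1=theta[a:b],
        W2=theta[b:c].reshape(n_out, n_h),
        b2=theta[c:],
    )


def train_mlp(
    features: np.ndarray, targets: np.ndarray, cfg: ModelConfig
) -> tuple[MLPModel, list[float]]:
    """Fit the MLP on normalized matrices by full-batch conjugate gradient.

    ``cfg.optimizer`` selects ``"cg"`` (default here: SciPy's nonlinear
    conjugate gradient with analytic gradients) or ``"adam"`` (full-batch).
    ``cfg.max_epochs`` bounds the iteration count; the per-iteration loss
    trace is returned.
    """
    X = np.asarray(features, dtype=float)
    T = np.asarray(targets, dtype=float)
    if X.shape[1] != T.shape[1]:
        raise ValueError("features and targets must be column-aligned")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(T))):
        raise ValueError("non-finite values in training data")
    n_in, n_h, n_out = cfg.input_dim, cfg.mlp_hidden, cfg.output_dim
    rng = np.random.default_rng(cfg.seed)
    b1 = 1.0 / np.sqrt(n_in)
    b2 = 1.0 / np.sqrt(n_h)
    p0 = MLPParams(
        W1=rng.uniform(-b1, b1, (n_h, n_in)),
        b1=np.zeros(n_h),
        W2=rng.uniform(-b2, b2, (n_out, n_h)),
        b2=np.zeros(n_out),
    )
    N = X.shape[1]

    def loss_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = _mlp_unpack(theta, n_in, n_h, n_out)
        A = np.tanh(p.W1 @ X + p.b1[:, None])
        Y = p.W2 @ A + p.b2[:, None]
        D = Y - T
        loss = float(np.mean(D * D))
        dY = (2.0 / D.size) * D
        gW2 = dY @ A.T
        gb2 = dY.sum(axis=1)
        dA = (p.W2.T @ dY) * (1.0 - A * A)
        gW1 = dA @ X.T
        gb1 = dA.sum(axis=1)
        return loss, np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])

    trace: list[float] = []
    if cfg.optimizer == "adam":
        theta = _mlp_pack(p0)
        opt = _Adam([theta], lr=cfg.lr, betas=cfg.betas)
        for epoch in range(cfg.max_epochs):
            loss, g = loss_grad(theta)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.step([g])
            trace.append(loss)
        params = _mlp_unpack(theta, n_in, n_h, n_out)
    else:  # conjugate gradient
        evals: list[float] = []

        def fg(theta: np.ndarray) -> tuple[float, np.ndarray]:
            loss, g = loss_grad(theta)
            evals.append(loss)
            return loss, g

        res = minimize(
            fg,
            _mlp_pack(p0),
            jac=True,
            method="CG",
            callback=lambda th: trace.append(evals[-1]),
            options={"maxiter": cfg.max_epochs},
        )
        if not np.isfinite(res.fun):
            raise DivergenceError(len(trace))
        params = _mlp_unpack(res.x, n_in, n_h, n_out)
    return MLPModel(params, cfg), trace
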