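"""The sulfenylation predictor: per-stream modified BiLSTMs, adaptive
self/cross-attention fusion, and a dense classifier head.

Each 21-position feature stream — the evolutionary profile (21 × 20) and the
trigram-embedding stream (21 × Dim) — runs through its own bidirectional
LSTM.  Two departures from a textbook BiLSTM: the backward pass is
initialised from a trainable weighted sum of all forward hidden states
(``h0_b = σ(Σ_i w_i · h_i_f)``), letting the reverse sweep start from what
the forward sweep learned; and a residual blend
``h_t ← α_res·h_t + (1−α_res)·h_{t−1}`` is applied along the forward
direction to ease long-range credit assignment.

The two BiLSTM outputs are fused adaptively: both are projected to a common
width d (sigmoid-activated linear maps), refined by multi-head
self-attention, exchanged through two cross-attentions (queries from one
stream, keys/values from the other), and combined as

    H_F = α·(H_PW + H2_W) + (1−α)·(H_WP + H2_P)

with α a trainable logistic-squashed scalar.  Mean-pooling over the 21
positions and a small dense stack produce the site probability.

Everything runs on the in-package autodiff engine; training (Adam, binary
cross-entropy, early stopping on a carved-out validation split) is
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field as dataclasses_field

import numpy as np

from .autodiff import Adam, Tensor, bce_with_logits, concat, stack

logger = logging.getLogger(__name__)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


# ---------------------------------------------------------------------------
# LSTM cell and BiLSTM
# ---------------------------------------------------------------------------

@dataclass
class LSTMCellParams:
    """Gate weights over the concatenation [h_prev, x_t] (input/forget/output
    gates and candidate), hidden_size units each."""

    W_i: Tensor
    W_f: Tensor
    W_o: Tensor
    W_c: Tensor
    b_i: Tensor
    b_f: Tensor
    b_o: Tensor
    b_c: Tensor
    hidden_size: int

    @classmethod
    def init(cls, input_dim: int, hidden_size: int, rng: np.random.Generator,
             dtype=np.float64) -> "LSTMCellParams":
        d = hidden_size + input_dim
        mk = lambda: Tensor(_glorot(rng, d, hidden_size).astype(dtype),
                            requires_grad=True)
        bias = lambda v: Tensor(np.full(hidden_size, v, dtype=dtype),
                                requires_grad=True)
        # forget-gate bias starts at 1 (retain memory early in training)
        return cls(mk(), mk(), mk(), mk(),
                   bias(0.0), bias(1.0), bias(0.0), bias(0.0), hidden_size)

    def tensors(self) -> list[Tensor]:
        return [self.W_i, self.W_f, self.W_o, self.W_c,
                self.b_i, self.b_f, self.b_o, self.b_c]


def lstm_cell_step(params: LSTMCellParams, x_t, h_prev, c_prev):
    """One gated recurrence step.

    i, f, o = σ(W·[h_prev, x_t] + b);  c_t = f·c_prev + i·tanh(W_c·[...] + b_c);
    h_t = o·tanh(c_t).  Accepts vectors or (batch, dim) arrays / Tensors.
    """
    x_t, h_prev, c_prev = map(_as_tensor, (x_t, h_prev, c_prev))
    hx = concat([h_prev, x_t], axis=-1)
    i = (hx @ params.W_i + params.b_i).sigmoid()
    f = (hx @ params.W_f + params.b_f).sigmoid()
    o = (hx @ params.W_o + params.b_o).sigmoid()
    g = (hx @ params.W_c + params.b_c).tanh()
    c_t = f * c_prev + i * g
    h_t = o * c_t.tanh()
    return h_t, c_t


def backward_init(h_forward, w):
    """Initial backward hidden state: σ(Σ_i w_i · h_i_forward).

    ``h_forward`` is (T, h) or (batch, T, h); ``w`` has length T.
    """
    h_forward, w = _as_tensor(h_forward), _as_tensor(w)
    T = h_forward.shape[-2]
    if w.shape != (T,):
        raise ValueError(f"weight vector must have length {T}")
    weighted = h_forward * w.reshape(T, 1)
    return weighted.sum(axis=-2).sigmoid()


def residual_update(h_next, h_curr, alpha_res: float):
    """Blend consecutive hidden states: α·h_next + (1−α)·h_curr."""
    if not (0.0 <= alpha_res <= 1.0):
        raise ValueError("alpha_res must lie in [0, 1]")
    return _as_tensor(h_next) * alpha_res + _as_tensor(h_curr) * (1.0 - alpha_res)


@dataclass
class BiLSTMParams:
    forward: LSTMCellParams
    backward: LSTMCellParams
    w_init: Tensor            # length-T trainable backward-init weights
    alpha_res: float = 0.5
    mirror_residual: bool = False  # also apply the residual blend backward

    @classmethod
    def init(cls, input_dim: int, hidden_size: int, seq_len: int,
             rng: np.random.Generator, alpha_res: float = 0.5,
             dtype=np.float64) -> "BiLSTMParams":
        return cls(LSTMCellParams.init(input_dim, hidden_size, rng, dtype),
                   LSTMCellParams.init(input_dim, hidden_size, rng, dtype),
                   Tensor(np.zeros(seq_len, dtype=dtype), requires_grad=True),
                   alpha_res)

    def tensors(self) -> list[Tensor]:
        return self.forward.tensors() + self.backward.tensors() + [self.w_init]


def _sigmoid_np(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _lstm_sweep(Wh: Tensor, Wx: Tensor, b4: Tensor, Xt: Tensor,
                h0: Tensor, alpha_res: float, reverse: bool) -> Tensor:
    """Full gated recurrence over a constant input sequence, as one graph op.

    Forward stores the per-step gate activations; the closure replays the
    recurrence backwards (standard backpropagation through time), emitting
    gradients for the fused weight/bias tensors and the initial hidden state.
    Dramatically fewer graph nodes than composing per-step tensor operations
    — the per-step reference path (:func:`lstm_cell_step`) remains the oracle
    it is tested against.  ``alpha_res`` blends consecutive hidden states
    (1.0 disables the blend); ``reverse`` runs right-to-left.
    """
    X = np.ascontiguousarray(Xt.data)
    B, T, _ = X.shape
    h = Wh.shape[0]
    order = range(T - 1, -1, -1) if reverse else range(T)
    order = list(order)

    Zx = X @ Wx.data + b4.data          # (B, T, 4h), input contribution
    i_s = np.empty((T, B, h), dtype=X.dtype)
    f_s = np.empty_like(i_s)
    o_s = np.empty_like(i_s)
    g_s = np.empty_like(i_s)
    tc_s = np.empty_like(i_s)           # tanh(c_t)
    hprev_s = np.empty_like(i_s)        # recurrent input at each step
    cprev_s = np.empty_like(i_s)
    hout = np.empty((B, T, h), dtype=X.dtype)

    h_t = h0.data
    c_t = np.zeros((B, h), dtype=X.dtype)
    for k, t in enumerate(order):
        hprev_s[k] = h_t
        cprev_s[k] = c_t
        z = h_t @ Wh.data + Zx[:, t, :]
        s = _sigmoid_np(z[:, : 3 * h])
        g = np.tanh(z[:, 3 * h:])
        i, f, o = s[:, :h], s[:, h:2 * h], s[:, 2 * h:]
        c_t = f * c_t + i * g
        tc = np.tanh(c_t)
        h_new = o * tc
        if k > 0 and alpha_res != 1.0:
            h_t = alpha_res * h_new + (1.0 - alpha_res) * h_t
        else:
            h_t = h_new
        i_s[k], f_s[k], o_s[k], g_s[k], tc_s[k] = i, f, o, g, tc
        hout[:, t, :] = h_t

    def backward(gout):
        dWh = np.zeros_like(Wh.data)
        dWx = np.zeros_like(Wx.data)
        db = np.zeros_like(b4.data)
        dX = np.zeros_like(X) if Xt.requires_grad else None
        dh_carry = np.zeros((B, h), dtype=X.dtype)
        dc_carry = np.zeros((B, h), dtype=X.dtype)
        dh0 = None
        for k in range(T - 1, -1, -1):
            t = order[k]
            dh_total = gout[:, t, :] + dh_carry
            if k > 0 and alpha_res != 1.0:
                dh_raw = alpha_res * dh_total
                dres_prev = (1.0 - alpha_res) * dh_total
            else:
                dh_raw = dh_total
                dres_prev = 0.0
            i, f, o, g, tc = i_s[k], f_s[k], o_s[k], g_s[k], tc_s[k]
            do = dh_raw * tc
            dc = dh_raw * o * (1.0 - tc * tc) + dc_carry
            di = dc * g
            dg = dc * i
            df = dc * cprev_s[k]
            dc_carry = dc * f
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 do * o * (1 - o), dg * (1 - g * g)], axis=1)
            dWh += hprev_s[k].T @ dz
            dWx += X[:, t, :].T @ dz
            db += dz.sum(axis=0)
            if dX is not None:
                dX[:, t, :] = dz @ Wx.data.T
            dh_carry = dz @ Wh.data.T + dres_prev
            if k == 0:
                dh0 = dh_carry
        return dWh, dWx, db, dh0, dX

    req = (Wh.requires_grad or Wx.requires_grad or b4.requires_grad
           or h0.requires_grad or Xt.requires_grad)
    return Tensor(hout, requires_grad=req,
                  _parents=(Wh, Wx, b4, h0, Xt) if req else (),
                  _backward=backward if req else None)


def bilstm_forward(params: BiLSTMParams, X) -> Tensor:
    """Run the modified BiLSTM over X ((T, d_in) or (batch, T, d_in)).

    Returns per-position concatenated forward/backward states:
    (T, 2h) or (batch, T, 2h).  Inputs are treated as constants (features,
    not trainable quantities); the left-to-right pass applies the residual
    blend and the right-to-left pass starts from the weighted-sum
    initialisation over the completed forward states.
    """
    X = _as_tensor(X)
    squeeze = X.ndim == 2
    if squeeze:
        X = X.reshape(1, *X.shape)
    B, T, _ = X.shape
    h = params.forward.hidden_size

    def gate_mats(cell: LSTMCellParams):
        W4 = concat([cell.W_i, cell.W_f, cell.W_o, cell.W_c], axis=1)
        b4 = concat([cell.b_i, cell.b_f, cell.b_o, cell.b_c], axis=0)
        return W4[:h, :], W4[h:, :], b4

    Wh_f, Wx_f, b4f = gate_mats(params.forward)
    Wh_b, Wx_b, b4b = gate_mats(params.backward)

    zeros = Tensor(np.zeros((B, h), dtype=X.data.dtype))
    h_fwd = _lstm_sweep(Wh_f, Wx_f, b4f, X, zeros, params.alpha_res,
                        reverse=False)

    h_b0 = backward_init(h_fwd, params.w_init)
    alpha_b = params.alpha_res if params.mirror_residual else 1.0
    h_bwd = _lstm_sweep(Wh_b, Wx_b, b4b, X, h_b0, alpha_b, reverse=True)

    out = concat([h_fwd, h_bwd], axis=-1)
    return out.reshape(T, 2 * h) if squeeze else out


def bilstm_forward_reference(params: BiLSTMParams, X) -> Tensor:
    """Step-by-step composition of the public per-step operations.

    Slow path kept as the independent oracle for :func:`bilstm_forward`.
    """
    X = _as_tensor(X)
    squeeze = X.ndim == 2
    if squeeze:
        X = X.reshape(1, *X.shape)
    B, T, _ = X.shape
    h = params.forward.hidden_size

    zeros = Tensor(np.zeros((B, h), dtype=X.data.dtype))
    h_t, c_t = zeros, zeros
    fwd: list[Tensor] = []
    for t in range(T):
        h_new, c_t = lstm_cell_step(params.forward, X[:, t, :], h_t, c_t)
        h_t = residual_update(h_new, h_t, params.alpha_res) if t > 0 else h_new
        fwd.append(h_t)
    h_fwd = stack(fwd, axis=1)  # (B, T, h)

    h_b = backward_init(h_fwd, params.w_init)
    c_b = zeros
    bwd: list[Tensor] = [None] * T
    first = True
    for t in range(T - 1, -1, -1):
        h_new, c_b = lstm_cell_step(params.backward, X[:, t, :], h_b, c_b)
        if params.mirror_residual and not first:
            h_b = residual_update(h_new, h_b, params.alpha_res)
        else:
            h_b = h_new
        first = False
        bwd[t] = h_b
    h_bwd = stack(bwd, axis=1)

    out = concat([h_fwd, h_bwd], axis=-1)
    return out.reshape(T, 2 * h) if squeeze else out


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Multi-head scaled dot-product attention projections (queries, keys,
    values stored head-concatenated; per-head width d / head_count)."""

    W_q: Tensor
    W_k: Tensor
    W_v: Tensor
    head_count: int
    model_dim: int

    @classmethod
    def init(cls, model_dim: int, head_count: int, rng: np.random.Generator,
             dtype=np.float64) -> "AttentionParams":
        if model_dim % head_count:
            raise ValueError("model_dim must be divisible by head_count")
        mk = lambda: Tensor(_glorot(rng, model_dim, model_dim).astype(dtype),
                            requires_grad=True)
        return cls(mk(), mk(), mk(), head_count, model_dim)

    def tensors(self) -> list[Tensor]:
        return [self.W_q, self.W_k, self.W_v]


def _attend(params: AttentionParams, H_q: Tensor, H_kv: Tensor,
            return_weights: bool = False):
    B, Nq, d = H_q.shape
    Nc = H_kv.shape[1]
    heads = params.head_count
    dh = d // heads

    def split(x, N):
        return x.reshape(B, N, heads, dh).transpose((0, 2, 1, 3))

    Q = split(H_q @ params.W_q, Nq)
    K = split(H_kv @ params.W_k, Nc)
    V = split(H_kv @ params.W_v, Nc)
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
    A = scores.softmax(axis=-1)                      # (B, heads, Nq, Nc)
    out = (A @ V).transpose((0, 2, 1, 3)).reshape(B, Nq, d)
    return (out, A) if return_weights else out


def _promote(H):
    H = _as_tensor(H)
    if H.ndim == 2:
        return H.reshape(1, *H.shape), True
    return H, False


def self_attention(params: AttentionParams, H, return_weights: bool = False):
    """softmax(QKᵀ/√d_head)·V per head with Q, K, V linear in H."""
    Hb, squeeze = _promote(H)
    res = _attend(params, Hb, Hb, return_weights)
    out, A = res if return_weights else (res, None)
    if squeeze:
        out = out.reshape(out.shape[1], out.shape[2])
    return (out, A) if return_weights else out


def cross_attention(params: AttentionParams, H_query, H_context,
                    return_weights: bool = False):
    """As self-attention but queries from one stream, keys/values from the other."""
    Hq, squeeze = _promote(H_query)
    Hc, _ = _promote(H_context)
    if Hq.shape[-1] != Hc.shape[-1]:
        raise ValueError("query and context streams must share model_dim")
    res = _attend(params, Hq, Hc, return_weights)
    out, A = res if return_weights else (res, None)
    if squeeze:
        out = out.reshape(out.shape[1], out.shape[2])
    return (out, A) if return_weights else out


# ---------------------------------------------------------------------------
# adaptive fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionParams:
    W1: Tensor                 # evolutionary-stream projection (d1 -> d)
    W2: Tensor                 # semantic-stream projection (d2 -> d)
    self_p: AttentionParams
    self_w: AttentionParams
    cross_pw: AttentionParams  # queries from the semantic stream
    cross_wp: AttentionParams  # queries from the evolutionary stream
    alpha_logit: Tensor        # trainable; α_fuse = σ(alpha_logit)

    @classmethod
    def init(cls, d1: int, d2: int, d: int, head_count: int,
             rng: np.random.Generator, dtype=np.float64) -> "FusionParams":
        return cls(
            Tensor(_glorot(rng, d1, d).astype(dtype), requires_grad=True),
            Tensor(_glorot(rng, d2, d).astype(dtype), requires_grad=True),
            AttentionParams.init(d, head_count, rng, dtype),
            AttentionParams.init(d, head_count, rng, dtype),
            AttentionParams.init(d, head_count, rng, dtype),
            AttentionParams.init(d, head_count, rng, dtype),
            Tensor(np.zeros((), dtype=dtype), requires_grad=True),  # σ(0) = 0.5
        )

    def tensors(self) -> list[Tensor]:
        out = [self.W1, self.W2, self.alpha_logit]
        for att in (self.self_p, self.self_w, self.cross_pw, self.cross_wp):
            out += att.tensors()
        return out

    @property
    def alpha_fuse(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.alpha_logit.data)))


def adaptive_fuse(fp: FusionParams, H_P, H_W, alpha: float | None = None) -> Tensor:
    """Fuse the evolutionary (H_P) and semantic (H_W) streams.

    Project → self-attend per stream → exchange via cross-attention →
    α-weighted sum.  ``alpha`` overrides the trained fusion weight (used by
    the endpoint identities α = 0 / α = 1).
    """
    H_P, H_W = _as_tensor(H_P), _as_tensor(H_W)
    if H_P.shape[-2] != H_W.shape[-2]:
        raise ValueError("streams must have equal position counts")
    H1P = (H_P @ fp.W1).sigmoid()
    H1W = (H_W @ fp.W2).sigmoid()
    H2P = self_attention(fp.self_p, H1P)
    H2W = self_attention(fp.self_w, H1W)
    H_PW = cross_attention(fp.cross_pw, H2W, H2P)
    H_WP = cross_attention(fp.cross_wp, H2P, H2W)
    if alpha is None:
        a = fp.alpha_logit.sigmoid()
        return (H_PW + H2W) * a + (H_WP + H2P) * (1.0 - a)
    return (H_PW + H2W) * alpha + (H_WP + H2P) * (1.0 - alpha)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 3
    min_epochs: int = 1    # early stopping is not consulted before this
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        for name in ("epochs", "batch_size", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class FusionModel:
    """BiLSTM-per-stream + adaptive fusion + dense head."""

    bilstm_p: BiLSTMParams
    bilstm_w: BiLSTMParams
    fusion: FusionParams
    head: list[Tensor]
    hidden_size: int
    model_dim: int
    head_count: int
    trained: bool = False
    # optional deeper recurrent stacks (layer i > 0 consumes 2h-wide input)
    extra_p: list[BiLSTMParams] = dataclasses_field(default_factory=list)
    extra_w: list[BiLSTMParams] = dataclasses_field(default_factory=list)

    @classmethod
    def init(cls, d_evo: int = 20, d_sem: int = 60, seq_len: int = 21,
             hidden_size: int = 64, model_dim: int = 60, head_count: int = 3,
             head_dims: tuple[int, ...] = (128, 64), alpha_res: float = 0.5,
             n_layers: int = 1, seed: int = 0,
             dtype=np.float64) -> "FusionModel":
        rng = np.random.default_rng(seed)
        bilstm_p = BiLSTMParams.init(d_evo, hidden_size, seq_len, rng,
                                     alpha_res, dtype)
        bilstm_w = BiLSTMParams.init(d_sem, hidden_size, seq_len, rng,
                                     alpha_res, dtype)
        extra_p = [BiLSTMParams.init(2 * hidden_size, hidden_size, seq_len,
                                     rng, alpha_res, dtype)
                   for _ in range(n_layers - 1)]
        extra_w = [BiLSTMParams.init(2 * hidden_size, hidden_size, seq_len,
                                     rng, alpha_res, dtype)
                   for _ in range(n_layers - 1)]
        fusion = FusionParams.init(2 * hidden_size, 2 * hidden_size,
                                   model_dim, head_count, rng, dtype)
        head: list[Tensor] = []
        dims = (model_dim,) + tuple(head_dims) + (1,)
        for a, b in zip(dims[:-1], dims[1:]):
            head.append(Tensor(_glorot(rng, a, b).astype(dtype),
                               requires_grad=True))
            head.append(Tensor(np.zeros(b, dtype=dtype), requires_grad=True))
        return cls(bilstm_p, bilstm_w, fusion, head,
                   hidden_size, model_dim, head_count,
                   extra_p=extra_p, extra_w=extra_w)

    def parameters(self) -> list[Tensor]:
        out = self.bilstm_p.tensors() + self.bilstm_w.tensors()
        for layer in self.extra_p + self.extra_w:
            out += layer.tensors()
        return out + self.fusion.tensors() + self.head

    # ------------------------------------------------------------- forward
    def forward_logits(self, H_P, H_W) -> Tensor:
        """(batch, 21, d_evo) + (batch, 21, d_sem) → (batch,) logits."""
        out_p = bilstm_forward(self.bilstm_p, H_P)
        for layer in self.extra_p:
            out_p = bilstm_forward(layer, out_p)
        out_w = bilstm_forward(self.bilstm_w, H_W)
        for layer in self.extra_w:
            out_w = bilstm_forward(layer, out_w)
        fused = adaptive_fuse(self.fusion, out_p, out_w)    # (B, 21, d)
        pooled = fused.mean(axis=-2)                        # (B, d)
        z = pooled
        n_layers = len(self.head) // 2
        for li in range(n_layers):
            z = z @ self.head[2 * li] + self.head[2 * li + 1]
            if li < n_layers - 1:
                z = z.relu()
        return z.reshape(z.shape[0]) if z.ndim == 2 else z

    def predict(self, H_P, H_W) -> np.ndarray:
        """Site probabilities in [0, 1] for a batch (or a single window)."""
        if not self.trained:
            logger.warning("predicting with an untrained model")
        dtype = self.fusion.W1.data.dtype
        H_P = np.asarray(H_P, dtype=dtype)
        H_W = np.asarray(H_W, dtype=dtype)
        single = H_P.ndim == 2
        if single:
            H_P, H_W = H_P[None], H_W[None]
        logits = self.forward_logits(Tensor(H_P), Tensor(H_W)).data
        probs = 1.0 / (1.0 + np.exp(-logits))
        return float(probs[0]) if single else probs

    # ------------------------------------------------------------ training
    def train(self, H_P: np.ndarray, H_W: np.ndarray, y: np.ndarray,
              config: TrainConfig | None = None) -> list[dict]:
        """Fit by Adam on binary cross-entropy with early stopping.

        A ``validation_fraction`` stratified split of the training data is
        held out; training stops once validation loss has not improved for
        ``patience`` epochs and the best-epoch parameters are restored.
        Returns the per-epoch history (train/val loss, val auPRC).
        """
        from .evaluation import auprc, validation_split

        config = config or TrainConfig()
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(config.seed)
        tr_idx, va_idx = validation_split(y, config.validation_fraction,
                                          seed=config.seed)
        Hp_tr, Hw_tr, y_tr = H_P[tr_idx], H_W[tr_idx], y[tr_idx]
        Hp_va, Hw_va, y_va = H_P[va_idx], H_W[va_idx], y[va_idx]

        params = self.parameters()
        opt = Adam(params, lr=config.learning_rate)
        history: list[dict] = []
        best_val = np.inf
        best_state = [p.data.copy() for p in params]
        stale = 0
        n = len(y_tr)
        for epoch in range(1, config.epochs + 1):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                logits = self.forward_logits(Tensor(Hp_tr[idx]), Tensor(Hw_tr[idx]))
                loss = bce_with_logits(logits, y_tr[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
                seen += len(idx)
            val_logits = self.forward_logits(Tensor(Hp_va), Tensor(Hw_va)).data
            val_loss = float(np.mean(np.maximum(val_logits, 0)
                                     - val_logits * y_va
                                     + np.log1p(np.exp(-np.abs(val_logits)))))
            val_probs = 1.0 / (1.0 + np.exp(-val_logits))
            val_ap = auprc(y_va, val_probs) if 0 < y_va.sum() < len(y_va) else None
            history.append({"epoch": epoch, "train_loss": epoch_loss / seen,
                            "val_loss": val_loss, "val_auprc": val_ap})
            logger.info("epoch %d train %.4f val %.4f", epoch,
                        epoch_loss / seen, val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = [p.data.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= config.patience and epoch >= config.min_epochs:
                    break
        for p, s in zip(params, best_state):
            p.data = s
        self.trained = True
        return history

    # --------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Checkpoint: one .npz archive holding a JSON manifest + tensors."""
        head_dims = [int(self.head[2 * li].shape[1])
                     for li in range(len(self.head) // 2 - 1)]
        manifest = {"hidden_size": self.hidden_size, "model_dim": self.model_dim,
                    "head_count": self.head_count, "trained": self.trained,
                    "alpha_res": self.bilstm_p.alpha_res,
                    "head_dims": head_dims,
                    "d_evo": int(self.bilstm_p.forward.W_i.shape[0]
                                 - self.hidden_size),
                    "d_sem": int(self.bilstm_w.forward.W_i.shape[0]
                                 - self.hidden_size),
                    "seq_len": int(self.bilstm_p.w_init.shape[0]),
                    "n_layers": 1 + len(self.extra_p)}
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, manifest=json.dumps(manifest), **arrays)

    @classmethod
    def load(cls, path) -> "FusionModel":
        archive = np.load(path, allow_pickle=False)
        manifest = json.loads(str(archive["manifest"]))
        model = cls.init(d_evo=manifest["d_evo"], d_sem=manifest["d_sem"],
                         seq_len=manifest["seq_len"],
                         n_layers=manifest.get("n_layers", 1),
                         hidden_size=manifest["hidden_size"],
                         model_dim=manifest["model_dim"],
                         head_count=manifest["head_count"],
                         head_dims=tuple(manifest["head_dims"]),
                         alpha_res=manifest["alpha_res"])
        for i, p in enumerate(model.parameters()):
            stored = archive[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(f"checkpoint tensor {i} has shape "
                                 f"{stored.shape}, expected {p.data.shape}")
            p.data = stored.astype(np.float64)
        model.trained = bool(manifest["trained"])
        return model
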