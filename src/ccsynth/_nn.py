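"""Minimal NumPy neural-network primitives shared by the sequence models.

Implements exactly what the package's models need: dense/embedding layers,
a single-layer LSTM and GRU with full backpropagation through time, softmax
cross-entropy with index-0 (padding) masking, and the Adam optimizer.
Parameters live in plain ``{name: ndarray}`` dicts (float64 throughout) so
training is bit-deterministic for a fixed seed and thread-independent.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -1e30


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape or (fan_in, fan_out))


class Adam:
    """Adam optimizer over a parameter dict (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# LSTM (forget/input/output gates; gate order in the fused matrix: i, f, g, o)
# ---------------------------------------------------------------------------

def lstm_forward(X: np.ndarray, h0: np.ndarray, c0: np.ndarray,
                 Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run an LSTM over ``X`` of shape (B, T, D); returns (H, cache).

    ``H`` holds the hidden state at every step, shape (B, T, Hdim).
    """
    B, T, _ = X.shape
    H = h0.shape[1]
    h, c = h0, c0
    Hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        z = X[:, t] @ Wx + h @ Wh + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((X[:, t], h, c, i, f, g, o, tc))
        h, c = h_new, c_new
        Hs[:, t] = h
    return Hs, cache


def lstm_step(x: np.ndarray, h: np.ndarray, c: np.ndarray,
              Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Single LSTM step for incremental decoding; returns (h, c)."""
    H = h.shape[-1]
    z = x @ Wx + h @ Wh + b
    i = sigmoid(z[..., :H])
    f = sigmoid(z[..., H:2 * H])
    g = np.tanh(z[..., 2 * H:3 * H])
    o = sigmoid(z[..., 3 * H:])
    c_new = f * c + i * g
    return o * np.tanh(c_new), c_new


def lstm_backward(dHs: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray):
    """BPTT for :func:`lstm_forward`.

    ``dHs`` is the loss gradient w.r.t. every hidden state (B, T, H).
    Returns (dX, dh0, dc0, dWx, dWh, db).
    """
    B, T, H = dHs.shape
    D = Wx.shape[0]
    dX = np.empty((B, T, D))
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
        dh = dHs[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate([
            di * i * (1 - i),
            df * f * (1 - f),
            dg * (1 - g * g),
            do * o * (1 - o),
        ], axis=1)
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ Wh.T
        dX[:, t] = dz @ Wx.T
    return dX, dh_next, dc_next, dWx, dWh, db


# ---------------------------------------------------------------------------
# GRU (update gate z, reset gate r, candidate n; original formulation with
# the reset gate applied to the previous hidden state before the matmul)
# ---------------------------------------------------------------------------

def gru_forward(X: np.ndarray, h0: np.ndarray,
                Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run a GRU over (B, T, D); fused matrices order gates as z, r, n."""
    B, T, _ = X.shape
    H = h0.shape[1]
    h = h0
    Hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        zx = X[:, t] @ Wx + b
        zh = h @ Wh[:, :2 * H]
        z = sigmoid(zx[:, :H] + zh[:, :H])
        r = sigmoid(zx[:, H:2 * H] + zh[:, H:])
        rh = r * h
        n = np.tanh(zx[:, 2 * H:] + rh @ Wh[:, 2 * H:])
        h_new = (1 - z) * n + z * h
        cache.append((X[:, t], h, z, r, rh, n))
        h = h_new
        Hs[:, t] = h
    return Hs, cache


def gru_backward(dHs: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray):
    """BPTT for :func:`gru_forward`; returns (dX, dh0, dWx, dWh, db)."""
    B, T, H = dHs.shape
    D = Wx.shape[0]
    dX = np.empty((B, T, D))
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dh_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, z, r, rh, n = cache[t]
        dh = dHs[:, t] + dh_next
        dn = dh * (1 - z)
        dz = dh * (h_prev - n)
        dh_prev = dh * z
        dan = dn * (1 - n * n)
        drh = dan @ Wh[:, 2 * H:].T
        dr = drh * h_prev
        dh_prev += drh * r
        dz_pre = dz * z * (1 - z)
        dr_pre = dr * r * (1 - r)
        dWh[:, :H] += h_prev.T @ dz_pre
        dWh[:, H:2 * H] += h_prev.T @ dr_pre
        dWh[:, 2 * H:] += rh.T @ dan
        dzx = np.concatenate([dz_pre, dr_pre, dan], axis=1)
        dWx += x_t.T @ dzx
        db += dzx.sum(axis=0)
        dh_prev += dz_pre @ Wh[:, :H].T + dr_pre @ Wh[:, H:2 * H].T
        dX[:, t] = dzx @ Wx.T
        dh_next = dh_prev
    return dX, dh_next, dWx, dWh, db


# ---------------------------------------------------------------------------
# masked softmax cross-entropy over a vocabulary with padding index 0
# ---------------------------------------------------------------------------

def masked_ce_loss_and_dlogits(logits: np.ndarray, targets: np.ndarray):
    """Mean next-token cross-entropy over non-padding targets.

    ``logits``: (B, T, V) with column 0 already masked to ``NEG_INF``;
    ``targets``: (B, T) int, 0 = padding (excluded from the mean).
    Returns (loss, dlogits).
    """
    B, T, V = logits.shape
    mask = targets != 0
    n = int(mask.sum())
    if n == 0:
        raise ValueError("batch contains no non-padding targets")
    p = softmax(logits, axis=-1)
    flat_p = p.reshape(-1, V)
    flat_t = targets.reshape(-1)
    idx = np.arange(flat_t.size)
    logp = np.log(np.maximum(flat_p[idx, flat_t], 1e-300))
    loss = -(logp * mask.reshape(-1)).sum() / n
    dflat = flat_p
    dflat[idx, flat_t] -= 1.0
    dflat *= (mask.reshape(-1, 1) / n)
    dflat[:, 0] = 0.0  # padding column is a masked constant
    return loss, dflat.reshape(B, T, V)
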