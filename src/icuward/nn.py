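"""Minimal numpy neural-network core for the sequence risk model.

Implements exactly what the classifier needs — a bidirectional LSTM
encoder over padded variable-length hourly grids, a small fully
connected branch for static features, a two-layer classification head
with a sigmoid output, binary cross-entropy with L2 weight penalty, and
Adam — with hand-derived backpropagation through time.  Gradients are
verified against central finite differences in the test suite.

Gate order throughout is (input, forget, cell, output); the forget-gate
bias is initialized to 1 so early training does not wash out state.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@njit(cache=True, fastmath=True)
def _lstm_forward_loop(Z, Wh, cs, tanh_cs, hs):  # pragma: no cover (jitted)
    """In-place LSTM recurrence.  Z is (T, B, 4H) holding x_t·Wx + b on
    entry and the post-nonlinearity gates (i, f, g, o) on exit."""
    T, B, H4 = Z.shape
    H = H4 // 4
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        a = Z[t]
        a += np.dot(h, Wh)
        for b in range(B):
            for j in range(H):
                i = 1.0 / (1.0 + np.exp(-a[b, j]))
                f = 1.0 / (1.0 + np.exp(-a[b, H + j]))
                g = np.tanh(a[b, 2 * H + j])
                o = 1.0 / (1.0 + np.exp(-a[b, 3 * H + j]))
                a[b, j] = i
                a[b, H + j] = f
                a[b, 2 * H + j] = g
                a[b, 3 * H + j] = o
                cv = f * c[b, j] + i * g
                c[b, j] = cv
                tc = np.tanh(cv)
                tanh_cs[t, b, j] = tc
                cs[t, b, j] = cv
                hv = o * tc
                h[b, j] = hv
                hs[t, b, j] = hv


@njit(cache=True, fastmath=True)
def _lstm_backward_loop(gates, cs, tanh_cs, hs, WhT, dh_out, last,
                        dZ, dWh):  # pragma: no cover (jitted)
    """Backpropagation through time; fills dZ (T, B, 4H) and dWh."""
    T, B, H4 = gates.shape
    H = H4 // 4
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        g4 = gates[t]
        da = dZ[t]
        for b in range(B):
            if last[b] == t:
                for j in range(H):
                    dh[b, j] += dh_out[b, j]
            for j in range(H):
                i = g4[b, j]
                f = g4[b, H + j]
                g = g4[b, 2 * H + j]
                o = g4[b, 3 * H + j]
                tc = tanh_cs[t, b, j]
                dcv = dc[b, j] + dh[b, j] * o * (1.0 - tc * tc)
                c_prev = cs[t - 1, b, j] if t > 0 else 0.0
                da[b, j] = dcv * g * i * (1.0 - i)
                da[b, H + j] = dcv * c_prev * f * (1.0 - f)
                da[b, 2 * H + j] = dcv * i * (1.0 - g * g)
                da[b, 3 * H + j] = dh[b, j] * tc * o * (1.0 - o)
                dc[b, j] = dcv * f
        if t > 0:
            dWh += np.dot(hs[t - 1].T, da)
        dh = np.dot(da, WhT)


class BiLSTMClassifier:
    """biLSTM(H per direction) over (B, T, F) dynamic grids + dense static
    branch, concatenated into a classification head emitting P(event).

    Parameters are a flat dict of numpy arrays; ``forward`` returns
    probabilities plus a cache consumed by ``backward``.
    """

    def __init__(self, n_dynamic: int, n_static: int = 1, hidden: int = 20,
                 static_width: int = 8, head_width: int = 16,
                 seed: int = 0) -> None:
        self.n_dynamic = n_dynamic
        self.n_static = n_static
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        H, F = hidden, n_dynamic
        p: dict[str, np.ndarray] = {}
        for d in ("fw", "bw"):
            p[f"Wx_{d}"] = _glorot(rng, F + H, 4 * H, (F, 4 * H))
            p[f"Wh_{d}"] = _glorot(rng, F + H, 4 * H, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget gate
            p[f"b_{d}"] = b
        p["Ws"] = _glorot(rng, n_static, static_width,
                          (n_static, static_width))
        p["bs"] = np.zeros(static_width)
        concat = 2 * H + static_width
        p["W1"] = _glorot(rng, concat, head_width, (concat, head_width))
        p["b1"] = np.zeros(head_width)
        p["W2"] = _glorot(rng, head_width, 1, (head_width, 1))
        p["b2"] = np.zeros(1)
        self.params = p

    # -- parameter bookkeeping ------------------------------------------

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    # -- forward ---------------------------------------------------------

    def _lstm_forward(self, X: np.ndarray, direction: str) -> dict:
        p = self.params
        B, T, F = X.shape
        H = self.hidden
        # input contributions for all steps at once; the (T, B, 4H) layout
        # keeps each step's slice contiguous for the jitted recurrence
        Z = X.reshape(B * T, F) @ p[f"Wx_{direction}"]
        Z += p[f"b_{direction}"]
        Z = np.ascontiguousarray(Z.reshape(B, T, 4 * H).transpose(1, 0, 2))
        cs = np.empty((T, B, H))
        tanh_cs = np.empty((T, B, H))
        hs = np.empty((T, B, H))
        _lstm_forward_loop(Z, np.ascontiguousarray(p[f"Wh_{direction}"]),
                           cs, tanh_cs, hs)
        return {"X": X, "gates": Z, "cs": cs, "tanh_cs": tanh_cs,
                "hs": hs, "direction": direction}

    def _lstm_backward(self, cache: dict, dh_out: np.ndarray,
                       lengths: np.ndarray,
                       grads: dict[str, np.ndarray]) -> None:
        """dh_out (B, H) is the gradient at each sequence's last valid
        step (t = length - 1); padded steps contribute nothing."""
        p = self.params
        d = cache["direction"]
        X = cache["X"]
        B, T, F = X.shape
        H = self.hidden
        dZ = np.empty((T, B, 4 * H))
        dWh = np.zeros_like(p[f"Wh_{d}"])
        _lstm_backward_loop(cache["gates"], cache["cs"], cache["tanh_cs"],
                            cache["hs"],
                            np.ascontiguousarray(p[f"Wh_{d}"].T),
                            np.ascontiguousarray(dh_out),
                            np.ascontiguousarray(lengths - 1), dZ, dWh)
        Xt = np.ascontiguousarray(X.transpose(1, 0, 2)).reshape(T * B, F)
        grads[f"Wx_{d}"] += Xt.T @ dZ.reshape(T * B, 4 * H)
        grads[f"Wh_{d}"] += dWh
        grads[f"b_{d}"] += dZ.sum(axis=(0, 1))

    def forward(self, X: np.ndarray, lengths: np.ndarray,
                static: np.ndarray) -> tuple[np.ndarray, dict]:
        """Probabilities for a padded batch.

        X is (B, T, F) with zero rows beyond each sequence's length;
        the backward direction consumes each sequence reversed within
        its own length.
        """
        p = self.params
        B, T, F = X.shape
        lengths = np.asarray(lengths, dtype=int)
        idx = np.arange(T)
        rev_idx = np.clip(lengths[:, None] - 1 - idx[None, :], 0, None)
        valid = idx[None, :] < lengths[:, None]
        Xrev = np.where(valid[:, :, None],
                        X[np.arange(B)[:, None], rev_idx], 0.0)
        cache_f = self._lstm_forward(X, "fw")
        cache_b = self._lstm_forward(Xrev, "bw")
        last = lengths - 1
        hf = cache_f["hs"][last, np.arange(B)]
        hb = cache_b["hs"][last, np.arange(B)]
        a_s = static @ p["Ws"] + p["bs"]
        hs = np.tanh(a_s)
        z = np.concatenate([hf, hb, hs], axis=1)
        a1 = z @ p["W1"] + p["b1"]
        h1 = np.tanh(a1)
        logit = (h1 @ p["W2"] + p["b2"]).ravel()
        prob = sigmoid(logit)
        cache = {"cache_f": cache_f, "cache_b": cache_b, "z": z, "h1": h1,
                 "hs": hs, "static": static, "lengths": lengths,
                 "prob": prob}
        return prob, cache

    # -- loss and backward ----------------------------------------------

    def loss_and_grads(self, X: np.ndarray, lengths: np.ndarray,
                       static: np.ndarray, y: np.ndarray,
                       l2: float = 0.0) -> tuple[float, dict[str, np.ndarray]]:
        """Mean binary cross-entropy + (l2/2)·Σ‖W‖² over weight matrices."""
        prob, cache = self.forward(X, lengths, static)
        B = len(y)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(prob + eps)
                              + (1 - y) * np.log(1 - prob + eps)))
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogit = ((prob - y) / B)[:, None]
        p = self.params
        h1, z, hs = cache["h1"], cache["z"], cache["hs"]
        grads["W2"] += h1.T @ dlogit
        grads["b2"] += dlogit.sum(0)
        dh1 = dlogit @ p["W2"].T
        da1 = dh1 * (1 - h1 * h1)
        grads["W1"] += z.T @ da1
        grads["b1"] += da1.sum(0)
        dz = da1 @ p["W1"].T
        H = self.hidden
        dhf, dhb, dhs = dz[:, :H], dz[:, H:2 * H], dz[:, 2 * H:]
        das = dhs * (1 - hs * hs)
        grads["Ws"] += cache["static"].T @ das
        grads["bs"] += das.sum(0)
        self._lstm_backward(cache["cache_f"], dhf, cache["lengths"], grads)
        self._lstm_backward(cache["cache_b"], dhb, cache["lengths"], grads)
        if l2 > 0:
            for k, v in self.params.items():
                if k.startswith(("Wx", "Wh", "W")):
                    loss += 0.5 * l2 * float(np.sum(v * v))
                    grads[k] += l2 * v
        return loss, grads


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
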