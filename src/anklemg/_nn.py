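"""Minimal NumPy implementation of the per-channel-branch CNN-LSTM.

Topology (fixed, sizes configurable): for each of the two LSTM time steps,
each signal channel owns a branch of two length-preserving 1-D
convolutions (ReLU after each), a max-pool of 2 and a flatten; the branch
outputs concatenate into one vector per step. The two-step sequence feeds
a single LSTM layer whose final hidden state passes through dropout, a
ReLU dense layer, dropout again, and a softmax dense layer over the six
movement classes.

Everything here is plain NumPy: explicit forward caches, hand-derived
backward passes and an Adam optimizer. Gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CnnLstmNet", "Adam", "softmax", "cross_entropy_loss"]

_EPS = 1e-12


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray, eps: float = _EPS) -> float:
    """Mean negative log-probability of the true class."""
    p = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(p + eps)))


def _sigmoid(z):
    # clipped for stability on far-out-of-distribution inputs; saturated
    # gates have zero gradient anyway
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _same_pad(k: int) -> tuple[int, int]:
    # total padding k-1; extra sample on the right for even kernels
    left = (k - 1) // 2
    return left, k - 1 - left


class CnnLstmNet:
    """The network with explicit parameters, forward cache and backward pass.

    Input arrays have shape (batch, n_steps, n_channels, length, in_feat).
    """

    def __init__(
        self,
        in_len: int,
        in_feat: int,
        n_channels: int = 4,
        n_steps: int = 2,
        conv_filters: int = 32,
        conv1_kernel: int = 3,
        conv2_kernel: int = 2,
        pool: int = 2,
        lstm_units: int = 50,
        dense_units: int = 100,
        n_classes: int = 6,
        dropout: float = 0.6,
        seed: int = 0,
    ):
        if in_len // pool < 1:
            raise ValueError("pooled length would be < 1; input too short for the pool size")
        self.in_len = in_len
        self.in_feat = in_feat
        self.n_channels = n_channels
        self.n_steps = n_steps
        self.conv_filters = conv_filters
        self.conv1_kernel = conv1_kernel
        self.conv2_kernel = conv2_kernel
        self.pool = pool
        self.lstm_units = lstm_units
        self.dense_units = dense_units
        self.n_classes = n_classes
        self.dropout = dropout
        self.pooled_len = in_len // pool
        self.branch_out = self.pooled_len * conv_filters
        self.concat_dim = n_channels * self.branch_out

        rng = np.random.default_rng(seed)
        p = {}
        for c in range(n_channels):
            p[f"W1_{c}"] = _glorot(
                rng, (conv1_kernel, in_feat, conv_filters),
                conv1_kernel * in_feat, conv_filters,
            )
            p[f"b1_{c}"] = np.zeros(conv_filters)
            p[f"W2_{c}"] = _glorot(
                rng, (conv2_kernel, conv_filters, conv_filters),
                conv2_kernel * conv_filters, conv_filters,
            )
            p[f"b2_{c}"] = np.zeros(conv_filters)
        D, H = self.concat_dim, lstm_units
        p["Wx"] = _glorot(rng, (D, 4 * H), D, 4 * H)
        p["Wh"] = _glorot(rng, (H, 4 * H), H, 4 * H)
        p["b_lstm"] = np.zeros(4 * H)
        p["b_lstm"][H : 2 * H] = 1.0  # forget-gate bias
        p["W_d1"] = _glorot(rng, (H, dense_units), H, dense_units)
        p["b_d1"] = np.zeros(dense_units)
        p["W_d2"] = _glorot(rng, (dense_units, n_classes), dense_units, n_classes)
        p["b_d2"] = np.zeros(n_classes)
        self.params = p

    # ----- convolution primitives -------------------------------------
    @staticmethod
    def _conv_forward(x, W, b):
        """x (B, L, Cin), W (k, Cin, Cout) -> y (B, L, Cout), same padding."""
        k = W.shape[0]
        L = x.shape[1]
        pl, pr = _same_pad(k)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        y = np.tensordot(xp[:, 0:L, :], W[0], axes=([2], [0]))
        for j in range(1, k):
            y += np.tensordot(xp[:, j : j + L, :], W[j], axes=([2], [0]))
        return y + b, xp

    @staticmethod
    def _conv_backward(dy, xp, W, L):
        k = W.shape[0]
        pl, _ = _same_pad(k)
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for j in range(k):
            dW[j] = np.einsum("blc,blo->co", xp[:, j : j + L, :], dy)
            dxp[:, j : j + L, :] += dy @ W[j].T
        db = dy.sum(axis=(0, 1))
        dx = dxp[:, pl : pl + L, :]
        return dx, dW, db

    # ----- forward ----------------------------------------------------
    def forward(self, X, train: bool = False, rng: np.random.Generator | None = None):
        """Return class probabilities (B, n_classes) and a backward cache."""
        X = np.asarray(X, dtype=float)
        B, S, C, L, F = X.shape
        if (S, C, L, F) != (self.n_steps, self.n_channels, self.in_len, self.in_feat):
            raise ValueError(
                f"input shape {X.shape[1:]} does not match network "
                f"({self.n_steps}, {self.n_channels}, {self.in_len}, {self.in_feat})"
            )
        cache = {"B": B, "branches": []}
        seq_parts = []
        for c in range(self.n_channels):
            xc = X[:, :, c].reshape(B * S, L, F)
            a1, xp1 = self._conv_forward(xc, self.params[f"W1_{c}"], self.params[f"b1_{c}"])
            r1 = np.maximum(a1, 0.0)
            a2, xp2 = self._conv_forward(r1, self.params[f"W2_{c}"], self.params[f"b2_{c}"])
            r2 = np.maximum(a2, 0.0)
            P = self.pooled_len
            blocks = r2[:, : P * self.pool, :].reshape(B * S, P, self.pool, -1)
            arg = blocks.argmax(axis=2)
            pooled = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
            flat = pooled.reshape(B * S, -1)
            cache["branches"].append(
                {"xp1": xp1, "a1": a1, "r1": r1, "xp2": xp2, "a2": a2, "arg": arg}
            )
            seq_parts.append(flat)
        seq = np.concatenate(seq_parts, axis=1).reshape(B, S, self.concat_dim)
        cache["seq"] = seq

        # LSTM over the steps, final hidden state only
        H = self.lstm_units
        h = np.zeros((B, H))
        cc = np.zeros((B, H))
        steps = []
        for s in range(S):
            x_s = seq[:, s, :]
            z = x_s @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b_lstm"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * cc + i * g
            h_new = o * np.tanh(c_new)
            steps.append({"x": x_s, "h_prev": h, "c_prev": cc, "i": i, "f": f,
                          "g": g, "o": o, "c": c_new})
            h, cc = h_new, c_new
        cache["steps"] = steps

        keep = 1.0 - self.dropout
        if train and self.dropout > 0:
            if rng is None:
                rng = np.random.default_rng()
            m1 = (rng.random(h.shape) < keep) / keep
        else:
            m1 = np.ones_like(h)
        hd = h * m1
        a_d1 = hd @ self.params["W_d1"] + self.params["b_d1"]
        r_d1 = np.maximum(a_d1, 0.0)
        if train and self.dropout > 0:
            m2 = (rng.random(r_d1.shape) < keep) / keep
        else:
            m2 = np.ones_like(r_d1)
        rd = r_d1 * m2
        logits = rd @ self.params["W_d2"] + self.params["b_d2"]
        probs = softmax(logits)
        cache.update(h_last=h, m1=m1, hd=hd, a_d1=a_d1, m2=m2, rd=rd, probs=probs)
        return probs, cache

    # ----- backward ---------------------------------------------------
    def backward(self, cache, labels):
        """Gradients of the mean cross-entropy w.r.t. every parameter."""
        B = cache["B"]
        probs = cache["probs"]
        grads = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B

        grads["W_d2"] = cache["rd"].T @ dlogits
        grads["b_d2"] = dlogits.sum(axis=0)
        drd = dlogits @ self.params["W_d2"].T
        dr_d1 = drd * cache["m2"]
        da_d1 = dr_d1 * (cache["a_d1"] > 0)
        grads["W_d1"] = cache["hd"].T @ da_d1
        grads["b_d1"] = da_d1.sum(axis=0)
        dhd = da_d1 @ self.params["W_d1"].T
        dh = dhd * cache["m1"]

        # LSTM backward through time (gradient enters at the last step only)
        H = self.lstm_units
        S = self.n_steps
        grads["Wx"] = np.zeros_like(self.params["Wx"])
        grads["Wh"] = np.zeros_like(self.params["Wh"])
        grads["b_lstm"] = np.zeros_like(self.params["b_lstm"])
        dseq = np.zeros_like(cache["seq"])
        dc = np.zeros((B, H))
        for s in reversed(range(S)):
            st = cache["steps"][s]
            tanh_c = np.tanh(st["c"])
            do = dh * tanh_c
            dc = dc + dh * st["o"] * (1.0 - tanh_c**2)
            di = dc * st["g"]
            df = dc * st["c_prev"]
            dg = dc * st["i"]
            dz = np.concatenate(
                [
                    di * st["i"] * (1 - st["i"]),
                    df * st["f"] * (1 - st["f"]),
                    dg * (1 - st["g"] ** 2),
                    do * st["o"] * (1 - st["o"]),
                ],
                axis=1,
            )
            grads["Wx"] += st["x"].T @ dz
            grads["Wh"] += st["h_prev"].T @ dz
            grads["b_lstm"] += dz.sum(axis=0)
            dseq[:, s, :] = dz @ self.params["Wx"].T
            dh = dz @ self.params["Wh"].T
            dc = dc * st["f"]

        # branch backward
        dseq_flat = dseq.reshape(B * S, self.concat_dim)
        L, P = self.in_len, self.pooled_len
        for c in range(self.n_channels):
            br = cache["branches"][c]
            dflat = dseq_flat[:, c * self.branch_out : (c + 1) * self.branch_out]
            dpool = dflat.reshape(B * S, P, self.conv_filters)
            dr2 = np.zeros((B * S, L, self.conv_filters))
            dblocks = np.zeros((B * S, P, self.pool, self.conv_filters))
            np.put_along_axis(dblocks, br["arg"][:, :, None, :], dpool[:, :, None, :], axis=2)
            dr2[:, : P * self.pool, :] = dblocks.reshape(B * S, P * self.pool, -1)
            da2 = dr2 * (br["a2"] > 0)
            dr1, dW2, db2 = self._conv_backward(da2, br["xp2"], self.params[f"W2_{c}"], L)
            da1 = dr1 * (br["a1"] > 0)
            _, dW1, db1 = self._conv_backward(da1, br["xp1"], self.params[f"W1_{c}"], L)
            grads[f"W2_{c}"] = dW2
            grads[f"b2_{c}"] = db2
            grads[f"W1_{c}"] = dW1
            grads[f"b1_{c}"] = db1
        return grads

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
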