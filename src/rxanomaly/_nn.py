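"""Minimal feed-forward engine for the disease→drug relation network.

Implements exactly the pieces that network needs — dense layers, 3×3
convolutions (via im2col), sigmoid/ReLU, a gated output-refinement
recurrence, and Adam — with hand-written backward passes on numpy arrays.
The architecture is fixed by :class:`NetParams`; batches are row-major
``(batch, features)`` float32 arrays.

Loss gradients (multi-label binary cross-entropy and focal loss) are
computed analytically with respect to the logits.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np

EPS = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# im2col convolution


def _conv_geometry(h: int, w: int, k: int, stride: int, pad: int) -> Tuple[int, int]:
    return (h + 2 * pad - k) // stride + 1, (w + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    b, c, h, w = x.shape
    ho, wo = _conv_geometry(h, w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((b, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols.reshape(b, c * k * k, ho * wo)


def _col2im(dcols: np.ndarray, xshape: Tuple[int, ...], k: int, stride: int,
            pad: int) -> np.ndarray:
    b, c, h, w = xshape
    ho, wo = _conv_geometry(h, w, k, stride, pad)
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(b, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv_forward(x, kernel, bias, stride, pad):
    f, c, k, _ = kernel.shape
    b = x.shape[0]
    ho, wo = _conv_geometry(x.shape[2], x.shape[3], k, stride, pad)
    cols = _im2col(x, k, stride, pad)
    out = np.einsum("fq,bqp->bfp", kernel.reshape(f, -1), cols, optimize=True)
    out += bias[None, :, None]
    return out.reshape(b, f, ho, wo), cols


def conv_backward(dout, cols, x_shape, kernel, stride, pad):
    f = kernel.shape[0]
    b = dout.shape[0]
    dflat = dout.reshape(b, f, -1)
    dkernel = np.einsum("bfp,bqp->fq", dflat, cols, optimize=True).reshape(kernel.shape)
    dbias = dflat.sum(axis=(0, 2))
    dcols = np.einsum("fq,bfp->bqp", kernel.reshape(f, -1), dflat, optimize=True)
    dx = _col2im(dcols, x_shape, kernel.shape[2], stride, pad)
    return dx, dkernel, dbias


# ---------------------------------------------------------------------------
# the relation network


class NetParams:
    """Parameter container: dense 512 encoder, two convs (16×16×8, 4×4×32),
    dense decoder back to the drug-vocabulary logits, gated refinement."""

    GRID = (2, 16, 16)  # 512 = 2·16·16
    C1, C2 = 8, 32
    K = 3
    S1, P1 = 1, 1  # (2,16,16)  -> (8,16,16)
    S2, P2 = 4, 1  # (8,16,16)  -> (32,4,4)

    def __init__(self, input_dim: int, output_dim: int, hidden_dim: int,
                 refine_steps: int, rng: np.random.Generator,
                 output_prior: float = 0.003):
        if hidden_dim != int(np.prod(self.GRID)):
            raise ValueError("hidden_dim must equal 512 (the 2x16x16 grid)")
        self.input_dim = input_dim
        self.output_dim = output_dim
        self.refine_steps = refine_steps

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        flat2 = self.C2 * 4 * 4  # 512 after the second conv
        self.p: Dict[str, np.ndarray] = {
            "W0": he((input_dim, hidden_dim), input_dim),
            "b0": np.zeros(hidden_dim, dtype=np.float32),
            "K1": he((self.C1, self.GRID[0], self.K, self.K), self.GRID[0] * self.K**2),
            "c1": np.zeros(self.C1, dtype=np.float32),
            "K2": he((self.C2, self.C1, self.K, self.K), self.C1 * self.K**2),
            "c2": np.zeros(self.C2, dtype=np.float32),
            "W1": he((flat2, 256), flat2),
            "b1": np.zeros(256, dtype=np.float32),
            "W2": he((256, output_dim), 256),
            # prior initialization: start every label's probability near the
            # typical positive rate so the focal loss does not freeze the
            # background at an inflated level
            "b2": np.full(output_dim, -math.log((1 - output_prior) / output_prior),
                          dtype=np.float32),
        }
        if refine_steps > 0:
            self.p["Wc"] = he((output_dim, output_dim), output_dim) * 0.1
            self.p["bc"] = np.zeros(output_dim, dtype=np.float32)
            self.p["gz"] = np.ones(output_dim, dtype=np.float32)
            self.p["bz"] = np.full(output_dim, 2.0, dtype=np.float32)  # gate opens toward identity

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        cache: Dict[str, object] = {"x": x}
        h0 = x @ self.p["W0"] + self.p["b0"]
        a0 = np.maximum(h0, 0.0)
        cache["a0"] = a0
        g = a0.reshape(-1, *self.GRID)
        cache["g_shape"] = g.shape
        z1, cols1 = conv_forward(g, self.p["K1"], self.p["c1"], self.S1, self.P1)
        a1 = np.maximum(z1, 0.0)
        z2, cols2 = conv_forward(a1, self.p["K2"], self.p["c2"], self.S2, self.P2)
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(x.shape[0], -1)
        h1 = flat @ self.p["W1"] + self.p["b1"]
        a3 = np.maximum(h1, 0.0)
        logits = a3 @ self.p["W2"] + self.p["b2"]
        refine_cache: List[Tuple[np.ndarray, ...]] = []
        h = logits
        for _ in range(self.refine_steps):
            s = sigmoid(h)
            c = s @ self.p["Wc"] + self.p["bc"]
            z = sigmoid(s * self.p["gz"] + self.p["bz"])
            h_new = z * h + (1.0 - z) * c
            refine_cache.append((h, s, c, z))
            h = h_new
        if want_cache:
            cache.update(a1=a1, a2=a2, cols1=cols1, cols2=cols2, flat=flat,
                         a3=a3, z1=z1, z2=z2, h1=h1, refine=refine_cache,
                         a1_shape=a1.shape)
            return h, cache
        return h, None

    # -- backward ---------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: Dict[str, object]) -> Dict[str, np.ndarray]:
        g: Dict[str, np.ndarray] = {}
        dh = dlogits
        if self.refine_steps > 0:
            g["Wc"] = np.zeros_like(self.p["Wc"])
            g["bc"] = np.zeros_like(self.p["bc"])
            g["gz"] = np.zeros_like(self.p["gz"])
            g["bz"] = np.zeros_like(self.p["bz"])
            for h_in, s, c, z in reversed(cache["refine"]):
                dz = dh * (h_in - c)
                dh_prev = dh * z
                dc = dh * (1.0 - z)
                g["Wc"] += s.T @ dc
                g["bc"] += dc.sum(axis=0)
                ds = dc @ self.p["Wc"].T
                da = dz * z * (1.0 - z)
                g["gz"] += (da * s).sum(axis=0)
                g["bz"] += da.sum(axis=0)
                ds += da * self.p["gz"]
                dh = dh_prev + ds * s * (1.0 - s)
        a3 = cache["a3"]
        g["W2"] = a3.T @ dh
        g["b2"] = dh.sum(axis=0)
        da3 = dh @ self.p["W2"].T
        dh1 = da3 * (cache["h1"] > 0)
        flat = cache["flat"]
        g["W1"] = flat.T @ dh1
        g["b1"] = dh1.sum(axis=0)
        dflat = dh1 @ self.p["W1"].T
        da2 = dflat.reshape(cache["a2"].shape) * (cache["z2"] > 0)
        da1, g["K2"], g["c2"] = conv_backward(da2, cache["cols2"], cache["a1_shape"],
                                              self.p["K2"], self.S2, self.P2)
        da1 *= cache["z1"] > 0
        dg, g["K1"], g["c1"] = conv_backward(da1, cache["cols1"], cache["g_shape"],
                                             self.p["K1"], self.S1, self.P1)
        da0 = dg.reshape(cache["a0"].shape) * (cache["a0"] > 0)
        g["W0"] = cache["x"].T @ da0
        g["b0"] = da0.sum(axis=0)
        return g


class Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# loss gradients w.r.t. logits


def bce_grad(logits: np.ndarray, targets: np.ndarray) -> Tuple[float, np.ndarray]:
    p = np.clip(sigmoid(logits), EPS, 1.0 - EPS)
    loss = -(targets * np.log(p) + (1 - targets) * np.log(1 - p)).sum(axis=1).mean()
    dlogits = (p - targets) / logits.shape[0]
    return float(loss), dlogits.astype(np.float32)


def focal_grad(logits: np.ndarray, targets: np.ndarray, alpha: float,
               gamma: float) -> Tuple[float, np.ndarray]:
    p = np.clip(sigmoid(logits), EPS, 1.0 - EPS)
    pt = p * targets + (1 - p) * (1 - targets)
    at = alpha * targets + (1 - alpha) * (1 - targets)
    one_minus = 1.0 - pt
    loss = -(at * one_minus**gamma * np.log(pt)).sum(axis=1).mean()
    # d/dpt of -(1-pt)^g log(pt), times alpha_t
    dpt = at * (gamma * one_minus**np.maximum(gamma - 1.0, 0.0) * np.log(pt)
                - one_minus**gamma / pt)
    dlogits = dpt * (2 * targets - 1) * p * (1 - p) / logits.shape[0]
    return float(loss), dlogits.astype(np.float32)
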