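"""Minimal functional CNN in NumPy with hand-written backprop.

The interior-exterior classifier uses the classic few-shot architecture:
four blocks of 3x3 convolution -> batch normalization -> ReLU -> 2x2 max
pooling, followed by a linear 2-way head.  Parameters live in a flat dict
so that task adaptation can operate on cloned parameter sets; forward
returns a cache consumed by the corresponding backward.

Batch normalization uses batch statistics at adaptation and prediction
time (transductive, the standard choice for episodic few-shot training);
no running averages are kept.  All math is float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

EPS = 1e-5


def init_params(
    rng: np.random.Generator,
    in_channels: int = 3,
    channels: int = 32,
    input_side: int = 84,
    n_classes: int = 2,
    n_blocks: int = 4,
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    cin = in_channels
    side = input_side
    for i in range(n_blocks):
        fan_in = cin * 9
        params[f"W{i}"] = (
            rng.standard_normal((channels, cin, 3, 3)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        params[f"b{i}"] = np.zeros(channels, dtype=np.float32)
        params[f"g{i}"] = np.ones(channels, dtype=np.float32)
        params[f"beta{i}"] = np.zeros(channels, dtype=np.float32)
        cin = channels
        side = (side // 2) if side % 2 == 0 else ((side - 1) // 2)
    feat = channels * side * side
    params["Wf"] = (rng.standard_normal((feat, n_classes)) * np.sqrt(1.0 / feat)).astype(
        np.float32
    )
    params["bf"] = np.zeros(n_classes, dtype=np.float32)
    return params


def clone_params(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in params.items()}


def _conv_forward(x, W, b):
    B, C, H, Wd = x.shape
    cout = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B, C, H, Wd, 3, 3)
    cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * Wd, C * 9
    )
    Wm = W.reshape(cout, C * 9)
    out = cols @ Wm.T + b
    out = out.reshape(B, H, Wd, cout).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, W)


def _conv_backward(dout, cache):
    cols, xshape, W = cache
    B, C, H, Wd = xshape
    cout = W.shape[0]
    dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(B * H * Wd, cout)
    dW = (dmat.T @ cols).reshape(W.shape)
    db = dmat.sum(axis=0)
    # dx = full correlation of dout with the flipped kernels
    dpad = np.pad(
        dout.reshape(B, cout, H, Wd), ((0, 0), (0, 0), (1, 1), (1, 1))
    )
    dcols = sliding_window_view(dpad, (3, 3), axis=(2, 3))
    dcols = np.ascontiguousarray(dcols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * Wd, cout * 9
    )
    Wt = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(C, cout * 9)
    dx = (dcols @ Wt.T).reshape(B, H, Wd, C).transpose(0, 3, 1, 2)
    return dx, dW.astype(np.float32), db.astype(np.float32)


def _bn_forward(x, gamma, beta):
    mu = x.mean(axis=(0, 2, 3), keepdims=True)
    var = x.var(axis=(0, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + EPS)
    xhat = (x - mu) * inv
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out, (xhat, inv, gamma)


def _bn_backward(dout, cache):
    xhat, inv, gamma = cache
    m = dout.shape[0] * dout.shape[2] * dout.shape[3]
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * gamma[None, :, None, None]
    dx = (
        inv
        / m
        * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
    )
    return dx.astype(np.float32), dgamma.astype(np.float32), dbeta.astype(np.float32)


def _pool_forward(x):
    B, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    xc = x[:, :, : 2 * H2, : 2 * W2]
    win = xc.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, H2, W2, 4
    )
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout, cache):
    idx, xshape = cache
    B, C, H, W = xshape
    H2, W2 = H // 2, W // 2
    dwin = np.zeros((B, C, H2, W2, 4), dtype=np.float32)
    np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(xshape, dtype=np.float32)
    dx[:, :, : 2 * H2, : 2 * W2] = (
        dwin.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, 2 * H2, 2 * W2
        )
    )
    return dx


def forward(params: dict[str, np.ndarray], x: np.ndarray, n_blocks: int = 4):
    """Logits for a batch ``x`` of shape (B, 3, S, S); returns (logits, cache)."""
    caches = []
    h = x.astype(np.float32)
    for i in range(n_blocks):
        h, c_conv = _conv_forward(h, params[f"W{i}"], params[f"b{i}"])
        h, c_bn = _bn_forward(h, params[f"g{i}"], params[f"beta{i}"])
        relu_mask = h > 0
        h = h * relu_mask
        h, c_pool = _pool_forward(h)
        caches.append((c_conv, c_bn, relu_mask, c_pool))
    B = h.shape[0]
    flat = h.reshape(B, -1)
    logits = flat @ params["Wf"] + params["bf"]
    caches.append((flat, h.shape))
    return logits, caches


def backward(
    params: dict[str, np.ndarray], caches, dlogits: np.ndarray, n_blocks: int = 4
) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    flat, hshape = caches[-1]
    grads["Wf"] = flat.T @ dlogits
    grads["bf"] = dlogits.sum(axis=0)
    dh = (dlogits @ params["Wf"].T).reshape(hshape)
    for i in reversed(range(n_blocks)):
        c_conv, c_bn, relu_mask, c_pool = caches[i]
        dh = _pool_backward(dh, c_pool)
        dh = dh * relu_mask
        dh, grads[f"g{i}"], grads[f"beta{i}"] = _bn_backward(dh, c_bn)
        dh, grads[f"W{i}"], grads[f"b{i}"] = _conv_backward(dh, c_conv)
    return grads


def softmax_xent(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    B = len(y)
    loss = float(-np.log(probs[np.arange(B), y] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, (dlogits / B).astype(np.float32), probs


def loss_and_grads(params, x, y, n_blocks: int = 4):
    logits, caches = forward(params, x, n_blocks)
    loss, dlogits, probs = softmax_xent(logits, y)
    grads = backward(params, caches, dlogits, n_blocks)
    return loss, grads, probs


def sgd_step(params, grads, lr: float) -> dict[str, np.ndarray]:
    return {k: params[k] - lr * grads[k] for k in params}


class Adam:
    """Plain Adam for the meta (outer-loop) update."""

    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = {}
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out
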