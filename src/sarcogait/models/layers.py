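"""Minimal numpy/autograd neural-network primitives.

Pure functional layers over ``autograd.numpy`` arrays; parameters live in
plain nested dicts so they can be flattened for the optimizers and
inspected by tests.  Batch-norm running statistics are kept in a separate
mutable ``state`` dict, updated (outside the autodiff trace) only in
training mode.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

__all__ = [
    "conv2d", "relu", "batch_norm", "max_pool2d", "global_avg_pool",
    "linear", "softmax", "log_softmax", "cross_entropy",
    "he_conv", "he_linear", "bn_params", "bn_state",
]

# ---------------------------------------------------------------------------
# layers


def conv2d(x, w, b=None, stride=(1, 1), pad=(0, 0)):
    """2-D convolution (cross-correlation) as a sum of shifted matmuls.

    x: (N, C, H, W); w: (O, C, kh, kw); returns (N, O, H', W').
    One tensordot per kernel tap over strided slices — this avoids the
    large non-contiguous im2col gathers that dominate runtime in autograd.
    """
    N, C, H, W = x.shape
    O, _, kh, kw = w.shape
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (pad, pad) if isinstance(pad, int) else pad
    if ph or pw:
        x = anp.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode="constant")
    oh = (H + 2 * ph - kh) // sh + 1
    ow = (W + 2 * pw - kw) // sw + 1
    out = 0.0
    for di in range(kh):
        for dj in range(kw):
            sl = x[:, :, di:di + (oh - 1) * sh + 1:sh, dj:dj + (ow - 1) * sw + 1:sw]
            # (N, C, oh, ow) x (O, C) -> (N, oh, ow, O)
            out = out + anp.tensordot(sl, w[:, :, di, dj], axes=([1], [1]))
    out = anp.transpose(out, (0, 3, 1, 2))
    if b is not None:
        out = out + b[None, :, None, None]
    return out


def relu(x):
    return anp.maximum(x, 0.0)


def batch_norm(x, p, state, key, train, axes=(0, 2, 3), momentum=0.1, eps=1e-5):
    """Batch normalization with running statistics.

    ``p`` holds ``gamma``/``beta``; ``state[key]`` holds running mean/var.
    In training mode batch statistics normalize and the running stats are
    updated through ``getval`` (kept out of the gradient trace); in eval
    mode the running statistics are used, so outputs are per-sample.
    """
    gamma, beta = p["gamma"], p["beta"]
    shape = [1] * x.ndim
    shape[1] = x.shape[1]
    if train:
        mean = anp.mean(x, axis=axes)
        var = anp.var(x, axis=axes)
        st = state[key]
        st["mean"] = (1 - momentum) * st["mean"] + momentum * getval(mean)
        st["var"] = (1 - momentum) * st["var"] + momentum * getval(var)
    else:
        mean, var = state[key]["mean"], state[key]["var"]
    xn = (x - anp.reshape(mean, shape)) / anp.sqrt(anp.reshape(var, shape) + eps)
    return xn * anp.reshape(gamma, shape) + anp.reshape(beta, shape)


def max_pool2d(x, k=3, stride=2, pad=1):
    N, C, H, W = x.shape
    if pad:
        # pad with -inf so padding never wins the max
        x = anp.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                    mode="constant", constant_values=-np.inf)
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    taps = [x[:, :, di:di + (oh - 1) * stride + 1:stride,
              dj:dj + (ow - 1) * stride + 1:stride]
            for di in range(k) for dj in range(k)]
    return anp.max(anp.stack(taps, axis=0), axis=0)


def global_avg_pool(x):
    """Mean over all trailing spatial axes -> (N, C)."""
    return anp.mean(anp.reshape(x, (x.shape[0], x.shape[1], -1)), axis=2)


def linear(x, p):
    return x @ p["w"] + p["b"]


def log_softmax(z):
    zmax = anp.max(z, axis=1, keepdims=True)
    return z - zmax - anp.log(anp.sum(anp.exp(z - zmax), axis=1, keepdims=True))


def softmax(z):
    return anp.exp(log_softmax(z))


def cross_entropy(logits, labels):
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    lp = log_softmax(logits)
    return -anp.mean(lp[anp.arange(logits.shape[0]), labels])


# ---------------------------------------------------------------------------
# initializers


def he_conv(rng: np.random.Generator, out_ch, in_ch, kh, kw):
    fan_in = in_ch * kh * kw
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kh, kw))


def he_linear(rng: np.random.Generator, n_in, n_out):
    return {"w": rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)),
            "b": np.zeros(n_out)}


def bn_params(n_ch):
    return {"gamma": np.ones(n_ch), "beta": np.zeros(n_ch)}


def bn_state(n_ch):
    return {"mean": np.zeros(n_ch), "var": np.ones(n_ch)}
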