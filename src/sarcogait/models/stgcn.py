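"""Spatiotemporal graph-convolutional classifier for skeleton sequences.

Each block applies a spatial graph convolution (per-partition 1x1 channel
mixing contracted against the normalized adjacency), then a temporal
convolution with an odd kernel over frames, with batch norm, ReLU, and a
residual connection.  An optional joint-attention mask — one learned
weight per joint, softmax-normalized over joints — rescales node features
before global pooling.  The head is global average pooling over time and
joints followed by a linear layer and softmax over the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from . import layers as L

__all__ = ["STGCNConfig", "STGCN", "stgcn_forward"]

BRANCHES = ("position", "velocity", "bone")


@dataclass(frozen=True)
class STGCNConfig:
    """Architecture hyperparameters.

    ``block_channels`` gives the output width of each spatiotemporal block;
    the desk-scale profile is ``(32, 64)`` with ``temporal_kernel=9``.
    """

    input_branches: tuple[str, ...] = ("position", "velocity", "bone")
    block_channels: tuple[int, ...] = (64, 128, 256)
    temporal_kernel: int = 9
    attention_enabled: bool = True
    num_classes: int = 2
    partition_strategy: str = "spatial"
    norm: str = "batch"  # "batch" | "none"
    channels_per_branch: int = 3

    def __post_init__(self) -> None:
        if not self.input_branches:
            raise ValueError("at least one input branch must be enabled")
        unknown = set(self.input_branches) - set(BRANCHES)
        if unknown:
            raise ValueError(f"unknown branches {sorted(unknown)}; valid: {BRANCHES}")
        if self.temporal_kernel < 1 or self.temporal_kernel % 2 == 0:
            raise ValueError("temporal_kernel must be a positive odd integer")
        if self.num_classes != 2:
            raise ValueError("this analysis is binary: num_classes must be 2")
        if self.norm not in ("batch", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")

    @property
    def in_channels(self) -> int:
        return self.channels_per_branch * len(self.input_branches)


class STGCN:
    """Functional model: parameters in ``self.params``, BN stats in ``self.state``."""

    def __init__(self, config: STGCNConfig, adjacency: np.ndarray, seed: int = 0):
        adjacency = np.asarray(adjacency, dtype=float)
        if adjacency.ndim != 3 or adjacency.shape[1] != adjacency.shape[2]:
            raise ValueError(f"adjacency must be (K, V, V), got {adjacency.shape}")
        self.config = config
        self.adjacency = adjacency
        self.n_joints = adjacency.shape[1]
        rng = np.random.default_rng(seed)
        self.params, self.state = self._init(rng)

    def _init(self, rng: np.random.Generator):
        cfg = self.config
        k = self.adjacency.shape[0]
        params: dict = {"blocks": []}
        state: dict = {}
        c_in = cfg.in_channels
        for bi, c_out in enumerate(cfg.block_channels):
            blk = {
                # one 1x1 channel-mixing matrix per partition subset
                "spatial_w": rng.normal(0, np.sqrt(2.0 / (c_in * k)), size=(k, c_in, c_out)),
                "spatial_b": np.zeros(c_out),
                "bn1": L.bn_params(c_out),
                "temporal_w": L.he_conv(rng, c_out, c_out, cfg.temporal_kernel, 1),
                "temporal_b": np.zeros(c_out),
                "bn2": L.bn_params(c_out),
            }
            if c_in != c_out:
                blk["res_w"] = L.he_conv(rng, c_out, c_in, 1, 1)
            params["blocks"].append(blk)
            state[f"bn1_{bi}"] = L.bn_state(c_out)
            state[f"bn2_{bi}"] = L.bn_state(c_out)
            c_in = c_out
        if cfg.attention_enabled:
            params["attention"] = np.zeros(self.n_joints)
        params["fc"] = L.he_linear(rng, c_in, cfg.num_classes)
        return params, state

    # -- forward -----------------------------------------------------------

    def _validate(self, x) -> None:
        cfg = self.config
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, T, V) input, got shape {x.shape}")
        n, c, t, v = x.shape
        if c != cfg.in_channels:
            raise ValueError(f"expected C={cfg.in_channels} "
                             f"({len(cfg.input_branches)} branches x "
                             f"{cfg.channels_per_branch}), got C={c}")
        if v != self.n_joints:
            raise ValueError(f"expected V={self.n_joints} joints, got V={v}")
        if t < cfg.temporal_kernel:
            raise ValueError(f"T={t} is shorter than temporal kernel "
                             f"{cfg.temporal_kernel}")

    def logits(self, params, x, train: bool = False):
        self._validate(x)
        cfg = self.config
        kt = cfg.temporal_kernel
        h = x
        for bi, blk in enumerate(params["blocks"]):
            # spatial graph convolution: mix channels per subset, then
            # aggregate over neighboring joints through the adjacency
            # (two pairwise contractions; a single 3-operand einsum is
            # prohibitively slow under autograd)
            y = 0.0
            for k in range(self.adjacency.shape[0]):
                zk = anp.tensordot(h, blk["spatial_w"][k], axes=([1], [0]))  # n,t,v,d
                y = y + anp.tensordot(zk, self.adjacency[k], axes=([2], [0]))  # n,t,d,w
            y = anp.transpose(y, (0, 2, 1, 3))
            y = y + blk["spatial_b"][None, :, None, None]
            if cfg.norm == "batch":
                y = L.batch_norm(y, blk["bn1"], self.state, f"bn1_{bi}", train)
            y = L.relu(y)
            y = L.conv2d(y, blk["temporal_w"], blk["temporal_b"],
                         stride=(1, 1), pad=((kt - 1) // 2, 0))
            if cfg.norm == "batch":
                y = L.batch_norm(y, blk["bn2"], self.state, f"bn2_{bi}", train)
            if "res_w" in blk:
                res = L.conv2d(h, blk["res_w"], stride=(1, 1), pad=(0, 0))
            else:
                res = h
            h = L.relu(y + res)
        if cfg.attention_enabled:
            att = self.attention_weights(params)
            h = h * (self.n_joints * att)[None, None, None, :]
        pooled = L.global_avg_pool(h)           # mean over T and V
        return L.linear(pooled, params["fc"])

    def forward(self, x, params=None) -> np.ndarray:
        """Class probabilities (eval mode), rows summing to 1."""
        p = self.params if params is None else params
        probs = L.softmax(self.logits(p, x, train=False))
        return np.asarray(probs)

    def attention_weights(self, params=None):
        """Non-negative per-joint weights summing to 1."""
        p = self.params if params is None else params
        a = p["attention"]
        e = anp.exp(a - anp.max(a))
        return e / anp.sum(e)


def stgcn_forward(batch: np.ndarray, model: STGCN) -> np.ndarray:
    """Convenience wrapper: probabilities for a (N, C, T, V) batch."""
    return model.forward(batch)
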