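"""Residual CNN (ResNet-18 shape) for single-channel pressure images.

Four stages of two basic residual blocks each (8 residual blocks total)
behind a 7x7/2 stem and 3x3/2 max pool, ending in global average pooling,
a linear layer and softmax over the two classes.  The first convolution
takes the single pressure channel directly.  Trained from scratch;
``stage_channels`` is configurable so desk-scale tests can use a narrow
profile with the identical topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import layers as L

__all__ = ["CNNConfig", "ResidualCNN", "cnn_forward"]


@dataclass(frozen=True)
class CNNConfig:
    stage_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    in_channels: int = 1
    num_classes: int = 2
    skip_connections: bool = True  # ablation switch; True is the architecture
    norm: str = "batch"

    def __post_init__(self) -> None:
        if len(self.stage_channels) != 4:
            raise ValueError("expected 4 stages")
        if self.num_classes != 2:
            raise ValueError("this analysis is binary: num_classes must be 2")


class ResidualCNN:
    """Functional ResNet-18-shaped classifier on ``(N, C, H, W)`` batches."""

    MIN_INPUT = 32  # stem + 4 stages downsample by 32 overall

    def __init__(self, config: CNNConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params, self.state = self._init(rng)

    def _init(self, rng: np.random.Generator):
        cfg = self.config
        params: dict = {
            "stem_w": L.he_conv(rng, cfg.stage_channels[0], cfg.in_channels, 7, 7),
            "stem_bn": L.bn_params(cfg.stage_channels[0]),
            "stages": [],
        }
        state: dict = {"stem_bn": L.bn_state(cfg.stage_channels[0])}
        c_in = cfg.stage_channels[0]
        for si, c_out in enumerate(cfg.stage_channels):
            stage = []
            for bi in range(cfg.blocks_per_stage):
                stride = 2 if (si > 0 and bi == 0) else 1
                blk = {
                    "w1": L.he_conv(rng, c_out, c_in, 3, 3),
                    "bn1": L.bn_params(c_out),
                    "w2": L.he_conv(rng, c_out, c_out, 3, 3),
                    "bn2": L.bn_params(c_out),
                }
                if stride != 1 or c_in != c_out:
                    blk["proj_w"] = L.he_conv(rng, c_out, c_in, 1, 1)
                    blk["proj_bn"] = L.bn_params(c_out)
                    state[f"s{si}b{bi}_proj"] = L.bn_state(c_out)
                stage.append(blk)
                state[f"s{si}b{bi}_bn1"] = L.bn_state(c_out)
                state[f"s{si}b{bi}_bn2"] = L.bn_state(c_out)
                c_in = c_out
            params["stages"].append(stage)
        params["fc"] = L.he_linear(rng, c_in, cfg.num_classes)
        return params, state

    def _validate(self, x) -> None:
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels}-channel input, got "
                f"{x.shape[1]} channels (configure in_channels to adapt)")
        if min(x.shape[2], x.shape[3]) < self.MIN_INPUT:
            raise ValueError(f"input spatial size must be >= {self.MIN_INPUT}, "
                             f"got {x.shape[2]}x{x.shape[3]}")

    def logits(self, params, x, train: bool = False):
        self._validate(x)
        cfg = self.config
        use_bn = cfg.norm == "batch"
        h = L.conv2d(x, params["stem_w"], stride=(2, 2), pad=(3, 3))
        if use_bn:
            h = L.batch_norm(h, params["stem_bn"], self.state, "stem_bn", train)
        h = L.relu(h)
        h = L.max_pool2d(h, k=3, stride=2, pad=1)
        for si, stage in enumerate(params["stages"]):
            for bi, blk in enumerate(stage):
                stride = 2 if (si > 0 and bi == 0) else 1
                y = L.conv2d(h, blk["w1"], stride=(stride, stride), pad=(1, 1))
                if use_bn:
                    y = L.batch_norm(y, blk["bn1"], self.state, f"s{si}b{bi}_bn1", train)
                y = L.relu(y)
                y = L.conv2d(y, blk["w2"], stride=(1, 1), pad=(1, 1))
                if use_bn:
                    y = L.batch_norm(y, blk["bn2"], self.state, f"s{si}b{bi}_bn2", train)
                if cfg.skip_connections:
                    if "proj_w" in blk:
                        res = L.conv2d(h, blk["proj_w"], stride=(stride, stride), pad=(0, 0))
                        if use_bn:
                            res = L.batch_norm(res, blk["proj_bn"], self.state,
                                               f"s{si}b{bi}_proj", train)
                    else:
                        res = h
                    y = y + res
                h = L.relu(y)
        pooled = L.global_avg_pool(h)
        return L.linear(pooled, params["fc"])

    def forward(self, x, params=None) -> np.ndarray:
        """Class probabilities (eval mode), rows summing to 1."""
        p = self.params if params is None else params
        return np.asarray(L.softmax(self.logits(p, x, train=False)))


def cnn_forward(batch: np.ndarray, model: ResidualCNN) -> np.ndarray:
    """Convenience wrapper: probabilities for a (N, 1, H, W) batch."""
    return model.forward(batch)
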