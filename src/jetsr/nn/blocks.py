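"""Residual, dense and cross-stage-partial 3D convolution blocks.

All three block families map ``channels -> channels`` at fixed spatial size
and differ only in skip topology: identity addition (res), cumulative
concatenation of ``growth_rate``-channel layers with a 1x1 transition back
(dense), and a quarter/three-quarter channel split where only the quarter
runs through a partial dense block before cross-stage re-merging (csp).
"""

from __future__ import annotations

import numpy as np

from .layers import Conv1x1, Conv3d, LeakyReLU, Module

__all__ = ["ResBlock", "DenseBlock", "CSPBlock", "make_block"]


class ResBlock(Module):
    """conv-act-conv with an identity skip, activation after the add.

    With ``init="dirac"`` the second conv starts at zero so the block is the
    identity at initialisation.
    """

    def __init__(self, channels: int, rng, name="res", init="he"):
        self.conv1 = Conv3d(channels, channels, rng, f"{name}.conv1", init=init)
        self.conv2 = Conv3d(channels, channels, rng, f"{name}.conv2",
                            init="zero" if init == "dirac" else init)
        self.act1 = LeakyReLU()
        self.act2 = LeakyReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train=False):
        h = self.act1.forward(self.conv1.forward(x, train), train)
        h = self.conv2.forward(h, train)
        return self.act2.forward(h + x, train)

    def backward(self, dy):
        d = self.act2.backward(dy)
        dx_skip = d
        d = self.conv1.backward(self.act1.backward(self.conv2.backward(d)))
        return d + dx_skip


class _DenseLayers(Module):
    """``depth`` conv-act layers, each emitting ``growth`` channels that are
    cumulatively concatenated onto the input."""

    def __init__(self, c_in: int, growth: int, depth: int, rng, name):
        self.c_in, self.growth, self.depth = c_in, growth, depth
        self.convs = [
            Conv3d(c_in + i * growth, growth, rng, f"{name}.dense{i}")
            for i in range(depth)
        ]
        self.acts = [LeakyReLU() for _ in range(depth)]

    @property
    def c_out(self) -> int:
        return self.c_in + self.depth * self.growth

    def params(self):
        return [p for c in self.convs for p in c.params()]

    def forward(self, x, train=False):
        cat = x
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(cat, train), train)
            cat = np.concatenate([cat, h], axis=1)
        return cat

    def backward(self, dcat):
        g = self.growth
        for i in reversed(range(self.depth)):
            split = self.c_in + i * g
            d_out = dcat[:, split:split + g]
            d_in = self.convs[i].backward(self.acts[i].backward(d_out))
            dcat = dcat[:, :split] + d_in
        return dcat


class DenseBlock(Module):
    """Dense layers plus a 1x1 transition back to ``channels``."""

    def __init__(self, channels: int, rng, growth: int = 16, depth: int = 4,
                 name="dense"):
        self.dense = _DenseLayers(channels, growth, depth, rng, name)
        self.transition = Conv1x1(self.dense.c_out, channels, rng,
                                  f"{name}.transition")
        self.act = LeakyReLU()

    def params(self):
        return self.dense.params() + self.transition.params()

    def forward(self, x, train=False):
        cat = self.dense.forward(x, train)
        return self.act.forward(self.transition.forward(cat, train), train)

    def backward(self, dy):
        dcat = self.transition.backward(self.act.backward(dy))
        return self.dense.backward(dcat)


class CSPBlock(Module):
    """Cross-stage-partial block: a ``part_fraction`` share of the channels
    runs through a partial dense block and a 1x1 transition; the remainder
    bypasses; the merged stages pass a final 1x1 transition."""

    def __init__(self, channels: int, rng, growth: int = 16, depth: int = 4,
                 part_fraction: float = 0.25, name="csp"):
        self.channels = channels
        self.c_part = max(1, int(round(channels * part_fraction)))
        self.dense = _DenseLayers(self.c_part, growth, depth, rng, name)
        self.transition1 = Conv1x1(self.dense.c_out, channels, rng,
                                   f"{name}.transition1")
        self.act1 = LeakyReLU()
        c_bypass = channels - self.c_part
        self.transition2 = Conv1x1(channels + c_bypass, channels, rng,
                                   f"{name}.transition2")
        self.act2 = LeakyReLU()

    def params(self):
        return (self.dense.params() + self.transition1.params()
                + self.transition2.params())

    def forward(self, x, train=False):
        xp, xb = x[:, :self.c_part], x[:, self.c_part:]
        cat = self.dense.forward(np.ascontiguousarray(xp), train)
        stage = self.act1.forward(self.transition1.forward(cat, train), train)
        merged = np.concatenate([stage, xb], axis=1)
        return self.act2.forward(self.transition2.forward(merged, train), train)

    def backward(self, dy):
        d_merged = self.transition2.backward(self.act2.backward(dy))
        d_stage = d_merged[:, :self.channels]
        d_bypass = d_merged[:, self.channels:]
        dcat = self.transition1.backward(self.act1.backward(d_stage))
        d_part = self.dense.backward(dcat)
        return np.concatenate([d_part, d_bypass], axis=1)


def make_block(variant: str, channels: int, rng, growth: int = 16,
               depth: int = 4, part_fraction: float = 0.25, name="block",
               init: str = "he"):
    if variant == "res":
        return ResBlock(channels, rng, name, init=init)
    if variant == "dense":
        return DenseBlock(channels, rng, growth, depth, name)
    if variant == "csp":
        return CSPBlock(channels, rng, growth, depth, part_fraction, name)
    raise ValueError(f"unknown block variant: {variant!r}")
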