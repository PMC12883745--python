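"""Multitask U-Net generator and PatchGAN discriminators.

The generator shares a four-layer encoder across the four perfusion-map
branches (CBV, CBF, MTT, TTP).  Each branch continues with four private
encoding layers down to a 1x1 bottleneck, decodes through eight transposed
convolutions with U-Net skip concatenations, and ends in a
physician-in-the-loop (PILO) layer: a 1x1 transposed convolution that mixes
the decoded perfusion channel with the three anatomical (pseudo-RGB NCCT)
channels before the final Tanh.  Discriminators are independent 70x70
PatchGANs, one per map type.

Conventions that reproduce the published parameter counts: every
convolution carries a bias; normalization layers are parameter-free
instance-style; the first shared conv and the bottleneck conv have no norm.
At the default 256-px configuration the generator has 209,352,408 trainable
parameters and the four discriminators together have 11,063,044.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, concat
from .nn import count_parameters  # re-export  # noqa: F401

MAP_TYPES = ("CBV", "CBF", "MTT", "TTP")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults give the full-scale model."""

    image_size: int = 256
    input_channels: int = 3
    map_types: tuple = MAP_TYPES
    enc_shared: tuple = (64, 128, 256, 512)
    enc_branch: tuple = (512, 512, 512, 512)
    dec_channels: tuple = (512, 512, 512, 512, 256, 128, 64, 1)
    kernel: int = 4
    stride: int = 2
    padding: int = 1
    conv_bias: bool = True
    pilo_kernel: int = 1
    disc_channels: tuple = (64, 128, 256, 512, 1)
    disc_strides: tuple = (2, 2, 2, 1, 1)
    decoder_relu: bool = True          # ReLU in decoder (pix2pix); else LeakyReLU
    affine_norm: bool = False          # affine norm adds parameters; off by default

    def __post_init__(self):
        depth = len(self.enc_shared) + len(self.enc_branch)
        if self.image_size < 2 or (self.image_size & (self.image_size - 1)):
            raise ConfigError(f"image_size {self.image_size} is not a power of two")
        if 2 ** depth != self.image_size:
            raise ConfigError(
                f"encoder depth {depth} does not reduce image_size "
                f"{self.image_size} to a 1x1 bottleneck (needs 2^depth == size)")
        if len(self.dec_channels) != depth:
            raise ConfigError(
                f"decoder needs {depth} layers, got {len(self.dec_channels)}")
        if self.dec_channels[-1] != 1:
            raise ConfigError("last decoder layer must emit 1 channel")
        if self.affine_norm:
            raise ConfigError(
                "affine normalization changes the parameter counts; the "
                "published totals require parameter-free norm")

    @property
    def depth(self) -> int:
        return len(self.enc_shared) + len(self.enc_branch)

    @property
    def enc_all(self) -> tuple:
        return self.enc_shared + self.enc_branch

    @classmethod
    def tiny(cls, image_size: int = 64, base: int = 8) -> "ModelConfig":
        """Desk-scale preset: 64-px images, depth 6, 8 base channels."""
        b = base
        return cls(
            image_size=image_size,
            enc_shared=(b, 2 * b, 4 * b),
            enc_branch=(8 * b, 8 * b, 8 * b),
            dec_channels=(8 * b, 8 * b, 4 * b, 2 * b, b, 1),
            disc_channels=(b, 2 * b, 4 * b, 8 * b, 1),
        )


def _decoder_in_channels(cfg: ModelConfig) -> list[int]:
    """Input channels per decoder layer, accounting for skip concatenation."""
    enc = cfg.enc_all
    ins = [enc[-1]]
    for k in range(2, cfg.depth + 1):
        ins.append(cfg.dec_channels[k - 2] + enc[cfg.depth - k])
    return ins


class _Branch(nn.Module):
    """Private encoder tail + decoder + PILO for one map type."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c_prev = cfg.enc_shared[-1]
        self.enc = []
        for c in cfg.enc_branch:
            self.enc.append(nn.Conv2d(c_prev, c, cfg.kernel, cfg.stride,
                                      cfg.padding, cfg.conv_bias, rng))
            c_prev = c
        self.dec = []
        for c_in, c_out in zip(_decoder_in_channels(cfg), cfg.dec_channels):
            self.dec.append(nn.ConvTranspose2d(c_in, c_out, cfg.kernel, cfg.stride,
                                               cfg.padding, cfg.conv_bias, rng))
        self.pilo = nn.ConvTranspose2d(1 + cfg.input_channels, 1, cfg.pilo_kernel,
                                       1, 0, cfg.conv_bias, rng)
        # the 0.02-std convention is calibrated to conv fan-ins in the
        # hundreds; the 1x1 mixing layer has fan-in 4 and needs a
        # fan-in-aware scale to keep the output near unit magnitude
        fan_in = 1 + cfg.input_channels
        self.pilo.weight.data = rng.normal(
            0.0, 1.0 / np.sqrt(fan_in),
            self.pilo.weight.data.shape).astype(np.float32)


class Generator(nn.Module):
    """Shared-encoder multitask U-Net with per-map PILO mixing layers."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.norm = nn.InstanceNorm()
        self.shared = []
        c_prev = cfg.input_channels
        for c in cfg.enc_shared:
            self.shared.append(nn.Conv2d(c_prev, c, cfg.kernel, cfg.stride,
                                         cfg.padding, cfg.conv_bias, rng))
            c_prev = c
        self.branches = {m: _Branch(cfg, rng) for m in cfg.map_types}
        self._pilo_base = {m: None for m in cfg.map_types}

    def forward(self, x) -> dict:
        x = Tensor.as_tensor(x)
        if x.data.ndim != 4 or x.data.shape[1] != self.cfg.input_channels \
                or x.data.shape[2] != self.cfg.image_size:
            raise ValueError(
                f"expected input (N, {self.cfg.input_channels}, "
                f"{self.cfg.image_size}, {self.cfg.image_size}), got {x.data.shape}")
        act = (lambda t: t.relu()) if self.cfg.decoder_relu \
            else (lambda t: t.leaky_relu(0.2))
        out = {}
        # the shared-encoder features are computed once and reused by all
        # four branches; first conv carries no norm
        shared_feats = []
        h = x
        for i, layer in enumerate(self.shared):
            h = layer(h if i == 0 else h.leaky_relu(0.2))
            if i != 0:
                h = self.norm(h)
            shared_feats.append(h)
        depth = self.cfg.depth
        for m in self.cfg.map_types:
            br = self.branches[m]
            feats = list(shared_feats)
            hb = feats[-1]
            for j, layer in enumerate(br.enc):
                hb = layer(hb.leaky_relu(0.2))
                if j != len(br.enc) - 1:
                    hb = self.norm(hb)
                feats.append(hb)
            d = feats[-1]
            for k, layer in enumerate(br.dec, start=1):
                inp = d if k == 1 else concat([d, feats[depth - k]], axis=1)
                d = layer(act(inp))
                if k != depth:
                    d = self.norm(d)
            mixed = br.pilo(concat([d, x], axis=1))
            out[m] = mixed.tanh()
        return out

    # -- PILO control ----------------------------------------------------------
    def set_pilo_ratio(self, map_type: str, ratio: float) -> None:
        """Rescale PILO channel weights: perfusion channel by `ratio`, the
        anatomical channels by ``1 - ratio``; 0.5 restores the trained
        weights up to a global factor of one half."""
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"ratio must be in [0, 1], got {ratio}")
        if map_type not in self.branches:
            raise KeyError(f"unknown map type {map_type!r}")
        pilo = self.branches[map_type].pilo
        if self._pilo_base[map_type] is None:
            self._pilo_base[map_type] = pilo.weight.data.copy()
        base = self._pilo_base[map_type]
        scale = np.empty_like(base)
        scale[0] = ratio          # decoded perfusion channel
        scale[1:] = 1.0 - ratio   # three anatomical channels
        pilo.weight.data = base * scale


class Discriminator(nn.Module):
    """70x70 PatchGAN: input [pseudo-RGB NCCT || map], patch probabilities out."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.norm = nn.InstanceNorm()
        self.layers = []
        c_prev = cfg.input_channels + 1
        for c, s in zip(cfg.disc_channels, cfg.disc_strides):
            self.layers.append(nn.Conv2d(c_prev, c, cfg.kernel, s,
                                         cfg.padding, cfg.conv_bias, rng))
            c_prev = c

    def forward(self, xy):
        h = Tensor.as_tensor(xy)
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i == last:
                return h.sigmoid()
            if i != 0:
                h = self.norm(h)
            h = h.leaky_relu(0.2)
        raise AssertionError("unreachable")

    def receptive_field(self) -> int:
        rf, jump = 1, 1
        for layer in self.layers:
            k, s = layer.weight.data.shape[-1], layer.stride
            rf += (k - 1) * jump
            jump *= s
        return rf


def build_generator(config: ModelConfig | None = None, seed: int = 0) -> Generator:
    return Generator(config or ModelConfig(), seed)


def build_discriminators(config: ModelConfig | None = None, seed: int = 0) -> dict:
    """One independent PatchGAN per map type."""
    cfg = config or ModelConfig()
    return {m: Discriminator(cfg, seed + i) for i, m in enumerate(cfg.map_types)}


def generate_maps(gen: Generator, x: np.ndarray) -> dict:
    """Deterministic inference: forward without recording gradients.

    Returns ``{map_type: (N, 1, H, W) float array in [-1, 1]}``.
    """
    params = gen.parameters()
    flags = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        out = gen(np.asarray(x, dtype=np.float32))
    finally:
        for p, f in zip(params, flags):
            p.requires_grad = f
    return {m: t.data for m, t in out.items()}
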