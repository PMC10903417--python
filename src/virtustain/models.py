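"""Model builders for virtual staining.

Three architectures cover the workflow:

* a U-Net–shaped **generator** mapping a multi-slice bright-field stack
  (default 7 channels) to a 3-channel fluorescence image (lipid droplets,
  cytoplasm, nuclei), with a bounded (sigmoid) output so predictions live in
  the normalised intensity range [0, 1];
* a conditional **patch discriminator** scoring (bright-field, fluorescence)
  pairs locally with a logit map;
* a single-channel **U-Net baseline**, one instance per fluorescence channel,
  trained with MSE for comparison against the adversarial model.

All models are fully convolutional: any field whose sides are divisible by
``2**depth`` is accepted, which is what allows training on small crops and
predicting on large fields (via :func:`virtustain.training.predict`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn.core import (Conv2d, InstanceNorm, Layer, LeakyReLU, Param,
                      Sequential, Sigmoid, get_state, set_state)


class ShapeError(ValueError):
    """Raised when an input field violates a model's shape contract."""


@dataclass
class GeneratorConfig:
    in_channels: int = 7
    out_channels: int = 3
    depth: int = 4
    base_width: int = 32
    norm: str = "instance"  # "instance" | "none"

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.norm not in ("instance", "none"):
            raise ValueError(f"unknown norm flavour {self.norm!r}")


@dataclass
class DiscriminatorConfig:
    in_channels: int = 10  # bright-field slices + fluorescence channels
    depth: int = 3
    base_width: int = 32
    norm: str = "instance"

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class UNetConfig:
    in_channels: int = 7
    depth: int = 4
    base_width: int = 32
    norm: str = "instance"
    # output channel count is fixed to 1: one baseline model per stain

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _block(c_in: int, c_out: int, stride: int, norm: str,
           rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = [Conv2d(c_in, c_out, 3, stride, rng=rng)]
    if norm == "instance":
        layers.append(InstanceNorm(c_out))
    layers.append(LeakyReLU(0.2))
    return Sequential(*layers)


class _Upsample2x(Layer):
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet(Layer):
    """Encoder–decoder with skip connections and bounded output.

    Widths double per level, capped at ``8 * base_width``.
    """

    def __init__(self, in_channels: int, out_channels: int, depth: int,
                 base_width: int, norm: str, rng: np.random.Generator,
                 bounded: bool = True):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.depth = depth
        widths = [min(base_width * 2 ** i, base_width * 8)
                  for i in range(depth + 1)]
        self.widths = widths
        self.stem = _block(in_channels, widths[0], 1, norm, rng)
        self.downs = [_block(widths[i], widths[i + 1], 2, norm, rng)
                      for i in range(depth)]
        self.ups = [
            _block(widths[i + 1] + widths[i], widths[i], 1, norm, rng)
            for i in range(depth)
        ]
        self.upsamplers = [_Upsample2x() for _ in range(depth)]
        head: list[Layer] = [Conv2d(widths[0], out_channels, 3, 1, rng=rng)]
        if bounded:
            head.append(Sigmoid())
        self.head = Sequential(*head)

    def _check(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ShapeError("expected (N, C, H, W) input")
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ShapeError(
                f"expected {self.in_channels} input channels, got {c}")
        div = 2 ** self.depth
        if h % div or w % div:
            raise ShapeError(
                f"field size {h}x{w} must be divisible by 2**depth = {div}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check(x)
        h = self.stem.forward(x)
        enc = [h]
        for i, down in enumerate(self.downs):
            h = down.forward(h)
            if i < self.depth - 1:
                enc.append(h)
        for i in reversed(range(self.depth)):
            h = self.upsamplers[i].forward(h)
            h = np.concatenate([h, enc[i]], axis=1)
            h = self.ups[i].forward(h)
        return self.head.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.head.backward(dy)
        dskips: list[np.ndarray] = [None] * self.depth
        for i in range(self.depth):
            d = self.ups[i].backward(d)
            w_deep = self.widths[i + 1]
            dskips[i] = d[:, w_deep:]
            d = self.upsamplers[i].backward(d[:, :w_deep])
        for i in reversed(range(self.depth)):
            d = self.downs[i].backward(d)
            d = d + dskips[i]
        return self.stem.backward(d)

    def params(self) -> list[Param]:
        out = self.stem.params()
        for m in (*self.downs, *self.ups, self.head):
            out += m.params()
        return out


class PatchDiscriminator(Sequential):
    """Stride-2 convolution stack producing an unbounded patch-logit map.

    ``depth`` stride-2 stages reduce an (C, H, W) pair to a
    (1, H / 2**depth, W / 2**depth) score map; each logit judges the realism
    of the receptive-field patch it covers, conditioned on the bright-field
    channels concatenated with the candidate fluorescence image.
    """

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        widths = [min(cfg.base_width * 2 ** i, cfg.base_width * 8)
                  for i in range(cfg.depth)]
        layers: list[Layer] = [Conv2d(cfg.in_channels, widths[0], 3, 2, rng=rng),
                               LeakyReLU(0.2)]
        for i in range(1, cfg.depth):
            layers.append(Conv2d(widths[i - 1], widths[i], 3, 2, rng=rng))
            if cfg.norm == "instance":
                layers.append(InstanceNorm(widths[i]))
            layers.append(LeakyReLU(0.2))
        layers.append(Conv2d(widths[-1], 1, 3, 1, rng=rng))
        super().__init__(*layers)
        self.cfg = cfg
        self.depth = cfg.depth
        self.in_channels = cfg.in_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ShapeError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}")
        div = 2 ** self.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ShapeError(
                f"field size {x.shape[2]}x{x.shape[3]} must be divisible by "
                f"2**depth = {div}")
        return super().forward(x)


def build_generator(cfg: GeneratorConfig | None = None,
                    seed: int | None = None) -> UNet:
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    model = UNet(cfg.in_channels, cfg.out_channels, cfg.depth,
                 cfg.base_width, cfg.norm, rng, bounded=True)
    model.config = cfg
    return model


def build_discriminator(cfg: DiscriminatorConfig | None = None,
                        seed: int | None = None) -> PatchDiscriminator:
    cfg = cfg or DiscriminatorConfig()
    return PatchDiscriminator(cfg, np.random.default_rng(seed))


def build_unet(cfg: UNetConfig | None = None, seed: int | None = None) -> UNet:
    cfg = cfg or UNetConfig()
    rng = np.random.default_rng(seed)
    model = UNet(cfg.in_channels, 1, cfg.depth, cfg.base_width, cfg.norm,
                 rng, bounded=True)
    model.config = cfg
    return model


def n_parameters(model: Layer) -> int:
    return sum(p.value.size for p in model.params())


def save_checkpoint(model: Layer, path: str | Path) -> None:
    """Write weights as .npz with a JSON sidecar recording the config."""
    path = Path(path)
    np.savez(path, *(p.value for p in model.params()))
    cfg = getattr(model, "config", None) or getattr(model, "cfg", None)
    sidecar = {
        "config": asdict(cfg) if cfg is not None else None,
        "model": type(model).__name__,
        "normalization": {"divisor": 65535.0, "range": [0.0, 1.0]},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(model: Layer, path: str | Path) -> None:
    with np.load(Path(path).with_suffix(".npz")) as data:
        set_state(model.params(), [data[k] for k in data.files])


__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "UNetConfig", "UNet",
    "PatchDiscriminator", "ShapeError", "build_generator",
    "build_discriminator", "build_unet", "n_parameters",
    "save_checkpoint", "load_checkpoint", "get_state", "set_state",
]
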