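"""Training loops and large-field prediction.

``train_cgan`` alternates discriminator and generator updates.  The
discriminator minimises binary cross-entropy on (bright-field, fluorescence)
pairs, real vs. generated; its per-batch loss is the sum of the real and
fake terms, so a perfectly confused discriminator (probability 0.5
everywhere) sits at exactly 2 ln 2.  The generator minimises the
non-saturating adversarial term plus an L1 reconstruction term:

    l_gen = adv_weight * BCE(D(x, G(x)), real) + lambda_rec * |G(x) - y|_1

With ``adv_weight = 0`` training reduces to pure L1 regression, whose
optimum is the per-pixel conditional median; with the adversarial term the
generator is pushed onto the target distribution instead — the mechanism
that separates a cGAN from an MSE-trained U-Net (whose optimum is the
conditional mean) when the input does not determine the output.

``predict`` stitches tiled inference over fields too large for one forward
pass, with linear feathering across tile overlaps; a margin (``trim``) of
each interior tile edge gets zero weight so convolution edge effects do not
enter the blend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn.core import get_state, set_state, zero_grads
from .nn.losses import bce_with_logits, l1_loss, mse_loss
from .nn.optim import Adam
from .models import UNet, PatchDiscriminator

CHANNELS = ("droplets", "cytoplasm", "nuclei")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    crop_size: int = 64
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    lambda_rec: float = 100.0
    adv_weight: float = 1.0
    val_freq: int = 10
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lambda_rec < 0 or self.adv_weight < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainHistory:
    """Per-epoch losses and per-validation-point channel nMAE_px."""

    channels: tuple[str, ...]
    gen_loss: list[float] = field(default_factory=list)
    disc_loss: list[float] = field(default_factory=list)
    val_epochs: list[int] = field(default_factory=list)
    val_nmae: list[list[float]] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        n = len(self.gen_loss)
        df = pd.DataFrame({"epoch": np.arange(1, n + 1),
                           "gen_loss": self.gen_loss,
                           "disc_loss": self.disc_loss})
        for ci, name in enumerate(self.channels):
            col = np.full(n, np.nan)
            for e, vals in zip(self.val_epochs, self.val_nmae):
                col[e - 1] = vals[ci]
            df[f"val_nmae_{name}"] = col
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_pairs(pairs, name):
    if not pairs:
        raise ValueError(f"{name} dataset is empty")
    shapes = {(p[0].shape, p[1].shape) for p in pairs}
    if len(shapes) != 1:
        raise ValueError(f"{name} samples must be equally sized, got {shapes}")


def _batch(pairs, idxs, cfg: TrainConfig, rng: np.random.Generator):
    xs, ys = [], []
    for i in idxs:
        x, y = pairs[i]
        h, w = x.shape[1:]
        c = min(cfg.crop_size, h, w)
        sy = rng.integers(0, h - c + 1)
        sx = rng.integers(0, w - c + 1)
        xc, yc = x[:, sy:sy + c, sx:sx + c], y[:, sy:sy + c, sx:sx + c]
        if cfg.augment:
            k = rng.integers(0, 4)
            if k:
                xc = np.rot90(xc, k, axes=(1, 2))
                yc = np.rot90(yc, k, axes=(1, 2))
            if rng.integers(0, 2):
                xc, yc = xc[:, :, ::-1], yc[:, :, ::-1]
        xs.append(np.ascontiguousarray(xc, dtype=np.float32))
        ys.append(np.ascontiguousarray(yc, dtype=np.float32))
    return np.stack(xs), np.stack(ys)


def _val_nmae(model, val_pairs, channel: int | None = None) -> list[float]:
    """Mean over the validation set of per-channel nMAE_px."""
    sums = None
    for x, y in val_pairs:
        pred = model.forward(x[None].astype(np.float32))[0]
        t = y if channel is None else y[channel:channel + 1]
        vals = [float(np.abs(pred[c] - t[c]).mean() / max(t[c].mean(), 1e-12))
                for c in range(t.shape[0])]
        sums = vals if sums is None else [a + b for a, b in zip(sums, vals)]
    return [s / len(val_pairs) for s in sums]


def _maybe_validate(model, val_pairs, epoch, cfg, history, best, channel=None):
    if not (epoch == 1 or epoch == cfg.epochs or epoch % cfg.val_freq == 0):
        return best
    vals = _val_nmae(model, val_pairs, channel)
    history.val_epochs.append(epoch)
    history.val_nmae.append(vals)
    score = float(np.mean(vals))
    if best is None or score < best[0]:
        best = (score, get_state(model.params()), epoch)
    return best


def train_cgan(train_pairs, val_pairs, gen: UNet, disc: PatchDiscriminator,
               config: TrainConfig) -> tuple[UNet, TrainHistory]:
    """Adversarial training; retains the best-by-validation generator.

    ``train_pairs``/``val_pairs`` are sequences of ``(stack, target)`` pairs
    of float arrays on the [0, 1] scale, shapes (C_in, H, W) / (C_out, H, W).
    Raises on NaN losses with an epoch-tagged diagnostic.
    """
    _check_pairs(train_pairs, "train")
    _check_pairs(val_pairs, "val")
    if config.adv_weight > 0 and disc is None:
        raise ValueError("a discriminator is required unless adv_weight == 0")
    rng = np.random.default_rng(config.seed)
    opt_g = Adam(gen.params(), config.lr, config.beta1, config.beta2)
    opt_d = (Adam(disc.params(), config.lr, config.beta1, config.beta2)
             if disc is not None else None)
    history = TrainHistory(channels=CHANNELS[:gen.out_channels])
    best = None
    n = len(train_pairs)
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        eg, ed, nb = 0.0, 0.0, 0
        for s in range(0, n, config.batch_size):
            idxs = perm[s:s + config.batch_size]
            x, y = _batch(train_pairs, idxs, config, rng)
            fake = gen.forward(x)
            # --- discriminator step ---
            if config.adv_weight > 0:
                zero_grads(disc.params())
                lreal, dreal = bce_with_logits(
                    disc.forward(np.concatenate([x, y], axis=1)), 1.0)
                disc.backward(dreal)
                lfake, dfake = bce_with_logits(
                    disc.forward(np.concatenate([x, fake], axis=1)), 0.0)
                disc.backward(dfake)
                opt_d.step()
                ld = lreal + lfake
            else:
                ld = 0.0
            # --- generator step ---
            zero_grads(gen.params())
            l1, dl1 = l1_loss(fake, y)
            dfake_total = config.lambda_rec * dl1
            ladv = 0.0
            if config.adv_weight > 0:
                zero_grads(disc.params())
                logits = disc.forward(np.concatenate([x, fake], axis=1))
                ladv, dlog = bce_with_logits(logits, 1.0)
                dcat = disc.backward(dlog)
                dfake_total = dfake_total + config.adv_weight * dcat[:, x.shape[1]:]
            gen.backward(dfake_total.astype(np.float32))
            opt_g.step()
            lg = config.adv_weight * ladv + config.lambda_rec * l1
            if not (np.isfinite(lg) and np.isfinite(ld)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(gen={lg!r}, disc={ld!r}): aborting")
            eg += lg
            ed += ld
            nb += 1
        history.gen_loss.append(eg / nb)
        history.disc_loss.append(ed / nb)
        best = _maybe_validate(gen, val_pairs, epoch, config, history, best)
    set_state(gen.params(), best[1])
    history.best_epoch = best[2]
    return gen, history


def train_unet(train_pairs, val_pairs, net: UNet, channel: int,
               config: TrainConfig) -> tuple[UNet, TrainHistory]:
    """MSE training of the single-channel baseline on one target channel."""
    _check_pairs(train_pairs, "train")
    _check_pairs(val_pairs, "val")
    if channel not in range(train_pairs[0][1].shape[0]):
        raise ValueError(f"channel {channel} out of range")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params(), config.lr, config.beta1, config.beta2)
    name = CHANNELS[channel] if channel < len(CHANNELS) else str(channel)
    history = TrainHistory(channels=(name,))
    best = None
    n = len(train_pairs)
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        el, nb = 0.0, 0
        for s in range(0, n, config.batch_size):
            x, y = _batch(train_pairs, perm[s:s + config.batch_size],
                          config, rng)
            pred = net.forward(x)
            zero_grads(net.params())
            loss, dpred = mse_loss(pred, y[:, channel:channel + 1])
            net.backward(dpred)
            opt.step()
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            el += loss
            nb += 1
        history.gen_loss.append(el / nb)
        history.disc_loss.append(0.0)
        best = _maybe_validate(net, val_pairs, epoch, config, history, best,
                               channel=channel)
    set_state(net.params(), best[1])
    history.best_epoch = best[2]
    return net, history


def _weight_profile(tile: int, overlap: int, trim: int,
                    left_open: bool, right_open: bool) -> np.ndarray:
    """Per-axis blend weight: zero over trimmed interior edges, linear ramp
    across the rest of the overlap, one inside.  Field-boundary edges keep
    weight one (their padding matches whole-field inference)."""
    w = np.ones(tile)
    ramp = overlap - 2 * trim
    if ramp < 1:
        raise ValueError("overlap must exceed 2 * trim")
    up = np.linspace(0.0, 1.0, ramp + 2)[1:-1]
    if left_open:
        w[:trim] = 0.0
        w[trim:trim + ramp] = up
    if right_open:
        w[tile - trim:] = 0.0
        w[tile - trim - ramp:tile - trim] = up[::-1]
    return w


def predict(gen: UNet, stack: np.ndarray, tile: int = 128,
            overlap: int = 32, trim: int | None = None) -> np.ndarray:
    """Full-field prediction by tiled inference with feathered stitching.

    Falls back to whole-field inference when the stack fits in one tile
    (padding reflectively to the divisibility constraint if needed).
    """
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3:
        raise ValueError("expected a (C, H, W) stack")
    c, h, w = stack.shape
    div = 2 ** gen.depth
    if h <= tile and w <= tile:
        ph, pw = (-h) % div, (-w) % div
        x = np.pad(stack, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        return gen.forward(x[None])[0][:, :h, :w]
    if tile % div:
        raise ValueError(f"tile size must be divisible by 2**depth = {div}")
    if overlap >= tile:
        raise ValueError("overlap must be smaller than the tile size")
    trim = overlap // 4 if trim is None else trim
    step = tile - overlap

    def starts(extent):
        ss = list(range(0, max(extent - tile, 0) + 1, step))
        if ss[-1] != extent - tile:
            ss.append(extent - tile)
        return ss

    acc = np.zeros((gen.out_channels, h, w), dtype=np.float64)
    wacc = np.zeros((h, w), dtype=np.float64)
    for sy in starts(h):
        wy = _weight_profile(tile, overlap, trim, sy > 0, sy + tile < h)
        for sx in starts(w):
            wx = _weight_profile(tile, overlap, trim, sx > 0, sx + tile < w)
            pred = gen.forward(stack[None, :, sy:sy + tile, sx:sx + tile])[0]
            wt = wy[:, None] * wx[None, :]
            acc[:, sy:sy + tile, sx:sx + tile] += pred * wt
            wacc[sy:sy + tile, sx:sx + tile] += wt
    return (acc / wacc).astype(np.float32)


__all__ = ["TrainConfig", "TrainHistory", "train_cgan", "train_unet",
           "predict", "CHANNELS"]
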