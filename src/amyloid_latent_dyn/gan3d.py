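"""3D style-based generative model for volumetric PET.

Three networks in the style-GAN arrangement:

* a mapping network ``M`` — a stack of fully connected layers embedding a
  normally distributed input ``z`` into the intermediate latent space W,
* a synthesis network ``G`` — a learned constant volume refined by
  successive convolution blocks, each modulated per-channel by an affine
  transform of the single latent vector ``w`` (W space, not per-layer W+),
  with seeded per-layer noise that is frozen after construction so
  synthesis is a deterministic function of ``w``,
* a discriminator ``D`` — strided-by-pooling convolutional critic ending
  in a scalar logit.

Training uses the non-saturating logistic GAN loss.  A zero-centred
gradient penalty on real samples is estimated by a randomized finite
difference of the critic (``(D(x + eps*u) - D(x))^2 / eps^2`` with
``u ~ N(0, I)``), whose expectation is the squared gradient norm; this
keeps the whole procedure first-order.

The "paper-scale" profile (160x160x96 voxels, w of length 96, an 8-layer
mapping network) is config-complete but intended for GPU-class hardware;
the tiny profiles train on one CPU.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam, Parameter, Tensor

__all__ = ["GanConfig", "GanModel", "train_gan"]


@dataclasses.dataclass(frozen=True)
class GanConfig:
    volume_shape: tuple = (16, 16, 16)
    z_dim: int = 32
    w_dim: int = 32
    mapping_depth: int = 3
    channels: tuple = (16, 16, 8)  # per resolution level, coarse to fine
    lr_g: float = 2e-3
    lr_d: float = 2e-3
    r1_gamma: float = 1.0
    r1_interval: int = 4
    r1_eps: float = 1e-3
    total_steps: int = 400
    batch_size: int = 4
    log_interval: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mapping_depth < 1:
            raise ValueError("mapping_depth must be >= 1")
        f = 2 ** (len(self.channels) - 1)
        if any(s % f or s // f < 1 for s in self.volume_shape):
            raise ValueError(
                f"volume_shape {self.volume_shape} not divisible by 2^levels={f}"
            )

    @property
    def base_shape(self):
        f = 2 ** (len(self.channels) - 1)
        return tuple(s // f for s in self.volume_shape)

    @staticmethod
    def paper_default() -> "GanConfig":
        """Full-scale profile: 160x160x96 at 1.5 mm, w of length 96, 8 FC layers."""
        return GanConfig(
            volume_shape=(160, 160, 96),
            z_dim=96,
            w_dim=96,
            mapping_depth=8,
            channels=(256, 128, 64, 32, 16),
        )


def _dense_init(rng, n_in, n_out):
    w = Parameter(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32))
    b = Parameter(np.zeros(n_out, dtype=np.float32))
    return w, b


def _conv_init(rng, c_in, c_out):
    w = Parameter(
        rng.normal(0.0, np.sqrt(2.0 / (c_in * 27)), (c_out, c_in, 3, 3, 3)).astype(
            np.float32
        )
    )
    b = Parameter(np.zeros(c_out, dtype=np.float32))
    return w, b


class MappingNetwork:
    """z -> w: `mapping_depth` fully connected layers with leaky ReLU."""

    def __init__(self, cfg: GanConfig, rng):
        self.cfg = cfg
        self.layers = []
        dims = [cfg.z_dim] + [cfg.w_dim] * cfg.mapping_depth
        for n_in, n_out in zip(dims[:-1], dims[1:]):
            self.layers.append(_dense_init(rng, n_in, n_out))

    def parameters(self):
        return [p for layer in self.layers for p in layer]

    def forward(self, z: Tensor) -> Tensor:
        if z.shape[-1] != self.cfg.z_dim:
            raise ValueError(
                f"z has length {z.shape[-1]}, mapping network expects {self.cfg.z_dim}"
            )
        h = z
        for w, b in self.layers:
            h = h.matmul(w) + b
            h = h.leaky_relu(0.2)
        return h


class SynthesisNetwork:
    """w -> volume: learned constant refined by style-modulated conv blocks."""

    def __init__(self, cfg: GanConfig, rng):
        self.cfg = cfg
        c0 = cfg.channels[0]
        self.const = Parameter(rng.normal(0.0, 1.0, (1, c0, *cfg.base_shape)).astype(np.float32))
        self.blocks = []  # (style_w, style_b, conv_w, conv_b, noise_strength, noise_buf)
        shape = cfg.base_shape
        c_prev = c0
        for lvl, c in enumerate(cfg.channels):
            if lvl > 0:
                shape = tuple(2 * s for s in shape)
            sw, sb = _dense_init(rng, cfg.w_dim, c_prev)
            cw, cb = _conv_init(rng, c_prev, c)
            strength = Parameter(np.zeros(1, dtype=np.float32))
            noise = rng.normal(0.0, 1.0, (1, 1, *shape)).astype(np.float32)
            self.blocks.append((sw, sb, cw, cb, strength, noise))
            c_prev = c
        self.out_w, self.out_b = _conv_init(rng, c_prev, 1)

    def parameters(self):
        ps = [self.const, self.out_w, self.out_b]
        for sw, sb, cw, cb, strength, _ in self.blocks:
            ps += [sw, sb, cw, cb, strength]
        return ps

    def forward(self, w: Tensor) -> Tensor:
        if w.shape[-1] != self.cfg.w_dim:
            raise ValueError(
                f"w has length {w.shape[-1]}, synthesis network expects {self.cfg.w_dim}"
            )
        n = w.shape[0]
        x = self.const
        if n > 1:  # broadcast the learned constant over the batch
            x = x * Tensor(np.ones((n, 1, 1, 1, 1), dtype=np.float32))
        for lvl, (sw, sb, cw, cb, strength, noise) in enumerate(self.blocks):
            if lvl > 0:
                x = x.upsample_nearest()
            style = w.matmul(sw) + sb  # per-input-channel scale offset
            scale = style + Tensor(np.float32(1.0))
            x = x * scale.reshape(n, -1, 1, 1, 1)
            x = x.conv3d(cw, cb)
            x = x + strength * Tensor(noise)
            x = x.leaky_relu(0.2)
        return x.conv3d(self.out_w, self.out_b)


class Discriminator:
    """volume -> logit: conv + leaky ReLU + average-pool pyramid, dense head."""

    def __init__(self, cfg: GanConfig, rng):
        self.cfg = cfg
        chans = tuple(reversed(cfg.channels))
        self.from_pet = _conv_init(rng, 1, chans[0])
        self.blocks = []
        c_prev = chans[0]
        for c in chans[1:]:
            self.blocks.append(_conv_init(rng, c_prev, c))
            c_prev = c
        flat = c_prev * int(np.prod(cfg.base_shape))
        self.head = _dense_init(rng, flat, 1)

    def parameters(self):
        ps = list(self.from_pet) + list(self.head)
        for blk in self.blocks:
            ps += list(blk)
        return ps

    def forward(self, x: Tensor) -> Tensor:
        if tuple(x.shape[2:]) != tuple(self.cfg.volume_shape):
            raise ValueError(
                f"volume shape {tuple(x.shape[2:])} != configured {tuple(self.cfg.volume_shape)}"
            )
        h = x.conv3d(*self.from_pet).leaky_relu(0.2)
        for cw, cb in self.blocks:
            h = h.avg_pool3d()
            h = h.conv3d(cw, cb).leaky_relu(0.2)
        h = h.reshape(h.shape[0], -1)
        return h.matmul(self.head[0]) + self.head[1]


class GanModel:
    """Bundled mapping network M, synthesis network G and discriminator D."""

    def __init__(self, config: GanConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.mapping = MappingNetwork(config, rng)
        self.synthesis = SynthesisNetwork(config, rng)
        self.discriminator = Discriminator(config, rng)
        self.step = 0

    # -- inference ---------------------------------------------------------

    def map_latent(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float32))
        if z.shape[1] != self.config.z_dim:
            raise ValueError(
                f"z has length {z.shape[1]}, expected z_dim={self.config.z_dim}"
            )
        w = self.mapping.forward(Tensor(z)).data
        return w[0] if w.shape[0] == 1 else w

    def synthesize(self, w: np.ndarray) -> np.ndarray:
        w = np.atleast_2d(np.asarray(w, dtype=np.float32))
        if w.shape[1] != self.config.w_dim:
            raise ValueError(
                f"w has length {w.shape[1]}, expected w_dim={self.config.w_dim}"
            )
        vols = self.synthesis.forward(Tensor(w)).data[:, 0]
        return vols[0] if vols.shape[0] == 1 else vols

    def discriminate(self, volume: np.ndarray) -> float:
        volume = np.asarray(volume, dtype=np.float32)
        single = volume.ndim == 3
        if single:
            volume = volume[None]
        if tuple(volume.shape[1:]) != tuple(self.config.volume_shape):
            raise ValueError(
                f"volume shape {tuple(volume.shape[1:])} != configured "
                f"{tuple(self.config.volume_shape)}"
            )
        scores = self.discriminator.forward(Tensor(volume[:, None])).data[:, 0]
        return float(scores[0]) if single else scores

    # -- serialization -----------------------------------------------------

    def _param_dict(self):
        d = {}
        for name, net in (
            ("M", self.mapping),
            ("G", self.synthesis),
            ("D", self.discriminator),
        ):
            for i, p in enumerate(net.parameters()):
                d[f"{name}_{i}"] = p.data
        for i, blk in enumerate(self.synthesis.blocks):
            d[f"Gnoise_{i}"] = blk[5]
        return d

    def save(self, path: str | Path):
        meta = json.dumps(
            {"config": dataclasses.asdict(self.config), "step": self.step}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self._param_dict())

    @classmethod
    def load(cls, path: str | Path) -> "GanModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            cfg_d = meta["config"]
            for key in ("volume_shape", "channels"):
                cfg_d[key] = tuple(cfg_d[key])
            model = cls(GanConfig(**cfg_d))
            model.step = meta["step"]
            for name, net in (
                ("M", model.mapping),
                ("G", model.synthesis),
                ("D", model.discriminator),
            ):
                for i, p in enumerate(net.parameters()):
                    p.data = archive[f"{name}_{i}"].copy()
            for i in range(len(model.synthesis.blocks)):
                blk = list(model.synthesis.blocks[i])
                blk[5] = archive[f"Gnoise_{i}"].copy()
                model.synthesis.blocks[i] = tuple(blk)
        return model


def train_gan(
    volumes: np.ndarray, config: GanConfig, model: GanModel | None = None
) -> tuple[GanModel, pd.DataFrame]:
    """Adversarial training of the style GAN on a stack of volumes.

    `volumes` is (n, D, H, W).  Returns the trained model and a loss log
    with one row per `log_interval` steps (step, loss_G, loss_D).  Fully
    seeded: the same data, config and seed give identical parameters.
    """
    volumes = np.asarray(volumes, dtype=np.float32)
    if volumes.ndim != 4 or volumes.shape[0] == 0:
        raise ValueError("volumes must be a nonempty (n, D, H, W) stack")
    if tuple(volumes.shape[1:]) != tuple(config.volume_shape):
        raise ValueError(
            f"dataset volumes {volumes.shape[1:]} incompatible with config "
            f"volume_shape {config.volume_shape}"
        )
    model = model or GanModel(config)
    rng = np.random.default_rng(config.seed + 1)
    g_params = model.mapping.parameters() + model.synthesis.parameters()
    d_params = model.discriminator.parameters()
    opt_g = Adam(g_params, lr=config.lr_g)
    opt_d = Adam(d_params, lr=config.lr_d)
    log = []

    for step in range(config.total_steps):
        idx = rng.integers(0, volumes.shape[0], config.batch_size)
        real = Tensor(volumes[idx][:, None])
        z = rng.standard_normal((config.batch_size, config.z_dim)).astype(np.float32)

        # --- discriminator step ---
        fake_vol = model.synthesis.forward(model.mapping.forward(Tensor(z)))
        fake_detached = Tensor(fake_vol.data)
        d_real = model.discriminator.forward(real)
        d_fake = model.discriminator.forward(fake_detached)
        loss_d = (-d_real).softplus().mean() + d_fake.softplus().mean()
        if config.r1_gamma > 0 and step % config.r1_interval == 0:
            u = rng.standard_normal(real.shape).astype(np.float32)
            d_pert = model.discriminator.forward(
                Tensor(real.data + config.r1_eps * u)
            )
            diff = d_pert - d_real
            penalty = diff.square().mean() * Tensor(
                np.float32(config.r1_gamma / (2.0 * config.r1_eps**2))
            )
            loss_d = loss_d + penalty
        if not np.isfinite(loss_d.data):
            raise RuntimeError(f"NaN/Inf discriminator loss at step {step}")
        opt_d.zero_grad()
        loss_d.backward()
        opt_d.step()

        # --- generator step ---
        z = rng.standard_normal((config.batch_size, config.z_dim)).astype(np.float32)
        fake_vol = model.synthesis.forward(model.mapping.forward(Tensor(z)))
        d_fake = model.discriminator.forward(fake_vol)
        loss_g = (-d_fake).softplus().mean()
        if not np.isfinite(loss_g.data):
            raise RuntimeError(f"NaN/Inf generator loss at step {step}")
        opt_g.zero_grad()
        loss_g.backward()
        opt_g.step()

        if step % config.log_interval == 0 or step == config.total_steps - 1:
            log.append(
                {"step": step, "loss_G": float(loss_g.data), "loss_D": float(loss_d.data)}
            )
        model.step = step + 1

    return model, pd.DataFrame(log, columns=["step", "loss_G", "loss_D"])
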