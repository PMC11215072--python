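"""Inversion encoder: map a PET volume to its intermediate latent vector w.

The encoder E inverts a trained (and frozen) synthesis network G.  Each
block is filtered downsampling (2x block averaging) followed by a 3x3x3
convolution, with leaky ReLU (slope 0.2) after each block; a final linear
dense layer of size w_dim with no output activation produces w = E(PET).
The reference architecture uses five blocks with filter depths
16, 32, 32, 32 and 16 and a 96-unit head.

Training minimizes the mean squared voxel error ||PET - G(E(PET))||^2
with the generator parameters frozen.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .gan3d import GanModel, _conv_init, _dense_init
from .nn import Adam, Tensor

__all__ = ["EncoderConfig", "EncoderModel", "train_encoder", "reconstruct"]

logger = logging.getLogger(__name__)


def _max_blocks(shape) -> int:
    n = 0
    while all(s % 2 == 0 and s // 2 >= 1 for s in shape):
        shape = tuple(s // 2 for s in shape)
        n += 1
    return n


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    volume_shape: tuple = (16, 16, 16)
    filter_depths: tuple = (16, 32, 32, 32, 16)
    w_dim: int = 32
    lr: float = 1e-3
    total_steps: int = 300
    batch_size: int = 4
    log_interval: int = 10
    seed: int = 0

    def __post_init__(self):
        if len(self.filter_depths) < 1:
            raise ValueError("need at least one conv block")

    @property
    def n_blocks(self) -> int:
        """Configured block count, reduced to what the grid can support."""
        supported = _max_blocks(self.volume_shape)
        if supported < len(self.filter_depths):
            logger.warning(
                "grid %s supports only %d downsampling blocks; reducing from %d",
                self.volume_shape, supported, len(self.filter_depths),
            )
            return supported
        return len(self.filter_depths)

    @staticmethod
    def paper_default() -> "EncoderConfig":
        """Five blocks with depths 16/32/32/32/16 and a 96-unit linear head."""
        return EncoderConfig(
            volume_shape=(160, 160, 96), filter_depths=(16, 32, 32, 32, 16), w_dim=96
        )


class EncoderModel:
    """volume -> w.  Blocks: avg-pool downsample, 3x3x3 conv, leaky ReLU."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        depths = config.filter_depths[: config.n_blocks]
        self.blocks = []
        c_prev = 1
        shape = tuple(config.volume_shape)
        for c in depths:
            shape = tuple(s // 2 for s in shape)
            self.blocks.append(_conv_init(rng, c_prev, c))
            c_prev = c
        flat = c_prev * int(np.prod(shape))
        self.head = _dense_init(rng, flat, config.w_dim)

    @property
    def filter_depths(self):
        return tuple(cw.data.shape[0] for cw, _ in self.blocks)

    def parameters(self):
        ps = list(self.head)
        for blk in self.blocks:
            ps += list(blk)
        return ps

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for cw, cb in self.blocks:
            h = h.avg_pool3d()  # filtered downsampling
            h = h.conv3d(cw, cb)
            h = h.leaky_relu(0.2)
        h = h.reshape(h.shape[0], -1)
        return h.matmul(self.head[0]) + self.head[1]  # linear, no activation

    def encode(self, volume: np.ndarray) -> np.ndarray:
        volume = np.asarray(volume, dtype=np.float32)
        single = volume.ndim == 3
        if single:
            volume = volume[None]
        if tuple(volume.shape[1:]) != tuple(self.config.volume_shape):
            raise ValueError(
                f"volume shape {tuple(volume.shape[1:])} != configured "
                f"{tuple(self.config.volume_shape)}"
            )
        w = self.forward(Tensor(volume[:, None])).data
        return w[0] if single else w

    def save(self, path: str | Path):
        meta = json.dumps({"config": dataclasses.asdict(self.config)})
        arrays = {f"E_{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            cfg_d = meta["config"]
            for key in ("volume_shape", "filter_depths"):
                cfg_d[key] = tuple(cfg_d[key])
            model = cls(EncoderConfig(**cfg_d))
            for i, p in enumerate(model.parameters()):
                p.data = archive[f"E_{i}"].copy()
        return model


def train_encoder(
    volumes: np.ndarray,
    gan: GanModel,
    config: EncoderConfig,
    model: EncoderModel | None = None,
) -> tuple[EncoderModel, pd.DataFrame]:
    """Train E against the frozen generator by voxel-MSE reconstruction.

    Gradients flow through G(E(x)) but only encoder parameters are
    updated; G is byte-identical before and after.  Returns the trained
    encoder and a loss log (step, loss).
    """
    if config.w_dim != gan.config.w_dim:
        raise ValueError(
            f"encoder w_dim {config.w_dim} != generator w_dim {gan.config.w_dim}"
        )
    if tuple(config.volume_shape) != tuple(gan.config.volume_shape):
        raise ValueError(
            f"encoder volume_shape {config.volume_shape} != generator "
            f"{gan.config.volume_shape}"
        )
    volumes = np.asarray(volumes, dtype=np.float32)
    model = model or EncoderModel(config)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.lr, betas=(0.9, 0.999))
    log = []
    for step in range(config.total_steps):
        idx = rng.integers(0, volumes.shape[0], config.batch_size)
        x = Tensor(volumes[idx][:, None])
        w = model.forward(x)
        recon = gan.synthesis.forward(w)
        loss = (recon - x).square().mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(f"NaN/Inf encoder loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % config.log_interval == 0 or step == config.total_steps - 1:
            log.append({"step": step, "loss": float(loss.data)})
    return model, pd.DataFrame(log, columns=["step", "loss"])


def reconstruct(volume: np.ndarray, enc: EncoderModel, gan: GanModel) -> np.ndarray:
    """G(E(volume)): project onto the generator's manifold and render back."""
    return gan.synthesize(enc.encode(volume))
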