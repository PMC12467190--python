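"""The ErisNet denoising network.

A U-Net-style encoder-decoder with a DnCNN refinement head:

* **Encoder** — two stages of (3x3 conv -> ReLU -> 2x2 max-pool), growing
  the channel count (default 64 then 96) while halving resolution twice,
  so inputs must be divisible by 4.
* **Middle** — 3x3 conv (default 112 channels) -> ReLU -> dropout, the
  bottleneck.
* **Decoder** — two stages of (2x2 transposed conv -> ReLU), each followed
  by concatenation with the matching encoder stage's pre-pool features
  (skip connection) and a 3x3 conv -> ReLU back to the decoder width
  (default 96).
* **DnCNN head** — ``n_dncnn_blocks`` blocks of
  (conv -> batch-norm -> ReLU -> dropout) at full resolution
  (``convs_per_block`` allows two convs per block as an alternative
  reading of the block diagram), then a final 1-filter conv producing the
  denoised image.  An optional global residual adds the input back, the
  classical DnCNN noise-prediction formulation; the default predicts the
  image directly.

The network maps 1-channel images in [0, 1]; :func:`denoise` handles the
8-bit conversion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .dicom_io import Image8

__all__ = ["ErisNetConfig", "ErisNet", "build_erisnet", "denoise", "save_checkpoint", "load_checkpoint", "DESK_CONFIG"]


@dataclass(frozen=True)
class ErisNetConfig:
    """Architecture and regularisation hyperparameters.

    Defaults follow the final tuned configuration: dropout 0.5, middle
    width 112, decoder width 96, 4 DnCNN blocks, with the encoder plan
    (64, 96) from the architecture diagram.  ``enc_channels`` also accepts
    a single int c, expanded to (c, c).
    """

    enc_channels: tuple[int, int] = (64, 96)
    mid_channels: int = 112
    dec_channels: int = 96
    n_dncnn_blocks: int = 4
    dropout_rate: float = 0.5
    kernel_size: int = 3
    bn_eps: float = 1e-5
    convs_per_block: int = 1
    use_global_residual: bool = False

    def __post_init__(self) -> None:
        enc = self.enc_channels
        if isinstance(enc, int):
            enc = (enc, enc)
        enc = tuple(int(c) for c in enc)
        if len(enc) != 2:
            raise ValueError("enc_channels must be an int or a pair of ints")
        object.__setattr__(self, "enc_channels", enc)
        if min(*enc, self.mid_channels, self.dec_channels) < 1:
            raise ValueError("all channel counts must be >= 1")
        if self.n_dncnn_blocks < 1:
            raise ValueError("n_dncnn_blocks must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.bn_eps <= 0:
            raise ValueError("bn_eps must be > 0")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")


#: Reduced channel plan for CPU-scale experiments and the test suite.
#: The global residual (predict the noise correction) is essential at this
#: width: it preserves the sharp air/tissue boundary that a small direct
#: predictor would otherwise have to relearn pixel-by-pixel.
DESK_CONFIG = ErisNetConfig(
    enc_channels=(8, 12),
    mid_channels=16,
    dec_channels=12,
    n_dncnn_blocks=2,
    dropout_rate=0.0,
    use_global_residual=True,
)

_N_POOL_STAGES = 2
_DIVISOR = 2**_N_POOL_STAGES


class ErisNet:
    """Executable model; build via :func:`build_erisnet`."""

    def __init__(self, config: ErisNetConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        c1, c2 = config.enc_channels
        k = config.kernel_size
        p = config.dropout_rate

        self.enc1 = nn.Conv2D(1, c1, k, rng, "enc1")
        self.enc1_relu = nn.ReLU()
        self.pool1 = nn.MaxPool2x2()
        self.enc2 = nn.Conv2D(c1, c2, k, rng, "enc2")
        self.enc2_relu = nn.ReLU()
        self.pool2 = nn.MaxPool2x2()

        self.mid = nn.Conv2D(c2, config.mid_channels, k, rng, "mid")
        self.mid_relu = nn.ReLU()
        self.mid_drop = nn.Dropout(p, self._dropout_rng)

        d = config.dec_channels
        self.up1 = nn.ConvTranspose2x2(config.mid_channels, d, rng, "up1")
        self.up1_relu = nn.ReLU()
        self.dec1 = nn.Conv2D(d + c2, d, k, rng, "dec1")
        self.dec1_relu = nn.ReLU()
        self.up2 = nn.ConvTranspose2x2(d, d, rng, "up2")
        self.up2_relu = nn.ReLU()
        self.dec2 = nn.Conv2D(d + c1, d, k, rng, "dec2")
        self.dec2_relu = nn.ReLU()

        self.dncnn: list[dict] = []
        for i in range(config.n_dncnn_blocks):
            block = {"convs": [], "bns": [], "relus": [], "drop": nn.Dropout(p, self._dropout_rng)}
            for j in range(config.convs_per_block):
                block["convs"].append(nn.Conv2D(d, d, k, rng, f"dncnn{i}.conv{j}"))
                block["bns"].append(nn.BatchNorm2D(d, eps=config.bn_eps, name=f"dncnn{i}.bn{j}"))
                block["relus"].append(nn.ReLU())
            self.dncnn.append(block)

        self.final = nn.Conv2D(d, 1, k, rng, "final")

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        yield from (self.enc1, self.enc2, self.mid, self.up1, self.dec1, self.up2, self.dec2)
        for block in self.dncnn:
            yield from block["convs"]
            yield from block["bns"]
        yield self.final

    def parameters(self) -> list[nn.Parameter]:
        out: list[nn.Parameter] = []
        for layer in self._layers():
            out.extend(layer.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------

    def _check_shape(self, x: np.ndarray) -> None:
        h, w = x.shape[-2:]
        if h % _DIVISOR or w % _DIVISOR:
            raise ValueError(
                f"input height and width must be divisible by {_DIVISOR} "
                f"({_N_POOL_STAGES} pooling stages); got {h}x{w}"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (N, 1, H, W) in [0, 1] to a same-shape denoised estimate."""
        self._check_shape(x)
        t = training
        a1 = self.enc1_relu.forward(self.enc1.forward(x, t), t)  # pre-pool skip 1
        p1 = self.pool1.forward(a1, t)
        a2 = self.enc2_relu.forward(self.enc2.forward(p1, t), t)  # pre-pool skip 2
        p2 = self.pool2.forward(a2, t)
        m = self.mid_drop.forward(self.mid_relu.forward(self.mid.forward(p2, t), t), t)
        u1 = self.up1_relu.forward(self.up1.forward(m, t), t)
        d1 = self.dec1_relu.forward(self.dec1.forward(np.concatenate([u1, a2], axis=1), t), t)
        u2 = self.up2_relu.forward(self.up2.forward(d1, t), t)
        h = self.dec2_relu.forward(self.dec2.forward(np.concatenate([u2, a1], axis=1), t), t)
        for block in self.dncnn:
            for conv, bn, rl in zip(block["convs"], block["bns"], block["relus"]):
                h = rl.forward(bn.forward(conv.forward(h, t), t), t)
            h = block["drop"].forward(h, t)
        y = self.final.forward(h, t)
        if self.config.use_global_residual:
            y = x + y
        return y

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dOutput.

        Mirrors :meth:`forward` in reverse; gradients flowing through the
        skip concatenations are split and re-joined at the encoder side.
        The optional global residual contributes identity on the parameter
        path, so no extra term is needed.
        """
        g = self.final.backward(dy)
        for block in reversed(self.dncnn):
            g = block["drop"].backward(g)
            for conv, bn, rl in zip(
                reversed(block["convs"]), reversed(block["bns"]), reversed(block["relus"])
            ):
                g = conv.backward(bn.backward(rl.backward(g)))
        g = self.dec2.backward(self.dec2_relu.backward(g))
        c1 = self.config.enc_channels[0]
        g_u2, g_a1 = g[:, : g.shape[1] - c1], g[:, g.shape[1] - c1 :]
        g = self.up2.backward(self.up2_relu.backward(g_u2))
        g = self.dec1.backward(self.dec1_relu.backward(g))
        c2 = self.config.enc_channels[1]
        g_u1, g_a2 = g[:, : g.shape[1] - c2], g[:, g.shape[1] - c2 :]
        g = self.up1.backward(self.up1_relu.backward(g_u1))
        g = self.mid.backward(self.mid_relu.backward(self.mid_drop.backward(g)))
        g = self.pool2.backward(g) + g_a2  # skip 2 re-joins the encoder path
        g = self.enc2.backward(self.enc2_relu.backward(g))
        g = self.pool1.backward(g) + g_a1  # skip 1
        self.enc1.backward(self.enc1_relu.backward(g))


def build_erisnet(config: ErisNetConfig | None = None, seed: int = 0) -> ErisNet:
    """Construct an ErisNet with deterministic, seeded initialisation."""
    return ErisNet(config or ErisNetConfig(), seed=seed)


def denoise(model: ErisNet, img: Image8) -> Image8:
    """Run inference on one 8-bit slice (dropout off, running BN stats)."""
    x = img.pixels.astype(np.float32)[None, None] / 255.0
    y = model.forward(x, training=False)[0, 0]
    out = np.clip(np.floor(np.clip(y, 0.0, 1.0) * 255.0 + 0.5), 0, 255).astype(np.uint8)
    return Image8(out, window=img.window)


# ---------------------------------------------------------------------------
# Checkpointing

_CKPT_SCHEMA = 1


def save_checkpoint(model: ErisNet, path: str | Path) -> None:
    """Serialise weights, running statistics, config and seed (.npz)."""
    arrays = {p.name: p.value for p in model.parameters()}
    for layer in model._layers():
        if isinstance(layer, nn.BatchNorm2D):
            stem = layer.gamma.name.rsplit(".", 1)[0]
            arrays[f"{stem}.running_mean"] = layer.running_mean
            arrays[f"{stem}.running_var"] = layer.running_var
    meta = {"schema": _CKPT_SCHEMA, "seed": model.seed, "config": asdict(model.config)}
    np.savez(Path(path), __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> ErisNet:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["schema"] != _CKPT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        cfg = meta["config"]
        cfg["enc_channels"] = tuple(cfg["enc_channels"])
        model = ErisNet(ErisNetConfig(**cfg), seed=meta["seed"])
        for p in model.parameters():
            p.value[...] = data[p.name]
        for layer in model._layers():
            if isinstance(layer, nn.BatchNorm2D):
                stem = layer.gamma.name.rsplit(".", 1)[0]
                layer.running_mean[...] = data[f"{stem}.running_mean"]
                layer.running_var[...] = data[f"{stem}.running_var"]
    return model
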