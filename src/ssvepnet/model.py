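"""The residual filter-bank CNN for four-class SSVEP windows.

Input is a (4, 9, P) tensor: four bandpass slabs of a nine-channel window of
P samples.  A stem convolution with kernel (9, 3) collapses the electrode
axis while mixing the four bands into 16 feature maps; six residual layers,
each halving the temporal axis (stride 2), deepen the representation to 64
maps of width ceil(P/64); dropout (rate 0.25) separates layers 1-5; the
flattened features (length P when P is a multiple of 64) feed one dense
layer producing the 4 class scores.

Each residual layer's main path is conv(1,3)/BN/conv(1,3)/BN; the shortcut
is a 1x1 strided conv + BN whenever the stride differs from 1 or the channel
count changes, else the identity; the two paths are summed and passed
through ELU(alpha=1).  Changing the window length only changes P — the dense
head is sized from the traced flatten length, so no other edit is needed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = ["LayerSpec", "ModelConfig", "ShapeTrace", "ResidualBlock",
           "EEGResNet", "build_model", "shape_trace",
           "save_checkpoint", "load_checkpoint"]

DEFAULT_LAYERS = ((16, 16, 2), (16, 16, 2), (16, 32, 2),
                  (32, 32, 2), (32, 64, 2), (64, 64, 2))


@dataclass(frozen=True)
class LayerSpec:
    in_channels: int
    out_channels: int
    stride: int

    def __post_init__(self):
        if min(self.in_channels, self.out_channels, self.stride) < 1:
            raise ValueError("layer channel counts and stride must be positive")


@dataclass(frozen=True)
class ModelConfig:
    P: int = 64
    n_bands: int = 4
    n_channels: int = 9
    n_classes: int = 4
    stem_out: int = 16
    layers: tuple = tuple(LayerSpec(*l) for l in DEFAULT_LAYERS)
    dropout_rate: float = 0.25
    elu_alpha: float = 1.0

    def __post_init__(self):
        if self.P < 1:
            raise ValueError("window length P must be >= 1")
        if len(self.layers) != 6:
            raise ValueError("the architecture has exactly 6 residual layers")


@dataclass
class ShapeTrace:
    """Per-stage (channels, height, width) output shapes, input first."""

    stages: list = field(default_factory=list)  # (name, (c, h, w))

    @property
    def final_shape(self):
        return self.stages[-1][1]

    @property
    def flatten_length(self) -> int:
        c, h, w = self.final_shape
        return c * h * w

    def __str__(self):
        return "\n".join(f"{name:>10s}: {shape}" for name, shape in self.stages)


def _conv_out(size, kernel, stride, pad):
    return (size + 2 * pad - kernel) // stride + 1


def shape_trace(cfg: ModelConfig) -> ShapeTrace:
    """Trace shapes with out = floor((W + 2*pad - kernel)/stride) + 1."""
    tr = ShapeTrace()
    c, h, w = cfg.n_bands, cfg.n_channels, cfg.P
    tr.stages.append(("input", (c, h, w)))
    h = _conv_out(h, 9, 1, 0)   # stem kernel height 9, no pad
    w = _conv_out(w, 3, 1, 1)   # stem kernel width 3, pad 1 -> width preserved
    c = cfg.stem_out
    tr.stages.append(("stem", (c, h, w)))
    for i, spec in enumerate(cfg.layers, start=1):
        w = _conv_out(w, 3, spec.stride, 1)
        c = spec.out_channels
        tr.stages.append((f"layer{i}", (c, h, w)))
        if w < 1 or h < 1:
            raise ValueError(
                f"config invalid: width reaches {w} at layer {i} (P={cfg.P})")
    return tr


class ResidualBlock(nn.Module):
    """conv(1,3)/BN/conv(1,3)/BN main path + (projected or identity) shortcut,
    summed then ELU."""

    def __init__(self, spec: LayerSpec, elu_alpha: float, rng):
        s = spec.stride
        self.main = nn.Sequential(
            nn.Conv2d(spec.in_channels, spec.out_channels, (1, 3), (1, s), (0, 1), rng=rng),
            nn.BatchNorm2d(spec.out_channels),
            nn.Conv2d(spec.out_channels, spec.out_channels, (1, 3), (1, 1), (0, 1), rng=rng),
            nn.BatchNorm2d(spec.out_channels),
        )
        if s != 1 or spec.in_channels != spec.out_channels:
            self.shortcut = nn.Sequential(
                nn.Conv2d(spec.in_channels, spec.out_channels, (1, 1), (1, s), (0, 0), rng=rng),
                nn.BatchNorm2d(spec.out_channels),
            )
        else:
            self.shortcut = None
        self.elu = nn.ELU(elu_alpha)

    def params(self):
        p = self.main.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def forward(self, x, train=True):
        y = self.main.forward(x, train)
        sc = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.elu.forward(y + sc, train)

    def backward(self, dy):
        d = self.elu.backward(dy)
        dx = self.main.backward(d)
        dx = dx + (d if self.shortcut is None else self.shortcut.backward(d))
        return dx


class EEGResNet(nn.Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        trace = shape_trace(cfg)  # raises for invalid configs
        if cfg.P % 64 != 0:
            warnings.warn(
                f"P={cfg.P} is not a multiple of 64; flatten length is "
                f"{trace.flatten_length}, not P", stacklevel=2)
        self.cfg = cfg
        self.trace = trace
        rng = np.random.default_rng(seed)
        self.stem = nn.Sequential(
            nn.Conv2d(cfg.n_bands, cfg.stem_out, (9, 3), (1, 1), (0, 1), rng=rng),
            nn.BatchNorm2d(cfg.stem_out),
            nn.ELU(cfg.elu_alpha),
        )
        self.blocks = []
        self.dropouts = []
        for i, spec in enumerate(cfg.layers):
            self.blocks.append(ResidualBlock(spec, cfg.elu_alpha, rng))
            # dropout between layers: after each of layers 1-5, none after 6
            if i < len(cfg.layers) - 1:
                self.dropouts.append(nn.Dropout(cfg.dropout_rate, rng))
        self.flatten = nn.Flatten()
        self.head = nn.Linear(trace.flatten_length, cfg.n_classes, rng=rng)

    def params(self):
        p = self.stem.params()
        for b in self.blocks:
            p += b.params()
        return p + self.head.params()

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        expected = (self.cfg.n_bands, self.cfg.n_channels, self.cfg.P)
        if x.shape[1:] != expected:
            raise ValueError(f"expected input (n, {expected}), got {x.shape}")
        x = self.stem.forward(x, train)
        for i, block in enumerate(self.blocks):
            x = block.forward(x, train)
            if i < len(self.dropouts):
                x = self.dropouts[i].forward(x, train)
        return self.head.forward(self.flatten.forward(x, train), train)

    def backward(self, dy):
        d = self.flatten.backward(self.head.backward(dy))
        for i in reversed(range(len(self.blocks))):
            if i < len(self.dropouts):
                d = self.dropouts[i].backward(d)
            d = self.blocks[i].backward(d)
        return self.stem.backward(d)

    def predict(self, x, batch_size: int = 512) -> np.ndarray:
        """Eval-mode class predictions (dropout off, running BN statistics)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        out = [np.argmax(self.forward(x[i:i + batch_size], train=False), axis=1)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out)

    # -- state (for checkpointing and best-model selection) ----------------

    def _bn_modules(self):
        mods = []
        def collect(m):
            if isinstance(m, nn.BatchNorm2d):
                mods.append(m)
            elif isinstance(m, nn.Sequential):
                for sub in m.modules:
                    collect(sub)
        collect(self.stem)
        for b in self.blocks:
            collect(b.main)
            if b.shortcut is not None:
                collect(b.shortcut)
        return mods

    def get_state(self) -> dict:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_modules()):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        for i, bn in enumerate(self._bn_modules()):
            bn.running_mean[...] = state[f"bn_{i}_mean"]
            bn.running_var[...] = state[f"bn_{i}_var"]


def build_model(cfg: ModelConfig, seed: int = 0) -> EEGResNet:
    """Build a seeded, reproducibly initialized network; invalid shape
    configurations are rejected via the shape trace."""
    return EEGResNet(cfg, seed=seed)


def save_checkpoint(model: EEGResNet, path) -> None:
    cfg = model.cfg
    meta = dict(P=cfg.P, n_bands=cfg.n_bands, n_channels=cfg.n_channels,
                n_classes=cfg.n_classes, stem_out=cfg.stem_out,
                layers=[(l.in_channels, l.out_channels, l.stride) for l in cfg.layers],
                dropout_rate=cfg.dropout_rate, elu_alpha=cfg.elu_alpha)
    np.savez(path, __cfg__=json.dumps(meta), **model.get_state())


def load_checkpoint(path) -> EEGResNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__cfg__"]))
        cfg = ModelConfig(
            P=meta["P"], n_bands=meta["n_bands"], n_channels=meta["n_channels"],
            n_classes=meta["n_classes"], stem_out=meta["stem_out"],
            layers=tuple(LayerSpec(*l) for l in meta["layers"]),
            dropout_rate=meta["dropout_rate"], elu_alpha=meta["elu_alpha"])
        model = EEGResNet(cfg)
        model.set_state({k: z[k] for k in z.files if k != "__cfg__"})
    return model
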