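"""Encoder--decoder segmentation network.

A compact U-Net variant: residual blocks in the encoder, stride-2
convolutions for downsampling, nearest-neighbour upsampling plus 3x3
conv-norm-relu blocks with skip connections in the decoder, and a final
1x1 projection to class logits. Output spatial size equals input size.

The public tensor convention is channel-last (``(N, H, W, 3)`` images in
[0, 1], ``(N, H, W, L)`` logits); NCHW is internal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from segmatch.errors import ConfigurationError, DataError, GeometryError
from segmatch.nn.layers import (BatchNorm2d, Conv2d, GroupNorm2d, Layer, ReLU,
                                Sequential, UpsampleNearest2x)
from segmatch.rng import STREAM_MODEL, substream


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 2
    base_channels: int = 8
    n_classes: int = 2
    seed: int = 0
    #: normalization layer family: "batch" (running stats in eval mode) or
    #: "group" (per-image statistics, identical in train and eval mode).
    norm: str = "batch"

    def validate(self) -> "ModelConfig":
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.norm not in ("batch", "group"):
            raise ConfigurationError("norm must be 'batch' or 'group'")
        return self


def _make_norm(norm: str, channels: int) -> Layer:
    if norm == "batch":
        return BatchNorm2d(channels)
    if norm == "group":
        return GroupNorm2d(channels)
    raise ConfigurationError(f"unknown norm {norm!r}; use 'batch' or 'group'")


def _conv_bn_relu(cin: int, cout: int, stride: int,
                  rng: np.random.Generator, norm: str) -> Sequential:
    return Sequential(Conv2d(cin, cout, k=3, stride=stride, rng=rng),
                      _make_norm(norm, cout), ReLU())


class ResBlock(Layer):
    """conv-bn-relu-conv-bn plus identity shortcut, then relu."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 norm: str = "batch") -> None:
        self.c1 = Conv2d(channels, channels, k=3, rng=rng)
        self.b1 = _make_norm(norm, channels)
        self.r1 = ReLU()
        self.c2 = Conv2d(channels, channels, k=3, rng=rng)
        self.b2 = _make_norm(norm, channels)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.r1.forward(self.b1.forward(self.c1.forward(x, train), train), train)
        z = self.b2.forward(self.c2.forward(h, train), train)
        y = x + z
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy: np.ndarray, want_param_grads: bool = True) -> np.ndarray:
        d = dy * self._mask
        db = self.b2.backward(d, want_param_grads)
        db = self.c2.backward(db, want_param_grads)
        db = self.r1.backward(db, want_param_grads)
        db = self.b1.backward(db, want_param_grads)
        db = self.c1.backward(db, want_param_grads)
        return d + db

    def parameters(self):
        out = []
        for tag, mod in (("c1", self.c1), ("b1", self.b1),
                         ("c2", self.c2), ("b2", self.b2)):
            out.extend((f"{tag}.{n}", p) for n, p in mod.parameters())
        return out

    def grads(self):
        out = {}
        for tag, mod in (("c1", self.c1), ("b1", self.b1),
                         ("c2", self.c2), ("b2", self.b2)):
            out.update({f"{tag}.{n}": g for n, g in mod.grads().items()})
        return out


class SegmentationModel:
    """U-Net style network with explicit forward/backward wiring."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32) -> None:
        cfg.validate()
        self.cfg = cfg
        self.dtype = dtype
        rng = substream(cfg.seed, STREAM_MODEL)
        C, d = cfg.base_channels, cfg.depth
        norm = cfg.norm
        self.stem = _conv_bn_relu(3, C, 1, rng, norm)
        self.enc: List[ResBlock] = []
        self.down: List[Sequential] = []
        for i in range(d):
            self.enc.append(ResBlock(C * 2 ** i, rng, norm))
            self.down.append(_conv_bn_relu(C * 2 ** i, C * 2 ** (i + 1), 2, rng, norm))
        self.mid = ResBlock(C * 2 ** d, rng, norm)
        self.up: Dict[int, Sequential] = {}
        self.fuse: Dict[int, Sequential] = {}
        for i in reversed(range(d)):
            self.up[i] = Sequential(UpsampleNearest2x(),
                                    _conv_bn_relu(C * 2 ** (i + 1), C * 2 ** i, 1, rng, norm))
            self.fuse[i] = _conv_bn_relu(2 * C * 2 ** i, C * 2 ** i, 1, rng, norm)
        self.head = Conv2d(C, cfg.n_classes, k=1, rng=rng)
        self._modules: List[Tuple[str, Layer]] = [("stem", self.stem)]
        for i in range(d):
            self._modules += [(f"enc{i}", self.enc[i]), (f"down{i}", self.down[i])]
        self._modules.append(("mid", self.mid))
        for i in reversed(range(d)):
            self._modules += [(f"up{i}", self.up[i]), (f"fuse{i}", self.fuse[i])]
        self._modules.append(("head", self.head))
        if dtype is not np.float32:
            self._cast(dtype)

    def _cast(self, dtype) -> None:
        stack = [mod for _, mod in self._modules]
        while stack:
            m = stack.pop()
            if isinstance(m, Sequential):
                stack.extend(m.layers)
            elif isinstance(m, ResBlock):
                stack.extend([m.c1, m.b1, m.c2, m.b2])
            if isinstance(m, Conv2d):
                for attr in ("W", "b", "dW", "db"):
                    setattr(m, attr, getattr(m, attr).astype(dtype))
            if isinstance(m, BatchNorm2d):
                for attr in ("gamma", "beta", "running_mean", "running_var",
                             "dgamma", "dbeta"):
                    setattr(m, attr, getattr(m, attr).astype(dtype))
            if isinstance(m, GroupNorm2d):
                for attr in ("gamma", "beta", "dgamma", "dbeta"):
                    setattr(m, attr, getattr(m, attr).astype(dtype))

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> List[Tuple[str, np.ndarray]]:
        out = []
        for tag, mod in self._modules:
            out.extend((f"{tag}.{n}", p) for n, p in mod.parameters())
        return out

    def grads(self) -> Dict[str, np.ndarray]:
        out = {}
        for tag, mod in self._modules:
            out.update({f"{tag}.{n}": g for n, g in mod.grads().items()})
        return out

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g.fill(0.0)

    def set_freeze_stats(self, freeze: bool) -> None:
        """Toggle batch-stat mode without running-statistic updates, used for
        the no-gradient pseudo-label forward pass."""
        stack = [mod for _, mod in self._modules]
        while stack:
            m = stack.pop()
            if isinstance(m, Sequential):
                stack.extend(m.layers)
            elif isinstance(m, ResBlock):
                stack.extend([m.b1, m.b2])
            if isinstance(m, BatchNorm2d):
                m.freeze_stats = freeze

    def state_hash(self) -> str:
        """SHA-256 over all parameters; running statistics excluded."""
        h = hashlib.sha256()
        for name, p in self.parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- forward / backward ------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[-1] != 3:
            raise GeometryError(f"expected (N, H, W, 3) input, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise DataError("non-finite values in model input")
        h, w = x.shape[1:3]
        step = 2 ** self.cfg.depth
        if h < step or w < step or h % step or w % step:
            raise ConfigurationError(
                f"input {h}x{w} must be divisible by 2^depth = {step}")
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Images (N, H, W, 3) in [0, 1] -> logits (N, H, W, L)."""
        x = self._check_input(x)
        h = np.ascontiguousarray(x, dtype=self.dtype)
        h = self.stem.forward(h, train)
        skips = []
        for i in range(self.cfg.depth):
            h = self.enc[i].forward(h, train)
            skips.append(h)
            h = self.down[i].forward(h, train)
        h = self.mid.forward(h, train)
        self._skip_channels = []
        for i in reversed(range(self.cfg.depth)):
            h = self.up[i].forward(h, train)
            self._skip_channels.append(h.shape[3])
            h = np.concatenate([h, skips[i]], axis=3)
            h = self.fuse[i].forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray,
                 want_param_grads: bool = True) -> np.ndarray:
        """Backpropagate d(loss)/d(logits); returns d(loss)/d(input).

        Uses the caches of the most recent :meth:`forward` call.
        """
        d = np.asarray(dlogits)
        if d.ndim == 3:
            d = d[None]
        d = self.head.backward(np.ascontiguousarray(d), want_param_grads)
        dskips = {}
        for i in range(self.cfg.depth):
            d = self.fuse[i].backward(d, want_param_grads)
            n_up = self._skip_channels[self.cfg.depth - 1 - i]
            d, dskip = d[..., :n_up], d[..., n_up:]
            dskips[i] = dskip
            d = self.up[i].backward(np.ascontiguousarray(d), want_param_grads)
        d = self.mid.backward(d, want_param_grads)
        for i in reversed(range(self.cfg.depth)):
            d = self.down[i].backward(d, want_param_grads)
            d = d + dskips[i]
            d = self.enc[i].backward(d, want_param_grads)
        d = self.stem.backward(d, want_param_grads)
        return d

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> Dict[str, np.ndarray]:
        out = {name: p for name, p in self.parameters()}
        for tag, mod in self._modules:
            stack = [(tag, mod)]
            while stack:
                t, m = stack.pop()
                if isinstance(m, BatchNorm2d):
                    out[f"{t}.running_mean"] = m.running_mean
                    out[f"{t}.running_var"] = m.running_var
                elif isinstance(m, Sequential):
                    stack.extend((f"{t}.{k}", sub) for k, sub in enumerate(m.layers))
                elif isinstance(m, ResBlock):
                    stack.extend([(f"{t}.b1", m.b1), (f"{t}.b2", m.b2)])
        return out

    def save(self, path: str) -> None:
        arrays = self.state_arrays()
        arrays["__depth"] = np.array(self.cfg.depth)
        arrays["__base_channels"] = np.array(self.cfg.base_channels)
        arrays["__n_classes"] = np.array(self.cfg.n_classes)
        arrays["__seed"] = np.array(self.cfg.seed)
        arrays["__norm"] = np.array(self.cfg.norm)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "SegmentationModel":
        data = np.load(path)
        cfg = ModelConfig(depth=int(data["__depth"]),
                          base_channels=int(data["__base_channels"]),
                          n_classes=int(data["__n_classes"]),
                          seed=int(data["__seed"]),
                          norm=str(data["__norm"]) if "__norm" in data else "batch")
        model = cls(cfg)
        for name, arr in model.state_arrays().items():
            arr[...] = data[name]
        return model


def build_model(cfg: ModelConfig) -> SegmentationModel:
    """Construct a seeded segmentation network."""
    return SegmentationModel(cfg)
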