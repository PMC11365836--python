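"""Dual-task 3D U-Net: shared encoder, segmentation decoder, pretext head(s).

The encoder ``e(.)`` has four blocks of two 3x3x3 convolutions (each followed
by ReLU then batch normalisation) and a 2x2x1 max pool, with channel widths
doubling from ``base_channels`` (32 by default) up to a two-convolution
512-channel bottleneck.  The decoder ``d(.)`` mirrors it with 2x2x1
nearest-neighbour upsampling and skip concatenation of the matching encoder
map; its last block has three convolutions, the final one softmax-activated
over the segmentation classes.  Each pretext head ``i(.)`` reads the
bottleneck features through three conv blocks (256 -> 128 -> 64 filters at
full width), a final conv down to its class count, global average pooling and
a softmax.

Because pooling only acts in-plane, in-plane input dims must be divisible by
``2**n_encoder_blocks`` (16 for the default depth); the slice count is free.
``width_scale`` multiplies every channel width, allowing faithful but tiny
models for CPU-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (Adam, BatchNorm, ChannelSoftmax, Conv3d, InstanceNorm,
                 Layer, MaxPool221, Param, ReLU, Sequential, Upsample221,
                 set_training)

__all__ = ["HeadSpec", "NetworkSpec", "DualTaskModel", "build_model",
           "encode", "count_parameters", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class HeadSpec:
    """One pretext classification branch."""
    name: str = "intensity"
    n_classes: int = 4
    start_filters: int = 256


@dataclass(frozen=True)
class NetworkSpec:
    base_channels: int = 32
    n_encoder_blocks: int = 4
    conv_kernel: tuple[int, int, int] = (3, 3, 3)
    pool_stride: tuple[int, int, int] = (2, 2, 1)
    n_seg_classes: int = 2
    pretext_heads: tuple[HeadSpec, ...] = (HeadSpec(),)
    width_scale: float = 1.0

    def __post_init__(self):
        if self.conv_kernel != (3, 3, 3):
            raise ValueError("only 3x3x3 kernels are supported")
        if self.pool_stride != (2, 2, 1):
            raise ValueError("only 2x2x1 pooling is supported")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        object.__setattr__(self, "pretext_heads",
                           tuple(HeadSpec(**h) if isinstance(h, dict) else h
                                 for h in self.pretext_heads))

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_scale)))

    @property
    def encoder_channels(self) -> list[int]:
        return [self.scaled(self.base_channels * 2 ** b)
                for b in range(self.n_encoder_blocks)]

    @property
    def bottleneck_channels(self) -> int:
        return self.scaled(self.base_channels * 2 ** self.n_encoder_blocks)

    @property
    def decoder_channels(self) -> list[int]:
        return self.encoder_channels[::-1]

    @property
    def pool_factor(self) -> int:
        return 2 ** self.n_encoder_blocks

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["conv_kernel"] = tuple(d.get("conv_kernel", (3, 3, 3)))
        d["pool_stride"] = tuple(d.get("pool_stride", (2, 2, 1)))
        d["pretext_heads"] = tuple(HeadSpec(**h) for h in d.get("pretext_heads", ()))
        return cls(**d)


def _conv_block(c_in: int, c_out: int, rng, n_convs: int = 2,
                norm: str | None = "batch") -> Sequential:
    """conv -> ReLU -> [norm], repeated; the literal layer order of the text."""
    layers: list[Layer] = []
    c = c_in
    for _ in range(n_convs):
        layers.append(Conv3d(c, c_out, rng))
        layers.append(ReLU())
        if norm == "batch":
            layers.append(BatchNorm(c_out))
        elif norm == "instance":
            layers.append(InstanceNorm(c_out))
        c = c_out
    return Sequential(layers)


class Encoder(Layer):
    """Four conv blocks with 2x2x1 pooling plus the two-conv bottleneck."""

    def __init__(self, spec: NetworkSpec, rng):
        self.spec = spec
        chans = spec.encoder_channels
        self.blocks: list[Sequential] = []
        self.pools: list[MaxPool221] = []
        c = 1
        for c_out in chans:
            self.blocks.append(_conv_block(c, c_out, rng))
            self.pools.append(MaxPool221())
            c = c_out
        self.bottleneck = _conv_block(c, spec.bottleneck_channels, rng)
        # the very first conv reads the raw volume; its input gradient is
        # never consumed, so skip computing it
        self.blocks[0].layers[0].need_input_grad = False

    def params(self):
        out = [p for b in self.blocks for p in b.params()]
        out += self.bottleneck.params()
        return out

    def forward(self, x):
        self._check_dims(x)
        skips = []
        for block, pool in zip(self.blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        return skips, self.bottleneck.forward(x)

    def backward(self, d_bottleneck, d_skips=None):
        dx = self.bottleneck.backward(d_bottleneck)
        for i in reversed(range(len(self.blocks))):
            dx = self.pools[i].backward(dx)
            if d_skips is not None and d_skips[i] is not None:
                dx = dx + d_skips[i]
            dx = self.blocks[i].backward(dx)
        return dx

    def _check_dims(self, x):
        f = self.spec.pool_factor
        _, r, c, _, _ = x.shape
        if r % f or c % f:
            raise ValueError(
                f"in-plane dims {(r, c)} must be divisible by the cumulative "
                f"pooling factor {f}")


class Decoder(Layer):
    """Mirror path with upsampling and skip concatenation; softmax output."""

    def __init__(self, spec: NetworkSpec, rng):
        self.spec = spec
        enc = spec.encoder_channels
        dec = spec.decoder_channels
        self.ups = [Upsample221() for _ in dec]
        self.blocks = []
        c_in = spec.bottleneck_channels
        for i, c_out in enumerate(dec):
            skip_c = enc[len(enc) - 1 - i]
            last = i == len(dec) - 1
            if not last:
                self.blocks.append(_conv_block(c_in + skip_c, c_out, rng,
                                               norm=None))
            else:
                # three convs, first two ReLU-activated, last one -> softmax
                self.blocks.append(Sequential([
                    Conv3d(c_in + skip_c, c_out, rng), ReLU(),
                    Conv3d(c_out, c_out, rng), ReLU(),
                    Conv3d(c_out, spec.n_seg_classes, rng),
                ]))
            c_in = c_out
        self.softmax = ChannelSoftmax()

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def forward(self, bottleneck, skips):
        x = bottleneck
        self._splits = []
        for i, (up, block) in enumerate(zip(self.ups, self.blocks)):
            x = up.forward(x)
            skip = skips[len(skips) - 1 - i]
            self._splits.append(x.shape[-1])
            x = np.concatenate([x, skip], axis=-1)
            x = block.forward(x)
        return self.softmax.forward(x)

    def backward(self, d_probs):
        dx = self.softmax.backward(d_probs)
        d_skips = [None] * len(self.blocks)
        for i in reversed(range(len(self.blocks))):
            dcat = self.blocks[i].backward(dx)
            split = self._splits[i]
            dx = dcat[..., :split]
            d_skips[len(self.blocks) - 1 - i] = dcat[..., split:]
            dx = self.ups[i].backward(dx)
        return dx, d_skips


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._inshape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dy):
        n, r, c, s, ch = self._inshape
        scale = dy.dtype.type(1.0 / (r * c * s))
        return np.broadcast_to(dy[:, None, None, None, :] * scale,
                               self._inshape).copy()


class PretextHead(Layer):
    """Three conv blocks on the bottleneck map, 1-conv class projection,
    global average pooling and softmax over the head's classes."""

    def __init__(self, spec: NetworkSpec, head: HeadSpec, rng):
        c_in = spec.bottleneck_channels
        widths = [spec.scaled(head.start_filters // 2 ** i) for i in range(3)]
        layers: list[Layer] = []
        c = c_in
        for w in widths:
            # per-sample normalisation: the head classifies single volumes,
            # so its features must not depend on batch composition
            block = _conv_block(c, w, rng, norm="instance")
            layers.extend(block.layers)
            c = w
        layers.append(Conv3d(c, head.n_classes, rng))
        self.body = Sequential(layers)
        self.gap = GlobalAvgPool()
        self.softmax = ChannelSoftmax()
        self.head = head

    def params(self):
        return self.body.params()

    def forward(self, bottleneck):
        logits = self.gap.forward(self.body.forward(bottleneck))
        return self.softmax.forward(logits)

    def backward(self, d_probs):
        dy = self.softmax.backward(d_probs)
        return self.body.backward(self.gap.backward(dy))


class DualTaskModel:
    """Shared encoder feeding a segmentation decoder and pretext head(s).

    ``segment``/``classify`` are stateless convenience wrappers; training code
    uses ``forward_seg``/``forward_pretext`` + the matching backward methods so
    gradients from both losses accumulate on the shared encoder parameters.
    """

    def __init__(self, spec: NetworkSpec, init_seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([init_seed, 2718]))
        self.encoder = Encoder(spec, rng)
        self.decoder = Decoder(spec, rng)
        self.heads = {h.name: PretextHead(spec, h, rng)
                      for h in spec.pretext_heads}

    # -- parameter groups -------------------------------------------------
    def encoder_params(self):
        return self.encoder.params()

    def decoder_params(self):
        return self.decoder.params()

    def head_params(self, name=None):
        if name is not None:
            return self.heads[name].params()
        return [p for h in self.heads.values() for p in h.params()]

    def params(self):
        return self.encoder_params() + self.decoder_params() + self.head_params()

    # -- train-time passes -------------------------------------------------
    def forward_seg(self, batch):
        skips, bott = self.encoder.forward(batch)
        self._seg_skips = skips
        return self.decoder.forward(bott, skips)

    def backward_seg(self, d_probs):
        d_bott, d_skips = self.decoder.backward(d_probs)
        return self.encoder.backward(d_bott, d_skips)

    def forward_pretext(self, batch, head: str):
        _, bott = self.encoder.forward(batch)
        return self.heads[head].forward(bott)

    def backward_pretext(self, d_probs, head: str):
        d_bott = self.heads[head].backward(d_probs)
        return self.encoder.backward(d_bott)

    # -- inference ---------------------------------------------------------
    def train_mode(self, flag: bool = True):
        for mod in [self.encoder, self.decoder, *self.heads.values()]:
            set_training(mod, flag)

    def calibrate(self, seg_batches, pretext_batches=None):
        """Estimate inference batch-norm statistics with frozen weights.

        Runs one forward pass in training mode over the given segmentation
        batches and (for dual-task models) per-head pretext batches — the
        same data streams the model was trained on — averaging the batch
        statistics into the population statistics used at inference.
        """
        bns = _batchnorms(self)
        self.train_mode(True)
        for bn in bns:
            bn.begin_calibration()
        try:
            for batch in seg_batches:
                self.forward_seg(batch)
            for head, batches in (pretext_batches or {}).items():
                for batch in batches:
                    self.forward_pretext(batch, head)
        finally:
            for bn in bns:
                bn.end_calibration()

    def segment(self, volume):
        """Per-voxel class probabilities for one volume or a batch."""
        batch, squeeze = _as_batch(volume)
        self.train_mode(False)
        try:
            probs = self.forward_seg(batch)
        finally:
            self.train_mode(True)
        return probs[0] if squeeze else probs

    def classify(self, volume, head: str = "intensity"):
        """Class distribution of a pretext head for one volume or a batch."""
        batch, squeeze = _as_batch(volume)
        self.train_mode(False)
        try:
            probs = self.forward_pretext(batch, head)
        finally:
            self.train_mode(True)
        return probs[0] if squeeze else probs


def _as_batch(volume):
    v = np.asarray(volume)
    if v.dtype != np.float64:
        v = v.astype(np.float32, copy=False)
    if v.ndim == 3:
        return v[None, ..., None], True
    if v.ndim == 4:
        return v[..., None], False
    if v.ndim == 5 and v.shape[-1] == 1:
        return v, False
    raise ValueError("expected a 3D volume, a (N, R, C, S) batch, or a "
                     "(N, R, C, S, 1) batch")


def build_model(spec: NetworkSpec, init_seed: int = 0) -> DualTaskModel:
    """Instantiate the dual-task network with seeded weight initialisation."""
    return DualTaskModel(spec, init_seed=init_seed)


def encode(model: DualTaskModel, volume) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-block encoder feature maps plus the bottleneck map."""
    batch, squeeze = _as_batch(volume)
    model.train_mode(False)
    try:
        skips, bott = model.encoder.forward(batch)
    finally:
        model.train_mode(True)
    if squeeze:
        return [s[0] for s in skips], bott[0]
    return skips, bott


def count_parameters(model: DualTaskModel) -> int:
    return int(sum(p.size for p in model.params()))


def save_checkpoint(model: DualTaskModel, path) -> None:
    """Weights as .npz plus a JSON sidecar recording the NetworkSpec."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    for i, layer in enumerate(_batchnorms(model)):
        arrays[f"bn{i}_mean"] = layer.pop_mean
        arrays[f"bn{i}_var"] = layer.pop_var
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"network_spec": model.spec.to_dict()}, indent=2))


def load_checkpoint(path) -> DualTaskModel:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    spec = NetworkSpec.from_dict(json.loads(sidecar.read_text())["network_spec"])
    model = build_model(spec)
    data = np.load(path if path.suffix == ".npz" else str(path))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    for i, layer in enumerate(_batchnorms(model)):
        layer.pop_mean[...] = data[f"bn{i}_mean"]
        layer.pop_var[...] = data[f"bn{i}_var"]
    return model


def _batchnorms(model: DualTaskModel) -> list[BatchNorm]:
    found: list[BatchNorm] = []

    def walk(layer):
        if isinstance(layer, BatchNorm):
            found.append(layer)
        for attr in vars(layer).values():
            if isinstance(attr, Layer):
                walk(attr)
            elif isinstance(attr, (list, tuple)):
                for a in attr:
                    if isinstance(a, Layer):
                        walk(a)

    for mod in [model.encoder, model.decoder] + [
            model.heads[k] for k in sorted(model.heads)]:
        walk(mod)
    return found
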