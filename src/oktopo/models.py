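"""U-Net, U-Net++ and U-Net3+ segmentation networks.

All three share a 4-stage encoder (channel widths w, 2w, 4w, 8w with a 16w
bottleneck, w = ``base_width``) of conv+ReLU blocks (optionally with batch
norm via ``use_bn``) and emit
``out_channels`` per-pixel sigmoid probabilities — one channel per region
(pupil, treatment zone), multi-label because the regions overlap.  They
differ only in how decoder stages are wired to the encoder:

* ``unet`` — plain long skip connections.  The 3×3 tally is the classic
  one: 19 3×3 convolutions, 4 max-pool stages, 4 upsampling stages and a
  single 1×1 output convolution.
* ``unetpp`` — nested dense skip pathways with deep supervision: every
  intermediate node at full resolution gets its own 1×1 head and the heads
  are averaged into the loss.
* ``unet3p`` — full-scale skips: every decoder aggregates feature maps
  from all shallower encoder stages (max-pooled down) and all deeper
  decoder stages plus the bottleneck, each through a 3×3 aggregation
  convolution run at the source scale and then upsampled, followed by a
  3×3 fusion convolution.  An optional classification-guided gate (off by
  default) multiplies the predicted probabilities by a per-channel
  presence score pooled from the bottleneck.

Forward passes return a list of full-resolution logit heads; ``heads[0]`` is the prediction head,
the rest are deep-supervision heads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    Conv2d,
    ConvBlock,
    ConvUnit,
    Tensor,
    concat,
    global_maxpool,
    maxpool2d,
    sigmoid,
    upsample_nearest,
)

ARCHS = ("unet", "unetpp", "unet3p")


@dataclass
class SegModelConfig:
    """Architecture hyper-parameters.

    ``base_width`` 64 matches the published full-scale networks; 8 is the
    reduced width used throughout the synthetic experiments.
    """

    arch: str = "unet"
    base_width: int = 64
    depth: int = 4
    out_channels: int = 2
    deep_supervision: bool = True
    use_cgm: bool = False
    use_bn: bool = False

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; expected one of {ARCHS}")
        if self.base_width < 1:
            raise ValueError("base_width must be positive")
        if self.depth != 4:
            raise ValueError("only depth-4 encoders are supported")
        if self.out_channels < 1:
            raise ValueError("out_channels must be positive")


class _SegModel:
    """Common plumbing: parameter collection, counting, prediction."""

    def __init__(self, config: SegModelConfig):
        self.config = config
        self._modules: list = []
        self.n_maxpool = 0
        self.n_upsample = 0
        self.skip_edges = 0
        # set by the trainer so inference knows the native network grid
        self.input_size_px: int | None = None

    def _add(self, module):
        self._modules.append(module)
        return module

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for m in self._modules:
            ps.extend(m.parameters())
        return ps

    def buffers(self) -> list[np.ndarray]:
        bs: list[np.ndarray] = []
        for m in self._modules:
            bs.extend(m.buffers())
        return bs

    def conv_layers(self) -> list[Conv2d]:
        convs: list[Conv2d] = []
        for m in self._modules:
            if isinstance(m, Conv2d):
                convs.append(m)
            elif isinstance(m, ConvUnit):
                convs.append(m.conv)
            elif isinstance(m, ConvBlock):
                convs.extend(m.convs)
        return convs

    def layer_counts(self) -> dict[str, int]:
        convs = self.conv_layers()
        return {
            "conv3x3": sum(1 for c in convs if c.k == 3),
            "conv1x1": sum(1 for c in convs if c.k == 1),
            "maxpool": self.n_maxpool,
            "upsample": self.n_upsample,
        }

    def forward(self, x: np.ndarray, training: bool = False) -> list[Tensor]:
        raise NotImplementedError  # pragma: no cover - abstract

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError(f"expected N×H×W×3 input, got shape {x.shape}")
        h, w = x.shape[1:3]
        if h % 16 or w % 16:
            raise ValueError(f"input {h}×{w} must be divisible by 16 (4 pooling stages)")
        # coordinate channels: the regions are near-circular, and the part
        # of the treatment zone occluded by the pupil must be extrapolated
        # from its visible arc — giving every pixel its normalised (x, y)
        # makes that geometric completion learnable by small convolutions
        n = x.shape[0]
        ys = np.linspace(-1.0, 1.0, h, dtype=np.float32)
        xs = np.linspace(-1.0, 1.0, w, dtype=np.float32)
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        coords = np.broadcast_to(np.stack([yy, xx], axis=-1), (n, h, w, 2))
        return np.concatenate([x, coords], axis=3)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-channel sigmoid probabilities of the prediction head, (N,H,W,C)."""
        heads = self.forward(x, training=False)
        logits = heads[0].data
        p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        gate = getattr(self, "_gate_proba", None)
        if self.config.use_cgm and gate is not None:
            p = p * gate
        return p


class UNet(_SegModel):
    def __init__(self, config: SegModelConfig, rng: np.random.Generator):
        super().__init__(config)
        w = config.base_width
        widths = [w, 2 * w, 4 * w, 8 * w]
        self.enc = [self._add(ConvBlock(cin, cout, rng, config.use_bn))
                    for cin, cout in zip([5] + widths[:-1], widths)]
        self.bottleneck = self._add(ConvBlock(8 * w, 16 * w, rng, config.use_bn))
        dec_in = [16 * w + 8 * w, 8 * w + 4 * w, 4 * w + 2 * w, 2 * w + w]
        dec_out = [8 * w, 4 * w, 2 * w, w]
        self.dec = [self._add(ConvBlock(ci, co, rng, config.use_bn)) for ci, co in zip(dec_in, dec_out)]
        self.final3 = self._add(ConvUnit(w, w, 3, rng, config.use_bn))
        self.head = self._add(Conv2d(w, config.out_channels, 1, rng))
        self.n_maxpool = 4
        self.n_upsample = 4
        self.skip_edges = 4

    def forward(self, x: np.ndarray, training: bool = False) -> list[Tensor]:
        t = Tensor(self._check_input(x))
        skips = []
        for blk in self.enc:
            t = blk(t, training)
            skips.append(t)
            t = maxpool2d(t, 2)
        t = self.bottleneck(t, training)
        for blk, s in zip(self.dec, reversed(skips)):
            t = blk(concat([upsample_nearest(t, 2), s]), training)
        return [self.head(self.final3(t, training))]


class UNetPP(_SegModel):
    """Nested U-Net: node X(i,j) fuses all same-scale predecessors X(i,0..j-1)
    with the upsampled deeper node X(i+1,j-1)."""

    def __init__(self, config: SegModelConfig, rng: np.random.Generator):
        super().__init__(config)
        w = config.base_width
        widths = [w * 2**i for i in range(5)]
        self.backbone = [self._add(ConvBlock(cin, cout, rng, config.use_bn))
                         for cin, cout in zip([5] + widths[:-1], widths)]
        self.nodes: dict[tuple[int, int], ConvBlock] = {}
        for j in range(1, 5):
            for i in range(0, 5 - j):
                cin = j * widths[i] + widths[i + 1]
                self.nodes[(i, j)] = self._add(ConvBlock(cin, widths[i], rng, config.use_bn))
                self.n_upsample += 1
                self.skip_edges += j
        n_heads = 4 if config.deep_supervision else 1
        self.heads = [
            self._add(Conv2d(widths[0], config.out_channels, 1, rng))
            for _ in range(n_heads)
        ]
        self.n_maxpool = 4

    def forward(self, x: np.ndarray, training: bool = False) -> list[Tensor]:
        t = Tensor(self._check_input(x))
        grid: dict[tuple[int, int], Tensor] = {}
        for i, blk in enumerate(self.backbone):
            t = blk(t, training)
            grid[(i, 0)] = t
            if i < 4:
                t = maxpool2d(t, 2)
        for j in range(1, 5):
            for i in range(0, 5 - j):
                inputs = [grid[(i, jj)] for jj in range(j)]
                inputs.append(upsample_nearest(grid[(i + 1, j - 1)], 2))
                grid[(i, j)] = self.nodes[(i, j)](concat(inputs), training)
        if self.config.deep_supervision:
            logits = [head(grid[(0, j)]) for head, j in zip(self.heads, range(1, 5))]
            return [logits[-1]] + logits[:-1]  # prediction head first
        return [self.heads[0](grid[(0, 4)])]


class UNet3P(_SegModel):
    """Full-scale skip connections: decoder D_i concatenates aggregation
    convolutions of encoders E_1..E_i (pooled to scale i) and of the deeper
    decoders plus the bottleneck (convolved at source scale, upsampled)."""

    def __init__(self, config: SegModelConfig, rng: np.random.Generator):
        super().__init__(config)
        w = config.base_width
        self.cat_ch = w
        self.fuse_ch = 5 * w
        widths = [w, 2 * w, 4 * w, 8 * w]
        self.enc = [self._add(ConvBlock(cin, cout, rng, config.use_bn))
                    for cin, cout in zip([5] + widths[:-1], widths)]
        self.bottleneck = self._add(ConvBlock(8 * w, 16 * w, rng, config.use_bn))
        self.n_maxpool = 4
        # aggregation convs: key (source, target_level); sources "e1".."e5"
        # (encoders + bottleneck) or "d2".."d4" (deeper decoders)
        self.branches: dict[tuple[str, int], ConvUnit] = {}
        self.fusions: dict[int, ConvUnit] = {}
        src_ch = {f"e{j}": widths[j - 1] for j in range(1, 5)}
        src_ch["e5"] = 16 * w
        for m in range(2, 5):
            src_ch[f"d{m}"] = self.fuse_ch
        for i in range(4, 0, -1):  # decoder levels, deep to shallow
            for j in range(1, i + 1):
                self.branches[(f"e{j}", i)] = self._add(ConvUnit(src_ch[f"e{j}"], w, 3, rng, config.use_bn))
                if j < i:
                    self.n_maxpool += 1
            for m in range(i + 1, 5):
                self.branches[(f"d{m}", i)] = self._add(ConvUnit(src_ch[f"d{m}"], w, 3, rng, config.use_bn))
                self.n_upsample += 1
                self.skip_edges += 1
            self.branches[("e5", i)] = self._add(ConvUnit(src_ch["e5"], w, 3, rng, config.use_bn))
            self.n_upsample += 1
            self.skip_edges += i  # encoder-side full-scale skips (e_j, j<=i)
            self.fusions[i] = self._add(ConvUnit(self.fuse_ch, self.fuse_ch, 3, rng, config.use_bn))
        self.heads = {
            i: self._add(Conv2d(self.fuse_ch, config.out_channels, 1, rng))
            for i in (range(1, 5) if config.deep_supervision else [1])
        }
        if config.use_cgm:
            self.cgm_conv = self._add(Conv2d(16 * w, config.out_channels, 1, rng))
        self._gate_proba: np.ndarray | None = None
        self._gate_logits: Tensor | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> list[Tensor]:
        t = Tensor(self._check_input(x))
        feats: dict[str, Tensor] = {}
        for j, blk in enumerate(self.enc, start=1):
            t = blk(t, training)
            feats[f"e{j}"] = t
            t = maxpool2d(t, 2)
        feats["e5"] = self.bottleneck(t, training)
        if self.config.use_cgm:
            self._gate_logits = self.cgm_conv(global_maxpool(feats["e5"]))
            self._gate_proba = sigmoid(self._gate_logits).data
        for i in range(4, 0, -1):
            parts = []
            for j in range(1, i + 1):
                src = feats[f"e{j}"]
                if j < i:
                    src = maxpool2d(src, 2 ** (i - j))
                parts.append(self.branches[(f"e{j}", i)](src, training))
            for m in range(i + 1, 5):
                parts.append(upsample_nearest(
                    self.branches[(f"d{m}", i)](feats[f"d{m}"], training), 2 ** (m - i)))
            parts.append(upsample_nearest(
                self.branches[("e5", i)](feats["e5"], training), 2 ** (5 - i)))
            feats[f"d{i}"] = self.fusions[i](concat(parts), training)
        logits = [self.heads[1](feats["d1"])]
        if self.config.deep_supervision:
            for i in range(2, 5):
                head = self.heads[i](feats[f"d{i}"])
                logits.append(upsample_nearest(head, 2 ** (i - 1)))
        return logits


def build_model(config: SegModelConfig, seed: int = 0) -> _SegModel:
    """Construct a freshly initialised network for ``config.arch``.

    All weights are drawn from a Generator seeded with ``seed``; two calls
    with equal arguments yield identical parameters.
    """
    rng = np.random.default_rng(seed)
    cls = {"unet": UNet, "unetpp": UNetPP, "unet3p": UNet3P}[config.arch]
    return cls(config, rng)


def save_checkpoint(model: _SegModel, path) -> None:
    """Serialise weights, BN buffers and embedded config JSON to an .npz."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    arrays.update({f"buf{i}": b for i, b in enumerate(model.buffers())})
    meta = dict(asdict(model.config), input_size_px=model.input_size_px)
    arrays["__config__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> _SegModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__config__"].tobytes()).decode())
        input_size = meta.pop("input_size_px", None)
        config = SegModelConfig(**meta)
        model = build_model(config, seed=0)
        for i, p in enumerate(model.parameters()):
            stored = z[f"p{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(f"checkpoint/model shape mismatch at parameter {i}")
            p.data = stored.astype(np.float32)
        for i, b in enumerate(model.buffers()):
            b[...] = z[f"buf{i}"]
    model.input_size_px = input_size
    return model
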