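"""The two-stream fusion classifier.

Each modality passes through its own encoder: a 3x3 stem convolution
followed by three densely connected blocks (every 3x3 layer sees the
concatenation of the block input and all previous layer outputs), each
block closed by a 1x1 transition convolution and 2x2 average pooling.  A
240x240 input therefore yields per-scale features at 120, 60 and 30 pixels,
with the deepest at 30x30x128 under the default widths.

The per-scale modality pairs are merged by the activity-level fusion layer
(see :mod:`neurofuse.fusion`), resized to the deepest grid and averaged into
one fused map.  Channel-then-spatial multiplicative attention gates are
applied to the two deep modality features and the fused map; the three are
concatenated (384 channels by default), flattened, and classified by two
fully connected layers with a softmax over the three tumor types.

Training minimises the mean categorical cross-entropy over slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .fusion import fuse_graph, DEFAULT_RADIUS

NUM_CLASSES = 3
INPUT_SIZE = 240


@dataclass
class DenseBlockConfig:
    num_layers: int = 5
    growth_rate: int = 16
    in_channels: int = 32

    def __post_init__(self):
        if self.num_layers < 1 or self.growth_rate < 1:
            raise ValueError("num_layers and growth_rate must be >= 1")

    @property
    def out_channels(self) -> int:
        return self.in_channels + self.num_layers * self.growth_rate


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``stage_channels`` are the widths after each block's 1x1 transition; the
    last entry is also the common channel count of the fusion layer, so the
    concatenated decoder input has 3x that many channels.
    """

    input_size: int = INPUT_SIZE
    num_classes: int = NUM_CLASSES
    stem_channels: int = 32
    growth_rate: int = 16
    layers_per_block: int = 5
    stage_channels: tuple[int, int, int] = (32, 64, 128)
    fusion_radius: int = DEFAULT_RADIUS
    fc_hidden: int = 256
    attention: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.input_size % 8:
            raise ValueError("input_size must be divisible by 8 (three 2x2 pools)")

    @property
    def fused_size(self) -> int:
        return self.input_size // 8

    @property
    def fused_channels(self) -> int:
        return self.stage_channels[-1]


def small_config(seed: int = 0, attention: bool = True) -> ModelConfig:
    """A narrow configuration sized for CPU-scale experiments.

    Same topology as the default (three 5-layer dense blocks per modality,
    fusion at every scale, attention, two FC layers) with reduced widths."""
    return ModelConfig(stem_channels=3, growth_rate=3, stage_channels=(6, 10, 12),
                       fc_hidden=32, seed=seed, attention=attention)


@dataclass
class ClassProbabilities:
    """A point on the 3-class probability simplex (GBM, SBM, PCNSL)."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("expected a probability vector")
        if np.any(self.p < -1e-9) or abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Tiny parameter container with named leaves and train/eval mode."""

    def __init__(self):
        self._params: dict[str, ad.Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def add_param(self, name: str, value: np.ndarray) -> ad.Tensor:
        t = ad.Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        return value

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def named_parameters(self, prefix: str = "") -> dict[str, ad.Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, child in self._children.items():
            out.update(child.named_buffers(prefix + name + "."))
        return out

    def parameters(self) -> list[ad.Tensor]:
        return list(self.named_parameters().values())

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def set_training(self, flag: bool):
        self.training = flag
        for c in self._children.values():
            c.set_training(flag)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    dtype = np.dtype(dtype)
    draw_dtype = dtype if dtype in (np.dtype(np.float32), np.dtype(np.float64)) else np.dtype(np.float64)
    out = rng.standard_normal(size=shape, dtype=draw_dtype) * draw_dtype.type(np.sqrt(2.0 / fan_in))
    return out.astype(dtype, copy=False)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, dtype):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.w = self.add_param("w", _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype))
        self.b = self.add_param("b", np.zeros(out_ch, dtype=dtype))

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, channels: int, dtype):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(channels, dtype=dtype))
        self.beta = self.add_param("beta", np.zeros(channels, dtype=dtype))
        self.running_mean = self.add_buffer("running_mean", np.zeros(channels, dtype=dtype))
        self.running_var = self.add_buffer("running_var", np.ones(channels, dtype=dtype))

    def __call__(self, x):
        return ad.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, training=self.training)


class Linear(Module):
    def __init__(self, rng, in_f: int, out_f: int, dtype):
        super().__init__()
        self.w = self.add_param("w", _he_init(rng, (out_f, in_f), in_f, dtype))
        self.b = self.add_param("b", np.zeros(out_f, dtype=dtype))

    def __call__(self, x):
        return ad.linear(x, self.w, self.b)


class DenseBlock(Module):
    """num_layers x (BatchNorm -> ReLU -> 3x3 conv(growth)) with dense
    channel concatenation of the block input and all previous outputs.

    Runs as one fused operation over a shared channel buffer (the dense
    concatenation pattern would otherwise copy every feature map once per
    layer); the backward pass is hand-derived and exercised by the
    finite-difference gradient test.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, rng, cfg: DenseBlockConfig, dtype):
        super().__init__()
        self.cfg = cfg
        ch = cfg.in_channels
        self.layers = []
        for i in range(cfg.num_layers):
            bn = self.add_child(f"bn{i}", BatchNorm2d(ch, dtype))
            conv = self.add_child(f"conv{i}", Conv2d(rng, ch, cfg.growth_rate, 3, dtype))
            self.layers.append((bn, conv))
            ch += cfg.growth_rate

    def __call__(self, x):
        from . import _kernels

        x = ad.as_tensor(x)
        n, c0, h, wd = x.data.shape
        if c0 != self.cfg.in_channels:
            raise ValueError(
                f"DenseBlock expects {self.cfg.in_channels} channels, got {c0}")
        growth = self.cfg.growth_rate
        training = self.training
        buf = np.empty((n, self.cfg.out_channels, h, wd), dtype=x.data.dtype)
        buf[:, :c0] = x.data
        stats = []
        off = c0
        for bn, conv in self.layers:
            if training:
                mu, inv = _kernels.bn_stats(buf, off, self.BN_EPS)
                var = 1.0 / inv.astype(np.float64) ** 2 - self.BN_EPS
                bn.running_mean *= 1.0 - self.BN_MOMENTUM
                bn.running_mean += self.BN_MOMENTUM * mu
                bn.running_var *= 1.0 - self.BN_MOMENTUM
                bn.running_var += self.BN_MOMENTUM * var.astype(bn.running_var.dtype)
            else:
                mu = bn.running_mean
                inv = (1.0 / np.sqrt(bn.running_var.astype(np.float64) + self.BN_EPS)
                       ).astype(buf.dtype)
            _kernels.dense_layer_fwd(buf, off, bn.gamma.data, bn.beta.data,
                                     conv.w.data, conv.b.data, mu, inv)
            stats.append((mu, inv))
            off += growth

        parents = [x]
        for bn, conv in self.layers:
            parents += [bn.gamma, bn.beta, conv.w, conv.b]

        def backward(gbuf):
            dbuf = np.array(gbuf, copy=True)
            pos = self.cfg.out_channels
            for (bn, conv), (mu, inv) in zip(reversed(self.layers), reversed(stats)):
                pos -= growth
                gw, gb, ggam, gbet = _kernels.dense_layer_bwd(
                    buf, dbuf, pos, bn.gamma.data, bn.beta.data, conv.w.data,
                    mu, inv, training)
                conv.w._accumulate(gw)
                conv.b._accumulate(gb)
                bn.gamma._accumulate(ggam)
                bn.beta._accumulate(gbet)
            x._accumulate(dbuf[:, :c0])

        return ad._make(buf, tuple(parents), backward)


class Encoder(Module):
    """Stem conv + three DenseBlock/transition/pool stages for one modality."""

    def __init__(self, rng, cfg: ModelConfig, dtype):
        super().__init__()
        self.cfg = cfg
        self.stem = self.add_child("stem", Conv2d(rng, 1, cfg.stem_channels, 3, dtype))
        ch = cfg.stem_channels
        self.stages = []
        for s, out_ch in enumerate(cfg.stage_channels):
            block = self.add_child(f"block{s}", DenseBlock(
                rng, DenseBlockConfig(cfg.layers_per_block, cfg.growth_rate, ch), dtype))
            trans = self.add_child(f"trans{s}", Conv2d(rng, block.cfg.out_channels, out_ch, 1, dtype))
            self.stages.append((block, trans))
            ch = out_ch

    def __call__(self, x) -> list[ad.Tensor]:
        """Returns [f0, f1, f2, f3]: stem output plus the pooled stage outputs."""
        if x.data.shape[2] != self.cfg.input_size or x.data.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"encoder expects {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {x.data.shape[2]}x{x.data.shape[3]}")
        f = ad.relu(self.stem(x))
        feats = [f]
        for block, trans in self.stages:
            f = ad.avg_pool2(trans(block(f)))
            feats.append(f)
        return feats


class Attention(Module):
    """Sequential channel-then-spatial multiplicative gating.

    The channel gate is a sigmoid over a two-layer bottleneck applied to the
    spatially pooled descriptor; the spatial gate is a sigmoid over a 3x3
    convolution of the channel-mean map.  ``force_identity`` bypasses both
    gates (used to verify the identity contract)."""

    def __init__(self, rng, channels: int, dtype, reduction: int = 4):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = self.add_child("fc1", Linear(rng, channels, hidden, dtype))
        self.fc2 = self.add_child("fc2", Linear(rng, hidden, channels, dtype))
        self.spatial = self.add_child("spatial", Conv2d(rng, 1, 1, 3, dtype))
        self.force_identity = False

    def __call__(self, x):
        if self.force_identity:
            return x
        desc = ad.mean(x, axis=(2, 3))                      # (N, C)
        cgate = ad.sigmoid(self.fc2(ad.relu(self.fc1(desc))))
        n, c = cgate.data.shape
        x = ad.mul(x, ad.reshape(cgate, (n, c, 1, 1)))
        smap = ad.mean(x, axis=1, keepdims=True)            # (N, 1, H, W)
        sgate = ad.sigmoid(self.spatial(smap))
        return ad.mul(x, sgate)


class FusionClassifier(Module):
    """The full two-stream model; forward returns class logits."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        self.enc_t1ce = self.add_child("enc_t1ce", Encoder(rng, cfg, dtype))
        self.enc_flair = self.add_child("enc_flair", Encoder(rng, cfg, dtype))
        fc = cfg.fused_channels
        # shared per-scale 1x1 projections so fusion compares like with like
        self.projections = [
            self.add_child(f"proj{s}", Conv2d(rng, ch, fc, 1, dtype))
            for s, ch in enumerate(cfg.stage_channels)
        ]
        self.att_t1ce = self.add_child("att_t1ce", Attention(rng, fc, dtype))
        self.att_flair = self.add_child("att_flair", Attention(rng, fc, dtype))
        self.att_fused = self.add_child("att_fused", Attention(rng, fc, dtype))
        flat = cfg.fused_size * cfg.fused_size * 3 * fc
        self.fc1 = self.add_child("fc1", Linear(rng, flat, cfg.fc_hidden, dtype))
        self.fc2 = self.add_child("fc2", Linear(rng, cfg.fc_hidden, cfg.num_classes, dtype))

    # -- forward ----------------------------------------------------------
    def forward(self, x_t1ce: np.ndarray, x_flair: np.ndarray,
                capture: dict | None = None) -> ad.Tensor:
        """Class logits for a batch of paired slices.

        ``x_*`` are (N, H, W) arrays in [0, 255].  When ``capture`` is a
        dict, named intermediate tensors (branch features, fused map) are
        stored in it with gradients retained — the Grad-CAM hook.
        """
        cfg = self.cfg
        if x_t1ce.shape != x_flair.shape:
            raise ValueError("modality batches must share a shape")
        dtype = np.dtype(cfg.dtype).type
        a = ad.Tensor((np.asarray(x_t1ce, dtype=dtype) / 255.0)[:, None])
        b = ad.Tensor((np.asarray(x_flair, dtype=dtype) / 255.0)[:, None])
        feats_a = self.enc_t1ce(a)
        feats_b = self.enc_flair(b)
        size = cfg.fused_size
        fused_scales = []
        for s, proj in enumerate(self.projections):
            pa, pb = proj(feats_a[s + 1]), proj(feats_b[s + 1])
            fused = fuse_graph([pa, pb], r=cfg.fusion_radius)
            fused_scales.append(ad.bilinear_resize(fused, size, size))
        acc = fused_scales[0]
        for f in fused_scales[1:]:
            acc = ad.add(acc, f)
        f_fusion = ad.mul(acc, 1.0 / len(fused_scales))

        f3a, f3b = feats_a[-1], feats_b[-1]  # natively fused_size x fused_channels
        if cfg.attention:
            f3a, f3b = self.att_t1ce(f3a), self.att_flair(f3b)
            f_fusion = self.att_fused(f_fusion)
        if capture is not None:
            for name, t in (("t1ce", f3a), ("flair", f3b), ("fusion", f_fusion)):
                t.retain_grad()
                capture[name] = t
        f_all = ad.concat([f3a, f3b, f_fusion], axis=1)
        n = f_all.data.shape[0]
        flat = ad.reshape(f_all, (n, -1))
        return self.fc2(ad.relu(self.fc1(flat)))

    def predict_proba(self, x_t1ce: np.ndarray, x_flair: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, eval mode, no graph retained."""
        was_training = self.training
        self.set_training(False)
        try:
            logits = self.forward(x_t1ce, x_flair)
        finally:
            self.set_training(was_training)
        return ad.softmax(logits.data, axis=1)


# ---------------------------------------------------------------------------
# loss (slice-level categorical cross-entropy)
# ---------------------------------------------------------------------------

def cross_entropy_loss(probs: list[ClassProbabilities], labels: list[np.ndarray]) -> float:
    """Mean over slices of -sum_l y_l log p_l, with probabilities clamped at
    1e-12 so the loss stays finite."""
    if len(probs) != len(labels):
        raise ValueError("probs and labels differ in length")
    if not probs:
        raise ValueError("need at least one slice")
    total = 0.0
    for cp, y in zip(probs, labels):
        y = np.asarray(y, dtype=float)
        total -= float((y * np.log(np.maximum(cp.p, 1e-12))).sum())
    return total / len(probs)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FusionClassifier, path: str | Path) -> None:
    """Write parameters + buffers as .npz with a JSON config sidecar."""
    path = Path(path)
    arrays = {f"param:{k}": v.data for k, v in model.named_parameters().items()}
    arrays.update({f"buffer:{k}": v for k, v in model.named_buffers().items()})
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(asdict(model.cfg), indent=2))


def load_checkpoint(path: str | Path) -> FusionClassifier:
    path = Path(path)
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    cfg_dict["stage_channels"] = tuple(cfg_dict["stage_channels"])
    model = FusionClassifier(ModelConfig(**cfg_dict))
    data = np.load(path.with_suffix(".npz"))
    params = model.named_parameters()
    buffers = model.named_buffers()
    for key in data.files:
        kind, name = key.split(":", 1)
        if kind == "param":
            params[name].data = data[key]
        else:
            buffers[name][...] = data[key]
    return model
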