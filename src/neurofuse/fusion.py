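"""L1-norm activity-level feature fusion.

Two co-registered modalities are encoded separately; their feature maps are
merged pixel-wise by a convex combination whose weights come from each
modality's *activity level* — the channel-wise L1 norm of its feature map,
smoothed by a small box window:

    C_i(x, y)   = sum_m |Phi_i(x, y, m)|                 (activity map)
    Chat_i      = box-sum of C_i over (2r+1)^2 / (2r+1)^2 (smoothed, r=2)
    w_i(x, y)   = Chat_i(x, y) / sum_n Chat_n(x, y)       (fusion weights)
    f_fused     = sum_i w_i(x, y) * Phi_i(x, y, m)        (fused feature)

The box window is zero-padded with the divisor held fixed at (2r+1)^2, so
border pixels are down-weighted rather than renormalised.  Where the weight
denominator vanishes (all modalities inactive) the weights fall back to the
uniform 1/K.

Functions here operate on plain (H, W, M) numpy arrays wrapped in small
dataclasses; the same graph operators back the trainable network, so the
fused forward pass and its gradient share one implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import autodiff as ad

DEFAULT_RADIUS = 2
DEFAULT_EPS = 1e-8
FUSED_SIZE = 30
FUSED_CHANNELS = 128


class Modality(str, Enum):
    T1CE = "CE-T1WI"
    FLAIR = "T2-Flair"
    FUSED = "fused"


@dataclass
class FeatureMap:
    """An (H, W, M) activation block produced by an encoder or the fusion layer."""

    values: np.ndarray
    scale_index: int = 0
    modality: Modality = Modality.FUSED

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("FeatureMap expects an (H, W, M) array")
        if min(self.values.shape) < 1:
            raise ValueError("FeatureMap dimensions must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap values must be finite")


@dataclass
class ActivityMap:
    """Per-pixel channel L1 norm of a feature map (nonnegative)."""

    values: np.ndarray
    smoothed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("activity levels are nonnegative by construction")


@dataclass
class WeightMaps:
    """K per-modality weight maps; at each pixel the weights sum to 1."""

    values: np.ndarray  # (K, H, W)
    k: int = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.k = self.values.shape[0]


def _to_nchw(values: np.ndarray) -> np.ndarray:
    return np.moveaxis(values, -1, 0)[None]  # (H,W,M) -> (1,M,H,W)


def activity_map(phi: FeatureMap) -> ActivityMap:
    """Channel-wise L1 norm at every pixel."""
    return ActivityMap(np.abs(phi.values).sum(axis=-1), smoothed=False)


def smooth_activity(c: ActivityMap, r: int = DEFAULT_RADIUS) -> ActivityMap:
    """Box-window smoothing with zero padding and fixed divisor (2r+1)^2."""
    if r < 0:
        raise ValueError("window radius r must be nonnegative")
    if c.smoothed:
        raise ValueError("activity map already smoothed")
    x = ad.Tensor(c.values[None, None])
    return ActivityMap(ad.box_filter(x, r).data[0, 0], smoothed=True)


def fusion_weights(cs: list[ActivityMap], eps: float = DEFAULT_EPS) -> WeightMaps:
    """Pixel-wise normalisation of smoothed activities into convex weights."""
    if len(cs) < 2:
        raise ValueError("fusion requires at least two modalities")
    shapes = {c.values.shape for c in cs}
    if len(shapes) > 1:
        raise ValueError(f"activity maps have mismatched shapes: {shapes}")
    tensors = [ad.Tensor(c.values[None, None]) for c in cs]
    ws = ad.activity_weights(tensors, eps=eps)
    return WeightMaps(np.stack([w.data[0, 0] for w in ws]))


def fuse(phis: list[FeatureMap], r: int = DEFAULT_RADIUS, eps: float = DEFAULT_EPS) -> FeatureMap:
    """Fuse K same-shape feature maps into one by activity-weighted averaging."""
    if len(phis) < 2:
        raise ValueError("fusion requires at least two feature maps")
    shapes = {p.values.shape for p in phis}
    if len(shapes) > 1:
        raise ValueError(f"feature maps have mismatched shapes: {shapes}")
    xs = [ad.Tensor(_to_nchw(p.values)) for p in phis]
    fused = fuse_graph(xs, r=r, eps=eps)
    return FeatureMap(np.moveaxis(fused.data[0], 0, -1), scale_index=phis[0].scale_index,
                      modality=Modality.FUSED)


def fuse_graph(xs: list[ad.Tensor], r: int = DEFAULT_RADIUS, eps: float = DEFAULT_EPS) -> ad.Tensor:
    """Graph-level fusion of K (N, M, H, W) tensors (differentiable path)."""
    cs = [ad.box_filter(ad.sum_(ad.absolute(x), axis=1, keepdims=True), r) for x in xs]
    ws = ad.activity_weights(cs, eps=eps)
    out = ad.mul(ws[0], xs[0])
    for w, x in zip(ws[1:], xs[1:]):
        out = ad.add(out, ad.mul(w, x))
    return out


def resize_feature(phi: FeatureMap, target_h: int, target_w: int) -> FeatureMap:
    """Per-channel bilinear resize (half-pixel centres, edge clamped)."""
    if target_h < 1 or target_w < 1:
        raise ValueError("target dimensions must be >= 1")
    x = ad.Tensor(_to_nchw(phi.values))
    y = ad.bilinear_resize(x, target_h, target_w)
    return FeatureMap(np.moveaxis(y.data[0], 0, -1), scale_index=phi.scale_index,
                      modality=phi.modality)


def multi_scale_fuse(features_a: list[FeatureMap], features_b: list[FeatureMap],
                     r: int = DEFAULT_RADIUS, eps: float = DEFAULT_EPS,
                     target_size: int = FUSED_SIZE) -> FeatureMap:
    """Fuse each per-scale modality pair, resize every fused map to the
    deepest grid and average the scales element-wise.

    The per-scale maps must already share channel count (the network applies
    1x1 projections before calling this)."""
    if len(features_a) < 1 or len(features_a) != len(features_b):
        raise ValueError("need the same nonzero number of scales per modality")
    fused_scales = []
    for fa, fb in zip(features_a, features_b):
        fused = fuse([fa, fb], r=r, eps=eps)
        fused_scales.append(resize_feature(fused, target_size, target_size).values)
    return FeatureMap(np.mean(fused_scales, axis=0), scale_index=len(features_a) - 1,
                      modality=Modality.FUSED)
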