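"""Attention-refined multiscale feature extraction for tumor ROIs.

The feature network composes four ideas from modern CNN design:

* **Dense blocks** — every stage consumes the concatenation of all
  previous stage outputs and emits ``g`` (the growth rate) new
  channels, so a block maps ``g0`` input channels to ``g0 + N * g``.
  Transition layers (1x1 convolution + 2x2 average pooling) halve the
  spatial size between blocks.
* **Multiscale (inception-style) extraction** — four parallel branches
  (1x1; 1x1 -> 3x3; 1x1 -> 5x5; 3x3 max pool -> 1x1) are concatenated
  along channels, capturing context at several receptive fields.
* **Self- and spatial attention** — the map is reshaped to (Y, D) with
  Y = H*W and refined by multi-head scaled dot-product self-attention
  (``softmax(Q K^T / C_k) V`` per head, heads concatenated and
  projected back to D); in parallel a spatial gate built from
  cross-channel average/max pooling, ReLU, a 1x1 convolution and a
  sigmoid rescales each position.  The two refined maps are aggregated
  by elementwise addition (a concat + 1x1-conv variant is available).
* **Channel attention** — global max pooling per channel, a bottleneck
  of two 1x1 convolutions (ReLU then sigmoid, bottleneck width
  C_hat = max(1, round(C/8))) gates each channel of the aggregate.

A global average pool turns the final map into one feature vector per
ROI.  The trunk is trained end-to-end with a small classification head
(discarded afterwards); the pooled vectors feed the ensemble
classifier.  Note the attention logits are divided by ``C_k`` itself by
default; ``divide_by_sqrt_Ck`` switches to the more common
``sqrt(C_k)`` scaling.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn.autograd import Tensor
from .phantom import LabeledImage


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

from dataclasses import dataclass


@dataclass(frozen=True)
class DenseBlockConfig:
    """stages N, growth rate g, input channels g0, number of blocks O."""

    stages: int = 2
    growth_rate: int = 4
    initial_channels: int = 8
    blocks: int = 2

    def __post_init__(self) -> None:
        if min(self.growth_rate, self.initial_channels, self.blocks) < 1:
            raise ValueError("growth_rate, initial_channels, blocks must be >= 1")
        if self.stages < 0:
            raise ValueError("stages must be >= 0")

    @property
    def output_channels(self) -> int:
        return self.initial_channels + self.stages * self.growth_rate


@dataclass(frozen=True)
class AttentionConfig:
    heads: int = 4
    key_dim: int | None = None  # default D // heads
    value_dim: int | None = None
    scale_rule: str = "divide_by_Ck"
    channel_reduction: int = 8  # C_hat = max(1, round(C / channel_reduction))

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.scale_rule not in ("divide_by_Ck", "divide_by_sqrt_Ck"):
            raise ValueError("unknown scale_rule")


@dataclass(frozen=True)
class FeatureNetConfig:
    """End-to-end feature-extractor configuration (test-scale defaults)."""

    input_size: int = 64
    stem_channels: int = 8
    dense: DenseBlockConfig = DenseBlockConfig()
    branch_widths: tuple[int, int, int, int] = (8, 8, 8, 8)
    attention: AttentionConfig = AttentionConfig()
    aggregation: str = "add"  # or "concat"
    n_classes: int = 3
    seed: int = 0
    # representation-learning hyperparameters
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.003
    dropout: float = 0.5


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class DenseBlock(nn.Module):
    """N stages; stage n sees the concat of the input and all previous
    stage outputs and emits ``growth_rate`` channels (3x3 conv + ReLU)."""

    def __init__(self, config: DenseBlockConfig, rng: np.random.Generator):
        self.config = config
        self.stages = [
            nn.Conv2d(
                config.initial_channels + i * config.growth_rate,
                config.growth_rate, 3, rng,
            )
            for i in range(config.stages)
        ]

    def forward(self, x: Tensor) -> Tensor:
        outputs = [x]
        for stage in self.stages:
            inp = outputs[0] if len(outputs) == 1 else nn.concat(outputs, axis=1)
            outputs.append(stage(inp).relu())
        return outputs[0] if len(outputs) == 1 else nn.concat(outputs, axis=1)


class Transition(nn.Module):
    """1x1 convolution then 2x2 average pooling (even dims required)."""

    def __init__(self, c_in: int, c_out: int | None, rng: np.random.Generator):
        self.conv = nn.Conv2d(c_in, c_out or c_in, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return nn.avg_pool2d(self.conv(x), 2)


class MultiScaleBlock(nn.Module):
    """Four-branch inception-style extractor, concatenated on channels."""

    def __init__(self, c_in: int, widths: tuple[int, int, int, int],
                 rng: np.random.Generator):
        w1, w2, w3, w4 = widths
        self.b1 = nn.Conv2d(c_in, w1, 1, rng)
        self.b2a = nn.Conv2d(c_in, w2, 1, rng)
        self.b2b = nn.Conv2d(w2, w2, 3, rng)
        self.b3a = nn.Conv2d(c_in, w3, 1, rng)
        self.b3b = nn.Conv2d(w3, w3, 5, rng)
        self.b4 = nn.Conv2d(c_in, w4, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.b1(x).relu()
        y2 = self.b2b(self.b2a(x).relu()).relu()
        y3 = self.b3b(self.b3a(x).relu()).relu()
        y4 = self.b4(_max_pool3_same(x)).relu()
        return nn.concat([y1, y2, y3, y4], axis=1)


def _max_pool3_same(x: Tensor) -> Tensor:
    """3x3 stride-1 max pooling with same-size output."""
    n, c, h, w = x.shape
    padded = Tensor(
        np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)),
               constant_values=-np.inf),
        x.requires_grad,
    )
    padded._prev = (x,)

    def backward() -> None:
        if x.requires_grad:
            x._accum(padded.grad[:, :, 1:-1, 1:-1])

    padded._backward = backward

    out = None
    for di in range(3):
        for dj in range(3):
            window = padded[:, :, di : di + h, dj : dj + w]
            out = window if out is None else _maximum(out, window)
    return out


def _maximum(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, b.data), a.requires_grad or b.requires_grad)
    out._prev = (a, b)

    def backward() -> None:
        pick_a = a.data >= b.data  # ties go to the first argument
        if a.requires_grad:
            a._accum(out.grad * pick_a)
        if b.requires_grad:
            b._accum(out.grad * ~pick_a)

    out._backward = backward
    return out


class SelfAttentionBlock(nn.Module):
    """Multi-head self-attention over spatial positions.

    The H x W x D map is flattened to Y x D (Y = H*W); per head i,
    Q_i = F W_i^Q + e^Q, K_i = F W_i^K + e^K, V_i = F W_i^V + e^V, and
    attention = softmax(Q K^T / s) V with s = C_k (as configured).
    Heads are concatenated and projected back to D.
    """

    def __init__(self, d: int, cfg: AttentionConfig, rng: np.random.Generator):
        if d % cfg.heads and cfg.key_dim is None:
            raise ValueError(
                f"feature dim {d} not divisible by heads {cfg.heads}; "
                "set key_dim/value_dim explicitly"
            )
        self.cfg = cfg
        self.d = d
        ck = cfg.key_dim or d // cfg.heads
        cv = cfg.value_dim or d // cfg.heads
        self.ck, self.cv = ck, cv
        std = 1.0 / np.sqrt(d)
        make = lambda *shape: Tensor(rng.normal(0, std, shape), requires_grad=True)  # noqa: E731
        self.wq = [make(d, ck) for _ in range(cfg.heads)]
        self.wk = [make(d, ck) for _ in range(cfg.heads)]
        self.wv = [make(d, cv) for _ in range(cfg.heads)]
        self.eq = [Tensor(np.zeros(ck), requires_grad=True) for _ in range(cfg.heads)]
        self.ek = [Tensor(np.zeros(ck), requires_grad=True) for _ in range(cfg.heads)]
        self.ev = [Tensor(np.zeros(cv), requires_grad=True) for _ in range(cfg.heads)]
        self.wo = make(cfg.heads * cv, d)
        self.bo = Tensor(np.zeros(d), requires_grad=True)

    def attention_rows(self, F: np.ndarray, head: int) -> np.ndarray:
        """Softmax attention matrix of one head for an (Y, D) input
        (diagnostic surface used by the tests)."""
        q = F @ self.wq[head].data + self.eq[head].data
        k = F @ self.wk[head].data + self.ek[head].data
        s = self.ck if self.cfg.scale_rule == "divide_by_Ck" else np.sqrt(self.ck)
        logits = q @ k.T / s
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C, H, W) -> same shape, attention over Y = H*W."""
        n, c, h, w = x.shape
        if c != self.d:
            raise ValueError(f"expected {self.d} channels, got {c}")
        F = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, Y, D)
        s = self.ck if self.cfg.scale_rule == "divide_by_Ck" else np.sqrt(self.ck)
        heads = []
        for i in range(self.cfg.heads):
            q = F @ self.wq[i] + self.eq[i]
            k = F @ self.wk[i] + self.ek[i]
            v = F @ self.wv[i] + self.ev[i]
            attn = nn.softmax(q @ k.transpose(0, 2, 1) * (1.0 / s), axis=-1)
            heads.append(attn @ v)
        out = nn.concat(heads, axis=-1) @ self.wo + self.bo  # (N, Y, D)
        return out.transpose(0, 2, 1).reshape(n, c, h, w)


class SpatialAttentionBlock(nn.Module):
    """Position gating from cross-channel average and max pooling."""

    def __init__(self, rng: np.random.Generator):
        self.conv = nn.Conv2d(2, 1, 1, rng)

    def attention_map(self, x: Tensor) -> Tensor:
        cap = x.mean(axis=1, keepdims=True)
        cmp_ = x.max(axis=1, keepdims=True)
        f_prime = nn.concat([cap, cmp_], axis=1).relu()
        return self.conv(f_prime).sigmoid()  # (N, 1, H, W) in (0, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention_map(x)


class ChannelAttentionBlock(nn.Module):
    """Channel gating: GMP -> 1x1 conv to C_hat + ReLU -> 1x1 conv to C
    + sigmoid -> channelwise multiply.  C_hat = max(1, round(C / 8))."""

    def __init__(self, c: int, reduction: int, rng: np.random.Generator):
        self.c_hat = max(1, round(c / reduction))
        self.fc1 = nn.Linear(c, self.c_hat, rng)
        self.fc2 = nn.Linear(self.c_hat, c, rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        pooled = x.reshape(n, c, -1).max(axis=2)  # GMP: (N, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.channel_weights(x).reshape(n, c, 1, 1)


class AggregateBlock(nn.Module):
    """Combine the self- and spatial-attention maps.

    ``"add"`` (default) is elementwise addition; ``"concat"``
    concatenates and remaps with a 1x1 convolution back to C channels.
    """

    def __init__(self, mode: str, c: int, rng: np.random.Generator):
        if mode not in ("add", "concat"):
            raise ValueError("aggregation mode must be 'add' or 'concat'")
        self.mode = mode
        self.conv = nn.Conv2d(2 * c, c, 1, rng) if mode == "concat" else None

    def forward(self, a: Tensor, b: Tensor) -> Tensor:
        if a.shape != b.shape:
            raise ValueError("aggregation inputs must have identical shapes")
        if self.mode == "add":
            return a + b
        return self.conv(nn.concat([a, b], axis=1))


# ---------------------------------------------------------------------------
# full extractor
# ---------------------------------------------------------------------------

class FeatureExtractor(nn.Module):
    """ROI -> feature vector: stem -> dense blocks + transitions ->
    multiscale -> (self-attention || spatial attention) -> aggregate ->
    channel attention -> global average pool."""

    def __init__(self, config: FeatureNetConfig | None = None):
        config = config or FeatureNetConfig()
        rng = np.random.default_rng(config.seed)
        self.config = config
        d = config.dense
        self.stem = nn.Conv2d(1, config.stem_channels, 3, rng)

        self.dense_blocks: list[nn.Module] = []
        self.transitions: list[nn.Module] = []
        c = config.stem_channels
        for _ in range(d.blocks):
            block_cfg = DenseBlockConfig(
                stages=d.stages, growth_rate=d.growth_rate,
                initial_channels=c, blocks=1,
            )
            self.dense_blocks.append(DenseBlock(block_cfg, rng))
            c = block_cfg.output_channels
            self.transitions.append(Transition(c, c, rng))

        self.multiscale = MultiScaleBlock(c, config.branch_widths, rng)
        c = sum(config.branch_widths)
        self.out_channels = c
        self.self_attn = SelfAttentionBlock(c, config.attention, rng)
        self.spatial_attn = SpatialAttentionBlock(rng)
        self.aggregate = AggregateBlock(config.aggregation, c, rng)
        self.channel_attn = ChannelAttentionBlock(
            c, config.attention.channel_reduction, rng
        )
        self.head = nn.Linear(c, config.n_classes, rng)
        self._rng = rng

    def feature_map(self, x: Tensor) -> Tensor:
        x = nn.max_pool2d(self.stem(x).relu(), 2)
        for block, trans in zip(self.dense_blocks, self.transitions):
            x = trans(block(x))
        x = self.multiscale(x)
        f_sab = self.self_attn(x)
        f_sb = self.spatial_attn(x)
        agg = self.aggregate(f_sab, f_sb)
        return self.channel_attn(agg)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N, C_final) pooled feature vectors."""
        return self.feature_map(x).mean(axis=(2, 3))

    def logits(self, x: Tensor) -> Tensor:
        feats = self.forward(x)
        feats = nn.dropout(feats, self.config.dropout, self._rng, self.training)
        return self.head(feats)


# ---------------------------------------------------------------------------
# functional op surface (numpy H x W x C in / out)
# ---------------------------------------------------------------------------

def _to_nchw(hwc: np.ndarray) -> Tensor:
    arr = np.asarray(hwc, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected an H x W x C array")
    return Tensor(arr.transpose(2, 0, 1)[None])


def _to_hwc(t: Tensor) -> np.ndarray:
    return t.data[0].transpose(1, 2, 0)


def dense_block(
    input_map: np.ndarray,
    config: DenseBlockConfig,
    module: DenseBlock | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Run one dense block on an H x W x C map (C must equal g0);
    output has g0 + N*g channels at unchanged spatial size."""
    if input_map.shape[2] != config.initial_channels:
        raise ValueError("input channels must equal initial_channels (g0)")
    module = module or DenseBlock(config, np.random.default_rng(seed))
    return _to_hwc(module(_to_nchw(input_map)))


def transition(
    input_map: np.ndarray,
    out_channels: int | None = None,
    module: Transition | None = None,
    seed: int = 0,
) -> np.ndarray:
    """1x1 conv + 2x2 average pool; rejects odd spatial dimensions."""
    h, w, c = input_map.shape
    if h % 2 or w % 2:
        raise ValueError(f"transition requires even spatial dims, got {h}x{w}")
    module = module or Transition(c, out_channels, np.random.default_rng(seed))
    return _to_hwc(module(_to_nchw(input_map)))


def multiscale_extract(
    input_map: np.ndarray,
    branch_widths: tuple[int, int, int, int] = (8, 8, 8, 8),
    module: MultiScaleBlock | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Four-branch multiscale extraction; output channels = sum(widths)."""
    module = module or MultiScaleBlock(
        input_map.shape[2], branch_widths, np.random.default_rng(seed)
    )
    return _to_hwc(module(_to_nchw(input_map)))


def self_attention(
    F: np.ndarray,
    cfg: AttentionConfig | None = None,
    module: SelfAttentionBlock | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Multi-head self-attention over spatial positions of H x W x D."""
    cfg = cfg or AttentionConfig()
    module = module or SelfAttentionBlock(
        F.shape[2], cfg, np.random.default_rng(seed)
    )
    return _to_hwc(module(_to_nchw(F)))


def spatial_attention(
    F: np.ndarray,
    module: SpatialAttentionBlock | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Spatial gating of H x W x C by the pooled-and-convolved map."""
    module = module or SpatialAttentionBlock(np.random.default_rng(seed))
    return _to_hwc(module(_to_nchw(F)))


def aggregate_attention(f_sab: np.ndarray, f_sb: np.ndarray) -> np.ndarray:
    """Elementwise addition of two identically shaped maps."""
    f_sab = np.asarray(f_sab, dtype=float)
    f_sb = np.asarray(f_sb, dtype=float)
    if f_sab.shape != f_sb.shape:
        raise ValueError("aggregation inputs must have identical shapes")
    return f_sab + f_sb


def channel_attention(
    F_agg: np.ndarray,
    cfg: AttentionConfig | None = None,
    module: ChannelAttentionBlock | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Channel gating of H x W x C via global max pooling + bottleneck."""
    cfg = cfg or AttentionConfig()
    module = module or ChannelAttentionBlock(
        F_agg.shape[2], cfg.channel_reduction, np.random.default_rng(seed)
    )
    return _to_hwc(module(_to_nchw(F_agg)))


# ---------------------------------------------------------------------------
# extraction + representation learning
# ---------------------------------------------------------------------------

def extract_feature_vector(
    roi: LabeledImage | np.ndarray, extractor: FeatureExtractor
) -> np.ndarray:
    """Pooled feature vector (length C_final) of one ROI."""
    pixels = roi.pixels if isinstance(roi, LabeledImage) else np.asarray(roi)
    extractor.eval()
    batch = pixels[None, None].astype(extractor.dtype)
    return extractor(Tensor(batch)).data[0]


def extract_features(
    rois: list[LabeledImage], extractor: FeatureExtractor, batch: int = 16
) -> np.ndarray:
    """Feature matrix (n_rois, C_final); stateless across samples."""
    extractor.eval()
    stacks = np.stack([r.pixels[None] for r in rois]).astype(extractor.dtype)
    out = []
    for start in range(0, len(stacks), batch):
        out.append(extractor(Tensor(stacks[start : start + batch])).data)
    return np.concatenate(out, axis=0)


def train_feature_extractor(
    rois: list[LabeledImage],
    class_names: list[str] | tuple[str, ...],
    config: FeatureNetConfig | None = None,
) -> tuple[FeatureExtractor, list[dict]]:
    """Representation learning: train trunk + classification head with
    softmax cross-entropy, then keep only the trunk.

    The head exists solely to shape the pooled features; callers should
    train on a phantom sample disjoint from the evaluation set.
    """
    config = config or FeatureNetConfig()
    label_to_idx = {name: i for i, name in enumerate(class_names)}
    labels = np.array([label_to_idx[r.label] for r in rois])
    images = np.stack([r.pixels[None] for r in rois]).astype(np.float32)

    model = FeatureExtractor(config).astype(np.float32)
    opt = nn.Adagrad(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    history: list[dict] = []
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(images))
        losses, correct = [], 0
        for start in range(0, len(images), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.logits(Tensor(images[idx]))
            loss = nn.cross_entropy_logits(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "accuracy": correct / len(images),
            }
        )
    model.eval()
    return model, history
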