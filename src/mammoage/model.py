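"""Multi-view breast-age network and its loss terms.

Architecture
------------
Four mammographic views (R-CC, R-MLO, L-CC, L-MLO) pass through one
weight-shared convolutional backbone.  The pre-pooling token grids of the
four views ("local features") are fused by an instance-bag transformer:
per view, multi-head self-attention over the view's own tokens and
cross-attention against the concatenated token sequence of all four views
("global features"); the local, self- and cross-attention features are
concatenated channel-wise and projected back to the local size by
feed-forward layers.  The self- and cross-attention share projection
weights — the two paths differ only in the key/value source.

Each fused view branch is pooled and mapped to a probabilistic ordinal
embedding: a diagonal Gaussian N(mu, sigma^2) in a small latent space.
During training a reparameterized sample z feeds a 100-way softmax over
integer age bins 1..100; at inference z = mu, making the forward pass
deterministic.  A density head consumes the pooled concatenation of the
four fused view vectors for the auxiliary 4-class ACR task.

Losses: per-bin cross-entropy at the true age, mean-variance loss on the
age distribution, a probabilistic-ordinal-embedding composite (triplet
hinge on embedding distances respecting age order + unit-Gaussian KL), and
density cross-entropy; the total is a configurable weighted sum.

Backbones
---------
The registry ids mirror the standard ImageNet family names but resolve to
compact CPU-scale renditions of each architectural family (plain stack,
residual, bottleneck-residual, depthwise/pointwise, dense connectivity,
inverted bottleneck), all with total stride 32 and 32 output channels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, conv2d, depthwise_conv2d

__all__ = [
    "ModelConfig", "MammoAgeModel", "BACKBONES", "FEATURE_CHANNELS",
    "ViewFeatureSet", "LossBundle", "MultiHeadAttention",
    "expected_age", "mean_variance_loss", "ce_age_loss", "poe_loss",
    "density_ce_loss", "total_loss", "compute_losses",
    "DENSITY_CLASSES", "save_checkpoint", "load_checkpoint",
]

EPS = 1e-12  # floor inside logarithms
FEATURE_CHANNELS = 32
AGE_BINS = np.arange(1, 101, dtype=np.float64)
DENSITY_CLASSES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# Parameter plumbing
# ---------------------------------------------------------------------------

class Module:
    """Lightweight parameter container with recursive collection."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor) and attr.requires_grad:
                out[key] = attr
            elif isinstance(attr, Module):
                out.update(attr.named_parameters(f"{key}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (cin + cout))
        self.w = Tensor(rng.uniform(-bound, bound, (cin, cout)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, scale, (cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.pad = stride, k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class DepthwiseConv(Module):
    def __init__(self, c: int, rng: np.random.Generator, k: int = 3, stride: int = 1):
        scale = np.sqrt(2.0 / (k * k))
        self.w = Tensor(rng.normal(0.0, scale, (c, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c), requires_grad=True)
        self.stride, self.pad = stride, k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Backbones — compact renditions of the standard families, total stride 32
# ---------------------------------------------------------------------------

class PlainBackbone(Module):
    """tiny_cnn: five stride-2 3x3 convolutions, 1->8->16->16->32->32."""

    def __init__(self, rng):
        chans = [1, 8, 16, 16, 32, FEATURE_CHANNELS]
        self.convs = [Conv(chans[i], chans[i + 1], rng, stride=2) for i in range(5)]

    def __call__(self, x: Tensor) -> Tensor:
        for c in self.convs:
            x = c(x).relu()
        return x


class _ResBlock(Module):
    def __init__(self, cin, cout, rng, stride):
        self.c1 = Conv(cin, cout, rng, stride=stride)
        self.c2 = Conv(cout, cout, rng)
        self.proj = Conv(cin, cout, rng, k=1, stride=stride) if (stride != 1 or cin != cout) else None

    def __call__(self, x):
        h = self.c2(self.c1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class ResidualBackbone(Module):
    """resnet18 rendition: stem + four residual stages."""

    def __init__(self, rng):
        self.stem = Conv(1, 8, rng, stride=2)
        chans = [8, 16, 16, 32, FEATURE_CHANNELS]
        self.blocks = [_ResBlock(chans[i], chans[i + 1], rng, stride=2) for i in range(4)]

    def __call__(self, x):
        x = self.stem(x).relu()
        for b in self.blocks:
            x = b(x)
        return x


class _Bottleneck(Module):
    def __init__(self, cin, cout, rng, stride):
        mid = max(4, cout // 4)
        self.c1 = Conv(cin, mid, rng, k=1)
        self.c2 = Conv(mid, mid, rng, stride=stride)
        self.c3 = Conv(mid, cout, rng, k=1)
        self.proj = Conv(cin, cout, rng, k=1, stride=stride) if (stride != 1 or cin != cout) else None

    def __call__(self, x):
        h = self.c3(self.c2(self.c1(x).relu()).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class BottleneckBackbone(Module):
    """resnet50 rendition: bottleneck residual stages."""

    def __init__(self, rng):
        self.stem = Conv(1, 8, rng, stride=2)
        chans = [8, 16, 32, 32, FEATURE_CHANNELS]
        self.blocks = [_Bottleneck(chans[i], chans[i + 1], rng, stride=2) for i in range(4)]

    def __call__(self, x):
        x = self.stem(x).relu()
        for b in self.blocks:
            x = b(x)
        return x


class _DwBlock(Module):
    def __init__(self, cin, cout, rng, stride):
        self.dw = DepthwiseConv(cin, rng, stride=stride)
        self.pw1 = Conv(cin, 2 * cout, rng, k=1)
        self.pw2 = Conv(2 * cout, cout, rng, k=1)

    def __call__(self, x):
        return self.pw2(self.pw1(self.dw(x)).relu())


class DepthwiseBackbone(Module):
    """convnext_tiny rendition: depthwise spatial mixing + pointwise MLP."""

    def __init__(self, rng):
        self.stem = Conv(1, 8, rng, stride=2)
        chans = [8, 16, 16, 32, FEATURE_CHANNELS]
        self.blocks = [_DwBlock(chans[i], chans[i + 1], rng, stride=2) for i in range(4)]

    def __call__(self, x):
        x = self.stem(x).relu()
        for b in self.blocks:
            x = b(x).relu()
        return x


class _DenseStage(Module):
    def __init__(self, cin, growth, rng, n_layers=2):
        self.layers = [Conv(cin + i * growth, growth, rng) for i in range(n_layers)]

    def __call__(self, x):
        for layer in self.layers:
            x = concat([x, layer(x).relu()], axis=1)
        return x


class DenseBackbone(Module):
    """densenet121 rendition: dense concatenation stages + strided transitions."""

    def __init__(self, rng):
        self.stem = Conv(1, 8, rng, stride=2)
        growth = 8
        self.stages, self.transitions = [], []
        cin = 8
        outs = [12, 16, 24, FEATURE_CHANNELS]
        for out in outs:
            self.stages.append(_DenseStage(cin, growth, rng))
            self.transitions.append(Conv(cin + 2 * growth, out, rng, k=1, stride=2))
            cin = out

    def __call__(self, x):
        x = self.stem(x).relu()
        for stage, trans in zip(self.stages, self.transitions):
            x = trans(stage(x)).relu()
        return x


class _MBConv(Module):
    def __init__(self, cin, cout, rng, stride, expand=2):
        mid = cin * expand
        self.pw1 = Conv(cin, mid, rng, k=1)
        self.dw = DepthwiseConv(mid, rng, stride=stride)
        self.pw2 = Conv(mid, cout, rng, k=1)

    def __call__(self, x):
        return self.pw2(self.dw(self.pw1(x).relu()).relu())


class InvertedBottleneckBackbone(Module):
    """efficientnet_b0 rendition: inverted-bottleneck (MBConv) stages."""

    def __init__(self, rng):
        self.stem = Conv(1, 8, rng, stride=2)
        chans = [8, 16, 16, 32, FEATURE_CHANNELS]
        self.blocks = [_MBConv(chans[i], chans[i + 1], rng, stride=2) for i in range(4)]

    def __call__(self, x):
        x = self.stem(x).relu()
        for b in self.blocks:
            x = b(x).relu()
        return x


BACKBONES = {
    "tiny_cnn": PlainBackbone,
    "resnet18": ResidualBackbone,
    "resnet50": BottleneckBackbone,
    "convnext_tiny": DepthwiseBackbone,
    "densenet121": DenseBackbone,
    "efficientnet_b0": InvertedBottleneckBackbone,
}

#: total spatial downsampling of every registered backbone
BACKBONE_STRIDE = 32


# ---------------------------------------------------------------------------
# Instance-bag transformer
# ---------------------------------------------------------------------------

@dataclass
class ViewFeatureSet:
    """Per-view token grids from the shared backbone.

    ``tokens`` has shape (batch, 4 views, tokens, channels); ``grid`` is the
    (rows, cols) spatial layout the tokens were flattened from.
    """

    tokens: Tensor
    grid: tuple[int, int]

    def __post_init__(self):
        if self.tokens.shape[1] != 4:
            raise ValueError("a view feature set holds exactly four views")


class MultiHeadAttention(Module):
    """Multi-head attention with h parallel channel splits.

    One module serves both the self- and cross-attention paths: the query
    always comes from the local tokens, while key/value come from either
    the local (self) or the global (cross) token sequence.
    """

    def __init__(self, channels: int, heads: int, rng: np.random.Generator):
        if channels % heads:
            raise ValueError(f"channels ({channels}) must divide by heads ({heads})")
        self.heads = heads
        self.wq = Linear(channels, channels, rng)
        self.wk = Linear(channels, channels, rng)
        self.wv = Linear(channels, channels, rng)
        self.wo = Linear(channels, channels, rng)

    def __call__(self, query: Tensor, keyvalue: Tensor) -> Tensor:
        N, Tq, C = query.shape
        Tk = keyvalue.shape[1]
        h, dh = self.heads, C // self.heads
        q = self.wq(query).reshape(N, Tq, h, dh).transpose(0, 2, 1, 3)
        k = self.wk(keyvalue).reshape(N, Tk, h, dh).transpose(0, 2, 1, 3)
        v = self.wv(keyvalue).reshape(N, Tk, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(N, Tq, C)
        return self.wo(out)


class InstanceBagBlock(Module):
    def __init__(self, channels: int, heads: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(channels, heads, rng)
        self.ff1 = Linear(3 * channels, channels, rng)
        self.ff2 = Linear(channels, channels, rng)

    def __call__(self, tokens: Tensor) -> Tensor:
        B, V, T, C = tokens.shape
        local = tokens.reshape(B * V, T, C)
        global_seq = tokens.reshape(B, V * T, C)
        rep = np.repeat(np.arange(B), V)
        global_rep = global_seq[rep]           # (B*V, V*T, C)
        self_out = self.attn(local, local)
        cross_out = self.attn(local, global_rep)
        fused = concat([local, self_out, cross_out], axis=-1)
        out = self.ff2(self.ff1(fused).relu())
        return out.reshape(B, V, T, C)


# ---------------------------------------------------------------------------
# The full model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    backbone_id: str = "tiny_cnn"
    heads: int = 8
    n_repeats: int = 1
    embed_dim: int = 16
    margin: float = 0.1
    dropout: float = 0.5
    n_age_bins: int = 100
    view_embedding: bool = False
    density_into_embedding: bool = False
    loss_weights: dict[str, float] = field(default_factory=lambda: {
        "ce_age": 1.0, "mean": 1.0, "variance": 1.0,
        "poe_ordinal": 1.0, "poe_kl": 1.0, "density_ce": 1.0})


class MammoAgeModel(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.backbone_id not in BACKBONES:
            raise ValueError(f"unknown backbone {config.backbone_id!r}; "
                             f"known: {sorted(BACKBONES)}")
        self.config = config
        rng = np.random.default_rng(seed)
        C = FEATURE_CHANNELS
        self.backbone = BACKBONES[config.backbone_id](rng)
        self.blocks = [InstanceBagBlock(C, config.heads, rng)
                       for _ in range(config.n_repeats)]
        if config.view_embedding:
            self.view_emb = Tensor(rng.normal(0, 0.02, (4, C)), requires_grad=True)
        else:
            self.view_emb = None
        head_in = C + (len(DENSITY_CLASSES) if config.density_into_embedding else 0)
        self.mu_layer = Linear(head_in, config.embed_dim, rng)
        self.logvar_layer = Linear(head_in, config.embed_dim, rng)
        # start the ordinal embedding near-deterministic (sigma^2 ~ 0.14):
        # unit variance at init drowns the age signal in sampling noise
        self.logvar_layer.b.data[:] = -2.0
        self.cls_layer = Linear(config.embed_dim, config.n_age_bins, rng)
        self.density_layer = Linear(4 * C, len(DENSITY_CLASSES), rng)

    # -- spec operations -------------------------------------------------
    def forward_views(self, images: np.ndarray) -> ViewFeatureSet:
        """Run the weight-shared backbone over the four views.

        ``images``: (batch, 4, H, W) preprocessed views.
        Returns per-view token grids flattened to (batch, 4, tokens, C).
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[1] != 4:
            raise ValueError("expected images of shape (batch, 4, H, W)")
        B, V, H, W = images.shape
        x = Tensor(images.reshape(B * V, 1, H, W))
        feat = self.backbone(x)                       # (B*V, C, Hg, Wg)
        _, C, Hg, Wg = feat.shape
        if Hg * Wg == 0:
            raise ValueError(f"input {H}x{W} too small for stride-{BACKBONE_STRIDE} backbone")
        tokens = feat.reshape(B * V, C, Hg * Wg).transpose(0, 2, 1)
        return ViewFeatureSet(tokens=tokens.reshape(B, V, Hg * Wg, C), grid=(Hg, Wg))

    def instance_bag_fuse(self, feats: ViewFeatureSet) -> ViewFeatureSet:
        """Self/cross attention fusion; shape-preserving."""
        tokens = feats.tokens
        if self.view_emb is not None:
            B, V, T, C = tokens.shape
            tokens = tokens + self.view_emb.reshape(1, V, 1, C)
        for block in self.blocks:
            tokens = block(tokens)
        return ViewFeatureSet(tokens=tokens, grid=feats.grid)

    def age_head(self, fused: ViewFeatureSet, training: bool = False,
                 rng: np.random.Generator | None = None,
                 density_probs: Tensor | None = None
                 ) -> tuple[Tensor, Tensor, Tensor]:
        """Per-view age distribution and ordinal embedding.

        Training samples z ~ N(mu, sigma^2) (reparameterized); inference
        uses z = mu, so the eval path is deterministic.
        Returns (age_probs (B,4,K), mu (B,4,E), sigma2 (B,4,E)).
        """
        B, V, T, C = fused.tokens.shape
        pooled = fused.tokens.mean(axis=2).reshape(B * V, C)
        pooled = _dropout(pooled, self.config.dropout if training else 0.0, rng)
        if self.config.density_into_embedding:
            if density_probs is None:
                raise ValueError("density_into_embedding requires density_probs")
            rep = np.repeat(np.arange(B), V)
            pooled = concat([pooled, density_probs[rep]], axis=-1)
        mu = self.mu_layer(pooled)
        sigma2 = self.logvar_layer(pooled).exp()
        if training and rng is not None:
            z = mu + sigma2.sqrt() * Tensor(rng.standard_normal(mu.shape))
        else:
            z = mu
        probs = self.cls_layer(z).softmax(axis=-1)
        E, K = self.config.embed_dim, self.config.n_age_bins
        return (probs.reshape(B, V, K), mu.reshape(B, V, E), sigma2.reshape(B, V, E))

    def density_head(self, fused: ViewFeatureSet, training: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
        """4-class density probabilities from the pooled concatenation of
        the four fused view vectors."""
        B, V, T, C = fused.tokens.shape
        pooled = fused.tokens.mean(axis=2).reshape(B, V * C)
        pooled = _dropout(pooled, self.config.dropout if training else 0.0, rng)
        return self.density_layer(pooled).softmax(axis=-1)

    def forward(self, images: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        feats = self.forward_views(images)
        fused = self.instance_bag_fuse(feats)
        density_probs = self.density_head(fused, training, rng)
        dp = density_probs if self.config.density_into_embedding else None
        age_probs, mu, sigma2 = self.age_head(fused, training, rng, dp)
        view_ages = expected_age(age_probs.data)           # (B, 4)
        return {
            "age_probs": age_probs, "mu": mu, "sigma2": sigma2,
            "density_probs": density_probs,
            "view_ages": view_ages,
            "exam_age": view_ages.mean(axis=1),
        }


# ---------------------------------------------------------------------------
# Losses (Tensor-aware; plain arrays pass through unchanged maths)
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def expected_age(dist: np.ndarray) -> np.ndarray:
    """Mean of the age distribution: sum_k k * p_k over bins 1..K."""
    dist = np.asarray(dist, dtype=np.float64)
    _check_dist(dist)
    bins = np.arange(1, dist.shape[-1] + 1, dtype=np.float64)
    return dist @ bins


def _check_dist(dist: np.ndarray) -> None:
    if np.any(dist < -1e-9) or np.any(np.abs(dist.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("age distribution must be nonnegative and sum to 1")


def mean_variance_loss(dist, true_age) -> tuple:
    """Mean loss 0.5*(m - y)^2 and variance loss sum_k p_k (k - m)^2.

    Accepts a single distribution or a batch (..., K); Tensor inputs yield
    differentiable Tensor outputs, arrays yield floats/arrays.
    """
    is_tensor = isinstance(dist, Tensor)
    d = dist if is_tensor else Tensor(np.asarray(dist, dtype=np.float64))
    _check_dist(d.data)
    K = d.shape[-1]
    bins = Tensor(np.arange(1, K + 1, dtype=np.float64))
    y = _as_tensor(true_age)
    m = (d * bins).sum(axis=-1)
    mean_loss = (m - y) ** 2.0 * 0.5
    m_col = m.reshape(m.shape + (1,))
    var_loss = (d * (bins - m_col) ** 2.0).sum(axis=-1)
    if d.data.ndim == 1:
        var_loss = var_loss.reshape(())
        mean_loss = mean_loss.reshape(())
    if is_tensor:
        return mean_loss, var_loss
    return (float(mean_loss.data), float(var_loss.data)) if mean_loss.data.ndim == 0 \
        else (mean_loss.data, var_loss.data)


def ce_age_loss(dist, true_age) -> float | Tensor:
    """Cross-entropy -log p_y at the integer true-age bin (1-based),
    with an epsilon floor inside the log."""
    is_tensor = isinstance(dist, Tensor)
    d = dist if is_tensor else Tensor(np.asarray(dist, dtype=np.float64))
    _check_dist(d.data)
    ages = np.atleast_1d(np.asarray(true_age))
    if np.any((ages < 1) | (ages > d.shape[-1])):
        raise ValueError("true age outside the bin range")
    idx = np.round(ages).astype(int) - 1
    if d.data.ndim == 1:
        p = d[int(idx[0])]
    else:
        p = d[np.arange(d.shape[0]), idx]
    loss = -((p + EPS).log())
    if is_tensor:
        return loss
    return float(loss.data) if loss.data.ndim == 0 else loss.data


def poe_loss(mu, sigma2, ages: np.ndarray, margin: float = 0.1,
             rng: np.random.Generator | None = None,
             max_triplets: int = 256) -> tuple:
    """Probabilistic ordinal embedding composite.

    ``ordinal``: mean hinge(margin + d(mu_i, mu_j) - d(mu_i, mu_k)) over
    triplets with |age_i - age_j| < |age_i - age_k| (zero when the batch
    has fewer than 3 samples or no valid triplet).
    ``kl``: mean per-dimension KL(N(mu, sigma^2) || N(0, 1)).
    """
    is_tensor = isinstance(mu, Tensor)
    m = mu if is_tensor else Tensor(np.asarray(mu, dtype=np.float64))
    s2 = sigma2 if is_tensor else Tensor(np.asarray(sigma2, dtype=np.float64))
    if np.any(s2.data <= 0):
        raise ValueError("sigma^2 must be strictly positive")
    ages = np.asarray(ages, dtype=np.float64)
    B = m.shape[0]

    kl = ((s2 + m * m - 1.0 - (s2 + EPS).log()) * 0.5).mean()

    triplets = _ordinal_triplets(ages, rng, max_triplets)
    if len(triplets) == 0:
        ordinal = Tensor(np.array(0.0))
    else:
        tri = np.asarray(triplets)
        di = m[tri[:, 0]]
        dj = ((di - m[tri[:, 1]]) ** 2.0).sum(axis=-1)
        dk = ((di - m[tri[:, 2]]) ** 2.0).sum(axis=-1)
        hinge = ((dj + EPS) ** 0.5 - (dk + EPS) ** 0.5 + margin).relu()
        ordinal = hinge.mean()
    if is_tensor:
        return ordinal, kl
    return float(ordinal.data), float(kl.data)


def _ordinal_triplets(ages: np.ndarray, rng: np.random.Generator | None,
                      max_triplets: int) -> list[tuple[int, int, int]]:
    B = len(ages)
    if B < 3:
        return []
    valid = [(i, j, k)
             for i in range(B) for j in range(B) for k in range(B)
             if i != j and i != k and j != k
             and abs(ages[i] - ages[j]) < abs(ages[i] - ages[k])]
    if rng is not None and len(valid) > max_triplets:
        pick = rng.choice(len(valid), size=max_triplets, replace=False)
        valid = [valid[i] for i in pick]
    return valid


def density_ce_loss(density_probs, labels) -> tuple:
    """Masked 4-class cross-entropy.

    ``labels``: sequence of category names; 'unknown' rows contribute zero
    and are excluded from the mean's denominator.  Returns (loss, n_known);
    a batch of all-unknown labels yields (0, 0).
    """
    is_tensor = isinstance(density_probs, Tensor)
    p = density_probs if is_tensor else Tensor(np.asarray(density_probs, dtype=np.float64))
    if p.data.ndim == 1:
        p = p.reshape(1, -1)
        labels = [labels] if isinstance(labels, str) else labels
    if np.any(np.abs(p.data.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("density probabilities must sum to 1")
    idx = []
    rows = []
    for i, lab in enumerate(labels):
        if lab == "unknown":
            continue
        if lab not in DENSITY_CLASSES:
            raise ValueError(f"unknown density label {lab!r}")
        rows.append(i)
        idx.append(DENSITY_CLASSES.index(lab))
    if not rows:
        zero = Tensor(np.array(0.0))
        return (zero, 0) if is_tensor else (0.0, 0)
    sel = p[np.asarray(rows), np.asarray(idx)]
    loss = -(((sel + EPS).log()).mean())
    return (loss, len(rows)) if is_tensor else (float(loss.data), len(rows))


@dataclass
class LossBundle:
    """All loss terms, their weights, and the weighted total."""

    terms: dict[str, float]
    weights: dict[str, float]
    total: float
    total_tensor: Tensor | None = None

    @classmethod
    def build(cls, terms: dict, weights: dict[str, float]) -> "LossBundle":
        for name, w in weights.items():
            if w < 0:
                raise ValueError(f"negative loss weight for {name!r}")
        tensor_terms = {k: _as_tensor(v) for k, v in terms.items()}
        full_weights = {k: float(weights.get(k, 1.0)) for k in tensor_terms}
        total = Tensor(np.array(0.0))
        for name, t in tensor_terms.items():
            total = total + t * full_weights[name]
        return cls(terms={k: float(t.data) for k, t in tensor_terms.items()},
                   weights=full_weights, total=float(total.data),
                   total_tensor=total)


def total_loss(terms: dict, weights: dict[str, float] | None = None) -> LossBundle:
    """Weighted sum of loss terms (default weight 1 per term)."""
    if weights is None:
        weights = {k: 1.0 for k in terms}
    return LossBundle.build(terms, weights)


def compute_losses(outputs: dict, ages: np.ndarray, density_labels,
                   config: ModelConfig, rng: np.random.Generator | None = None
                   ) -> LossBundle:
    """All training losses for one batch; per-view terms are averaged
    across views and samples."""
    B, V, K = outputs["age_probs"].shape
    probs = outputs["age_probs"].reshape(B * V, K)
    ages = np.asarray(ages, dtype=np.float64)
    ages_rep = np.repeat(ages, V)
    ce = ce_age_loss(probs, ages_rep).mean()
    mean_l, var_l = mean_variance_loss(probs, ages_rep)
    mean_l, var_l = mean_l.mean(), var_l.mean()
    E = config.embed_dim
    ordinal, kl = poe_loss(outputs["mu"].reshape(B * V, E),
                           outputs["sigma2"].reshape(B * V, E),
                           ages_rep, margin=config.margin, rng=rng)
    dens, _ = density_ce_loss(outputs["density_probs"], list(density_labels))
    return LossBundle.build(
        {"ce_age": ce, "mean": mean_l, "variance": var_l,
         "poe_ordinal": ordinal, "poe_kl": kl, "density_ce": dens},
        config.loss_weights)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: MammoAgeModel, path: str, seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Serialize weights (.npz) plus a JSON sidecar with the config."""
    params = model.named_parameters()
    np.savez(path, **{k: v.data for k, v in params.items()})
    sidecar = {
        "backbone_id": model.config.backbone_id,
        "config": {k: (v if not isinstance(v, dict) else dict(v))
                   for k, v in vars(model.config).items()},
        "seed": seed,
    }
    if extra:
        sidecar.update(extra)
    with open(os.fspath(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str) -> MammoAgeModel:
    with open(os.fspath(path) + ".json") as fh:
        sidecar = json.load(fh)
    cfg = ModelConfig(**sidecar["config"])
    model = MammoAgeModel(cfg, seed=sidecar.get("seed") or 0)
    data = np.load(path)
    params = model.named_parameters()
    if set(data.files) != set(params):
        raise ValueError("checkpoint does not match the model architecture")
    for k, p in params.items():
        if p.data.shape != data[k].shape:
            raise ValueError(f"shape mismatch for parameter {k}")
        p.data = data[k].astype(np.float64)
    return model
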