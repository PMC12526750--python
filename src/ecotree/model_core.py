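"""Knowledge-augmented attention layers and a miniature windowed backbone.

The layers here inject ecological knowledge into visual features:

* :func:`kv_guided_attention` — scaled dot-product attention of a visual
  query over knowledge-graph entity embeddings projected to keys/values;
* :func:`hierarchical_fusion`  — the same attention applied per taxonomy
  level with a residual connection, so each backbone stage attends to the
  knowledge view of its level (coarse taxonomy at coarse resolution);
* :func:`query_offset`         — a learnable, bounded shift of the query
  toward the matched entity's embedding (``q + mu * tanh(W K + b)``);
* :func:`cooccurrence_bias`    — an additive pre-softmax bias
  ``eta * log(1 + w)`` from co-occurrence prior weights, which preserves the
  softmax normalization and vanishes at ``eta = 0``;
* :func:`conditional_fuse`     — re-attention of a region feature over the
  KG neighborhood of its decoded species, conditioning vision on the
  predicted label path.

The :class:`TinyBackbone` is a reduced-width, 4-stage windowed self-attention
network whose stage resolutions follow input/4, /8, /16, /32 (so 56/28/14/7
at a 224 input); weights are seeded random and frozen, making it a
deterministic feature extractor at desk scale.  A full-width preset
(96 base channels, heads 3/6/12/24) is available via configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .knowledge_graph import KnowledgeEmbedding, KnowledgeGraph
from .taxonomy import LabelPath

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class AttentionConfig:
    """Geometry of the backbone and knowledge-attention layers."""

    d_model: int = 128
    d_k: int = 32
    n_heads: int = 4
    window: int = 7
    mu_init: float = 0.0
    eta: float = 1.0
    base_channels: int = 16
    stage_heads: tuple[int, ...] = (1, 2, 4, 8)
    blocks_per_stage: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ModelError("window must be >= 1")
        if self.eta < 0:
            raise ModelError("eta must be >= 0")

    @classmethod
    def swin_tiny(cls) -> "AttentionConfig":
        """Full-width preset: 96 base channels, heads 3/6/12/24, window 7."""
        return cls(base_channels=96, stage_heads=(3, 6, 12, 24), d_model=768)


@dataclass(frozen=True)
class RegionFeature:
    """A pooled feature vector for one detected region."""

    vector: np.ndarray
    box: tuple[float, float, float, float]
    image_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ModelError("region feature contains non-finite entries")


class CoOccurrencePrior:
    """Nonnegative pairwise weights between entities, from KG confidences."""

    def __init__(self, weights: Mapping[tuple[str, str], float]):
        for pair, w in weights.items():
            if w < 0:
                raise ModelError(f"negative prior weight for {pair}")
        self._w = dict(weights)

    @classmethod
    def from_graph(
        cls, graph: KnowledgeGraph, relations: Sequence[str] = ("predation", "cohabitation", "competition")
    ) -> "CoOccurrencePrior":
        """Symmetric max-confidence weight over the ecological relations."""
        weights: dict[tuple[str, str], float] = {}
        for (h, r, t), conf in graph.triples.items():
            if r not in relations:
                continue
            for key in ((h, t), (t, h)):
                weights[key] = max(conf, weights.get(key, 0.0))
        return cls(weights)

    def weight(self, a: Optional[str], b: Optional[str]) -> float:
        if a is None or b is None:
            return 0.0
        return self._w.get((a, b), 0.0)


# ---------------------------------------------------------------------------
# Attention operations
# ---------------------------------------------------------------------------

def kv_guided_attention(
    q: np.ndarray,
    K_set: np.ndarray,
    W_k: np.ndarray,
    W_v: np.ndarray,
    d: Optional[float] = None,
) -> np.ndarray:
    """Attend a query over knowledge embeddings: ``sum_j softmax(q.k_j/sqrt(d)) v_j``.

    ``K_set`` is (N, d_k); keys and values are ``W_k K_j`` and ``W_v K_j``.
    ``d`` defaults to the key dimension.  Raises on an empty knowledge set —
    the caller must skip fusion rather than attend over nothing.
    """
    K_set = np.atleast_2d(np.asarray(K_set, dtype=np.float64))
    if K_set.shape[0] == 0:
        raise ModelError("empty knowledge set: nothing to attend over")
    keys = K_set @ W_k.T
    values = K_set @ W_v.T
    if d is None:
        d = keys.shape[1]
    logits = (keys @ np.asarray(q, dtype=np.float64)) / np.sqrt(d)
    logits -= logits.max()
    w = np.exp(logits)
    w /= w.sum()
    return w @ values


def hierarchical_fusion(
    x: np.ndarray,
    K_level: Optional[np.ndarray],
    W_q: np.ndarray,
    W_k: np.ndarray,
    W_v: np.ndarray,
) -> np.ndarray:
    """Residual knowledge attention for one level: ``Attn(W_q x, W_k K, W_v K) + x``.

    ``x`` may be a single vector or any (..., d_model) feature array; every
    position attends independently.  With no level embeddings available the
    layer degrades to identity (residual only).
    """
    x = np.asarray(x, dtype=np.float64)
    if K_level is None or np.size(K_level) == 0:
        logger.warning("hierarchical_fusion: missing level embeddings, identity fallback")
        return x.copy()
    flat = x.reshape(-1, x.shape[-1])
    out = np.empty_like(flat)
    for i, xi in enumerate(flat):
        out[i] = kv_guided_attention(W_q @ xi, K_level, W_k, W_v) + xi
    return out.reshape(x.shape)


def query_offset(
    q: np.ndarray,
    K_i: np.ndarray,
    mu: float,
    phi_W: np.ndarray,
    phi_b: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Shift the query toward knowledge: ``q + mu * tanh(W K + b)``.

    The tanh bound keeps every coordinate of the shift within ``|mu|``, so the
    knowledge influence is controllable; ``mu = 0`` is exact identity.
    """
    q = np.asarray(q, dtype=np.float64)
    if mu == 0.0:
        return q.copy()
    z = phi_W @ np.asarray(K_i, dtype=np.float64)
    if phi_b is not None:
        z = z + phi_b
    return q + mu * np.tanh(z)


def cooccurrence_bias(
    logits: np.ndarray,
    prior: CoOccurrencePrior,
    region_entities: Mapping[int, str],
    eta: float,
) -> np.ndarray:
    """Add ``eta * log(1 + w(entity_i, entity_j))`` to region-pair attention logits.

    Regions without an entity mapping contribute zero bias.  The bias is added
    before softmax, so rows still normalize downstream; ``eta = 0`` or an
    all-zero prior leaves the logits unchanged.
    """
    logits = np.asarray(logits, dtype=np.float64)
    n, m = logits.shape
    if n != m:
        raise ModelError("co-occurrence bias expects a square region-pair matrix")
    out = logits.copy()
    for i in range(n):
        ei = region_entities.get(i)
        if ei is None:
            continue
        for j in range(n):
            w = prior.weight(ei, region_entities.get(j))
            if w > 0.0:
                out[i, j] += eta * np.log1p(w)
    return out


@dataclass
class FusionParams:
    """Learnable pieces of the conditional knowledge-fusion path."""

    W_k: np.ndarray
    W_v: np.ndarray
    phi_W: np.ndarray
    phi_b: np.ndarray
    mu: float = 0.0

    @classmethod
    def init(cls, d_model: int, d_k: int, mu: float = 0.0, seed: int = 0) -> "FusionParams":
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(d_k)
        return cls(
            W_k=rng.normal(scale=scale, size=(d_model, d_k)),
            W_v=rng.normal(scale=scale, size=(d_model, d_k)),
            phi_W=rng.normal(scale=scale, size=(d_model, d_k)),
            phi_b=np.zeros(d_model),
            mu=mu,
        )


def conditional_fuse(
    x: RegionFeature,
    path: Optional[LabelPath],
    graph: KnowledgeGraph,
    embedding: KnowledgeEmbedding,
    params: FusionParams,
    taxon_to_entity: Optional[Mapping[str, str]] = None,
) -> np.ndarray:
    """Condition a region feature on its decoded label path via the KG.

    The path's species is mapped to its KG entity; that entity's embedding
    drives a query offset, and the offset query re-attends over the entity's
    KG neighborhood.  Without a path (or without a matching entity) the
    feature passes through unchanged; with an empty neighborhood only the
    query offset applies.
    """
    vec = np.asarray(x.vector, dtype=np.float64)
    if path is None:
        return vec.copy()
    species = path.species
    entity_id = (taxon_to_entity or {}).get(species, species)
    if entity_id not in embedding.entity_vectors:
        logger.warning("conditional_fuse: species %s has no KG entity", species)
        return vec.copy()
    K_i = embedding.entity_vectors[entity_id]
    q = query_offset(vec, K_i, params.mu, params.phi_W, params.phi_b)
    neighbor_ids = [other for (_r, other, _c) in graph.neighbors(entity_id)]
    neighbor_vecs = [
        embedding.entity_vectors[n] for n in neighbor_ids if n in embedding.entity_vectors
    ]
    if not neighbor_vecs:
        return q
    K_nbhd = np.stack(neighbor_vecs)
    # W_k/W_v are (d_model, d_k): keys/values live in the feature space of q
    return q + kv_guided_attention(q, K_nbhd, params.W_k, params.W_v)


# ---------------------------------------------------------------------------
# Tiny windowed-attention backbone
# ---------------------------------------------------------------------------

def _layer_norm(x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def _window_attention(x: np.ndarray, n_heads: int, Wqkv: np.ndarray, Wo: np.ndarray, window: int) -> np.ndarray:
    """Non-overlapping window multi-head self-attention on an (H, W, C) map."""
    H, W, C = x.shape
    win = min(window, H, W)
    pad_h = (-H) % win
    pad_w = (-W) % win
    xp = np.pad(x, ((0, pad_h), (0, pad_w), (0, 0)))
    Hp, Wp, _ = xp.shape
    head_dim = C // n_heads
    out = np.empty_like(xp)
    for r in range(0, Hp, win):
        for c in range(0, Wp, win):
            tokens = xp[r : r + win, c : c + win].reshape(-1, C)
            qkv = tokens @ Wqkv  # (T, 3C)
            q, k, v = np.split(qkv, 3, axis=1)
            merged = np.empty_like(tokens)
            for h in range(n_heads):
                sl = slice(h * head_dim, (h + 1) * head_dim)
                logits = q[:, sl] @ k[:, sl].T / np.sqrt(head_dim)
                logits -= logits.max(axis=1, keepdims=True)
                a = np.exp(logits)
                a /= a.sum(axis=1, keepdims=True)
                merged[:, sl] = a @ v[:, sl]
            out[r : r + win, c : c + win] = (merged @ Wo).reshape(win, win, C)
    return out[:H, :W]


class TinyBackbone:
    """Four-stage windowed-attention feature pyramid with frozen seeded weights.

    Stage s halves the resolution of stage s-1 (input/4 at stage 1) and
    doubles the channel count from ``base_channels``.  Biases are zero and
    normalization is bias-free, so an all-zero input yields all-zero features.
    """

    def __init__(self, config: AttentionConfig | None = None):
        self.config = config or AttentionConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.stage_channels = [cfg.base_channels * (2**s) for s in range(4)]
        c0 = self.stage_channels[0]
        self.patch_W = rng.normal(scale=1.0 / np.sqrt(48), size=(48, c0))
        self.blocks: list[list[dict]] = []
        self.merges: list[np.ndarray] = []
        for s, C in enumerate(self.stage_channels):
            stage_blocks = []
            for _ in range(cfg.blocks_per_stage):
                stage_blocks.append(
                    {
                        "Wqkv": rng.normal(scale=1.0 / np.sqrt(C), size=(C, 3 * C)),
                        "Wo": rng.normal(scale=1.0 / np.sqrt(C), size=(C, C)),
                        "W1": rng.normal(scale=1.0 / np.sqrt(C), size=(C, 2 * C)),
                        "W2": rng.normal(scale=1.0 / np.sqrt(2 * C), size=(2 * C, C)),
                    }
                )
            self.blocks.append(stage_blocks)
            if s < 3:
                self.merges.append(
                    rng.normal(scale=1.0 / np.sqrt(4 * C), size=(4 * C, 2 * C))
                )

    def patch_embedding(self, image: np.ndarray) -> np.ndarray:
        """Linear 4x4 patch embedding of an image (the stage-1 input tokens).

        Being a pure linear map of pixels, this stem preserves color content
        exactly; region features built on it keep object appearance intact.
        """
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ModelError(f"expected H x W x 3 image, got {image.shape}")
        H, W = image.shape[:2]
        if H % 32 or W % 32:
            raise ModelError(f"image sides must be divisible by 32, got {(H, W)}")
        x = image / 255.0
        h4, w4 = H // 4, W // 4
        patches = x.reshape(h4, 4, w4, 4, 3).transpose(0, 2, 1, 3, 4).reshape(h4, w4, 48)
        return patches @ self.patch_W

    def forward(self, image: np.ndarray) -> list[np.ndarray]:
        """Return the 4-level feature pyramid for one H x W x 3 image.

        The image side must be divisible by 32; pixel values are scaled to
        [0, 1] internally.
        """
        feat = self.patch_embedding(image)
        cfg = self.config
        pyramid = []
        for s in range(4):
            heads = cfg.stage_heads[s]
            for blk in self.blocks[s]:
                feat = feat + _window_attention(
                    _layer_norm(feat), heads, blk["Wqkv"], blk["Wo"], cfg.window
                )
                z = _layer_norm(feat) @ blk["W1"]
                feat = feat + np.maximum(z, 0.0) @ blk["W2"]
            pyramid.append(feat)
            if s < 3:
                Hs, Ws, C = feat.shape
                merged = (
                    feat.reshape(Hs // 2, 2, Ws // 2, 2, C)
                    .transpose(0, 2, 1, 3, 4)
                    .reshape(Hs // 2, Ws // 2, 4 * C)
                )
                feat = merged @ self.merges[s]
        return pyramid


def tiny_backbone_forward(
    image: np.ndarray, config: AttentionConfig | None = None
) -> list[np.ndarray]:
    """Convenience wrapper: build a seeded backbone and run one image."""
    return TinyBackbone(config).forward(image)


# ---------------------------------------------------------------------------
# RoI feature extraction
# ---------------------------------------------------------------------------

def _bilinear_sample(feat: np.ndarray, y: float, x: float) -> np.ndarray:
    H, W = feat.shape[:2]
    y = min(max(y, 0.0), H - 1.0)
    x = min(max(x, 0.0), W - 1.0)
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    y1, x1 = min(y0 + 1, H - 1), min(x0 + 1, W - 1)
    fy, fx = y - y0, x - x0
    return (
        feat[y0, x0] * (1 - fy) * (1 - fx)
        + feat[y0, x1] * (1 - fy) * fx
        + feat[y1, x0] * fy * (1 - fx)
        + feat[y1, x1] * fy * fx
    )


def roi_align(
    feat: np.ndarray,
    box: tuple[float, float, float, float],
    stride: float,
    grid: int = 7,
    samples: int = 2,
) -> np.ndarray:
    """RoI-align a half-open image-space box onto a ``grid x grid x C`` tensor.

    Each output bin averages ``samples x samples`` bilinear samples placed at
    regular fractions of the bin, following the standard continuous-coordinate
    alignment (no quantization of box edges).
    """
    x1, y1, x2, y2 = (v / stride for v in box)
    if x2 <= x1 or y2 <= y1:
        raise ModelError(f"degenerate box {box}")
    bw, bh = (x2 - x1) / grid, (y2 - y1) / grid
    out = np.zeros((grid, grid, feat.shape[2]))
    for gy in range(grid):
        for gx in range(grid):
            acc = np.zeros(feat.shape[2])
            for sy in range(samples):
                for sx in range(samples):
                    yy = y1 + (gy + (sy + 0.5) / samples) * bh - 0.5
                    xx = x1 + (gx + (sx + 0.5) / samples) * bw - 0.5
                    acc += _bilinear_sample(feat, yy, xx)
            out[gy, gx] = acc / (samples * samples)
    return out


def roi_features(
    pyramid: Sequence[np.ndarray],
    boxes: Sequence[tuple[float, float, float, float]],
    image_id: str = "",
    stage: int = 1,
    strides: Sequence[int] = (4, 8, 16, 32),
    grid: int = 7,
) -> list[RegionFeature]:
    """Pool each box into one feature vector from a chosen pyramid stage.

    The aligned ``grid x grid`` patch is mean-pooled to a vector; box order is
    preserved.  Degenerate (zero-area) boxes raise an error naming the box.
    """
    feat = pyramid[stage]
    out = []
    for box in boxes:
        aligned = roi_align(feat, box, stride=strides[stage], grid=grid)
        out.append(RegionFeature(vector=aligned.mean(axis=(0, 1)), box=tuple(box), image_id=image_id))
    return out
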