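"""Ecological alignment losses: tree-path, classification+embedding, relation.

Four terms supervise the recognizer:

* ``tree_path_loss``  — depth-weighted count of wrong levels along a path,
  with weights growing toward the species level (fine-grained mistakes cost
  more); used as a decoding-time penalty and optional auxiliary term;
* ``L_cls``           — per-level cross-entropy of the predicted candidate
  distributions against the true path;
* ``L_embed``         — squared distance between the knowledge embeddings of
  the predicted and true labels at each level, pulling predictions toward
  semantically close taxa even when wrong;
* ``L_rel``           — cosine disagreement between predicted and reference
  relation embeddings for co-occurring pest-predator pairs.

The total objective averages classification+embedding over the ``N`` targets
and the relation term over the ``M`` pairs, then combines them with weights
``lambda1/2/3``, so batch size does not rescale the objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .taxonomy import LabelPath

DeltaFn = Callable[[int], float]


class LossError(ValueError):
    pass


def linear_delta(i: int) -> float:
    """Default depth weighting: level i costs i (species mistakes cost most)."""
    return float(i)


def normalized_delta(i: int) -> float:
    """Depth weighting normalized to sum 2 over the three levels: i / 3."""
    return i / 3.0


@dataclass
class LossWeights:
    """Weights of the combined objective; delta must not decrease with depth."""

    lambda1: float = 1.0
    lambda2: float = 0.5
    lambda3: float = 0.5
    lambda_tree: float = 0.0
    delta: DeltaFn = linear_delta

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda_tree"):
            if getattr(self, name) < 0:
                raise LossError(f"{name} must be nonnegative")
        ds = [self.delta(i) for i in (1, 2, 3)]
        if not (ds[0] <= ds[1] <= ds[2]):
            raise LossError("delta(i) must be nondecreasing in depth")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-component values of one batch objective evaluation."""

    L_cls: float
    L_embed: float
    L_rel: float
    L_tree: float
    total: float
    N: int
    M: int

    def __post_init__(self) -> None:
        for name in ("L_cls", "L_embed", "L_rel", "L_tree"):
            if getattr(self, name) < -1e-12:
                raise LossError(f"{name} must be nonnegative")


def tree_path_loss(
    pred: LabelPath | Sequence[str],
    truth: LabelPath | Sequence[str],
    delta: DeltaFn = linear_delta,
) -> float:
    """Depth-weighted mismatch count: ``sum_i 1[pred_i != truth_i] * delta(i)``.

    Zero exactly when the paths agree at every level.
    """
    p = tuple(pred.labels) if isinstance(pred, LabelPath) else tuple(pred)
    t = tuple(truth.labels) if isinstance(truth, LabelPath) else tuple(truth)
    if len(p) != 3 or len(t) != 3:
        raise LossError(f"paths must have 3 levels, got {len(p)} and {len(t)}")
    return float(sum(delta(i + 1) for i in range(3) if p[i] != t[i]))


def esa_loss(
    pred_probs: Sequence[Mapping[str, float]],
    truth: LabelPath,
    embed: Mapping[str, np.ndarray],
) -> tuple[float, float]:
    """Classification and embedding-alignment terms for one target.

    ``pred_probs[l]`` is the predicted distribution over level-``l+1``
    candidates (label id -> probability, normalized).  ``L_cls`` sums the
    cross-entropy of the true label; ``L_embed`` sums the squared embedding
    distance between the argmax label and the true label — zero when the
    argmax is right at every level.  The lambda weights are applied at batch
    aggregation, not here.
    """
    if len(pred_probs) != 3:
        raise LossError("expected one distribution per level")
    l_cls = 0.0
    l_embed = 0.0
    for level, dist in enumerate(pred_probs):
        y = truth[level]
        if y not in dist:
            raise LossError(f"true label {y!r} missing from level-{level + 1} distribution")
        l_cls += -float(np.log(max(dist[y], 1e-300)))
        y_hat = max(dist, key=lambda k: (dist[k], k))
        for label in (y_hat, y):
            if label not in embed:
                raise LossError(f"label {label!r} has no embedding")
        diff = np.asarray(embed[y_hat], dtype=np.float64) - np.asarray(embed[y], dtype=np.float64)
        l_embed += float(diff @ diff)
    return l_cls, l_embed


def relation_loss(
    pred_rel: np.ndarray,
    true_rel: str,
    relation_vectors: Mapping[str, np.ndarray],
    phi: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> float:
    """Cosine disagreement ``1 - cos(phi(pred), phi(reference))`` in [0, 2]."""
    if true_rel not in relation_vectors:
        raise LossError(f"unknown relation {true_rel!r}")
    a = np.asarray(pred_rel, dtype=np.float64)
    b = np.asarray(relation_vectors[true_rel], dtype=np.float64)
    if phi is not None:
        a, b = phi(a), phi(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise LossError("cosine undefined for zero-norm relation vector")
    return float(1.0 - (a @ b) / (na * nb))


def total_loss(
    pred_probs_batch: Sequence[Sequence[Mapping[str, float]]],
    truth_batch: Sequence[LabelPath],
    embed: Mapping[str, np.ndarray],
    pair_predictions: Sequence[tuple[np.ndarray, str]] = (),
    relation_vectors: Optional[Mapping[str, np.ndarray]] = None,
    weights: Optional[LossWeights] = None,
    pred_paths: Optional[Sequence[LabelPath]] = None,
) -> LossBreakdown:
    """Batch objective: ``lambda1 * <L_cls> + lambda2 * <L_embed> + lambda3 * <L_rel>``.

    Classification and embedding terms average over the ``N`` targets; the
    relation term averages over the ``M`` (predicted-embedding, true-relation)
    pairs and vanishes when there are none.  The optional tree-path penalty
    (weight ``lambda_tree``, default 0) averages over targets when predicted
    paths are supplied.
    """
    weights = weights or LossWeights()
    N = len(truth_batch)
    if N < 1:
        raise LossError("batch must contain at least one target")
    if len(pred_probs_batch) != N:
        raise LossError(
            f"batch size mismatch: {len(pred_probs_batch)} predictions, {N} truths"
        )
    l_cls = 0.0
    l_embed = 0.0
    for probs, truth in zip(pred_probs_batch, truth_batch):
        c, e = esa_loss(probs, truth, embed)
        l_cls += c
        l_embed += e
    l_cls /= N
    l_embed /= N
    if weights.lambda2 == 0.0:
        l_embed = 0.0  # switched-off components report as zero

    M = len(pair_predictions)
    l_rel = 0.0
    if M and weights.lambda3 > 0.0:
        if relation_vectors is None:
            raise LossError("relation_vectors required when pairs are supplied")
        for pred_vec, true_rel in pair_predictions:
            l_rel += relation_loss(pred_vec, true_rel, relation_vectors)
        l_rel /= M

    l_tree = 0.0
    if weights.lambda_tree > 0.0 and pred_paths is not None:
        if len(pred_paths) != N:
            raise LossError("pred_paths length must match batch size")
        l_tree = sum(
            tree_path_loss(p, t, weights.delta) for p, t in zip(pred_paths, truth_batch)
        ) / N

    total = (
        weights.lambda1 * l_cls
        + weights.lambda2 * l_embed
        + weights.lambda3 * l_rel
        + weights.lambda_tree * l_tree
    )
    return LossBreakdown(
        L_cls=l_cls, L_embed=l_embed, L_rel=l_rel, L_tree=l_tree, total=total, N=N, M=M
    )


def label_embedding_table(
    tree, embedding, taxon_to_entity: Optional[Mapping[str, str]] = None, d_k: Optional[int] = None
) -> dict[str, np.ndarray]:
    """Reference geometry k(.) for the embedding term, frozen from the KG.

    Species take their KG entity vectors; order/family nodes without entities
    take the mean of their descendant species' vectors.  Nodes with no
    embedded descendant get zeros (their embedding term is then uninformative
    but defined).
    """
    from .taxonomy import label_path as _label_path

    lookup = taxon_to_entity or {}
    table: dict[str, np.ndarray] = {}
    dim = d_k or embedding.d_k
    for sid in tree.species():
        eid = lookup.get(sid, sid)
        if eid in embedding.entity_vectors:
            table[sid] = np.asarray(embedding.entity_vectors[eid], dtype=np.float64)
        else:
            table[sid] = np.zeros(dim)
    for rank in ("order", "family"):
        for node in tree.nodes_at_rank(rank):
            descendants = [
                table[s] for s in tree.species() if node.id in _label_path(tree, s).labels
            ]
            table[node.id] = (
                np.mean(descendants, axis=0) if descendants else np.zeros(dim)
            )
    return table
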