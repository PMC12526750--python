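"""Ecological knowledge graph: triples, GCN embeddings, completion.

The graph holds typed ecological facts between species, crops and factors —
predation, cohabitation, competition — plus taxonomic membership links.
Entities are optionally anchored to taxonomy nodes, which is what lets the
attention layers select level-specific knowledge views.

Two embedding paths are provided:

* :func:`gcn_embed` — light graph-convolutional propagation over the
  undirected triple graph, giving each entity (and relation) a fixed vector
  used by knowledge-guided attention and the semantic-alignment loss;
* :func:`complete_graph` — translational (TransE-style) link prediction that
  proposes plausible unobserved triples, attaches calibrated confidences and
  prunes low-confidence additions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)


def _stable_id(text: str) -> int:
    """Process-independent 31-bit hash of a string (id -> RNG stream key)."""
    import zlib

    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF

DEFAULT_RELATIONS = ("predation", "cohabitation", "competition", "none")


class KGError(ValueError):
    """Raised on malformed triples or invalid graph queries."""


@dataclass(frozen=True)
class Entity:
    id: str
    name: str
    taxon: Optional[str] = None  # taxonomy node id, if the entity is a taxon


@dataclass
class KnowledgeGraph:
    """Entities, relation types and confidence-weighted (h, r, t) triples."""

    entities: dict[str, Entity] = field(default_factory=dict)
    relations: set[str] = field(default_factory=lambda: set(DEFAULT_RELATIONS))
    triples: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def add_entity(self, entity: Entity) -> None:
        self.entities[entity.id] = entity

    def add_triple(self, h: str, r: str, t: str, confidence: float = 1.0) -> None:
        if r not in self.relations:
            raise KGError(f"undeclared relation {r!r}")
        if not 0.0 <= confidence <= 1.0:
            raise KGError(f"confidence must be in [0,1], got {confidence}")
        for eid in (h, t):
            if eid not in self.entities:
                self.add_entity(Entity(eid, eid))
        key = (h, r, t)
        # duplicates keep the max confidence
        self.triples[key] = max(confidence, self.triples.get(key, 0.0))

    def neighbors(self, entity_id: str) -> list[tuple[str, str, float]]:
        """(relation, other-entity, confidence) triples touching an entity."""
        out = []
        for (h, r, t), conf in self.triples.items():
            if h == entity_id:
                out.append((r, t, conf))
            elif t == entity_id:
                out.append((r, h, conf))
        return out

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(
            entities=dict(self.entities),
            relations=set(self.relations),
            triples=dict(self.triples),
        )


@dataclass
class KnowledgeEmbedding:
    """Per-entity and per-relation vectors sharing one dimension ``d_k``."""

    entity_vectors: dict[str, np.ndarray]
    relation_vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.entity_vectors.values()} | {
            v.shape for v in self.relation_vectors.values()
        }
        if len(dims) > 1:
            raise KGError(f"inconsistent embedding dimensions: {dims}")
        for v in list(self.entity_vectors.values()) + list(self.relation_vectors.values()):
            if not np.all(np.isfinite(v)):
                raise KGError("non-finite embedding vector")

    @property
    def d_k(self) -> int:
        any_vec = next(iter(self.entity_vectors.values()), None)
        if any_vec is None:
            any_vec = next(iter(self.relation_vectors.values()))
        return int(any_vec.shape[0])


@dataclass
class LevelSubgraph:
    """Entities of one taxonomy level, grouped under their depth-l ancestors.

    ``embedding_view`` holds one aggregated (mean) vector per ancestor group —
    the K^(l) matrix consumed by hierarchical knowledge-guided attention.
    """

    level: int
    groups: dict[str, list[str]]  # ancestor taxonomy node -> member entity ids
    embedding_view: dict[str, np.ndarray]

    @property
    def members(self) -> set[str]:
        return {eid for members in self.groups.values() for eid in members}


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_triples(
    path,
    entity_map: Optional[Mapping[str, str]] = None,
    extra_relations: Iterable[str] = (),
) -> KnowledgeGraph:
    """Read a ``head<TAB>relation<TAB>tail[<TAB>confidence]`` TSV.

    Comment lines starting ``# relations:`` declare additional relation types
    beyond the ecological default set; any other relation string is rejected.
    ``entity_map`` links entity ids to taxonomy node ids.
    """
    graph = KnowledgeGraph()
    graph.relations.update(extra_relations)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("relations:"):
                    declared = body.split(":", 1)[1]
                    graph.relations.update(
                        r.strip() for r in declared.split(",") if r.strip()
                    )
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise KGError(f"line {lineno}: expected 3 or 4 columns, got {len(parts)}")
            h, r, t = (p.strip() for p in parts[:3])
            if r not in graph.relations:
                raise KGError(f"line {lineno}: undeclared relation {r!r}")
            try:
                conf = float(parts[3]) if len(parts) == 4 else 1.0
            except ValueError as exc:
                raise KGError(f"line {lineno}: bad confidence {parts[3]!r}") from exc
            if not 0.0 <= conf <= 1.0:
                raise KGError(f"line {lineno}: confidence {conf} outside [0,1]")
            graph.add_triple(h, r, t, conf)
    if entity_map:
        for eid, taxon in entity_map.items():
            name = graph.entities[eid].name if eid in graph.entities else eid
            graph.add_entity(Entity(eid, name, taxon=taxon))
    return graph


def save_triples(graph: KnowledgeGraph, path) -> None:
    extra = sorted(graph.relations - set(DEFAULT_RELATIONS))
    with open(path, "w", encoding="utf-8") as fh:
        if extra:
            fh.write("# relations: " + ", ".join(extra) + "\n")
        for (h, r, t), conf in sorted(graph.triples.items()):
            fh.write(f"{h}\t{r}\t{t}\t{conf:g}\n")


# ---------------------------------------------------------------------------
# GCN embedding
# ---------------------------------------------------------------------------

def gcn_embed(
    graph: KnowledgeGraph,
    d_k: int = 64,
    n_layers: int = 2,
    seed: int = 0,
) -> KnowledgeEmbedding:
    """Graph-convolutional entity embeddings with seeded random weights.

    Node features start as seeded random normals concatenated with per-relation
    incidence counts, then propagate ``n_layers`` times through symmetric-
    normalized mean aggregation (self-loops included) with a random linear map
    and tanh per layer.  Isolated nodes keep their (transformed) initial
    features.  Relation vectors are seeded random unit vectors; completion can
    later replace them with learned ones.
    """
    if d_k < 1 or n_layers < 1:
        raise KGError("d_k and n_layers must be >= 1")
    rng = np.random.default_rng(seed)
    ids = sorted(graph.entities)
    rels = sorted(graph.relations)
    rel_vectors = {}
    for r in rels:
        v = rng.normal(size=d_k)
        rel_vectors[r] = v / np.linalg.norm(v)
    if not ids:
        return KnowledgeEmbedding({}, rel_vectors)
    index = {eid: i for i, eid in enumerate(ids)}
    n = len(ids)

    # adjacency over the undirected triple graph, plus self-loops
    adj = np.eye(n)
    incidence = np.zeros((n, len(rels)))
    rel_index = {r: j for j, r in enumerate(rels)}
    for (h, r, t), _conf in graph.triples.items():
        i, j = index[h], index[t]
        if i != j:
            adj[i, j] = adj[j, i] = 1.0
        incidence[i, rel_index[r]] += 1.0
        incidence[j, rel_index[r]] += 1.0
    deg = adj.sum(axis=1)
    norm = adj / np.sqrt(np.outer(deg, deg))

    # initial features are tied to entity ids, not enumeration order, so that
    # relabeling nodes permutes outputs (permutation equivariance)
    feats = np.empty((n, d_k + len(rels)))
    for eid, i in index.items():
        feats[i, :d_k] = np.random.default_rng([seed, _stable_id(eid)]).normal(size=d_k)
    feats[:, d_k:] = incidence

    h = feats
    d_in = h.shape[1]
    wrng = np.random.default_rng([seed, 1])
    for _ in range(n_layers):
        W = wrng.normal(scale=1.0 / np.sqrt(d_in), size=(d_in, d_k))
        h = np.tanh(norm @ h @ W)
        d_in = d_k
    return KnowledgeEmbedding({eid: h[index[eid]].copy() for eid in ids}, rel_vectors)


def level_subgraphs(
    graph: KnowledgeGraph,
    tree: TaxonomyTree,
    embedding: KnowledgeEmbedding,
) -> list[LevelSubgraph]:
    """Group taxonomy-linked entities under their depth-1/2/3 ancestors.

    A species-linked entity contributes to all three level views (under its
    order, family and itself); entities without a resolvable taxonomy link are
    excluded with a warning.  Each group's view vector is the mean embedding
    of its members.
    """
    out = []
    ancestry: dict[str, list[str]] = {}
    for eid, ent in graph.entities.items():
        if ent.taxon is None or ent.taxon not in tree:
            if ent.taxon is not None:
                logger.warning("entity %s links to unknown taxon %s", eid, ent.taxon)
            continue
        node = tree.node(ent.taxon)
        chain = [node.id]
        while node.parent is not None:
            node = tree.node(node.parent)
            chain.append(node.id)
        ancestry[eid] = chain[::-1]  # root ... self
    for level in (1, 2, 3):
        groups: dict[str, list[str]] = {}
        for eid, chain in sorted(ancestry.items()):
            node_rank_depth = len(chain)  # depth of the linked node
            if node_rank_depth >= level:
                groups.setdefault(chain[level - 1], []).append(eid)
        view = {}
        for anc, members in groups.items():
            vecs = [embedding.entity_vectors[m] for m in members if m in embedding.entity_vectors]
            if vecs:
                view[anc] = np.mean(vecs, axis=0)
        out.append(LevelSubgraph(level=level, groups=groups, embedding_view=view))
    return out


# ---------------------------------------------------------------------------
# Translational completion (TransE-style)
# ---------------------------------------------------------------------------

def train_transe(
    graph: KnowledgeGraph,
    d_k: int = 32,
    margin: float = 1.0,
    epochs: int = 200,
    lr: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Learn translational embeddings ``h + r ≈ t`` by margin ranking SGD.

    Negatives corrupt the head or tail uniformly; entity vectors are
    renormalized to the unit sphere each epoch.  Returns entity and relation
    vector tables.
    """
    if graph.n_triples < 1:
        raise KGError("cannot train on an empty graph")
    rng = np.random.default_rng(seed)
    ents = sorted(graph.entities)
    rels = sorted(graph.relations)
    e_idx = {e: i for i, e in enumerate(ents)}
    r_idx = {r: i for i, r in enumerate(rels)}
    E = rng.uniform(-0.5, 0.5, size=(len(ents), d_k)) / np.sqrt(d_k)
    R = rng.uniform(-0.5, 0.5, size=(len(rels), d_k)) / np.sqrt(d_k)
    R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)
    triples = [(e_idx[h], r_idx[r], e_idx[t]) for (h, r, t) in sorted(graph.triples)]
    triple_set = set(triples)

    for _ in range(epochs):
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        order = rng.permutation(len(triples))
        for k in order:
            h, r, t = triples[k]
            # uniform corruption of head or tail
            for _attempt in range(10):
                if rng.random() < 0.5:
                    neg = (int(rng.integers(len(ents))), r, t)
                else:
                    neg = (h, r, int(rng.integers(len(ents))))
                if neg not in triple_set:
                    break
            nh, nr, nt = neg
            d_pos = E[h] + R[r] - E[t]
            d_neg = E[nh] + R[nr] - E[nt]
            loss = margin + np.linalg.norm(d_pos) - np.linalg.norm(d_neg)
            if loss <= 0:
                continue
            g_pos = d_pos / max(np.linalg.norm(d_pos), 1e-12)
            g_neg = d_neg / max(np.linalg.norm(d_neg), 1e-12)
            E[h] -= lr * g_pos
            E[t] += lr * g_pos
            R[r] -= lr * g_pos
            E[nh] += lr * g_neg
            E[nt] -= lr * g_neg
            R[nr] += lr * g_neg
    E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
    return (
        {e: E[e_idx[e]].copy() for e in ents},
        {r: R[r_idx[r]].copy() for r in rels},
    )


def transe_score(
    ent: Mapping[str, np.ndarray],
    rel: Mapping[str, np.ndarray],
    h: str,
    r: str,
    t: str,
) -> float:
    """Plausibility score ``-||h + r - t||`` (larger is more plausible)."""
    return float(-np.linalg.norm(ent[h] + rel[r] - ent[t]))


def complete_graph(
    graph: KnowledgeGraph,
    d_k: int = 32,
    margin: float = 1.0,
    epochs: int = 200,
    threshold: float = 0.9,
    prune_floor: float = 0.5,
    seed: int = 0,
    candidate_relations: Optional[Iterable[str]] = None,
) -> KnowledgeGraph:
    """Propose unobserved triples by translational link prediction.

    All absent (h, r, t) candidates over the chosen relations are scored with
    the trained model; scores are calibrated to [0, 1) by a sigmoid centered
    on the asserted triples' score distribution, candidates at or above
    ``threshold`` are added with that confidence, and added triples below
    ``prune_floor`` are removed again.  Asserted (confidence 1) triples are
    never pruned.
    """
    ent, rel = train_transe(graph, d_k=d_k, margin=margin, epochs=epochs, seed=seed)
    scores = np.array(
        [transe_score(ent, rel, h, r, t) for (h, r, t) in graph.triples]
    )
    center = float(np.median(scores))
    scale = float(np.std(scores)) or 1.0

    def calibrate(s: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(s - center) / scale)))

    out = graph.copy()
    rels = sorted(candidate_relations) if candidate_relations else sorted(graph.relations)
    for h in sorted(graph.entities):
        for t in sorted(graph.entities):
            if h == t:
                continue
            for r in rels:
                if (h, r, t) in graph.triples:
                    continue
                conf = calibrate(transe_score(ent, rel, h, r, t))
                if conf >= threshold:
                    out.add_triple(h, r, t, confidence=min(conf, 1.0 - 1e-9))
    # prune noisy additions; asserted triples are untouchable
    for key in list(out.triples):
        conf = out.triples[key]
        if conf < 1.0 and conf < prune_floor and key not in graph.triples:
            del out.triples[key]
    return out
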