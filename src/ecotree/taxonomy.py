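"""Ecological taxonomy tree: label paths, candidate sets, co-occurrence pairs.

The taxonomy is a three-rank forest (order -> family -> species).  Every
species is a leaf carrying an ecological role (pest or predator).  The tree
is the structural prior for hierarchical decoding: predictions are
root-to-leaf *label paths*, not flat species labels, and the per-level
candidate sets it exposes are what constrains decoding to valid paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional, Sequence

RANKS = ("order", "family", "species")
ROLES = ("pest", "predator")


class TaxonomyError(ValueError):
    """Raised when a taxonomy file or query violates the tree invariants."""


@dataclass(frozen=True)
class TaxNode:
    """One node of the taxonomy: an order, a family or a species.

    ``role`` is set exactly for species nodes and records whether the species
    is an agricultural pest or one of its natural predators.
    """

    id: str
    name: str
    rank: str
    parent: Optional[str] = None
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise TaxonomyError(f"node {self.id!r}: unknown rank {self.rank!r}")
        if (self.role is not None) != (self.rank == "species"):
            raise TaxonomyError(
                f"node {self.id!r}: role must be set iff rank is species"
            )
        if self.role is not None and self.role not in ROLES:
            raise TaxonomyError(f"node {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class LabelPath:
    """An ordered (order, family, species) triple of node ids."""

    labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.labels) != 3:
            raise TaxonomyError(f"label path must have 3 levels, got {len(self.labels)}")

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    @property
    def species(self) -> str:
        return self.labels[2]


@dataclass(frozen=True)
class CoOccurrencePair:
    """An ordered (pest, predator) species pair with an ecological relation."""

    pest: str
    predator: str
    relation: str = "none"

    RELATIONS = ("predation", "cohabitation", "competition", "none")

    def __post_init__(self) -> None:
        if self.relation not in self.RELATIONS:
            raise TaxonomyError(f"unknown relation {self.relation!r}")


class TaxonomyTree:
    """A validated three-rank forest of :class:`TaxNode`.

    Construction checks every invariant: each non-root has exactly one
    existing parent, ranks follow depth (order at depth 1, family 2,
    species 3), species are leaves with unique names.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self._nodes: dict[str, TaxNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise TaxonomyError(f"duplicate node id {node.id!r}")
            self._nodes[node.id] = node
        self._children: dict[str, list[str]] = {nid: [] for nid in self._nodes}
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        expected_parent_rank = {"order": None, "family": "order", "species": "family"}
        seen_species_names: set[str] = set()
        for node in self._nodes.values():
            want = expected_parent_rank[node.rank]
            if want is None:
                if node.parent is not None:
                    raise TaxonomyError(f"order {node.id!r} must be a root")
            else:
                if node.parent is None:
                    raise TaxonomyError(f"{node.rank} {node.id!r} has no parent")
                parent = self._nodes.get(node.parent)
                if parent is None:
                    raise TaxonomyError(f"node {node.id!r}: unknown parent {node.parent!r}")
                if parent.rank != want:
                    raise TaxonomyError(
                        f"node {node.id!r} (rank {node.rank}) has parent "
                        f"{parent.id!r} of rank {parent.rank}, expected {want}"
                    )
                self._children[parent.id].append(node.id)
            if node.rank == "species":
                if node.name in seen_species_names:
                    raise TaxonomyError(f"duplicate species name {node.name!r}")
                seen_species_names.add(node.name)
        # rank-by-depth implies acyclicity; children sorted for determinism
        for nid in self._children:
            self._children[nid].sort(key=lambda cid: self._nodes[cid].name)

    # -- queries --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> TaxNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise TaxonomyError(f"unknown node id {node_id!r}") from None

    def nodes_at_rank(self, rank: str) -> list[TaxNode]:
        out = [n for n in self._nodes.values() if n.rank == rank]
        out.sort(key=lambda n: n.name)
        return out

    @property
    def roots(self) -> list[str]:
        return [n.id for n in self.nodes_at_rank("order")]

    def children(self, node_id: str) -> list[str]:
        self.node(node_id)
        return list(self._children[node_id])

    def species(self, role: Optional[str] = None) -> list[str]:
        out = [n for n in self.nodes_at_rank("species") if role is None or n.role == role]
        return [n.id for n in out]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def load_taxonomy(path) -> TaxonomyTree:
    """Load and validate a taxonomy from its JSON record list.

    The schema is a JSON array of node records
    ``{"id", "name", "rank", "parent", "role"}`` with ``parent``/``role``
    null where inapplicable.
    """
    with open(path, "r", encoding="utf-8") as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise TaxonomyError("taxonomy JSON must be a list of node records")
    nodes = [
        TaxNode(
            id=str(rec["id"]),
            name=str(rec["name"]),
            rank=str(rec["rank"]),
            parent=rec.get("parent"),
            role=rec.get("role"),
        )
        for rec in records
    ]
    return TaxonomyTree(nodes)


def save_taxonomy(tree: TaxonomyTree, path) -> None:
    records = [
        {"id": n.id, "name": n.name, "rank": n.rank, "parent": n.parent, "role": n.role}
        for n in sorted(tree._nodes.values(), key=lambda n: (RANKS.index(n.rank), n.name))
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)


def label_path(tree: TaxonomyTree, species: str) -> LabelPath:
    """Return the unique root-to-leaf path (order, family, species) for a species."""
    leaf = tree.node(species)
    if leaf.rank != "species":
        raise TaxonomyError(f"node {species!r} has rank {leaf.rank}, expected species")
    family = tree.node(leaf.parent)
    order = tree.node(family.parent)
    return LabelPath((order.id, family.id, leaf.id))


def candidate_set(tree: TaxonomyTree, level: int, parent: Optional[str] = None) -> list[str]:
    """Candidate label ids at a level, ordered lexicographically by name.

    Level 1 candidates are all orders; deeper levels are the children of the
    decoded parent.  Deterministic ordering is what makes argmax tie-breaking
    in decoding reproducible.
    """
    if level not in (1, 2, 3):
        raise TaxonomyError(f"level must be 1..3, got {level}")
    if (parent is None) != (level == 1):
        raise TaxonomyError("parent must be omitted iff level == 1")
    if level == 1:
        return list(tree.roots)
    parent_node = tree.node(parent)
    if RANKS.index(parent_node.rank) != level - 2:
        raise TaxonomyError(
            f"parent {parent!r} has rank {parent_node.rank}, not valid for level {level}"
        )
    kids = tree.children(parent)
    if not kids:
        raise TaxonomyError(f"parent {parent!r} has no children at level {level}")
    return kids


def build_cooccurrence_pairs(
    tree: TaxonomyTree, pests: Iterable[str], predators: Iterable[str]
) -> set[CoOccurrencePair]:
    """Cartesian product of pest and predator species as ordered pairs.

    Every candidate (pest, predator) pair in an image is a potential
    ecological interaction; relations start as ``none`` and are filled in by
    relation prediction or expert annotation.
    """
    pests = sorted(set(pests))
    predators = sorted(set(predators))
    for sid, want in [(p, "pest") for p in pests] + [(e, "predator") for e in predators]:
        node = tree.node(sid)
        if node.rank != "species" or node.role != want:
            raise TaxonomyError(f"node {sid!r} is not a {want}-role species")
    return {CoOccurrencePair(p, e) for p, e in product(pests, predators)}


def validate_path(tree: TaxonomyTree, path: LabelPath | Sequence[str]) -> bool:
    """True iff the path follows tree edges with ranks order->family->species."""
    labels = tuple(path.labels) if isinstance(path, LabelPath) else tuple(path)
    if len(labels) != 3:
        return False
    try:
        nodes = [tree.node(l) for l in labels]
    except TaxonomyError:
        return False
    if tuple(n.rank for n in nodes) != RANKS:
        return False
    return nodes[1].parent == nodes[0].id and nodes[2].parent == nodes[1].id
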