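"""Synthetic ecological scenes: taxonomies, knowledge graphs, images, labels.

Field datasets of pest-predator scenes are rarely redistributable, so this
module generates desk-scale stand-ins with the statistical structure the
framework assumes: multi-object RGB scenes over textured backgrounds
(soil / foliage / sky color fields), a balanced three-rank taxonomy whose
species are procedurally drawn parametric glyphs (ellipse / triangle / star
families with distinct base colors), an ecological knowledge graph mirroring
the taxonomy plus seeded predation edges, and per-image annotations with
boxes, species labels, an exact background mask and realized co-occurrence
pairs.

Two difficulty presets: ``separable`` (no texture noise, no occlusion —
recognition targets are attainable by construction) and ``hard`` (texture
noise, occlusion and scale jitter emulating field conditions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .knowledge_graph import Entity, KnowledgeGraph, save_triples
from .metrics import Box
from .taxonomy import (
    CoOccurrencePair,
    TaxNode,
    TaxonomyTree,
    save_taxonomy,
)

_SYLLABLES = [
    "la", "mi", "cor", "dax", "ve", "tu", "pho", "ran", "sel", "qui",
    "bor", "nec", "ta", "lis", "mor", "ze", "pli", "ka", "dro", "vin",
]


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without excessive overlap."""


def _make_name(rng: np.random.Generator, suffix: str) -> str:
    parts = [_SYLLABLES[int(rng.integers(len(_SYLLABLES)))] for _ in range(3)]
    return "".join(parts).capitalize() + suffix


@dataclass(frozen=True)
class GlyphDescriptor:
    """How one species is drawn: shape family, base color, size, texture."""

    shape: str  # ellipse | triangle | star
    color: tuple[int, int, int]
    size_range: tuple[float, float]  # fraction of image side
    texture_noise: float  # std of per-pixel color jitter, 0 = flat


@dataclass
class CoOccurrenceRule:
    pest: str
    predator: str
    relation: str
    probability: float


@dataclass
class SceneSpec:
    """Generation parameters for one scene corpus."""

    image_size: int = 96
    n_objects: tuple[int, int] = (2, 5)
    background_families: tuple[str, ...] = ("soil", "foliage", "sky")
    background_noise: float = 4.0
    glyphs: dict[str, GlyphDescriptor] = field(default_factory=dict)
    occlusion_rate: float = 0.0
    rules: list[CoOccurrenceRule] = field(default_factory=list)
    max_pairwise_iou: float = 0.3
    seed: int = 0

    def validate(self, tree: TaxonomyTree) -> None:
        species = set(tree.species())
        for rule in self.rules:
            if rule.pest not in species or rule.predator not in species:
                raise ValueError(f"rule references unknown species: {rule}")
            if not 0.0 <= rule.probability <= 1.0:
                raise ValueError(f"rule probability outside [0,1]: {rule}")


@dataclass
class PairAnnotation:
    pair: CoOccurrencePair
    pest_box: int
    predator_box: int


@dataclass
class SceneAnnotation:
    """Ground truth for one generated scene."""

    image_id: str
    boxes: list[Box]
    species: list[str]
    pairs: list[PairAnnotation]


_BG_BASE = {
    "soil": (110, 85, 60),
    "foliage": (60, 110, 55),
    "sky": (150, 180, 215),
}


# ---------------------------------------------------------------------------
# Taxonomy and KG generation
# ---------------------------------------------------------------------------

def generate_taxonomy(
    n_orders: int = 4,
    n_families_per_order: int = 3,
    n_species_per_family: int = 5,
    pest_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> TaxonomyTree:
    """Balanced three-rank tree with deterministic procedural names.

    The default preset yields 60 species — 40 pests and 20 predators — the
    scale of a moderately rich agroecosystem inventory.  Roles are assigned
    by a seeded shuffle to match ``pest_fraction`` within rounding.
    """
    if min(n_orders, n_families_per_order, n_species_per_family) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0.0 < pest_fraction < 1.0:
        raise ValueError("pest_fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    n_species = n_orders * n_families_per_order * n_species_per_family
    n_pests = int(round(pest_fraction * n_species))
    roles = ["pest"] * n_pests + ["predator"] * (n_species - n_pests)
    rng.shuffle(roles)
    nodes: list[TaxNode] = []
    used_names: set[str] = set()

    def fresh_name(suffix: str) -> str:
        while True:
            name = _make_name(rng, suffix)
            if name not in used_names:
                used_names.add(name)
                return name

    s = 0
    for o in range(n_orders):
        oid = f"o{o}"
        nodes.append(TaxNode(oid, fresh_name("ptera"), "order"))
        for f in range(n_families_per_order):
            fid = f"{oid}f{f}"
            nodes.append(TaxNode(fid, fresh_name("idae"), "family", parent=oid))
            for k in range(n_species_per_family):
                sid = f"{fid}s{k}"
                nodes.append(
                    TaxNode(sid, fresh_name("us"), "species", parent=fid, role=roles[s])
                )
                s += 1
    return TaxonomyTree(nodes)


def generate_kg(
    tree: TaxonomyTree,
    predation_density: float = 0.5,
    competition_density: float = 0.0,
    cohabitation_density: float = 0.0,
    seed: int = 0,
) -> KnowledgeGraph:
    """Knowledge graph mirroring the taxonomy plus seeded ecology edges.

    ``belongs_to`` triples reproduce the tree (species -> family -> order);
    each ordered (pest, predator) pair receives a predation triple with
    probability ``predation_density``; competition links same-role species
    pairs and cohabitation any non-predation pest-predator pair, at their own
    densities.  All asserted confidences are 1.
    """
    pests = tree.species("pest")
    predators = tree.species("predator")
    if not pests or not predators:
        raise ValueError("tree must contain at least one pest and one predator")
    rng = np.random.default_rng(seed)
    graph = KnowledgeGraph()
    graph.relations.add("belongs_to")
    for rank in ("order", "family", "species"):
        for node in tree.nodes_at_rank(rank):
            graph.add_entity(Entity(node.id, node.name, taxon=node.id))
            if node.parent is not None:
                graph.add_triple(node.id, "belongs_to", node.parent)
    for p in pests:
        for e in predators:
            if rng.random() < predation_density:
                graph.add_triple(p, "predation", e)
            elif rng.random() < cohabitation_density:
                graph.add_triple(p, "cohabitation", e)
    if competition_density > 0:
        for pool in (pests, predators):
            for i, a in enumerate(pool):
                for b in pool[i + 1 :]:
                    if rng.random() < competition_density:
                        graph.add_triple(a, "competition", b)
    return graph


def rules_from_kg(
    graph: KnowledgeGraph, tree: TaxonomyTree, probability: float = 1.0
) -> list[CoOccurrenceRule]:
    """One co-occurrence rule per ecological pest->predator triple in the KG."""
    pests = set(tree.species("pest"))
    predators = set(tree.species("predator"))
    rules = []
    for (h, r, t) in sorted(graph.triples):
        if r in ("predation", "cohabitation") and h in pests and t in predators:
            rules.append(CoOccurrenceRule(h, t, r, probability))
    return rules


# ---------------------------------------------------------------------------
# Glyphs and scenes
# ---------------------------------------------------------------------------

def make_glyphs(
    tree: TaxonomyTree, texture_noise: float = 0.0, size_range=(0.15, 0.25), seed: int = 0
) -> dict[str, GlyphDescriptor]:
    """Distinct glyphs per species: hue-separated colors, shape by family.

    Colors are evenly spaced on the hue wheel so that mean glyph color alone
    separates species when ``texture_noise`` is zero.
    """
    import colorsys

    species = tree.species()
    shapes = ("ellipse", "triangle", "star")
    glyphs = {}
    for i, sid in enumerate(species):
        hue = i / max(len(species), 1)
        r, g, b = colorsys.hsv_to_rgb(hue, 0.9, 0.95)
        family = tree.node(tree.node(sid).parent)
        shape = shapes[abs(hash_stable(family.id)) % len(shapes)]
        glyphs[sid] = GlyphDescriptor(
            shape=shape,
            color=(int(r * 255), int(g * 255), int(b * 255)),
            size_range=size_range,
            texture_noise=texture_noise,
        )
    return glyphs


def hash_stable(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


def separable_spec(tree: TaxonomyTree, graph: KnowledgeGraph, seed: int = 0) -> SceneSpec:
    """Clean preset: flat glyph colors, disjoint boxes, no occlusion, rules fire surely."""
    spec = SceneSpec(
        glyphs=make_glyphs(tree, texture_noise=0.0, seed=seed),
        background_noise=3.0,
        occlusion_rate=0.0,
        rules=rules_from_kg(graph, tree, probability=1.0),
        max_pairwise_iou=0.0,
        seed=seed,
    )
    spec.validate(tree)
    return spec


def hard_spec(tree: TaxonomyTree, graph: KnowledgeGraph, seed: int = 0) -> SceneSpec:
    """Field-like preset: texture noise, occlusion, scale jitter, flaky rules."""
    spec = SceneSpec(
        glyphs=make_glyphs(tree, texture_noise=18.0, size_range=(0.10, 0.30), seed=seed),
        background_noise=12.0,
        occlusion_rate=0.3,
        rules=rules_from_kg(graph, tree, probability=0.7),
        seed=seed,
    )
    spec.validate(tree)
    return spec


def _paint_background(size: int, family: str, noise: float, rng) -> np.ndarray:
    base = np.array(_BG_BASE[family], dtype=np.float64)
    img = np.tile(base, (size, size, 1))
    # low-frequency field: coarse noise bilinearly upsampled
    coarse = rng.normal(scale=noise, size=(size // 8 + 2, size // 8 + 2, 3))
    ys = np.linspace(0, coarse.shape[0] - 1.001, size)
    xs = np.linspace(0, coarse.shape[1] - 1.001, size)
    y0 = ys.astype(int)
    x0 = xs.astype(int)
    fy = (ys - y0)[:, None, None]
    fx = (xs - x0)[None, :, None]
    up = (
        coarse[y0][:, x0] * (1 - fy) * (1 - fx)
        + coarse[y0][:, x0 + 1] * (1 - fy) * fx
        + coarse[y0 + 1][:, x0] * fy * (1 - fx)
        + coarse[y0 + 1][:, x0 + 1] * fy * fx
    )
    img += up + rng.normal(scale=noise / 3.0, size=img.shape)
    return np.clip(img, 0, 255)


def _glyph_mask(shape: str, h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if shape == "ellipse":
        return ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2 <= 1.0
    if shape == "triangle":
        # upward triangle: width grows linearly from apex to base
        frac = np.clip(yy / max(h - 1, 1), 0, 1)
        return np.abs(xx - cx) <= frac * (w / 2.0)
    if shape == "star":
        theta = np.arctan2(yy - cy, xx - cx)
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        rmax = (min(h, w) / 2.0) * (0.55 + 0.45 * np.cos(5 * theta))
        return r <= rmax
    raise ValueError(f"unknown glyph shape {shape!r}")


def _boxes_iou(a: tuple, b: tuple) -> float:
    ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def generate_scene(
    spec: SceneSpec,
    tree: TaxonomyTree,
    rng: np.random.Generator,
    image_id: str = "scene",
) -> tuple[np.ndarray, np.ndarray, SceneAnnotation]:
    """Render one scene: image, exact background mask and annotation.

    Co-occurring species come first: each rule fires with its probability and
    schedules its pest and predator; remaining slots are filled with random
    species.  Placement rejection-samples boxes to cap pairwise IoU; realized
    rules whose two participants were both placed become annotation pairs.
    """
    size = spec.image_size
    family = spec.background_families[int(rng.integers(len(spec.background_families)))]
    img = _paint_background(size, family, spec.background_noise, rng)
    bg_mask = np.ones((size, size), dtype=bool)

    lo, hi = spec.n_objects
    n_objects = int(rng.integers(lo, hi + 1))
    species_list = tree.species()

    placements: list[str] = []
    n_fired = 0
    for rule_idx in rng.permutation(len(spec.rules)):
        rule = spec.rules[rule_idx]
        if len(placements) + 2 > n_objects:
            break
        if rng.random() < rule.probability:
            placements.append(rule.pest)
            placements.append(rule.predator)
            n_fired += 1
    while len(placements) < n_objects:
        placements.append(species_list[int(rng.integers(len(species_list)))])

    boxes: list[tuple[int, int, int, int]] = []
    kept_species: list[str] = []
    for sid in placements:
        glyph = spec.glyphs[sid]
        side = int(rng.uniform(*glyph.size_range) * size)
        side = max(side, 6)
        gw = side
        gh = max(6, int(side * rng.uniform(0.7, 1.3)))
        placed = False
        for _ in range(1000):
            x1 = int(rng.integers(0, size - gw))
            y1 = int(rng.integers(0, size - gh))
            cand = (x1, y1, x1 + gw, y1 + gh)
            if all(_boxes_iou(cand, b) <= spec.max_pairwise_iou for b in boxes):
                placed = True
                break
        if not placed:
            raise PlacementError(
                "could not place all objects within 1000 rejections; "
                "reduce object sizes or counts"
            )
        mask = _glyph_mask(glyph.shape, gh, gw)
        patch = np.tile(np.array(glyph.color, dtype=np.float64), (gh, gw, 1))
        if glyph.texture_noise > 0:
            patch += rng.normal(scale=glyph.texture_noise, size=patch.shape)
        region = img[y1 : y1 + gh, x1 : x1 + gw]
        region[mask] = np.clip(patch[mask], 0, 255)
        bg_mask[y1 : y1 + gh, x1 : x1 + gw][mask] = False
        boxes.append(cand)
        kept_species.append(sid)

    # a rule is realized whenever both of its species are present in the scene,
    # whether or not its probability draw drove their placement: the relation
    # is an ecological fact about the species pair, not about the draw
    pairs = []
    for rule in spec.rules:
        if rule.pest in kept_species and rule.predator in kept_species:
            pairs.append(
                PairAnnotation(
                    CoOccurrencePair(rule.pest, rule.predator, rule.relation),
                    kept_species.index(rule.pest),
                    kept_species.index(rule.predator),
                )
            )

    annotation = SceneAnnotation(
        image_id=image_id,
        boxes=[Box(float(x1), float(y1), float(x2), float(y2)) for x1, y1, x2, y2 in boxes],
        species=kept_species,
        pairs=pairs,
    )
    return np.round(img).astype(np.uint8), bg_mask, annotation


# ---------------------------------------------------------------------------
# Dataset corpus
# ---------------------------------------------------------------------------

@dataclass
class SceneRecord:
    image: np.ndarray
    bg_mask: np.ndarray
    annotation: SceneAnnotation
    split: str


def generate_corpus(
    spec: SceneSpec,
    tree: TaxonomyTree,
    n_images: int,
    split_fracs: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> list[SceneRecord]:
    """In-memory corpus with stratified train/val/test assignment.

    Splits honor the requested fractions exactly (by count rounding); a
    repair pass then swaps images so every species present in the corpus
    also appears in the training split whenever possible.
    """
    if abs(sum(split_fracs) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_images):
        img, mask, ann = generate_scene(spec, tree, rng, image_id=f"img{i:05d}")
        scenes.append((img, mask, ann))
    n_train = int(round(split_fracs[0] * n_images))
    n_val = int(round(split_fracs[1] * n_images))
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * (n_images - n_train - n_val)
    order = rng.permutation(n_images)
    records = [
        SceneRecord(*scenes[idx], split=splits[j]) for j, idx in enumerate(order)
    ]
    # repair: every observed species should appear in train
    train_species = {s for r in records if r.split == "train" for s in r.annotation.species}
    for rec in records:
        if rec.split == "train":
            continue
        missing = set(rec.annotation.species) - train_species
        if missing:
            # swap with a train record whose species are all covered elsewhere
            for other in records:
                if other.split != "train":
                    continue
                still_covered = all(
                    any(
                        s in r2.annotation.species
                        for r2 in records
                        if r2.split == "train" and r2 is not other
                    )
                    for s in other.annotation.species
                )
                if still_covered:
                    other.split, rec.split = rec.split, other.split
                    train_species |= missing
                    break
    return records


def write_dataset(
    records: Sequence[SceneRecord],
    tree: TaxonomyTree,
    graph: KnowledgeGraph,
    out_dir,
    seed: int = 0,
) -> Path:
    """Write a corpus as PNGs + COCO-style JSON + taxonomy JSON + KG TSV."""
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    categories = [
        {
            "id": i,
            "name": tree.node(sid).name,
            "species_id": sid,
            "supercategory": tree.node(tree.node(sid).parent).name,
        }
        for i, sid in enumerate(tree.species())
    ]
    cat_index = {c["species_id"]: c["id"] for c in categories}
    images_json = []
    annotations_json = []
    cooccurrence_json = []
    ann_id = 0
    for img_idx, rec in enumerate(records):
        ann = rec.annotation
        Image.fromarray(rec.image).save(out / "images" / f"{ann.image_id}.png")
        Image.fromarray((rec.bg_mask * 255).astype(np.uint8)).save(
            out / "masks" / f"{ann.image_id}.png"
        )
        images_json.append(
            {
                "id": img_idx,
                "file_name": f"{ann.image_id}.png",
                "height": rec.image.shape[0],
                "width": rec.image.shape[1],
                "split": rec.split,
            }
        )
        box_ann_ids = []
        for box, sid in zip(ann.boxes, ann.species):
            annotations_json.append(
                {
                    "id": ann_id,
                    "image_id": img_idx,
                    "category_id": cat_index[sid],
                    "species_id": sid,
                    "bbox": [box.x1, box.y1, box.x2 - box.x1, box.y2 - box.y1],
                    "area": box.area,
                    "iscrowd": 0,
                }
            )
            box_ann_ids.append(ann_id)
            ann_id += 1
        for pair in ann.pairs:
            cooccurrence_json.append(
                {
                    "image_id": img_idx,
                    "pest_ann_id": box_ann_ids[pair.pest_box],
                    "predator_ann_id": box_ann_ids[pair.predator_box],
                    "relation": pair.pair.relation,
                }
            )
    payload = {
        "images": images_json,
        "annotations": annotations_json,
        "categories": categories,
        "cooccurrence": cooccurrence_json,
    }
    with open(out / "annotations.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    save_taxonomy(tree, out / "taxonomy.json")
    save_triples(graph, out / "kg.tsv")
    import yaml

    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"seed": seed, "n_images": len(records), "format_version": 1}, fh
        )
    return out


def read_dataset(root) -> tuple[list[SceneRecord], TaxonomyTree, KnowledgeGraph]:
    """Round-trip loader for :func:`write_dataset` output."""
    from PIL import Image

    from .knowledge_graph import load_triples
    from .taxonomy import load_taxonomy

    root = Path(root)
    tree = load_taxonomy(root / "taxonomy.json")
    graph = load_triples(root / "kg.tsv")
    for node_rank in ("order", "family", "species"):
        for node in tree.nodes_at_rank(node_rank):
            if node.id in graph.entities:
                graph.add_entity(Entity(node.id, node.name, taxon=node.id))
    with open(root / "annotations.json", "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    ann_by_image: dict[int, list[dict]] = {}
    for a in payload["annotations"]:
        ann_by_image.setdefault(a["image_id"], []).append(a)
    pairs_by_image: dict[int, list[dict]] = {}
    for c in payload["cooccurrence"]:
        pairs_by_image.setdefault(c["image_id"], []).append(c)
    records = []
    for img_rec in payload["images"]:
        img = np.asarray(Image.open(root / "images" / img_rec["file_name"]))
        mask = np.asarray(Image.open(root / "masks" / img_rec["file_name"])) > 0
        anns = sorted(ann_by_image.get(img_rec["id"], []), key=lambda a: a["id"])
        ann_pos = {a["id"]: i for i, a in enumerate(anns)}
        boxes = [
            Box(a["bbox"][0], a["bbox"][1], a["bbox"][0] + a["bbox"][2], a["bbox"][1] + a["bbox"][3])
            for a in anns
        ]
        species = [a["species_id"] for a in anns]
        pairs = []
        for c in pairs_by_image.get(img_rec["id"], []):
            p_idx = ann_pos[c["pest_ann_id"]]
            e_idx = ann_pos[c["predator_ann_id"]]
            pairs.append(
                PairAnnotation(
                    CoOccurrencePair(species[p_idx], species[e_idx], c["relation"]),
                    p_idx,
                    e_idx,
                )
            )
        records.append(
            SceneRecord(
                image=img,
                bg_mask=mask,
                annotation=SceneAnnotation(
                    image_id=Path(img_rec["file_name"]).stem,
                    boxes=boxes,
                    species=species,
                    pairs=pairs,
                ),
                split=img_rec.get("split", "train"),
            )
        )
    return records, tree, graph


def generate_dataset(
    spec: SceneSpec,
    tree: TaxonomyTree,
    graph: KnowledgeGraph,
    n_images: int,
    out_dir,
    split_fracs: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> Path:
    """Generate a corpus and write it to disk in one call."""
    records = generate_corpus(spec, tree, n_images, split_fracs, seed)
    return write_dataset(records, tree, graph, out_dir, seed=seed)
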