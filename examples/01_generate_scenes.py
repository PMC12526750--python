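"""Generate a synthetic pest-predator scene corpus and inspect one scene.

Builds a small balanced taxonomy (2 orders, 6 species: 4 pests + 2 natural
predators), a knowledge graph with predation links, and renders one annotated
scene: an RGB image of colored glyphs on a textured background, its exact
background mask, bounding boxes with species labels and the realized
pest-predator co-occurrence pairs.
"""

import numpy as np

from ecotree import (
    generate_kg,
    generate_scene,
    generate_taxonomy,
    label_path,
    separable_spec,
)

tree = generate_taxonomy(n_orders=2, n_families_per_order=1, n_species_per_family=3, seed=0)
graph = generate_kg(tree, predation_density=0.5, seed=0)
spec = separable_spec(tree, graph, seed=0)

print(f"taxonomy: {len(tree)} nodes, {len(tree.species('pest'))} pests, "
      f"{len(tree.species('predator'))} predators")
print(f"knowledge graph: {graph.n_triples} triples "
      f"({sum(1 for k in graph.triples if k[1] == 'predation')} predation)")

image, bg_mask, ann = generate_scene(spec, tree, np.random.default_rng(42))
print(f"\nscene: {image.shape[1]}x{image.shape[0]} RGB, "
      f"{100 * (1 - bg_mask.mean()):.1f}% foreground pixels")
for box, sid in zip(ann.boxes, ann.species):
    names = " > ".join(tree.node(n).name for n in label_path(tree, sid))
    print(f"  box ({box.x1:.0f},{box.y1:.0f})-({box.x2:.0f},{box.y2:.0f})  {names}")
for p in ann.pairs:
    print(f"  pair: {tree.node(p.pair.pest).name} --{p.pair.relation}--> "
          f"{tree.node(p.pair.predator).name}")

# Each box is one organism; the pair lines are the expert-style co-occurrence
# annotations the relation head learns to reproduce.
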