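"""Taxonomy-constrained hierarchical decoding with prompts.

Decoding runs three rounds — order, family, species — and at each round only
the children of the previous decision are candidates, so every decoded path
is a valid walk of the taxonomy.  A noisy scorer shows why self-consistency
(sampling several paths and voting) stabilizes the output.
"""

import numpy as np

from ecotree import (
    decode_path,
    generate_taxonomy,
    label_path,
    render_prompt,
    self_consistency_decode,
    validate_path,
)
from ecotree.taxonomy import candidate_set

tree = generate_taxonomy(2, 2, 2, seed=3)
target = tree.species()[0]
truth = label_path(tree, target)
print("true path:", " > ".join(tree.node(n).name for n in truth))

# the prompt a text-capable scorer would see at round 1
names = [tree.node(c).name for c in candidate_set(tree, 1)]
print("\nround-1 prompt:")
print(" ", render_prompt(1, names))


def noisy_scorer(x, level, candidates, prefix):
    """Mass 0.7 on the true branch, the rest spread uniformly."""
    rng = np.random.default_rng([x, level, len(candidates)])
    logp = np.full(len(candidates), np.log(0.3 / max(len(candidates) - 1, 1)))
    want = truth[level - 1]
    if want in candidates:
        logp[list(candidates).index(want)] = np.log(0.7)
    else:
        logp[0] = np.log(0.7)
    return logp + rng.normal(scale=0.05, size=len(candidates))


greedy = decode_path(noisy_scorer, 0, tree)
voted = self_consistency_decode(noisy_scorer, 0, tree, k=7, temperature=1.0, seed=1)
print("\ngreedy decode:", " > ".join(tree.node(n).name for n in greedy.path),
      f"(log-prob {greedy.total_log_prob:.2f})")
print("self-consistent (k=7):", " > ".join(tree.node(n).name for n in voted.path))
print("both structurally valid:",
      validate_path(tree, greedy.path) and validate_path(tree, voted.path))

# Constrained decoding guarantees the path exists in the taxonomy even when
# individual level scores are noisy; the vote picks the modal full path.
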