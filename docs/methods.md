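# Methods

This note records what the package computes, the assumptions behind each
component, the defaults and why they were chosen, and what the synthetic
benchmark does and does not establish.

## Recognition model

A scene is a set of annotated boxes, each holding one organism from a
three-rank taxonomy (order → family → species); species carry an ecological
role, pest or natural predator. The recognizer answers two questions per
scene: the taxonomic path of every box, and the typed co-occurrence
relations (predation / cohabitation / competition) among the (pest,
predator) box pairs.

### Backbone and region features

The visual backbone is a four-stage windowed self-attention network:
4×4 linear patch embedding, then per stage two blocks of (pre-norm window
attention + two-layer MLP) and a 2×2 patch-merging downsample. Stage
resolutions follow input/4, /8, /16, /32 — 56/28/14/7 at a 224 input — with
channels doubling from `base_channels`. Two presets exist: the desk-scale
default (16 base channels, heads 1/2/4/8) and a full-width configuration
(96 channels, heads 3/6/12/24) selectable via `AttentionConfig.swin_tiny()`.
Biases are zero and normalization is offset-free, so the network is linear
at the origin (an all-zero image maps to all-zero features) — a cheap
sanity anchor used in the tests.

The backbone runs with **frozen seeded random weights** as a deterministic
feature extractor; only the decoding scorer and the relation head train.
This is the central desk-scale design decision: random windowed-attention
features preserve enough local appearance for a small head to classify
well-separated species, training stays within seconds on one CPU, and every
result is exactly reproducible from the seed. Nothing in the API precludes
swapping in a pretrained or trainable backbone; the attention operations
expose analytic contracts (see below) that are independent of where the
features come from.

A region feature concatenates three RoI-aligned views of a box: the
center-pooled patch-embedding tokens (the stem is linear in pixels, so
object color survives background bleed; the box center is glyph-dominated),
the box-pooled stem, and the box-pooled stage-1 attention features.
RoI alignment uses a 7×7 grid with 2×2 bilinear samples per bin on
continuous, half-open box coordinates. Features are standardized by the
training-split mean and deviation before any head sees them.

### Knowledge injection

The knowledge graph holds typed triples over entities that may link to
taxonomy nodes. Entity embeddings come from `n_layers = 2` rounds of
symmetric-normalized graph convolution (self-loops included, tanh
nonlinearity, seeded random weights) over features made of a per-entity
seeded normal vector plus relation incidence counts; two layers are the
smallest configuration that mixes two-hop ecology (pest–crop–predator
motifs). `d_k = 64` by default, 32 in the training pipeline. Initial
features key on the entity id (via a stable CRC hash), which makes the
embedding independent of enumeration order.

Four injection mechanisms, each with an exact switch-off limit that the
acceptance tests pin:

- **KV-guided attention**: a query attends over projected entity embeddings
  with softmax scale √d, d the projected key dimension.
- **Hierarchical fusion**: per taxonomy level, a residual attention over
  that level's knowledge view (entities grouped under their depth-l
  ancestors, one mean vector per group). Missing views degrade to identity.
- **Query offset** q̃ = q + μ·tanh(W K + b): the tanh bounds every
  coordinate of the shift by |μ|, so knowledge influence is controllable;
  μ initializes at 0 (the model starts purely visual).
- **Co-occurrence bias**: region-pair logits gain η·log(1 + w) where w is
  the symmetric max-confidence of ecological triples between the regions'
  entities. The additive log-domain form keeps softmax normalization and is
  exactly identity at η = 0 or w ≡ 0.

Graph completion trains translational embeddings (h + r ≈ t) by margin
ranking (margin 1.0, uniform head/tail corruption, per-epoch entity
renormalization), scores absent candidates by −‖h + r − t‖, calibrates
scores to (0, 1) with a sigmoid centered on the median and scaled by the
deviation of the asserted triples' scores, adds candidates at or above the
confidence threshold (default 0.9), and prunes additions below the floor
(default 0.5). Asserted triples are never pruned.

### Decoding

Decoding is three rounds of argmax over the candidate sets the taxonomy
induces: all orders at level 1, then the children of each decision. Ties
break to the lexicographically first candidate (candidate sets are ordered
by name), so decoding is deterministic. Because candidates are tree
children, every decoded path validates structurally — consistency is a
guarantee, not a penalty. Self-consistency decoding samples k paths at
temperature T (per-level softmax of log-probabilities over T) and returns
the modal whole path, ties to the highest cumulative log-probability;
defaults k = 5, T = 1.0, and (k = 1, T = 0) reduces exactly to greedy. The
vote is over whole paths rather than per-level, which keeps the winner a
valid path by construction. A memoizing prefix cache makes the repeated
(feature, prefix) queries of sampling cost one scorer call each.

The scorer is a contract: log-softmax scores over the candidate set given
the region feature and the decoded prefix. The bundled implementation is a
one-hidden-layer tanh classifier over [feature ; mean prefix embedding]
with fixed seeded prefix vectors; prompts for text-capable scorers are
rendered from a fixed template with the decoded ancestors appended as
context lines.

### Losses

- Tree-path penalty: Σ_i 1[ŷ_i ≠ y_i]·δ(i) with δ(i) = i by default
  (δ(i) = i/3 available); used as an evaluation penalty and optional
  auxiliary term (weight `lambda_tree`, default 0, hence off).
- Classification: per-level cross-entropy of the full candidate
  distribution.
- Embedding alignment: squared distance between the knowledge embeddings of
  the argmax and true labels per level. Labels embed via the KG: species
  take their entity vectors, order/family nodes the mean of their
  descendant species. The table is frozen (reference geometry, no
  gradient). Argmax labels, not expectations, feed the term, matching its
  discrete definition; the pipeline consequently treats it as a monitored
  quantity and backpropagates through the cross-entropy term.
- Relation consistency: 1 − cos between predicted and reference relation
  embeddings, in [0, 2].
- Total: λ₁·⟨L_cls⟩_N + λ₂·⟨L_embed⟩_N + λ₃·⟨L_rel⟩_M with defaults
  λ₁ = 1.0, λ₂ = 0.5, λ₃ = 0.5. The two aggregation conventions in
  circulation — averaged and unnormalized sums — disagree; this package
  averages so that batch size does not rescale the objective, and zeroed-out
  λ terms report as exactly 0 in the breakdown. M = 0 contributes 0.

### Relation head and pair prediction

The relation head is a small tanh MLP mapping a pair of **species
posteriors** (the scorer's flat distribution over species for each box) to
a relation embedding, trained with the cosine loss toward the reference
relation vectors and decoded by nearest-cosine among
{predation, cohabitation, competition, none}. Conditioning on the
recognition output rather than raw appearance is deliberate: an ecological
relation is a fact about the species pair, not about a particular image
crop, so routing prediction through the class posterior is what makes it
generalize across scenes (and mirrors the conditional path-to-graph
guidance of the fusion design). Supervision enumerates all ordered
(pest, predator) box pairs per image: annotated species pairs carry their
relation, the rest are `none` negatives. A training-free alternative reads
relations straight from the KG's ecological triples (`pair_source="kg"`),
which is the structural-prior ceiling used in tests.

### Metrics

mAP@50 follows detection practice: per class, detections sort by descending
score (insertion order on ties) and greedily claim the highest-IoU
unmatched truth in their image, counting as true positives at IoU ≥ 0.5; AP
integrates the monotone envelope of the precision–recall curve (all-points
interpolation, the modern convention; an 11-point flag exists). Classes
with detections but no ground truth contribute false positives without
being averaged as classes. H-Acc defaults to node mode — the fraction of
correct nodes along the path — because that is the more informative of the
two definitions in circulation; the strict whole-path indicator is kept as
a mode and never exceeds node mode. C-Acc defaults to exact per-image
pair-set equality with relation labels included (pair-level micro-averaging
and relation-free equality are flags). Precision/recall use the 0/0 → 0
convention. The pipeline evaluates on ground-truth boxes by default, so
mAP@50 isolates recognition quality from box-proposal quality; a detection
head is out of scope.

## Augmentation and text normalization

Background perturbation applies clip(α·I + β, 0, 255) to masked background
pixels only, α ∈ [0.7, 1.3], β ∈ [−20, 20]. Occlusion paints a rectangle or
inscribed ellipse covering 2–15 % of the image a uniform random color.
Local deformation inverse-warps a rectangular region under x' = Ax + t with
bilinear interpolation, A within ±0.2 of identity, |t| ≤ 10 px;
out-of-region source samples clamp to the region boundary, and forward
splatting was rejected because it leaves holes. Each stage gates on its own
probability (default 0.5 each — the stage-gating probabilities are
otherwise unspecified, and 0.5 exercises all code paths evenly); pixels are
8-bit with saturating clip, and a fixed seed reproduces output
byte-for-byte. Elastic (non-affine) deformation is not implemented: no
parameterization is defined for it, and the affine family already covers
pose/scale jitter.

Text cleaning applies an ordered, versioned rule list — strip control
characters and emoji, collapse repeated punctuation, collapse whitespace —
and is idempotent and length-non-increasing. Entity normalization scans the
cleaned text with case-insensitive longest-match lookup against a synonym
dictionary whose values are fixed points; unmatched mentions drop. A
learned NER model is intentionally out of scope — the dictionary path is
the testable core, and dictionary construction is where domain authority
(GBIF-style checklists) lives.

## Synthetic benchmark

The generator emulates the schema of a field dataset: multi-object RGB
scenes, three-rank labels, expert-style typed pairs, exact background
masks. The default taxonomy preset is 60 species (40 pests, 20 predators)
in 4 orders × 3 families × 5 species; the training benchmark scales down to
6 species over 2 orders with 200 scenes of 96×96 px, 2–5 objects each,
split 70/10/20 with a repair pass guaranteeing every observed species
appears in training. Species are parametric glyphs (ellipse / triangle /
star by family) with hue-equispaced colors; the co-occurrence rule table is
derived from the KG's predation/cohabitation triples, and a rule is
*realized* in a scene whenever both its species are present, whether or not
its probability draw drove the placement — the relation is a property of
the species pair. Placement rejection-samples boxes up to 1000 times
against a pairwise-IoU cap.

Two presets: `separable` (flat colors, disjoint boxes, no occlusion, rules
fire surely) and `hard` (texture noise σ = 18, background noise σ = 12,
occlusion, scale jitter, rules fire at 0.7). The separable preset is a
*sanity anchor*, not a claim about field data: a nearest-centroid on mean
glyph color already separates its species perfectly, so passing the
end-to-end bars (node H-Acc ≥ 0.90, image C-Acc ≥ 0.80 after 10 epochs)
shows the pipeline's plumbing — features, constrained decoding, pair
supervision, metrics — is sound, not that the method would reach such
numbers on real imagery. What the generator does not emulate: natural image
statistics, intra-species appearance variation, class imbalance, infrared
modality, annotation noise.

## Numerical choices

- Softmax computations subtract the row max before exponentiation.
- Attention scale is √(projected key dimension).
- Relation-cosine gradients nudge a numerically zero prediction off the
  undefined point rather than raising mid-training.
- Window attention pads feature maps with zeros to a window multiple and
  crops after; windows never mix across the pad boundary's unpadded side.
- Optimization is Adam (β₁ = 0.9, β₂ = 0.999) at 1e−3 for the scorer and
  3e−3 with 3 passes/epoch for the relation head — the cosine objective
  converges slower than cross-entropy and the pair set is smaller, so it
  gets more passes at a higher rate.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-entity streams derive from CRC32 of the
  id, keeping every artifact reproducible across processes and platforms at
  identical numpy versions.

## Limitations

- The backbone is frozen; end-to-end gradient training of the attention
  stack is out of scope (gradient-finiteness of each operation is verified
  numerically, so a future trainable path has no analytic obstruction).
- Detection boxes are taken as given; no proposal network or box
  regression.
- The relation head sees species posteriors only; context beyond class
  identity (spatial arrangement, counts) is not used.
- KG completion uses a single translational model; rotational or bilinear
  scorers are not implemented.
- Synthetic difficulty is a knob, not a calibration against any real
  dataset.
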