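"""The alignment losses and the hierarchical/co-occurrence metrics.

Evaluates the combined objective on a tiny hand-built batch, then scores a
small prediction set with the metric suite: precision/recall/F1, IoU and
mAP@50, hierarchical accuracy (node and strict) and co-occurrence accuracy.
"""

import numpy as np

from ecotree import (
    Box,
    CoOccurrencePair,
    Detection,
    LabelPath,
    LossWeights,
    c_acc,
    h_acc,
    iou,
    map50,
    total_loss,
    tree_path_loss,
)

truth = LabelPath(("o1", "f1", "s1"))
embed = {k: v.astype(float) for k, v in {
    "o1": np.array([0, 0]), "f1": np.array([0, 1]),
    "s1": np.array([2, 0]), "s2": np.array([2, 1]),
}.items()}
probs = [{"o1": 1.0}, {"f1": 1.0}, {"s1": 0.4, "s2": 0.6}]  # wrong at species
relation_vecs = {"predation": np.array([1.0, 0.0]), "none": np.array([0.0, 1.0])}
pair_pred = (np.array([0.9, 0.1]), "predation")

breakdown = total_loss([probs], [truth], embed,
                       pair_predictions=[pair_pred],
                       relation_vectors=relation_vecs,
                       weights=LossWeights(lambda1=1.0, lambda2=0.5, lambda3=0.5))
print(f"L_cls   = {breakdown.L_cls:.4f}   (cross-entropy of the true path)")
print(f"L_embed = {breakdown.L_embed:.4f}   (distance k(s2)->k(s1) for the wrong argmax)")
print(f"L_rel   = {breakdown.L_rel:.4f}   (1 - cos to the predation vector)")
print(f"total   = {breakdown.total:.4f}")
print(f"tree-path penalty of the argmax path: "
      f"{tree_path_loss(('o1', 'f1', 's2'), truth):.0f}  (species level, delta(3)=3)")

# metrics on a two-image toy evaluation
pred_paths = [("o1", "f1", "s2"), ("o1", "f1", "s1")]
true_paths = [truth.labels, truth.labels]
print(f"\nH-Acc node   = {h_acc(pred_paths, true_paths, 'node'):.3f}")
print(f"H-Acc strict = {h_acc(pred_paths, true_paths, 'strict'):.3f}")

a, b = Box(0, 0, 10, 10), Box(5, 5, 15, 15)
print(f"IoU of offset boxes = {iou(a, b):.4f}  (25 overlap / 175 union)")
dets = [[Detection(a, 0.9, "s1")]]
print(f"mAP@50 single hit  = {map50(dets, [[(a, 's1')]]):.1f}")

pairs_pred = [{CoOccurrencePair('s1', 'e1', 'predation')}]
pairs_true = [{CoOccurrencePair('s1', 'e1', 'predation')}]
print(f"C-Acc image mode   = {c_acc(pairs_pred, pairs_true, 'image'):.1f}")
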