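"""Detection and ecological-reasoning metrics.

Beyond the standard detection quartet (precision, recall, F1, mAP@50 with
greedy IoU >= 0.5 matching and all-points PR interpolation), two metrics are
specific to hierarchical ecological recognition:

* **H-Acc** — agreement between predicted and true taxonomy paths.  The
  default "node" mode scores the proportion of correct nodes along the
  order->family->species path; "strict" mode scores whole-path equality.
  Strict never exceeds node.
* **C-Acc** — agreement between predicted and true pest-predator
  co-occurrence pair sets per image.  The default "image" mode requires
  exact set equality (relations included); "pair" mode micro-averages
  matched pairs over the union.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .taxonomy import CoOccurrencePair, LabelPath


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class Box:
    """An axis-aligned box on half-open pixel coordinates [x1,x2) x [y1,y2)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise MetricError(f"box must have positive area: {self}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


@dataclass(frozen=True)
class Detection:
    box: Box
    score: float
    species: str
    path: LabelPath | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.score) and 0.0 <= self.score <= 1.0):
            raise MetricError(f"score must be finite in [0,1], got {self.score}")


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    f1: float
    map50: float
    h_acc: float
    c_acc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "map50": self.map50,
            "h_acc": self.h_acc,
            "c_acc": self.c_acc,
        }


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 their harmonic mean; 0/0 -> 0."""
    if min(tp, fp, fn) < 0:
        raise MetricError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union on continuous coordinates, in [0, 1]."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def _average_precision(matches: list[tuple[float, int, bool]], n_truth: int, all_points: bool) -> float:
    """AP from (score, order, is_tp) records under the chosen interpolation."""
    if n_truth == 0:
        return 0.0
    matches = sorted(matches, key=lambda m: (-m[0], m[1]))  # score desc, insertion order
    tps = np.cumsum([m[2] for m in matches])
    fps = np.cumsum([not m[2] for m in matches])
    recall = tps / n_truth
    precision = tps / (tps + fps)
    if all_points:
        # monotone envelope, integrate over recall steps
        mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
        mpre = np.concatenate([[0.0], precision, [0.0]])
        for i in range(len(mpre) - 2, -1, -1):
            mpre[i] = max(mpre[i], mpre[i + 1])
        idx = np.where(mrec[1:] != mrec[:-1])[0]
        return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    # legacy 11-point interpolation
    ap = 0.0
    for r in np.linspace(0, 1, 11):
        mask = recall >= r
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / 11.0


def map50(
    detections: Sequence[Sequence[Detection]],
    truths: Sequence[Sequence[tuple[Box, str]]],
    iou_threshold: float = 0.5,
    all_points: bool = True,
) -> float:
    """Mean average precision at IoU >= 0.5 over classes with ground truth.

    Per class, detections sort by descending score (insertion order on ties)
    and greedily claim the highest-IoU unmatched same-class truth in their
    image; a claim below the IoU threshold is a false positive.  Classes that
    are only predicted, never annotated, contribute false positives but are
    not averaged as classes.
    """
    if len(detections) != len(truths):
        raise MetricError("detections and truths must cover the same images")
    truth_classes = {cls for per_img in truths for _box, cls in per_img}
    per_class_matches: dict[str, list[tuple[float, int, bool]]] = defaultdict(list)
    per_class_truth_n: dict[str, int] = defaultdict(int)
    for per_img in truths:
        for _box, cls in per_img:
            per_class_truth_n[cls] += 1

    # flatten detections per class preserving (image, insertion) order
    flat: dict[str, list[tuple[float, int, int, Detection]]] = defaultdict(list)
    counter = 0
    for img_idx, per_img in enumerate(detections):
        for det in per_img:
            flat[det.species].append((det.score, counter, img_idx, det))
            counter += 1

    for cls, dets in flat.items():
        dets = sorted(dets, key=lambda d: (-d[0], d[1]))
        matched: set[tuple[int, int]] = set()  # (image, truth index)
        for score, order, img_idx, det in dets:
            candidates = [
                (iou(det.box, tbox), t_idx)
                for t_idx, (tbox, tcls) in enumerate(truths[img_idx])
                if tcls == cls and (img_idx, t_idx) not in matched
            ]
            best = max(candidates, default=(0.0, -1))
            is_tp = best[0] >= iou_threshold
            if is_tp:
                matched.add((img_idx, best[1]))
            per_class_matches[cls].append((score, order, is_tp))

    if not truth_classes:
        return 0.0
    aps = [
        _average_precision(per_class_matches.get(cls, []), per_class_truth_n[cls], all_points)
        for cls in sorted(truth_classes)
    ]
    return float(np.mean(aps))


def h_acc(
    pred_paths: Sequence[LabelPath | Sequence[str]],
    true_paths: Sequence[LabelPath | Sequence[str]],
    mode: str = "node",
) -> float:
    """Hierarchical accuracy over label paths.

    ``node`` mode: mean fraction of the three levels predicted correctly.
    ``strict`` mode: mean whole-path indicator.  Strict <= node always.
    """
    if mode not in ("node", "strict"):
        raise MetricError(f"unknown H-Acc mode {mode!r}")
    if len(pred_paths) != len(true_paths):
        raise MetricError("prediction and truth counts differ")
    if not pred_paths:
        return 0.0
    total = 0.0
    for pred, truth in zip(pred_paths, true_paths):
        p = tuple(pred.labels) if isinstance(pred, LabelPath) else tuple(pred)
        t = tuple(truth.labels) if isinstance(truth, LabelPath) else tuple(truth)
        if len(p) != 3 or len(t) != 3:
            raise MetricError("paths must have exactly 3 levels")
        if mode == "node":
            total += sum(a == b for a, b in zip(p, t)) / 3.0
        else:
            total += 1.0 if p == t else 0.0
    return total / len(pred_paths)


def _pair_key(pair: CoOccurrencePair, with_relations: bool):
    return (pair.pest, pair.predator, pair.relation if with_relations else None)


def c_acc(
    pred_pairs: Sequence[Iterable[CoOccurrencePair]],
    true_pairs: Sequence[Iterable[CoOccurrencePair]],
    mode: str = "image",
    with_relations: bool = True,
) -> float:
    """Co-occurrence accuracy over per-image pair sets.

    ``image`` mode scores exact set equality per image (relation labels
    included unless ``with_relations=False``); ``pair`` mode micro-averages
    ``|matched| / |union|`` over all images.
    """
    if mode not in ("image", "pair"):
        raise MetricError(f"unknown C-Acc mode {mode!r}")
    if len(pred_pairs) != len(true_pairs):
        raise MetricError("image counts differ")
    if not true_pairs:
        return 0.0
    if mode == "image":
        hits = 0
        for pred, truth in zip(pred_pairs, true_pairs):
            ps = {_pair_key(p, with_relations) for p in pred}
            ts = {_pair_key(t, with_relations) for t in truth}
            hits += ps == ts
        return hits / len(true_pairs)
    matched = 0
    union = 0
    for pred, truth in zip(pred_pairs, true_pairs):
        ps = {_pair_key(p, with_relations) for p in pred}
        ts = {_pair_key(t, with_relations) for t in truth}
        matched += len(ps & ts)
        union += len(ps | ts)
    return matched / union if union else 1.0
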