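"""Tree-guided hierarchical decoding: constrained argmax paths over the taxonomy.

Decoding runs three rounds, one per taxonomy level.  Round ``i`` scores only
the candidate set reachable from the level-``i-1`` decision (children of the
decoded parent), so every decoded path is a valid order->family->species walk
by construction — hierarchical consistency is structural, not penalized.

The scorer is a pluggable contract (a conditional distribution over the
candidate set given the region feature and the decoded prefix); the bundled
:class:`ConditionalLevelScorer` is a small trainable classifier over region
features concatenated with a prefix embedding.  A large vision-language
backbone honoring the same contract can be dropped in unchanged.

Self-consistency decoding samples several paths at a temperature and returns
the modal one, which damps single-level scoring noise; a shared prefix cache
makes the repeated level queries cheap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .taxonomy import LabelPath, TaxonomyTree, candidate_set, validate_path

PROMPT_TEMPLATE = (
    "A target has been detected. Please identify its category at the "
    "{level} from the candidates: {candidates}"
)


class DecodingError(RuntimeError):
    pass


class LevelScorer(Protocol):
    """Contract: log-probabilities over a candidate set, given feature and prefix.

    Implementations must return one finite log-score per candidate,
    log-softmax-normalized over the candidate set.
    """

    def __call__(
        self,
        x: np.ndarray,
        level: int,
        candidates: Sequence[str],
        prefix: tuple[str, ...],
    ) -> np.ndarray: ...


@dataclass(frozen=True)
class DecodedPath:
    """A decoded label path with its per-level and total log-probabilities."""

    path: LabelPath
    level_scores: tuple[float, float, float]
    total_log_prob: float

    def __post_init__(self) -> None:
        if not np.isclose(self.total_log_prob, sum(self.level_scores)):
            raise DecodingError("total log-prob must equal the sum of level scores")


def decode_level(scores: np.ndarray, candidates: Sequence[str]) -> str:
    """Argmax over a candidate set; exact ties go to the earliest candidate.

    Candidate order comes from :func:`ecotree.taxonomy.candidate_set`
    (lexicographic by name), which makes tie-breaking deterministic.
    """
    if len(candidates) == 0:
        raise DecodingError("empty candidate set")
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(candidates),):
        raise DecodingError(
            f"scores shape {scores.shape} does not match {len(candidates)} candidates"
        )
    return candidates[int(np.argmax(scores))]


def _level_candidates(tree: TaxonomyTree, level: int, prefix: tuple[str, ...]) -> list[str]:
    try:
        return candidate_set(tree, level, prefix[-1] if level > 1 else None)
    except Exception:
        # corrupted tree: fall back to every node of the level
        import logging

        logging.getLogger(__name__).warning(
            "no candidates under %s at level %d; falling back to all nodes", prefix, level
        )
        from .taxonomy import RANKS

        return [n.id for n in tree.nodes_at_rank(RANKS[level - 1])]


def decode_path(scorer: LevelScorer, x: np.ndarray, tree: TaxonomyTree) -> DecodedPath:
    """Greedy constrained decoding: three rounds of argmax over tree children."""
    if len(tree) == 0:
        raise DecodingError("cannot decode against an empty taxonomy")
    prefix: tuple[str, ...] = ()
    level_scores = []
    for level in (1, 2, 3):
        candidates = _level_candidates(tree, level, prefix)
        try:
            scores = np.asarray(scorer(x, level, candidates, prefix), dtype=np.float64)
        except Exception as exc:
            raise DecodingError(f"scorer failed at level {level} (prefix {prefix})") from exc
        chosen = decode_level(scores, candidates)
        level_scores.append(float(scores[candidates.index(chosen)]))
        prefix = prefix + (chosen,)
    path = LabelPath(prefix)  # type: ignore[arg-type]
    assert validate_path(tree, path), "constrained decoding produced an invalid path"
    return DecodedPath(path, tuple(level_scores), float(sum(level_scores)))


def self_consistency_decode(
    scorer: LevelScorer,
    x: np.ndarray,
    tree: TaxonomyTree,
    k: int = 5,
    temperature: float = 1.0,
    seed: int = 0,
) -> DecodedPath:
    """Sample ``k`` paths at a temperature and return the modal one.

    Per level, candidates are drawn from ``softmax(log p / T)``; ``T -> 0``
    (or ``T = 0`` exactly) collapses sampling to argmax, so ``k = 1, T = 0``
    reproduces :func:`decode_path`.  Ties between equally frequent paths go to
    the highest cumulative log-probability.
    """
    if k < 1:
        raise DecodingError("k must be >= 1")
    if temperature <= 0.0:
        return decode_path(scorer, x, tree)
    rng = np.random.default_rng(seed)
    scorer = prefix_cache(scorer)
    samples: list[DecodedPath] = []
    for _ in range(k):
        prefix: tuple[str, ...] = ()
        level_scores = []
        for level in (1, 2, 3):
            candidates = _level_candidates(tree, level, prefix)
            logp = np.asarray(scorer(x, level, candidates, prefix), dtype=np.float64)
            z = logp / temperature
            z -= z.max()
            p = np.exp(z)
            p /= p.sum()
            idx = int(rng.choice(len(candidates), p=p))
            level_scores.append(float(logp[idx]))
            prefix = prefix + (candidates[idx],)
        samples.append(
            DecodedPath(LabelPath(prefix), tuple(level_scores), float(sum(level_scores)))  # type: ignore[arg-type]
        )
    counts = Counter(s.path.labels for s in samples)
    top = max(counts.values())
    modal = [s for s in samples if counts[s.path.labels] == top]
    return max(modal, key=lambda s: s.total_log_prob)


def render_prompt(
    level: int,
    candidates: Sequence[str],
    prefix: Sequence[str] = (),
    rank_names: Sequence[str] = ("order", "family", "species"),
) -> str:
    """Render the structured identification prompt for one decoding round.

    Decoded ancestors are appended as context lines for levels beyond the
    first.  The template is fixed; scorers that consume text see identical
    prompts across runs.
    """
    text = PROMPT_TEMPLATE.format(
        level=rank_names[level - 1], candidates=", ".join(candidates)
    )
    for rank, name in zip(rank_names, prefix):
        text += f"\nContext: the {rank} was identified as {name}."
    return text


def prefix_cache(scorer: LevelScorer) -> "CachedScorer":
    """Memoize scorer calls per (feature, level, prefix).

    Transparent for pure scorers: identical queries return the cached scores,
    so self-consistency sampling pays for each distinct prefix once.
    """
    if isinstance(scorer, CachedScorer):
        return scorer
    return CachedScorer(scorer)


class CachedScorer:
    def __init__(self, scorer: LevelScorer):
        self._scorer = scorer
        self._cache: dict[tuple, np.ndarray] = {}
        self.calls = 0  # underlying scorer invocations, for cache diagnostics

    def __call__(self, x, level, candidates, prefix):
        key = (id(x) if isinstance(x, np.ndarray) else x, level, tuple(candidates), tuple(prefix))
        if key not in self._cache:
            self.calls += 1
            self._cache[key] = np.asarray(self._scorer(x, level, candidates, prefix))
        return self._cache[key]


# ---------------------------------------------------------------------------
# Default trainable scorer
# ---------------------------------------------------------------------------

class ConditionalLevelScorer:
    """Small conditional classifier implementing the :class:`LevelScorer` contract.

    One hidden tanh layer maps ``[region feature ; prefix embedding]`` to a
    logit per node; scores at a query are the log-softmax of the candidate
    logits.  Prefix embeddings are fixed seeded vectors per node id, so the
    same parent decision always conditions the lower level the same way.
    Training (see :mod:`ecotree.pipeline`) uses hand-derived softmax
    cross-entropy gradients with Adam.
    """

    def __init__(
        self,
        d_feature: int,
        node_ids: Sequence[str],
        d_prefix: int = 8,
        d_hidden: int = 64,
        seed: int = 0,
    ):
        self.node_ids = sorted(node_ids)
        self.node_index = {n: i for i, n in enumerate(self.node_ids)}
        rng = np.random.default_rng(seed)
        d_in = d_feature + d_prefix
        self.prefix_vectors = {
            n: np.random.default_rng([seed, 7, i]).normal(size=d_prefix)
            for i, n in enumerate(self.node_ids)
        }
        self.empty_prefix = np.zeros(d_prefix)
        self.W1 = rng.normal(scale=1.0 / np.sqrt(d_in), size=(d_in, d_hidden))
        self.b1 = np.zeros(d_hidden)
        self.W2 = rng.normal(scale=1.0 / np.sqrt(d_hidden), size=(d_hidden, len(self.node_ids)))
        self.b2 = np.zeros(len(self.node_ids))

    # -- forward pieces -------------------------------------------------------

    def _embed_prefix(self, prefix: Sequence[str]) -> np.ndarray:
        if not prefix:
            return self.empty_prefix
        return np.mean([self.prefix_vectors[p] for p in prefix], axis=0)

    def _forward(self, x: np.ndarray, prefix: Sequence[str]):
        inp = np.concatenate([np.asarray(x, dtype=np.float64), self._embed_prefix(prefix)])
        hidden = np.tanh(inp @ self.W1 + self.b1)
        logits = hidden @ self.W2 + self.b2
        return inp, hidden, logits

    def __call__(self, x, level, candidates, prefix) -> np.ndarray:
        _, _, logits = self._forward(x, prefix)
        idx = [self.node_index[c] for c in candidates]
        sub = logits[idx]
        sub = sub - sub.max()
        return sub - np.log(np.exp(sub).sum())

    # -- training -------------------------------------------------------------

    def grad_step_data(self, x: np.ndarray, candidates: Sequence[str], truth: str, prefix):
        """Cross-entropy value and parameter gradients for one level decision."""
        inp, hidden, logits = self._forward(x, prefix)
        idx = [self.node_index[c] for c in candidates]
        sub = logits[idx] - logits[idx].max()
        p = np.exp(sub)
        p /= p.sum()
        t = candidates.index(truth)
        loss = -float(np.log(max(p[t], 1e-300)))
        dlogits = np.zeros_like(logits)
        dsub = p.copy()
        dsub[t] -= 1.0
        for j, full_idx in enumerate(idx):
            dlogits[full_idx] = dsub[j]
        dW2 = np.outer(hidden, dlogits)
        db2 = dlogits
        dhidden = self.W2 @ dlogits
        dpre = dhidden * (1.0 - hidden**2)
        dW1 = np.outer(inp, dpre)
        db1 = dpre
        return loss, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}


def oracle_scorer(truth_paths: dict) -> LevelScorer:
    """A perfect scorer for testing ceilings: probability 1 on the true node.

    ``truth_paths`` maps a hashable region key (passed as the feature) to its
    true :class:`~ecotree.taxonomy.LabelPath`.
    """

    def score(x, level, candidates, prefix):
        truth = truth_paths[x if not isinstance(x, np.ndarray) else x.tobytes()]
        target = truth[level - 1]
        out = np.full(len(candidates), -1e9)
        if target in candidates:
            out[list(candidates).index(target)] = 0.0
        return out

    return score
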