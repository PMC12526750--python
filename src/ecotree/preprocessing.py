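"""Image augmentation and ecological-text normalization.

Field imagery of pests and their predators suffers from uneven illumination,
occlusion by foliage or soil, and pose variation; the augmentations here
simulate exactly those three effects on 8-bit RGB images:

* background perturbation  — per-pixel affine brightness change
  ``clip(alpha * I + beta)`` restricted to a background mask,
* occlusion                — painting a random rectangle/ellipse a constant
  random color,
* local affine deformation — inverse-warping a rectangular region under
  ``x' = A x + t`` with bilinear interpolation.

Text descriptions harvested from atlases and databases carry typos, repeated
punctuation and vernacular species names; :func:`clean_text` applies an
ordered rule list and :func:`normalize_entities` maps mentions to standard
Latin binomials through a synonym dictionary (longest match wins).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np

__all__ = [
    "AugmentationParams",
    "SynonymDictionary",
    "background_perturb",
    "occlude",
    "local_affine",
    "augment",
    "clean_text",
    "normalize_entities",
]


@dataclass
class AugmentationParams:
    """Knobs for the three-stage augmentation pipeline.

    Probabilities gate each stage independently; ranges are sampled uniformly.
    ``occ_size_range`` is the occluder area as a fraction of image area.
    """

    p_bg: float = 0.5
    p_occ: float = 0.5
    p_affine: float = 0.5
    alpha_range: tuple[float, float] = (0.7, 1.3)
    beta_range: tuple[float, float] = (-20.0, 20.0)
    occ_shapes: tuple[str, ...] = ("rectangle", "ellipse")
    occ_size_range: tuple[float, float] = (0.02, 0.15)
    affine_matrix_bounds: tuple[float, float] = (-0.2, 0.2)  # offsets from identity
    t_range: tuple[float, float] = (-10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_bg", "p_occ", "p_affine"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        for shape in self.occ_shapes:
            if shape not in ("rectangle", "ellipse"):
                raise ValueError(f"unknown occluder shape {shape!r}")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    return image


def background_perturb(
    image: np.ndarray, bg_mask: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Scale-and-offset brightness of background pixels, saturating at [0, 255].

    Foreground pixels (mask false) are bit-identical to the input.
    """
    image = _check_image(image)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if bg_mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {bg_mask.shape} does not match image {image.shape[:2]}"
        )
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise ValueError("alpha and beta must be finite")
    out = image.copy()
    perturbed = np.clip(alpha * image[bg_mask].astype(np.float64) + beta, 0, 255)
    out[bg_mask] = np.round(perturbed).astype(image.dtype)
    return out


def occlude(image: np.ndarray, region: np.ndarray, color) -> np.ndarray:
    """Paint the region (boolean mask or (N,2) row/col index array) a constant color."""
    image = _check_image(image)
    out = image.copy()
    color = np.asarray(color, dtype=image.dtype)
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != image.shape[:2]:
            raise ValueError("boolean region mask must match image shape")
        out[region] = color
        return out
    if region.size == 0:
        return out
    rows, cols = region[:, 0], region[:, 1]
    h, w = image.shape[:2]
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
        raise ValueError("occlusion region out of image bounds")
    out[rows, cols] = color
    return out


def local_affine(
    image: np.ndarray,
    region: tuple[int, int, int, int],
    A: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    """Resample a rectangular region under ``x' = A x + t`` (inverse warping).

    ``region`` is (r0, c0, r1, c1), half-open.  Destination pixels sample the
    source at ``A^-1 (x' - t)`` with bilinear interpolation, clamped to the
    region boundary so no out-of-region content leaks in.  Pixels outside the
    region are untouched.
    """
    image = _check_image(image)
    A = np.asarray(A, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64).reshape(2)
    if A.shape != (2, 2):
        raise ValueError("A must be 2x2")
    if abs(np.linalg.det(A)) <= 1e-6:
        raise ValueError("affine matrix A is (near-)singular")
    r0, c0, r1, c1 = region
    h, w = image.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"region {region} not within image bounds {(h, w)}")
    Ainv = np.linalg.inv(A)
    rows, cols = np.meshgrid(
        np.arange(r0, r1, dtype=np.float64),
        np.arange(c0, c1, dtype=np.float64),
        indexing="ij",
    )
    # coordinates relative to region origin; (x, y) = (col, row)
    dst = np.stack([cols - c0, rows - r0], axis=-1)
    src = (dst - t) @ Ainv.T
    sx = np.clip(src[..., 0], 0, c1 - c0 - 1)
    sy = np.clip(src[..., 1], 0, r1 - r0 - 1)
    x0 = np.floor(sx).astype(int)
    y0 = np.floor(sy).astype(int)
    x1 = np.minimum(x0 + 1, c1 - c0 - 1)
    y1 = np.minimum(y0 + 1, r1 - r0 - 1)
    fx = sx - x0
    fy = sy - y0
    patch = image[r0:r1, c0:c1].astype(np.float64)
    interp = (
        patch[y0, x0] * ((1 - fx) * (1 - fy))[..., None]
        + patch[y0, x1] * (fx * (1 - fy))[..., None]
        + patch[y1, x0] * ((1 - fx) * fy)[..., None]
        + patch[y1, x1] * (fx * fy)[..., None]
    )
    out = image.copy()
    out[r0:r1, c0:c1] = np.round(np.clip(interp, 0, 255)).astype(image.dtype)
    return out


def _sample_occluder(rng: np.random.Generator, shape_names, size_range, h: int, w: int):
    """Random rectangle or ellipse mask covering a sampled fraction of the image."""
    frac = rng.uniform(*size_range)
    area = frac * h * w
    aspect = rng.uniform(0.5, 2.0)
    oh = max(1, min(h, int(round(np.sqrt(area * aspect)))))
    ow = max(1, min(w, int(round(np.sqrt(area / aspect)))))
    r0 = int(rng.integers(0, h - oh + 1))
    c0 = int(rng.integers(0, w - ow + 1))
    mask = np.zeros((h, w), dtype=bool)
    shape = shape_names[int(rng.integers(0, len(shape_names)))]
    if shape == "rectangle":
        mask[r0 : r0 + oh, c0 : c0 + ow] = True
    else:  # ellipse inscribed in the sampled rectangle
        rr, cc = np.mgrid[0:h, 0:w]
        cy, cx = r0 + (oh - 1) / 2.0, c0 + (ow - 1) / 2.0
        mask = ((rr - cy) / max(oh / 2.0, 0.5)) ** 2 + (
            (cc - cx) / max(ow / 2.0, 0.5)
        ) ** 2 <= 1.0
    return mask


def augment(
    image: np.ndarray,
    bg_mask: np.ndarray,
    params: AugmentationParams,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Apply background perturbation, occlusion and local affine warp in order.

    Each stage fires independently with its configured probability; with all
    probabilities zero the input is returned unchanged.  A fixed seed gives
    byte-identical output.
    """
    image = _check_image(image)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    h, w = image.shape[:2]
    out = image

    if rng.random() < params.p_bg:
        alpha = rng.uniform(*params.alpha_range)
        beta = rng.uniform(*params.beta_range)
        out = background_perturb(out, bg_mask, alpha, beta)

    if rng.random() < params.p_occ:
        mask = _sample_occluder(rng, params.occ_shapes, params.occ_size_range, h, w)
        color = rng.integers(0, 256, size=3)
        out = occlude(out, mask, color.astype(out.dtype))

    if rng.random() < params.p_affine:
        lo, hi = params.affine_matrix_bounds
        A = np.eye(2) + rng.uniform(lo, hi, size=(2, 2))
        while abs(np.linalg.det(A)) <= 1e-6:  # resample the rare singular draw
            A = np.eye(2) + rng.uniform(lo, hi, size=(2, 2))
        t = rng.uniform(*params.t_range, size=2)
        side = int(min(h, w) * rng.uniform(0.3, 0.7))
        r0 = int(rng.integers(0, h - side + 1))
        c0 = int(rng.integers(0, w - side + 1))
        out = local_affine(out, (r0, c0, r0 + side, c0 + side), A, t)

    return out if out is not image else image.copy()


# ---------------------------------------------------------------------------
# Text
# ---------------------------------------------------------------------------

# Ordered, versioned rule list implementing the rule-based cleaner.  Order
# matters: control/emoji stripping precedes punctuation collapse precedes
# whitespace collapse.
_CLEAN_RULES: list[tuple[re.Pattern, str]] = [
    (re.compile(r"[\U0001F000-\U0001FAFF☀-➿️]"), ""),  # emoji & symbols
    (re.compile(r"([!\"#$%&'()*+,\-./:;<=>?@\[\]^_`{|}~])\1+"), r"\1"),  # !!! -> !
    (re.compile(r"\s+"), " "),
]
CLEAN_RULESET_VERSION = 1


def clean_text(text: str) -> str:
    """Strip control characters and emoji, collapse repeats, normalize spacing.

    Idempotent: cleaning a clean string returns it unchanged.
    """
    out = "".join(
        ch for ch in text if not unicodedata.category(ch).startswith("C") or ch in "\n\t "
    )
    for pattern, repl in _CLEAN_RULES:
        out = pattern.sub(repl, out)
    return out.strip()


@dataclass
class SynonymDictionary:
    """Raw name -> standardized Latin binomial lookup.

    Standard names map to themselves, so normalization is a projection:
    applying it twice equals applying it once.
    """

    mapping: Mapping[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        lowered = {k.lower(): v for k, v in self.mapping.items()}
        for std in set(self.mapping.values()):
            lowered.setdefault(std.lower(), std)
        self._lookup = lowered

    @classmethod
    def from_json(cls, path) -> "SynonymDictionary":
        import json

        with open(path, "r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    def get(self, raw: str) -> str | None:
        return self._lookup.get(raw.lower())

    def __len__(self) -> int:
        return len(self._lookup)


def normalize_entities(
    text: str, dictionary: SynonymDictionary
) -> tuple[str, set[str]]:
    """Clean the text and extract standardized species mentions.

    Candidate mentions are found by case-insensitive longest-match scanning
    over the cleaned text (an alias that is a substring of a longer alias
    never fires inside it); mentions absent from the dictionary are dropped.
    Returns ``(cleaned_text, standardized_name_set)``.
    """
    cleaned = clean_text(text)
    if not cleaned or len(dictionary) == 0:
        return cleaned, set()
    aliases = sorted(dictionary._lookup, key=len, reverse=True)
    found: set[str] = set()
    lowered = cleaned.lower()
    consumed = np.zeros(len(lowered), dtype=bool)
    for alias in aliases:
        start = 0
        while True:
            idx = lowered.find(alias, start)
            if idx < 0:
                break
            end = idx + len(alias)
            boundary_ok = (idx == 0 or not lowered[idx - 1].isalnum()) and (
                end == len(lowered) or not lowered[end].isalnum()
            )
            if boundary_ok and not consumed[idx:end].any():
                consumed[idx:end] = True
                found.add(dictionary._lookup[alias])
            start = idx + 1
    return cleaned, found
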