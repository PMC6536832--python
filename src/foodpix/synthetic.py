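"""Synthetic fixtures: buffet-style scenes, toy catalogue, toy FCDB, baseline segmenter.

Every stage of the pipeline is testable without external data. Scenes are
coloured regions (discs, rectangles, blobs) painted with each class's
palette colour over a background, with an exact ground-truth mask; palette
colours sit on a coarse RGB grid so they are maximally separated and the
nearest-colour baseline segmenter is well-posed. That separation is a
fixture property, not a claim about real food photographs.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from foodpix.catalogue import Catalogue, NutrientRecord
from foodpix.imageset import ClassRegistry

# 55 buffet food-class names; several appear verbatim in the toy catalogue
# so that scene classes standardize and link end to end.
FOOD_CLASS_NAMES = (
    "tomato",
    "pear",
    "apple",
    "banana",
    "cucumber",
    "carrot",
    "lettuce",
    "broccoli",
    "mushrooms",
    "green beans",
    "peas",
    "onion rings",
    "boiled potatoes",
    "fried potatoes",
    "rice",
    "fresh pasta",
    "dried pasta",
    "white bread",
    "wholegrain bread",
    "croissant",
    "butter",
    "cheese",
    "ham",
    "salami",
    "chicken breast",
    "beef steak",
    "fish fillet",
    "herring",
    "smoked salmon",
    "fish sticks",
    "sausage",
    "fried egg",
    "scrambled eggs",
    "boiled egg",
    "yogurt",
    "muesli",
    "jam",
    "honey",
    "chocolate",
    "chocolate cake",
    "apple pie",
    "strawberries",
    "grapes",
    "orange",
    "melon",
    "mixed salad",
    "pasta salad",
    "vegetable soup",
    "tomato sauce",
    "salad dressing",
    "french dressing",
    "orange juice",
    "apple juice",
    "coffee",
    "mineral water",
)

_GRID = (0, 85, 170, 255)


def _grid_palette(n: int) -> tuple[tuple[int, int, int], ...]:
    """First n colours of the 4x4x4 RGB grid, background black first.

    Adjacent grid colours differ by 85 in at least one channel, so mild
    per-pixel texture cannot move a pixel across the nearest-colour
    boundary.
    """
    if n > len(_GRID) ** 3:
        raise ValueError(f"palette supports at most {len(_GRID) ** 3} classes")
    colours = [
        (r, g, b) for r in _GRID for g in _GRID for b in _GRID
    ]
    # deterministic spread: background (0,0,0) first, then stride through
    # the grid so consecutive class indices get visually distinct colours
    rest = colours[1:]
    stride = 23  # coprime with 63: visits every remaining grid colour once
    order = [rest[(i * stride) % len(rest)] for i in range(len(rest))]
    return tuple([colours[0]] + order[: n - 1])


def toy_registry(n_classes: int = 56) -> ClassRegistry:
    """Background plus up to 55 named food classes with grid palette colours."""
    if not (2 <= n_classes <= 56):
        raise ValueError("n_classes must be in [2, 56]")
    names = ("background",) + FOOD_CLASS_NAMES[: n_classes - 1]
    return ClassRegistry(names=names, colours=_grid_palette(n_classes))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic buffet scene.

    Defaults mirror the buffet imagery being emulated: 500 x 375 px frames
    containing 5-15 food items (buffet photos average over eleven foods).
    ``texture_sigma`` adds mild per-pixel colour texture (well below the
    palette separation) so regions are not perfectly flat.
    """

    width: int = 500
    height: int = 375
    min_items: int = 5
    max_items: int = 15
    class_pool: tuple[int, ...] | None = None  # defaults to all non-background
    shapes: tuple[str, ...] = ("disc", "rectangle", "blob")
    texture_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_items < 0 or self.max_items < self.min_items:
            raise ValueError("need 0 <= min_items <= max_items")
        unknown = set(self.shapes) - {"disc", "rectangle", "blob"}
        if unknown:
            raise ValueError(f"unknown shapes {unknown}")


def _paint_disc(mask, rng, h, w):
    r = int(rng.integers(min(h, w) // 12, min(h, w) // 4))
    cy = int(rng.integers(r, h - r))
    cx = int(rng.integers(r, w - r))
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _paint_rect(mask, rng, h, w):
    rh = int(rng.integers(h // 10, h // 3))
    rw = int(rng.integers(w // 10, w // 3))
    y0 = int(rng.integers(0, h - rh))
    x0 = int(rng.integers(0, w - rw))
    sel = np.zeros((h, w), dtype=bool)
    sel[y0 : y0 + rh, x0 : x0 + rw] = True
    return sel


def _paint_blob(mask, rng, h, w):
    sel = np.zeros((h, w), dtype=bool)
    n_lobes = int(rng.integers(2, 5))
    cy = int(rng.integers(h // 6, 5 * h // 6))
    cx = int(rng.integers(w // 6, 5 * w // 6))
    for _ in range(n_lobes):
        r = int(rng.integers(min(h, w) // 16, min(h, w) // 6))
        oy = cy + int(rng.integers(-r, r + 1))
        ox = cx + int(rng.integers(-r, r + 1))
        yy, xx = np.ogrid[:h, :w]
        sel |= (yy - oy) ** 2 + (xx - ox) ** 2 <= r * r
    return sel


_SHAPE_PAINTERS = {"disc": _paint_disc, "rectangle": _paint_rect, "blob": _paint_blob}


def generate_scene(
    spec: SceneSpec, registry: ClassRegistry
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (image, mask) pair; deterministic per spec.seed.

    Items are layered in draw order (later items may partially cover
    earlier ones, as foods overlap on plates); each item's pixels carry its
    class index in the mask and its palette colour (plus texture) in the
    image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    pool = spec.class_pool or tuple(range(1, registry.n_classes))
    if any(c <= 0 or c >= registry.n_classes for c in pool):
        raise ValueError("class_pool must contain non-background registry indices")
    mask = np.zeros((h, w), dtype=np.uint8)
    n_items = int(rng.integers(spec.min_items, spec.max_items + 1))
    for _ in range(n_items):
        cls = int(pool[rng.integers(0, len(pool))])
        shape = spec.shapes[int(rng.integers(0, len(spec.shapes)))]
        sel = _SHAPE_PAINTERS[shape](mask, rng, h, w)
        mask[sel] = cls

    palette = registry.palette().astype(np.float64)
    image = palette[mask]
    if spec.texture_sigma > 0:
        image = image + rng.normal(0.0, spec.texture_sigma, size=image.shape)
    return np.clip(np.rint(image), 0, 255).astype(np.uint8), mask


def perturb_mask(
    mask: np.ndarray, error_rate: float, n_cl: int, seed: int
) -> np.ndarray:
    """Independently relabel each pixel to a uniform *different* class.

    Each pixel flips with probability ``error_rate``; a flipped pixel never
    keeps its class, so expected pixel accuracy against the original is
    exactly ``1 - error_rate``.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must lie in [0, 1]")
    mask = np.asarray(mask, dtype=np.int64)
    if mask.size and mask.max() >= n_cl:
        raise ValueError("mask labels must be < n_cl")
    rng = np.random.default_rng(seed)
    flip = rng.random(mask.shape) < error_rate
    offsets = rng.integers(1, n_cl, size=mask.shape)
    out = np.where(flip, (mask + offsets) % n_cl, mask)
    return out.astype(np.uint8)


def baseline_segment(image: np.ndarray, registry: ClassRegistry) -> np.ndarray:
    """Assign each pixel the class with the nearest palette colour (L2 in RGB).

    A desk-scale stand-in segmenter so the full recognition-to-nutrients
    pipeline runs end to end; on noiseless synthetic scenes it recovers the
    ground-truth mask exactly because palette colours are well separated.
    """
    img = np.asarray(image, dtype=np.int64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {img.shape}")
    palette = registry.palette().astype(np.int64)
    best = np.full(img.shape[:2], np.iinfo(np.int64).max, dtype=np.int64)
    out = np.zeros(img.shape[:2], dtype=np.uint8)
    for cls in range(registry.n_classes):
        dist = ((img - palette[cls]) ** 2).sum(axis=2)
        better = dist < best
        best[better] = dist[better]
        out[better] = cls
    return out


# ---------------------------------------------------------------------------
# Toy catalogue and FCDB

_TOY_CATALOGUE_ROWS: tuple[tuple[str, str, str], ...] = (
    ("A01TM", "tomato", "raw"),
    ("A01PE", "pear", "raw"),
    ("A01AP", "apple", "raw"),
    ("A01BA", "banana", "raw"),
    ("A01CU", "cucumber", "raw"),
    ("A01CA", "carrot", "raw"),
    ("A01LE", "lettuce", "raw"),
    ("A02HE", "herrings", "raw"),
    ("A02SA", "salmon", "raw"),
    ("A02EG", "egg", "raw"),
    ("A03SD", "salad dressing", "derivative"),
    ("A03FP", "fresh pasta", "derivative"),
    ("A03DP", "dried pasta", "derivative"),
    ("A03OJ", "orange juice", "derivative"),
    ("A03SS", "smoked salmon", "derivative"),
    ("A03WB", "white bread", "derivative"),
    ("A03TS", "tomato sauce", "derivative"),
    ("A03CH", "cheese", "derivative"),
    ("A04BB", "bread with butter", "simple composite"),
    ("A04SC", "strawberries with cream", "simple composite"),
    ("A04RP", "rice with peas", "simple composite"),
    ("A05MS", "mixed salad", "aggregated composite"),
    ("A05VS", "vegetable soup", "aggregated composite"),
    ("A05PS", "pasta salad with tuna and egg", "aggregated composite"),
    ("A05HS", "ham sandwich", "aggregated composite"),
)


def toy_catalogue() -> Catalogue:
    """A 25-entry FoodEx2-style catalogue spanning all four food categories.

    Contains the names a buffet vocabulary needs for the canonical matching
    walk-throughs: "salad dressing", "herrings", "fresh pasta", "dried
    pasta", plus plain raw foods such as "tomato" and "pear".
    """
    return Catalogue.from_rows(_TOY_CATALOGUE_ROWS)


def toy_fcdb(cat: Catalogue, seed: int = 20) -> list[NutrientRecord]:
    """One plausible nutrient row per catalogue code; deterministic per seed."""
    rng = np.random.default_rng(seed)
    records = []
    for entry in cat.entries:
        records.append(
            NutrientRecord(
                code=entry.code,
                name=entry.name,
                nutrients={
                    "energy_kcal": float(np.round(rng.uniform(15, 600), 1)),
                    "protein_g": float(np.round(rng.uniform(0, 30), 1)),
                    "carbohydrate_g": float(np.round(rng.uniform(0, 80), 1)),
                    "fat_g": float(np.round(rng.uniform(0, 40), 1)),
                },
            )
        )
    return records
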