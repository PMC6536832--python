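"""Paired RGB images and pixel-level label masks, class registry, dataset split.

An image is an ``(H, W, 3)`` uint8 array; its label mask is an ``(H, W)``
uint8 array of class indices into a :class:`ClassRegistry`, where index 0 is
always the background. Masks are stored as 8-bit single-channel PNGs holding
raw class indices (not palette colours), so the round trip is lossless and
validation against the registry is a range check.

Coordinate convention: row-major, origin top-left, 0-based indices.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage


class FormatError(ValueError):
    """Raised when an input file violates the expected image/CSV format."""


class MaskValidationError(ValueError):
    """Raised when a label mask contains indices outside the registry."""


# ---------------------------------------------------------------------------
# Class registry


@dataclass(frozen=True)
class ClassRegistry:
    """Ordered mapping of class index <-> food-class name <-> palette colour.

    Index 0 is the background class. Names and palette colours are unique;
    indices are contiguous from 0.
    """

    names: tuple[str, ...]
    colours: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.colours):
            raise ValueError("names and colours must have equal length")
        if not self.names:
            raise ValueError("registry must contain at least the background class")
        if self.names[0] != "background":
            raise ValueError("class 0 must be named 'background'")
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        if len(set(self.colours)) != len(self.colours):
            raise ValueError("palette colours must be unique")
        for c in self.colours:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValueError(f"invalid RGB colour {c!r}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def palette(self) -> np.ndarray:
        """Palette as an ``(n_classes, 3)`` uint8 array."""
        return np.asarray(self.colours, dtype=np.uint8)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassRegistry":
        """Load a registry from CSV with header ``index,name,r,g,b``."""
        rows: list[tuple[int, str, tuple[int, int, int]]] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"index", "name", "r", "g", "b"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise FormatError(
                    f"registry CSV must have header index,name,r,g,b; got {reader.fieldnames}"
                )
            for row in reader:
                rows.append(
                    (
                        int(row["index"]),
                        row["name"],
                        (int(row["r"]), int(row["g"]), int(row["b"])),
                    )
                )
        rows.sort(key=lambda r: r[0])
        if [r[0] for r in rows] != list(range(len(rows))):
            raise FormatError("registry indices must be contiguous from 0")
        return cls(
            names=tuple(r[1] for r in rows),
            colours=tuple(r[2] for r in rows),
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["index", "name", "r", "g", "b"])
            for i, (name, (r, g, b)) in enumerate(zip(self.names, self.colours)):
                writer.writerow([i, name, r, g, b])


# ---------------------------------------------------------------------------
# Image / mask I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG as an ``(H, W, 3)`` uint8 array.

    Raises :class:`FileNotFoundError` for a missing file and
    :class:`FormatError` for anything that is not 3-channel RGB.
    """
    with Image.open(path) as im:
        if im.mode != "RGB":
            raise FormatError(
                f"{path}: expected a 3-channel RGB image, got mode {im.mode!r}"
            )
        arr = np.asarray(im, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected shape (H, W, 3), got {arr.shape}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image, dtype=np.uint8)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {image.shape}")
    Image.fromarray(image, mode="RGB").save(path, format="PNG")


def validate_mask(mask: np.ndarray, registry: ClassRegistry) -> np.ndarray:
    """Check a label array against the registry; returns it as uint8."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MaskValidationError(
            f"label mask must be single-channel, got shape {mask.shape}"
        )
    if mask.size and mask.max() >= registry.n_classes:
        bad = int(mask.max())
        raise MaskValidationError(
            f"label value {bad} out of range for registry with "
            f"{registry.n_classes} classes (valid: 0..{registry.n_classes - 1})"
        )
    return mask.astype(np.uint8)


def read_mask(path: str | Path, registry: ClassRegistry) -> np.ndarray:
    """Read a single-channel label PNG and validate it against the registry."""
    with Image.open(path) as im:
        if im.mode != "L":
            raise FormatError(
                f"{path}: expected single-channel (mode 'L') mask, got {im.mode!r}"
            )
        arr = np.asarray(im, dtype=np.uint8)
    return validate_mask(arr, registry)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask, dtype=np.uint8)
    if mask.ndim != 2:
        raise ValueError(f"expected (H, W) mask, got shape {mask.shape}")
    Image.fromarray(mask, mode="L").save(path, format="PNG")


# ---------------------------------------------------------------------------
# Dataset manifest and split


@dataclass(frozen=True)
class ManifestItem:
    image: str
    mask: str
    subset: str  # "training" | "validation" | "testing"


SUBSETS = ("training", "validation", "testing")


@dataclass
class DatasetManifest:
    items: list[ManifestItem] = field(default_factory=list)

    def subset(self, tag: str) -> list[ManifestItem]:
        if tag not in SUBSETS:
            raise ValueError(f"unknown subset {tag!r}; expected one of {SUBSETS}")
        return [it for it in self.items if it.subset == tag]

    def sizes(self) -> tuple[int, int, int]:
        return tuple(len(self.subset(tag)) for tag in SUBSETS)  # type: ignore[return-value]

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        items = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"image", "mask", "subset"}.issubset(
                reader.fieldnames
            ):
                raise FormatError(
                    f"manifest CSV must have header image,mask,subset; got {reader.fieldnames}"
                )
            for row in reader:
                if row["subset"] not in SUBSETS:
                    raise FormatError(f"unknown subset tag {row['subset']!r}")
                items.append(ManifestItem(row["image"], row["mask"], row["subset"]))
        return cls(items)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "mask", "subset"])
            for it in self.items:
                writer.writerow([it.image, it.mask, it.subset])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    pairs: Sequence[tuple[str, str]], seed: int
) -> DatasetManifest:
    """Randomly split image/mask pairs into training/validation/testing.

    The split follows the 70 / 10 / 20 proportions with round-half-up
    counting: ``validation = round(0.10 N)``, ``testing = round(0.20 N)``,
    ``training = N - validation - testing``. For ``N = 121`` this yields
    (85, 12, 24). Each pair lands in exactly one subset; the assignment is a
    deterministic function of ``seed``.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need at least 3 pairs to populate three subsets, got {n}")
    n_val = _round_half_up(0.10 * n)
    n_test = _round_half_up(0.20 * n)
    n_train = n - n_val - n_test

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    items: list[ManifestItem | None] = [None] * n
    for rank, idx in enumerate(order):
        if rank < n_train:
            tag = "training"
        elif rank < n_train + n_val:
            tag = "validation"
        else:
            tag = "testing"
        img, msk = pairs[idx]
        items[idx] = ManifestItem(img, msk, tag)
    return DatasetManifest([it for it in items if it is not None])


# ---------------------------------------------------------------------------
# Food item regions


@dataclass(frozen=True)
class FoodItemRegion:
    """One food item: a 4-connected region of a single non-background class."""

    class_index: int
    pixel_count: int
    component_id: int

    def __post_init__(self) -> None:
        if self.class_index == 0:
            raise ValueError("background yields no food item regions")
        if self.pixel_count < 1:
            raise ValueError("a region has at least one pixel")


_FOUR_CONNECTED = np.array(
    [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool
)


def mask_to_items(mask: np.ndarray) -> list[FoodItemRegion]:
    """Decompose a mask into per-class 4-connected food item regions.

    Each connected component of each non-background class is one food or
    drink item; component ids are unique across the whole mask and assigned
    in (class, scan-order) order, so the output is deterministic.
    """
    mask = np.asarray(mask)
    regions: list[FoodItemRegion] = []
    next_id = 0
    for cls in np.unique(mask):
        if cls == 0:
            continue
        labelled, n_comp = ndimage.label(mask == cls, structure=_FOUR_CONNECTED)
        counts = np.bincount(labelled.ravel(), minlength=n_comp + 1)
        for comp in range(1, n_comp + 1):
            regions.append(
                FoodItemRegion(
                    class_index=int(cls),
                    pixel_count=int(counts[comp]),
                    component_id=next_id,
                )
            )
            next_id += 1
    return regions
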