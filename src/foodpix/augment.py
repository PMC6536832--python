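"""Joint data augmentation for image/mask pairs.

Four augmentation steps expand the training subset: rotation by 90/180/270
degrees, horizontal flip, additive colour noise (image only — ground-truth
labels must not change under noise) and a centre zoom that removes 25 % of
the image borders. Together with the original this gives seven variants per
training pair; validation and testing pairs are never augmented.

Geometric steps transform image and mask identically. The mask is always
resampled nearest-neighbour because its values are categorical class
indices; the image is resampled bilinearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from foodpix.imageset import DatasetManifest, ManifestItem, read_image, read_mask
from foodpix.imageset import ClassRegistry, write_image, write_mask

VARIANT_SUFFIXES = ("orig", "r90", "r180", "r270", "flip", "noise", "zoom")


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation parameters.

    noise_sigma is the standard deviation of the additive Gaussian colour
    noise in 8-bit intensity units; zoom_border is the total fraction of
    each dimension removed by the centre zoom (0.25 removes 12.5 % per
    side, keeping the central 75 % x 75 % window).
    """

    noise_sigma: float = 10.0
    zoom_border: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.zoom_border < 0.5):
            raise ValueError("zoom_border must lie in (0, 0.5)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def rotate_pair(
    image: np.ndarray, mask: np.ndarray, angle: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image and mask counter-clockwise by 90, 180 or 270 degrees."""
    if angle not in (90, 180, 270):
        raise ValueError(f"angle must be 90, 180 or 270, got {angle}")
    k = angle // 90
    return np.ascontiguousarray(np.rot90(image, k)), np.ascontiguousarray(
        np.rot90(mask, k)
    )


def flip_pair(
    image: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror image and mask about the vertical axis (horizontal flip)."""
    return np.ascontiguousarray(np.fliplr(image)), np.ascontiguousarray(
        np.fliplr(mask)
    )


def noise_image(
    image: np.ndarray, mask: np.ndarray, sigma: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Add seeded per-pixel, per-channel Gaussian colour noise to the image.

    The mask is returned bit-identical: labels are ground truth and do not
    change in the presence of noise. Output intensities are clipped to
    [0, 255].
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy(), mask.copy()
    rng = np.random.default_rng(seed)
    noisy = image.astype(np.float64) + rng.normal(0.0, sigma, size=image.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8), mask.copy()


def _crop_window(dim: int, border_fraction: float) -> tuple[int, int]:
    # floor((1-f)*dim) centred, extra pixel (if any) on the trailing side
    keep = math.floor((1.0 - border_fraction) * dim)
    lead = (dim - keep) // 2
    return lead, lead + keep


def zoom_pair(
    image: np.ndarray, mask: np.ndarray, border_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Centre-zoom: crop away ``border_fraction`` of each dimension, resize back.

    The retained window spans floor((1 - f) * dim) pixels per dimension,
    centred. The crop is resized back to the original resolution — the image
    bilinearly, the mask nearest-neighbour so labels stay categorical.
    Classes present only in the removed border disappear from the output.
    """
    if not (0.0 < border_fraction < 0.5):
        raise ValueError("border_fraction must lie in (0, 0.5)")
    h, w = mask.shape
    r0, r1 = _crop_window(h, border_fraction)
    c0, c1 = _crop_window(w, border_fraction)
    if r1 - r0 < 1 or c1 - c0 < 1:
        raise ValueError("crop window smaller than one pixel")
    img_crop = Image.fromarray(image[r0:r1, c0:c1], mode="RGB")
    msk_crop = Image.fromarray(mask[r0:r1, c0:c1], mode="L")
    img_out = img_crop.resize((w, h), resample=Image.BILINEAR)
    msk_out = msk_crop.resize((w, h), resample=Image.NEAREST)
    return np.asarray(img_out, dtype=np.uint8), np.asarray(msk_out, dtype=np.uint8)


def augment_pair(
    image: np.ndarray, mask: np.ndarray, config: AugmentConfig, seed: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Produce the seven-variant set {orig, r90, r180, r270, flip, noise, zoom}."""
    return {
        "orig": (image.copy(), mask.copy()),
        "r90": rotate_pair(image, mask, 90),
        "r180": rotate_pair(image, mask, 180),
        "r270": rotate_pair(image, mask, 270),
        "flip": flip_pair(image, mask),
        "noise": noise_image(image, mask, config.noise_sigma, seed),
        "zoom": zoom_pair(image, mask, config.zoom_border),
    }


def augment_training_set(
    manifest: DatasetManifest,
    config: AugmentConfig,
    registry: ClassRegistry,
    out_dir: str | Path,
) -> DatasetManifest:
    """Expand every training pair into its seven variants; write them to disk.

    Validation and testing pairs pass through untouched (their paths are
    preserved). The output manifest size is ``7 * |training| + |validation|
    + |testing|``. Each training pair's noise variant draws from a seed
    derived deterministically from ``config.seed`` and the pair's position.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    items: list[ManifestItem] = []
    train_pos = 0
    for it in manifest.items:
        if it.subset != "training":
            items.append(it)
            continue
        image = read_image(it.image)
        mask = read_mask(it.mask, registry)
        stem = Path(it.image).stem
        pair_seed = (config.seed * 1_000_003 + train_pos) % (2**31)
        variants = augment_pair(image, mask, config, pair_seed)
        for suffix in VARIANT_SUFFIXES:
            img_v, msk_v = variants[suffix]
            img_path = out_dir / f"{stem}_{suffix}.png"
            msk_path = out_dir / f"{stem}_{suffix}_mask.png"
            write_image(img_path, img_v)
            write_mask(msk_path, msk_v)
            items.append(ManifestItem(str(img_path), str(msk_path), "training"))
        train_pos += 1
    return DatasetManifest(items)


def augmented_size(n_train: int, n_val: int, n_test: int) -> int:
    """Size of the augmented dataset: seven variants per training pair."""
    return 7 * n_train + n_val + n_test
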