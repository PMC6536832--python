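"""End-to-end orchestration: image -> recognized classes -> codes -> nutrients.

One pipeline run takes a food image, predicts (or loads) a label mask,
collects the distinct non-background classes present, standardizes each
class name to a FoodEx2 code via the matching chain, and links each code to
its nutrient record. Recognized "items" for standardization are distinct
predicted classes per image — one food name maps to one code regardless of
how many separate portions appear; connected-component counts are available
separately through :func:`foodpix.imageset.mask_to_items`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from foodpix.augment import AugmentConfig, augment_training_set
from foodpix.catalogue import (
    Catalogue,
    CodeNotFoundError,
    NutrientRecord,
    link_fcdb,
)
from foodpix.imageset import (
    ClassRegistry,
    DatasetManifest,
    read_image,
    read_mask,
    split_dataset,
    write_image,
    write_mask,
)
from foodpix.segmetrics import SegReport, evaluate
from foodpix.standfood import StandardizedFood, standardize
from foodpix.synthetic import (
    SceneSpec,
    baseline_segment,
    generate_scene,
    toy_catalogue,
    toy_fcdb,
    toy_registry,
)


@dataclass(frozen=True)
class PipelineItem:
    """One recognized food class with its standardization and linkage."""

    class_index: int
    class_name: str
    pixel_count: int
    code: str
    final_category: str
    method: str
    nutrients: dict[str, float] | None  # None: code absent from the FCDB


@dataclass
class PipelineReport:
    items: list[PipelineItem]
    evaluation: SegReport | None = None

    def as_dict(self) -> dict:
        out = {
            "items": [asdict(it) for it in self.items],
        }
        if self.evaluation is not None:
            out["evaluation"] = self.evaluation.as_dict()
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def standardize_mask_classes(
    pred: np.ndarray,
    registry: ClassRegistry,
    cat: Catalogue,
    fcdb: Sequence[NutrientRecord],
) -> list[PipelineItem]:
    """Standardize and link every distinct non-background class in a mask.

    A class whose code is missing from the FCDB is reported with
    ``nutrients=None`` (a not-found marker) rather than aborting the report.
    """
    items: list[PipelineItem] = []
    classes, counts = np.unique(pred, return_counts=True)
    for cls, count in zip(classes, counts):
        if cls == 0:
            continue
        if cls >= registry.n_classes:
            raise ValueError(f"predicted class {cls} not in registry")
        name = registry.names[cls]
        food: StandardizedFood = standardize(name, cat)
        try:
            record = link_fcdb(food, fcdb)
            nutrients = dict(record.nutrients)
        except CodeNotFoundError:
            nutrients = None
        items.append(
            PipelineItem(
                class_index=int(cls),
                class_name=name,
                pixel_count=int(count),
                code=food.code,
                final_category=food.final_category,
                method=food.description.method,
                nutrients=nutrients,
            )
        )
    return items


def run_pipeline(
    image: np.ndarray | str | Path,
    registry: ClassRegistry,
    cat: Catalogue,
    fcdb: Sequence[NutrientRecord],
    segmenter: str = "baseline",
    prediction: np.ndarray | str | Path | None = None,
) -> PipelineReport:
    """Run one image through recognition, standardization and linkage.

    ``segmenter`` is ``"baseline"`` (nearest-palette-colour classification)
    or ``"external-mask"``, in which case ``prediction`` supplies a
    precomputed label mask (array or PNG path), e.g. from a trained
    segmentation model.
    """
    if isinstance(image, (str, Path)):
        image = read_image(image)
    if segmenter == "baseline":
        pred = baseline_segment(image, registry)
    elif segmenter == "external-mask":
        if prediction is None:
            raise ValueError("external-mask segmenter needs a prediction mask")
        if isinstance(prediction, (str, Path)):
            pred = read_mask(prediction, registry)
        else:
            pred = np.asarray(prediction, dtype=np.uint8)
    else:
        raise ValueError(f"unknown segmenter {segmenter!r}")
    return PipelineReport(items=standardize_mask_classes(pred, registry, cat, fcdb))


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a full synthetic experiment.

    The experiment simulates ``n_images`` scenes, splits them 70/10/20,
    augments the training subset, segments the testing subset with the
    baseline segmenter, evaluates the four measures on it, and standardizes
    every recognized class.
    """

    n_images: int = 10
    n_classes: int = 56
    width: int = 500
    height: int = 375
    texture_sigma: float = 0.0
    noise_sigma: float = 10.0
    zoom_border: float = 0.25
    seed: int = 0
    augment: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
        return cls(**raw)


def run_experiment(config: ExperimentConfig, workdir: str | Path) -> dict:
    """Simulate, split, augment, segment the testing subset, evaluate, standardize.

    Returns a summary dict (also written to ``workdir/report.json``) with the
    resolved config, subset sizes, augmented size, the four segmentation
    measures on the testing subset, and the standardized items per image.
    Deterministic: the same config yields a byte-identical report.
    """
    workdir = Path(workdir)
    (workdir / "images").mkdir(parents=True, exist_ok=True)
    registry = toy_registry(config.n_classes)
    cat = toy_catalogue()
    fcdb = toy_fcdb(cat)

    pairs: list[tuple[str, str]] = []
    for i in range(config.n_images):
        spec = SceneSpec(
            width=config.width,
            height=config.height,
            texture_sigma=config.texture_sigma,
            seed=(config.seed * 100_003 + i) % (2**31),
        )
        image, mask = generate_scene(spec, registry)
        img_path = workdir / "images" / f"scene_{i:03d}.png"
        msk_path = workdir / "images" / f"scene_{i:03d}_mask.png"
        write_image(img_path, image)
        write_mask(msk_path, mask)
        pairs.append((str(img_path), str(msk_path)))

    manifest = split_dataset(pairs, seed=config.seed)
    if not manifest.subset("testing"):
        raise ValueError("experiment manifest has no testing subset")

    if config.augment:
        aug_cfg = AugmentConfig(
            noise_sigma=config.noise_sigma,
            zoom_border=config.zoom_border,
            seed=config.seed,
        )
        manifest = augment_training_set(
            manifest, aug_cfg, registry, workdir / "augmented"
        )

    testing = manifest.subset("testing")
    predictions: dict[str, np.ndarray] = {}
    per_image_items = {}
    for it in testing:
        image = read_image(it.image)
        pred = baseline_segment(image, registry)
        predictions[it.image] = pred
        items = standardize_mask_classes(pred, registry, cat, fcdb)
        per_image_items[Path(it.image).name] = [
            {
                "class_name": x.class_name,
                "pixel_count": x.pixel_count,
                "code": x.code,
                "final_category": x.final_category,
                "linked": x.nutrients is not None,
            }
            for x in items
        ]
    seg_report = evaluate(testing, predictions, registry)

    summary = {
        "config": asdict(config),
        "subset_sizes": dict(zip(("training", "validation", "testing"),
                                 DatasetManifest(manifest.items).sizes())),
        "n_manifest_items": len(manifest),
        "evaluation": seg_report.as_dict(),
        "standardized": per_image_items,
    }
    with open(workdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
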