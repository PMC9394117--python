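"""Tissue-trait statistics from semantic label masks.

Given a semantic segmentation of an image into background and C tissue
classes, the phenotypes are: per-class pixel area ``Area_c``; the relative
area ``RArea_c = Area_c / sum_c' Area_c'`` with the sum over tissue classes
only (background excluded from numerator and denominator); the fraction of
all image pixels each class covers; and the number of isolated 4-connected
clusters per class.  Dataset summaries average these per class, optionally
within replicate groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .scene import FOUR_CONNECTED

__all__ = [
    "TraitRecord",
    "area_per_class",
    "relative_area",
    "cluster_count",
    "trait_record",
    "summarize_dataset",
]


@dataclass
class TraitRecord:
    image_id: str
    areas: dict[int, int]  # class -> pixel count (tissue classes)
    relative_areas: dict[int, float]  # class -> fraction of tissue pixels
    image_fractions: dict[int, float]  # class -> fraction of all pixels
    cluster_counts: dict[int, int]  # class -> isolated 4-connected clusters


def _check_mask(mask: np.ndarray, class_count: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("semantic mask must be 2-D")
    bad = np.setdiff1d(np.unique(mask), np.arange(class_count + 1))
    if bad.size:
        raise ValueError(f"unknown label values {bad.tolist()} in mask")
    return mask


def area_per_class(semantic_mask: np.ndarray, class_count: int) -> dict[int, int]:
    """Exact pixel counts per tissue class (absent classes report 0)."""
    mask = _check_mask(semantic_mask, class_count)
    counts = np.bincount(mask.ravel(), minlength=class_count + 1)
    return {c: int(counts[c]) for c in range(1, class_count + 1)}


def relative_area(areas: dict[int, int]) -> dict[int, float]:
    """Each tissue class's share of the total tissue area.

    All-zero input yields all zeros.  Scale-invariant: multiplying every
    area by a positive constant leaves the fractions unchanged.
    """
    total = sum(areas.values())
    if total == 0:
        return {c: 0.0 for c in areas}
    return {c: a / total for c, a in areas.items()}


def cluster_count(
    semantic_mask: np.ndarray, class_id: int, class_count: int | None = None
) -> int:
    """Number of isolated 4-connected components of one class."""
    if class_count is None:
        class_count = max(int(np.max(semantic_mask)), class_id)
    mask = _check_mask(semantic_mask, class_count)
    if not 1 <= class_id <= class_count:
        raise ValueError(f"unknown class {class_id}")
    _, n = ndimage.label(mask == class_id, structure=FOUR_CONNECTED)
    return int(n)


def trait_record(
    semantic_mask: np.ndarray, class_count: int, image_id: str = ""
) -> TraitRecord:
    mask = _check_mask(semantic_mask, class_count)
    areas = area_per_class(mask, class_count)
    n_pixels = mask.size
    return TraitRecord(
        image_id=image_id,
        areas=areas,
        relative_areas=relative_area(areas),
        image_fractions={c: a / n_pixels for c, a in areas.items()},
        cluster_counts={
            c: cluster_count(mask, c, class_count)
            for c in range(1, class_count + 1)
        },
    )


def summarize_dataset(
    masks: "dict[str, np.ndarray] | list[np.ndarray]",
    class_count: int,
    class_names: "dict[int, str] | None" = None,
    groups: "dict[str, str] | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image trait table plus per-class dataset averages.

    Returns ``(per_image, summary)`` DataFrames.  ``per_image`` has one row
    per image and per class with area, relative area, image-pixel fraction
    and cluster count.  ``summary`` averages the image-pixel percentage and
    cluster count per class, optionally within replicate ``groups`` first
    (per-replicate means are then averaged).
    """
    if isinstance(masks, dict):
        items = list(masks.items())
    else:
        items = [(str(i), m) for i, m in enumerate(masks)]
    if not items:
        raise ValueError("no masks given")
    names = class_names or {c: f"class_{c}" for c in range(1, class_count + 1)}

    rows = []
    for image_id, mask in items:
        rec = trait_record(mask, class_count, image_id)
        for c in range(1, class_count + 1):
            rows.append(
                {
                    "image_id": image_id,
                    "class_id": c,
                    "class_name": names[c],
                    "area_px": rec.areas[c],
                    "relative_area": rec.relative_areas[c],
                    "image_fraction": rec.image_fractions[c],
                    "cluster_count": rec.cluster_counts[c],
                    "group": (groups or {}).get(image_id, ""),
                }
            )
    per_image = pd.DataFrame(rows)

    working = per_image
    if groups:
        working = (
            per_image.groupby(["group", "class_id", "class_name"], as_index=False)[
                ["image_fraction", "cluster_count", "relative_area"]
            ].mean()
        )
    summary = (
        working.groupby(["class_id", "class_name"], as_index=False)[
            ["image_fraction", "cluster_count", "relative_area"]
        ]
        .mean()
        .rename(
            columns={
                "image_fraction": "mean_image_fraction",
                "cluster_count": "mean_cluster_count",
                "relative_area": "mean_relative_area",
            }
        )
    )
    summary["mean_image_percent"] = 100.0 * summary["mean_image_fraction"]
    return per_image, summary
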