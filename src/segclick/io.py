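"""Readers and writers for the standard on-disk formats.

Label masks travel as palette PNGs (pixel value = label index, palette =
display colour), instance masks as 16-bit grayscale PNGs, semantic priors as
multi-channel float32 TIFFs with a JSON sidecar naming the channels, and the
class/object hierarchy as JSON.  All writers are deterministic: stable
ordering, no timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .prior import SemanticPrior
from .scene import Scene

__all__ = [
    "Hierarchy",
    "write_label_png",
    "read_label_png",
    "write_instance_png",
    "read_instance_png",
    "write_prior_tiff",
    "read_prior_tiff",
    "export_scene",
    "nested_palette_color",
]


@dataclass
class Hierarchy:
    """Class/object hierarchy: classes carry colours, objects group classes."""

    classes: list[tuple[int, str, tuple[int, int, int]]]
    objects: list[tuple[int, str, list[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class ids")
        colors = [tuple(c[2]) for c in self.classes]
        if len(set(colors)) != len(colors):
            raise ValueError("duplicate class colors")
        known = set(ids)
        for oid, name, members in self.objects:
            missing = set(members) - known
            if missing:
                raise ValueError(f"object {name!r} references unknown classes {missing}")

    def class_color(self, class_id: int) -> tuple[int, int, int]:
        for cid, _, color in self.classes:
            if cid == class_id:
                return tuple(color)
        raise KeyError(f"class {class_id} not in hierarchy")

    def to_json(self) -> dict:
        return {
            "classes": [
                {"id": cid, "name": name, "color": list(color)}
                for cid, name, color in self.classes
            ],
            "objects": [
                {"id": oid, "name": name, "classes": list(members)}
                for oid, name, members in self.objects
            ],
        }

    @classmethod
    def from_json(cls, d: dict) -> "Hierarchy":
        return cls(
            classes=[
                (c["id"], c["name"], tuple(c["color"])) for c in d["classes"]
            ],
            objects=[
                (o["id"], o["name"], list(o["classes"])) for o in d["objects"]
            ],
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "Hierarchy":
        return cls.from_json(json.loads(Path(path).read_text()))

    @classmethod
    def default(cls, class_count: int = 3) -> "Hierarchy":
        names = {1: "shoot", 2: "callus", 3: "stem"}
        classes = [(0, "background", (0, 0, 0))]
        for c in range(1, class_count + 1):
            classes.append(
                (c, names.get(c, f"class_{c}"), nested_palette_color(c, 0))
            )
        return cls(classes=classes)


def nested_palette_color(index: int, salt: int = 0) -> tuple[int, int, int]:
    """Deterministic, well-spread palette colour via golden-ratio hue walk."""
    if index == 0:
        return (0, 0, 0)
    h = ((index + salt) * 0.61803398875) % 1.0
    i = int(h * 6.0)
    f = h * 6.0 - i
    v, s = 0.95, 0.75
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i % 6]
    return tuple(int(round(255 * x)) for x in rgb)


def _write_palette_png(indices: np.ndarray, palette: list[tuple], path) -> None:
    if indices.max(initial=0) > 255:
        raise ValueError("palette PNG supports at most 256 labels")
    img = Image.fromarray(indices.astype(np.uint8), mode="P")
    flat = []
    for color in palette:
        flat.extend(color)
    flat.extend([0] * (768 - len(flat)))
    img.putpalette(flat)
    img.save(path, format="PNG")


def write_label_png(
    mask: np.ndarray,
    hierarchy: Hierarchy,
    path,
    mode: str = "by_class",
    instance_mask: np.ndarray | None = None,
    object_classes: "dict[int, int] | None" = None,
) -> None:
    """Write a label mask as a palette PNG in one of three colourings.

    ``by_class``: pixel index = class id, colour from the hierarchy.
    ``by_object``: pixel index = object id (requires ``instance_mask``).
    ``nested``: distinct index per (object, class) pair; the pair table is
    stored in a JSON sidecar next to the PNG so two objects sharing a class
    decode to distinct ids.
    """
    path = Path(path)
    if mode == "by_class":
        known = {cid for cid, _, _ in hierarchy.classes}
        present = set(np.unique(mask).tolist())
        if not present <= known:
            raise ValueError(f"labels {present - known} not in hierarchy")
        max_id = max(cid for cid, _, _ in hierarchy.classes)
        palette = [(0, 0, 0)] * (max_id + 1)
        for cid, _, color in hierarchy.classes:
            palette[cid] = tuple(color)
        _write_palette_png(mask, palette, path)
    elif mode == "by_object":
        if instance_mask is None:
            raise ValueError("by_object mode needs an instance mask")
        ids = sorted(int(i) for i in np.unique(instance_mask))
        palette = [(0, 0, 0)] * (max(ids) + 1)
        for oid in ids:
            if oid > 0:
                palette[oid] = nested_palette_color(oid, salt=7)
        _write_palette_png(instance_mask, palette, path)
    elif mode == "nested":
        if instance_mask is None or object_classes is None:
            raise ValueError("nested mode needs instance mask and object classes")
        pairs = sorted(
            {(int(oid), int(cls)) for oid, cls in object_classes.items()}
        )
        index_of = {pair: i + 1 for i, pair in enumerate(pairs)}
        indices = np.zeros_like(instance_mask, dtype=np.uint16)
        for (oid, cls), idx in index_of.items():
            indices[(instance_mask == oid) & (mask == cls)] = idx
        palette = [(0, 0, 0)] + [
            nested_palette_color(i + 1, salt=13) for i in range(len(pairs))
        ]
        _write_palette_png(indices, palette, path)
        sidecar = {
            "pairs": [
                {"index": idx, "object_id": oid, "class_id": cls}
                for (oid, cls), idx in sorted(index_of.items(), key=lambda kv: kv[1])
            ]
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unknown mode {mode!r}")


def read_label_png(path, mode: str = "by_class"):
    """Read back a label PNG written by :func:`write_label_png`.

    ``by_class``/``by_object`` return the index array; ``nested`` returns
    ``(instance_mask, semantic_mask)`` reconstructed via the JSON sidecar.
    """
    path = Path(path)
    indices = np.asarray(Image.open(path))
    if mode in ("by_class", "by_object"):
        return indices.astype(np.int32)
    if mode == "nested":
        sidecar = json.loads(path.with_suffix(".json").read_text())
        instance = np.zeros(indices.shape, dtype=np.int32)
        semantic = np.zeros(indices.shape, dtype=np.int32)
        for entry in sidecar["pairs"]:
            sel = indices == entry["index"]
            instance[sel] = entry["object_id"]
            semantic[sel] = entry["class_id"]
        return instance, semantic
    raise ValueError(f"unknown mode {mode!r}")


def write_instance_png(instance_mask: np.ndarray, path) -> None:
    """Instance mask as 16-bit grayscale PNG (object ids up to 65535)."""
    if instance_mask.max(initial=0) > 65535 or instance_mask.min(initial=0) < 0:
        raise ValueError("instance ids must fit in uint16")
    Image.fromarray(instance_mask.astype(np.uint16)).save(path, format="PNG")


def read_instance_png(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.int32)


def write_prior_tiff(prior: SemanticPrior, path) -> None:
    """Multi-channel float32 TIFF plus a JSON sidecar naming the channels."""
    path = Path(path)
    tifffile.imwrite(
        path, prior.channels.astype(np.float32), photometric="minisblack"
    )
    sidecar = {"channel_names": list(prior.class_names)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_prior_tiff(path) -> SemanticPrior:
    path = Path(path)
    channels = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    names = sidecar["channel_names"]
    if len(names) != channels.shape[0]:
        raise ValueError(
            f"sidecar names {len(names)} channels, TIFF has {channels.shape[0]}"
        )
    return SemanticPrior(channels=channels, class_names=names)


def export_scene(scene: Scene, directory, stem: str, prior=None) -> dict[str, Path]:
    """Write a scene's image, masks (all colourings) and optional prior."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hierarchy = Hierarchy.default(scene.class_count)
    paths = {}

    img_path = directory / f"{stem}_image.png"
    Image.fromarray((scene.image * 255).round().astype(np.uint8)).save(img_path)
    paths["image"] = img_path

    inst_path = directory / f"{stem}_instances.png"
    write_instance_png(scene.instance_mask, inst_path)
    paths["instances"] = inst_path

    sem_path = directory / f"{stem}_classes.png"
    write_label_png(scene.semantic_mask, hierarchy, sem_path, mode="by_class")
    paths["classes"] = sem_path

    nested_path = directory / f"{stem}_nested.png"
    write_label_png(
        scene.semantic_mask,
        hierarchy,
        nested_path,
        mode="nested",
        instance_mask=scene.instance_mask,
        object_classes=scene.object_classes,
    )
    paths["nested"] = nested_path

    hier_path = directory / f"{stem}_hierarchy.json"
    hierarchy.save(hier_path)
    paths["hierarchy"] = hier_path

    if prior is not None:
        prior_path = directory / f"{stem}_prior.tiff"
        write_prior_tiff(prior, prior_path)
        paths["prior"] = prior_path
    return paths
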