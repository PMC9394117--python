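"""Synthetic multi-class instance scenes.

Generates images that mimic the structure of in-vitro plant tissue photographs:
a plate-like background with several irregular tissue regions (callus-, shoot-
and stem-like shapes), each carrying a class-specific colour so that an
appearance-based segmenter has something to learn.  Every scene comes with a
ground-truth instance mask and semantic class mask, and a corruptible semantic
prior can be derived from the ground truth to stand in for the output of an
offline semantic segmentation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Scene",
    "SceneConfig",
    "PriorNoise",
    "SceneGenerationError",
    "generate_scene",
    "generate_scenes",
    "make_prior",
]

# 4-connectivity is the framework-wide convention for what counts as one object
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# Distinct base colours: background + up to six tissue classes.  Chosen to be
# well separated in RGB so class appearance is learnable under additive noise.
_BASE_COLORS = np.array(
    [
        [0.92, 0.92, 0.88],  # background: pale plate
        [0.20, 0.55, 0.20],  # class 1: shoot-like green
        [0.75, 0.65, 0.25],  # class 2: callus-like yellow
        [0.45, 0.30, 0.15],  # class 3: stem-like brown
        [0.25, 0.35, 0.70],  # class 4
        [0.70, 0.25, 0.55],  # class 5
        [0.20, 0.65, 0.65],  # class 6
    ]
)


class SceneGenerationError(RuntimeError):
    """Raised when the requested objects cannot be placed on the canvas."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene.

    ``min_gap`` keeps distinct objects at least that many pixels apart so that
    objects are isolated by default (no touching same-class neighbours); set
    ``overlap_allowed=True`` to let objects touch.
    """

    height: int = 96
    width: int = 96
    n_objects: int = 3
    class_count: int = 3
    min_object_area: int = 64
    shape_family: str = "blob"  # blob | lobed | elongated
    overlap_allowed: bool = False
    min_gap: int = 2
    noise_std: float = 0.10
    color_jitter: float = 0.06
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("height and width must be >= 32")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if self.class_count < 1 or self.class_count > len(_BASE_COLORS) - 1:
            raise ValueError(
                f"class_count must be in [1, {len(_BASE_COLORS) - 1}]"
            )
        if self.min_object_area < 16:
            raise ValueError("min_object_area must be >= 16")
        if self.shape_family not in ("blob", "lobed", "elongated"):
            raise ValueError(f"unknown shape_family {self.shape_family!r}")


@dataclass
class Scene:
    """An image with ground-truth instance and semantic masks."""

    image: np.ndarray  # H x W x 3, float in [0, 1]
    instance_mask: np.ndarray  # H x W, int; 0 = background
    semantic_mask: np.ndarray  # H x W, int; 0 = background, 1..C classes
    object_classes: dict[int, int] = field(default_factory=dict)
    class_count: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.instance_mask.shape

    def object_ids(self) -> list[int]:
        ids = np.unique(self.instance_mask)
        return [int(i) for i in ids if i > 0]

    def object_mask(self, object_id: int) -> np.ndarray:
        if object_id not in self.object_classes:
            raise KeyError(f"object {object_id} not in scene")
        return self.instance_mask == object_id

    def validate(self) -> None:
        h, w = self.instance_mask.shape
        if self.image.shape != (h, w, 3):
            raise ValueError("image and mask shapes disagree")
        if self.semantic_mask.shape != (h, w):
            raise ValueError("semantic mask shape disagrees")
        for oid in self.object_ids():
            if oid not in self.object_classes:
                raise ValueError(f"object {oid} missing from object_classes")
            cls = self.object_classes[oid]
            if not np.all(self.semantic_mask[self.instance_mask == oid] == cls):
                raise ValueError(f"semantic mask inconsistent for object {oid}")
        if not np.all(self.semantic_mask[self.instance_mask == 0] == 0):
            raise ValueError("background pixels carry a tissue class")


@dataclass(frozen=True)
class PriorNoise:
    """Corruption model for derived semantic priors.

    ``softness`` is a temperature: 0 gives an exact one-hot encoding, larger
    values move channel scores toward uniform without changing the argmax.
    ``jitter_radius`` displaces class boundaries by a smooth random field of at
    most that many pixels.  ``confusion_rate`` is the per-pixel probability of
    swapping the winning channel with a random other channel.
    """

    softness: float = 0.25
    jitter_radius: float = 3.0
    confusion_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.softness < 0:
            raise ValueError("softness must be >= 0")
        if self.jitter_radius < 0:
            raise ValueError("jitter_radius must be >= 0")
        if not 0 <= self.confusion_rate <= 1:
            raise ValueError("confusion_rate must be in [0, 1]")

    @classmethod
    def none(cls) -> "PriorNoise":
        return cls(softness=0.0, jitter_radius=0.0, confusion_rate=0.0)


def _blob_shape(rng: np.random.Generator, size: int, family: str) -> np.ndarray:
    """One irregular binary shape in a ``size`` x ``size`` window.

    Thresholded smoothed noise yields curved organic boundaries; lobed shapes
    union several offset blobs, elongated shapes use anisotropic smoothing.
    """
    noise = rng.standard_normal((size, size))
    if family == "elongated":
        angle = rng.uniform(0, np.pi)
        # anisotropic smoothing: strong along one axis, weak across
        field_ = ndimage.gaussian_filter(noise, sigma=(size / 4.0, size / 14.0))
        field_ = ndimage.rotate(field_, np.degrees(angle), reshape=False, order=1)
    else:
        field_ = ndimage.gaussian_filter(noise, sigma=size / 7.0)
    # bias toward the window centre so the shape is compact
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / (c * c)
    score = field_ - field_.mean() + 0.9 * (1.0 - r2)
    mask = score > np.quantile(score, 0.72)
    if family == "lobed":
        n_lobes = int(rng.integers(2, 4))
        for _ in range(n_lobes):
            dy, dx = rng.integers(-size // 4, size // 4 + 1, size=2)
            mask |= np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
    # keep the largest 4-connected component
    labels, n = ndimage.label(mask, structure=FOUR_CONNECTED)
    if n == 0:
        return np.zeros((size, size), dtype=bool)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask, structure=FOUR_CONNECTED)
    return mask


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a deterministic synthetic scene from ``config``.

    Objects are placed one at a time; each is a single 4-connected region of
    at least ``min_object_area`` pixels.  Raises :class:`SceneGenerationError`
    if placement fails after ``max_attempts`` tries for some object.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    instance = np.zeros((h, w), dtype=np.int32)
    object_classes: dict[int, int] = {}

    target_size = max(
        int(2.2 * np.sqrt(config.min_object_area)),
        min(h, w) // (1 + config.n_objects // 2),
    )
    target_size = min(target_size, min(h, w) - 2)

    # round-robin class assignment in a seed-shuffled order: all classes appear
    # whenever n_objects >= class_count
    class_order = rng.permutation(np.arange(1, config.class_count + 1))

    for k in range(config.n_objects):
        oid = k + 1
        cls = int(class_order[k % config.class_count])
        placed = False
        for _ in range(config.max_attempts):
            size = int(rng.integers(max(8, target_size // 2), target_size + 1))
            shape = _blob_shape(rng, size, config.shape_family)
            if shape.sum() < config.min_object_area:
                continue
            top = int(rng.integers(0, h - size + 1))
            left = int(rng.integers(0, w - size + 1))
            canvas = np.zeros((h, w), dtype=bool)
            canvas[top : top + size, left : left + size] = shape
            if config.overlap_allowed:
                free = canvas & (instance == 0)
            else:
                forbidden = instance > 0
                if config.min_gap > 0:
                    forbidden = ndimage.binary_dilation(
                        forbidden, structure=FOUR_CONNECTED, iterations=config.min_gap
                    )
                free = canvas & ~forbidden
            if free.sum() < config.min_object_area:
                continue
            # carving away occupied pixels may split the shape: keep the
            # largest remaining 4-connected piece
            labels, n = ndimage.label(free, structure=FOUR_CONNECTED)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(free, labels, index=np.arange(1, n + 1))
            best = 1 + int(np.argmax(sizes))
            piece = labels == best
            if piece.sum() < config.min_object_area:
                continue
            instance[piece] = oid
            object_classes[oid] = cls
            placed = True
            break
        if not placed:
            raise SceneGenerationError(
                f"could not place object {oid} "
                f"({config.n_objects} objects of >= {config.min_object_area} px "
                f"on a {h}x{w} canvas)"
            )

    semantic = np.zeros((h, w), dtype=np.int32)
    for oid, cls in object_classes.items():
        semantic[instance == oid] = cls

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = _BASE_COLORS[0]
    for oid, cls in object_classes.items():
        jitter = rng.uniform(-config.color_jitter, config.color_jitter, size=3)
        image[instance == oid] = np.clip(_BASE_COLORS[cls] + jitter, 0, 1)
    image += rng.normal(0.0, config.noise_std, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)

    scene = Scene(
        image=image,
        instance_mask=instance,
        semantic_mask=semantic,
        object_classes=object_classes,
        class_count=config.class_count,
    )
    scene.validate()
    return scene


def generate_scenes(n: int, base_config: SceneConfig, seed: int) -> list[Scene]:
    """Generate ``n`` scenes with per-scene seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    scenes = []
    for _ in range(n):
        cfg_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SceneConfig(**{**base_config.__dict__, "seed": cfg_seed})
        scenes.append(generate_scene(cfg))
    return scenes


def make_prior(scene: Scene, noise: PriorNoise) -> "SemanticPrior":
    """Derive a (C+1)-channel semantic prior from the scene's ground truth.

    Emulates the output of an offline semantic segmentation model.  With all
    noise parameters zero the per-pixel argmax over channels reproduces
    ``scene.semantic_mask`` exactly.
    """
    from .prior import SemanticPrior  # local import to avoid a cycle

    rng = np.random.default_rng(noise.seed)
    h, w = scene.shape
    n_channels = scene.class_count + 1
    mask = scene.semantic_mask.copy()

    if noise.jitter_radius > 0:
        # smooth random displacement field, rescaled to max |d| = radius, so a
        # pixel's label can only change within `radius` px of a class boundary
        dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
        dx = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
        mag = np.sqrt(dy**2 + dx**2)
        scale = noise.jitter_radius / max(mag.max(), 1e-12)
        yy, xx = np.mgrid[0:h, 0:w]
        sy = np.clip(np.rint(yy + dy * scale).astype(int), 0, h - 1)
        sx = np.clip(np.rint(xx + dx * scale).astype(int), 0, w - 1)
        mask = mask[sy, sx]

    channels = np.zeros((n_channels, h, w), dtype=np.float64)
    for c in range(n_channels):
        channels[c] = mask == c

    if noise.confusion_rate > 0:
        confuse = rng.random((h, w)) < noise.confusion_rate
        ys, xs = np.nonzero(confuse)
        others = rng.integers(1, n_channels, size=ys.size)
        for y, x, delta in zip(ys, xs, others):
            winner = int(mask[y, x])
            other = (winner + int(delta)) % n_channels
            channels[winner, y, x], channels[other, y, x] = (
                channels[other, y, x],
                channels[winner, y, x],
            )

    if noise.softness > 0:
        # temperature softmax of the 0/1 scores: values strictly inside (0,1),
        # argmax unchanged
        logits = channels / noise.softness
        logits -= logits.max(axis=0, keepdims=True)
        e = np.exp(logits)
        channels = e / e.sum(axis=0, keepdims=True)

    names = ["background"] + [f"class_{c}" for c in range(1, n_channels)]
    return SemanticPrior(channels=channels.astype(np.float32), class_names=names)
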