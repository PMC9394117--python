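"""Click sets and guidance-map encodings.

User interaction is a sequence of positive (inside the object) and negative
(outside) point annotations.  The segmentation backend does not see raw
coordinates; it sees per-polarity *guidance maps*: either the minimum
Euclidean distance from each pixel to the click set (clipped), or the
pointwise maximum of unit-height Gaussians centred on the clicks.  An empty
click set of either polarity is encoded as an all-zero "blank" map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

__all__ = [
    "Polarity",
    "Click",
    "ClickSet",
    "GuidanceMap",
    "Window",
    "encode_distance",
    "encode_gaussian",
    "crop_to_window",
    "DISTANCE_CLIP_DEFAULT",
    "GAUSSIAN_SIGMA_DEFAULT",
]

DISTANCE_CLIP_DEFAULT = 255.0
GAUSSIAN_SIGMA_DEFAULT = 10.0


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class Click:
    row: int
    col: int
    polarity: Polarity

    def __post_init__(self) -> None:
        object.__setattr__(self, "row", int(self.row))
        object.__setattr__(self, "col", int(self.col))
        object.__setattr__(self, "polarity", Polarity(self.polarity))


class ClickSet:
    """Ordered click sequence; adjacent duplicates are collapsed."""

    def __init__(self, clicks: "list[Click] | None" = None):
        self._clicks: list[Click] = []
        for c in clicks or []:
            self.add(c)

    def add(self, click: Click) -> None:
        if self._clicks and self._clicks[-1] == click:
            return
        self._clicks.append(click)

    def extend(self, clicks) -> None:
        for c in clicks:
            self.add(c)

    def filtered(self, polarity: Polarity) -> "ClickSet":
        return ClickSet([c for c in self._clicks if c.polarity == polarity])

    @property
    def positives(self) -> "ClickSet":
        return self.filtered(Polarity.POSITIVE)

    @property
    def negatives(self) -> "ClickSet":
        return self.filtered(Polarity.NEGATIVE)

    def coords(self) -> np.ndarray:
        """(N, 2) array of (row, col)."""
        if not self._clicks:
            return np.empty((0, 2), dtype=int)
        return np.array([(c.row, c.col) for c in self._clicks], dtype=int)

    def copy(self) -> "ClickSet":
        return ClickSet(list(self._clicks))

    def __len__(self) -> int:
        return len(self._clicks)

    def __iter__(self):
        return iter(self._clicks)

    def __getitem__(self, i):
        return self._clicks[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, ClickSet) and self._clicks == other._clicks

    def __repr__(self) -> str:
        return f"ClickSet({self._clicks!r})"

    def to_json(self) -> list[dict]:
        return [
            {"row": c.row, "col": c.col, "polarity": c.polarity.value}
            for c in self._clicks
        ]

    @classmethod
    def from_json(cls, items) -> "ClickSet":
        return cls([Click(d["row"], d["col"], Polarity(d["polarity"])) for d in items])


@dataclass
class GuidanceMap:
    values: np.ndarray  # H x W float
    encoding: str  # "distance" | "gaussian"
    empty_flag: bool
    clip: float | None = None
    sigma: float | None = None

    def scaled(self) -> np.ndarray:
        """Values mapped to [0, 1] for backend input.

        Gaussian maps are already in [0, 1]; distance maps are divided by the
        clip so that 0 = at a click, 1 = at or beyond the clip.
        """
        if self.encoding == "gaussian" or self.empty_flag:
            return self.values
        return self.values / self.clip

    def click_pixels(self) -> np.ndarray:
        """(N, 2) pixel coordinates recoverable from the map's extrema.

        Distance maps are exactly 0 at clicks; Gaussian maps are exactly 1.
        Blank maps yield no pixels.
        """
        if self.empty_flag:
            return np.empty((0, 2), dtype=int)
        if self.encoding == "distance":
            ys, xs = np.nonzero(self.values == 0.0)
        else:
            ys, xs = np.nonzero(self.values >= 1.0 - 1e-12)
        return np.stack([ys, xs], axis=1)


def _check_clicks(clicks: ClickSet, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    pts = clicks.coords()
    if pts.size and (
        (pts[:, 0] < 0).any()
        or (pts[:, 0] >= h).any()
        or (pts[:, 1] < 0).any()
        or (pts[:, 1] >= w).any()
    ):
        raise ValueError(f"click outside image bounds {shape}")
    return pts


def _min_sq_distance(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Exact per-pixel squared Euclidean distance to the nearest click."""
    seed = np.ones(shape, dtype=bool)
    seed[pts[:, 0], pts[:, 1]] = False
    d = ndimage.distance_transform_edt(seed)
    return d * d


def encode_distance(
    clicks: ClickSet, shape: tuple[int, int], clip: float = DISTANCE_CLIP_DEFAULT
) -> GuidanceMap:
    """Minimum-Euclidean-distance guidance map, clipped at ``clip``.

    The value at every click pixel is exactly 0.  An empty click set encodes
    as a blank (all-zero) map with ``empty_flag`` set.
    """
    if clip <= 0:
        raise ValueError("clip must be positive")
    pts = _check_clicks(clicks, shape)
    if pts.shape[0] == 0:
        return GuidanceMap(
            np.zeros(shape), encoding="distance", empty_flag=True, clip=clip
        )
    values = np.minimum(np.sqrt(_min_sq_distance(pts, shape)), clip)
    return GuidanceMap(values, encoding="distance", empty_flag=False, clip=clip)


def encode_gaussian(
    clicks: ClickSet, shape: tuple[int, int], sigma: float = GAUSSIAN_SIGMA_DEFAULT
) -> GuidanceMap:
    """Pointwise-max-of-Gaussians guidance map with unit peaks at clicks.

    Because all Gaussians share one sigma, the pointwise max equals
    exp(-d^2 / (2 sigma^2)) for d the distance to the nearest click.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = _check_clicks(clicks, shape)
    if pts.shape[0] == 0:
        return GuidanceMap(
            np.zeros(shape), encoding="gaussian", empty_flag=True, sigma=sigma
        )
    values = np.exp(-_min_sq_distance(pts, shape) / (2.0 * sigma * sigma))
    return GuidanceMap(values, encoding="gaussian", empty_flag=False, sigma=sigma)


@dataclass(frozen=True)
class Window:
    """A crop placement record: restores windowed results to full frame."""

    top: int
    left: int
    height: int
    width: int
    full_shape: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.full_shape
        if not (
            0 <= self.top
            and 0 <= self.left
            and self.height > 0
            and self.width > 0
            and self.top + self.height <= h
            and self.left + self.width <= w
        ):
            raise ValueError("window outside image bounds")

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "Window":
        return cls(0, 0, shape[0], shape[1], tuple(shape))

    def crop(self, array: np.ndarray) -> np.ndarray:
        return array[
            self.top : self.top + self.height, self.left : self.left + self.width
        ]

    def embed(self, windowed: np.ndarray, fill=0) -> np.ndarray:
        """Place a windowed result at full resolution, ``fill`` outside."""
        if windowed.shape[:2] != (self.height, self.width):
            raise ValueError("windowed array does not match window size")
        out_shape = self.full_shape + windowed.shape[2:]
        full = np.full(out_shape, fill, dtype=windowed.dtype)
        full[
            self.top : self.top + self.height, self.left : self.left + self.width
        ] = windowed
        return full

    def shift_clicks(self, clicks: ClickSet) -> ClickSet:
        return ClickSet(
            [Click(c.row - self.top, c.col - self.left, c.polarity) for c in clicks]
        )


@dataclass
class WindowedInputs:
    image: np.ndarray
    prior_channels: np.ndarray | None
    guidance: list[GuidanceMap]
    clicks: ClickSet
    window: Window


def crop_to_window(
    window: Window,
    image: np.ndarray,
    clicks: ClickSet,
    prior_channels: np.ndarray | None = None,
    guidance: "list[GuidanceMap] | None" = None,
) -> WindowedInputs:
    """Crop image, prior and guidance maps identically to ``window``.

    Positive clicks must all lie inside the window (the object of interest is
    inside the box); negative clicks outside the window are dropped.
    """
    for c in clicks.positives:
        if not (
            window.top <= c.row < window.top + window.height
            and window.left <= c.col < window.left + window.width
        ):
            raise ValueError(f"positive click {c} outside window")
    kept = ClickSet(
        [
            c
            for c in clicks
            if window.top <= c.row < window.top + window.height
            and window.left <= c.col < window.left + window.width
        ]
    )
    cropped_prior = None
    if prior_channels is not None:
        cropped_prior = np.stack([window.crop(ch) for ch in prior_channels])
    cropped_guidance = []
    for g in guidance or []:
        cropped_guidance.append(
            GuidanceMap(
                values=window.crop(g.values).copy(),
                encoding=g.encoding,
                empty_flag=g.empty_flag,
                clip=g.clip,
                sigma=g.sigma,
            )
        )
    return WindowedInputs(
        image=window.crop(image).copy(),
        prior_channels=cropped_prior,
        guidance=cropped_guidance,
        clicks=window.shift_clicks(kept),
        window=window,
    )
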