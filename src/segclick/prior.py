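"""Semantic prior maps and prior-channel selection.

A semantic prior is a (C+1)-channel per-pixel class-score map produced by an
offline semantic segmentation model (channel 0 is background).  The backend
receives a single channel of it: the tissue class scoring highest at the
positive click locations.  When no prior is available a blank (all-zero)
channel is substituted and the backend behaves as a click-only segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import ClickSet

__all__ = ["SemanticPrior", "PriorChannel", "select_channel", "blank_prior"]


@dataclass
class SemanticPrior:
    channels: np.ndarray  # (C+1) x H x W, channel 0 = background
    class_names: list[str]

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] < 2:
            raise ValueError("prior needs >= 2 channels (background + classes)")
        if len(self.class_names) != self.channels.shape[0]:
            raise ValueError("class_names length must match channel count")

    @property
    def n_classes(self) -> int:
        return self.channels.shape[0] - 1

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def argmax_mask(self) -> np.ndarray:
        return np.argmax(self.channels, axis=0)


@dataclass
class PriorChannel:
    """The single channel handed to a backend; blank when absent."""

    values: np.ndarray  # H x W
    class_id: int | None  # None for a blank prior
    is_blank: bool


def select_channel(prior: SemanticPrior, positive_clicks: ClickSet) -> PriorChannel:
    """Pick the tissue channel scoring highest at the positive clicks.

    Scores are summed over the click pixels per class; the background channel
    is never selectable and ties break toward the lowest class index.  The
    selection is invariant to click order and to any strictly monotone
    per-pixel transform applied to all channels alike (so it does not matter
    whether the prior stores probabilities or pre-sigmoid scores).
    """
    if len(positive_clicks) == 0:
        raise ValueError("channel selection requires at least one positive click")
    pts = positive_clicks.coords()
    h, w = prior.spatial_shape
    if (pts[:, 0] >= h).any() or (pts[:, 1] >= w).any() or (pts < 0).any():
        raise ValueError("positive click outside prior bounds")
    sums = prior.channels[1:, pts[:, 0], pts[:, 1]].sum(axis=1)
    class_id = 1 + int(np.argmax(sums))  # np.argmax takes the lowest index on ties
    return PriorChannel(
        values=np.asarray(prior.channels[class_id], dtype=np.float64),
        class_id=class_id,
        is_blank=False,
    )


def blank_prior(shape: tuple[int, int]) -> PriorChannel:
    """An all-zero prior channel flagged as absent."""
    return PriorChannel(values=np.zeros(shape), class_id=None, is_blank=True)
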