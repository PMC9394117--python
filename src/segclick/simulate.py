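"""Simulated user interaction.

Two samplers emulate an annotator: an *initial* sampler that scatters a fixed
budget of positive and negative clicks over an object and its surroundings,
and a *corrective* sampler that compares a prediction with ground truth,
groups the wrong pixels into 4-connected error regions, and places clicks
inside regions drawn with probability proportional to their size.  A full
refinement *session* alternates prediction and correction until the target
IoU is reached or the click budget (20 by default) is exhausted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .encoding import Click, ClickSet, Polarity
from .scene import FOUR_CONNECTED, Scene

__all__ = [
    "SimConfig",
    "ErrorRegion",
    "SessionRecord",
    "sample_initial",
    "find_error_regions",
    "sample_corrections",
    "simulate_session",
    "object_center",
]


@dataclass(frozen=True)
class SimConfig:
    """Interaction-protocol constants.

    ``total_clicks``: overall click budget per object (the protocol cap).
    ``d_step``: minimum spacing between successive positive clicks.
    ``iou_target``: refinement stops once IoU reaches this fraction.
    ``r_max`` / ``k_max``: at most R regions corrected per round and at most
    K clicks placed over them, K >= R.
    ``d_near`` / ``ring_inner`` / ``ring_outer``: dilation radii defining
    "touching/nearby objects" and the background ring for negative clicks.
    """

    total_clicks: int = 20
    d_step: int = 10
    iou_target: float = 0.85
    r_max: int = 1
    k_max: int = 1
    d_near: int = 10
    ring_inner: int = 5
    ring_outer: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_clicks < 1:
            raise ValueError("total_clicks must be >= 1")
        if self.d_step < 1:
            raise ValueError("d_step must be >= 1")
        if not 0 < self.iou_target <= 1:
            raise ValueError("iou_target must be in (0, 1]")
        if self.r_max < 1 or self.k_max < self.r_max:
            raise ValueError("need k_max >= r_max >= 1")


@dataclass
class ErrorRegion:
    """One 4-connected component of mispredicted pixels."""

    pixels: np.ndarray  # (N, 2) rows/cols
    kind: str  # "false_negative" | "false_positive"

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SessionStep:
    cumulative_clicks: int
    iou: float
    prediction_hash: str


@dataclass
class SessionRecord:
    """Trajectory of one refinement session on one object."""

    object_id: int
    steps: list[SessionStep] = field(default_factory=list)
    clicks_to_target: int = 0
    reached: bool = False
    clicks: ClickSet = field(default_factory=ClickSet)
    prior_mode: str = "with_prior"
    seed: int | None = None

    def iou_at(self, k: int) -> float:
        """IoU after ``k`` cumulative clicks, carrying the last value forward."""
        iou = 0.0
        for step in self.steps:
            if step.cumulative_clicks <= k:
                iou = step.iou
            else:
                break
        return iou

    def to_json(self) -> dict:
        return {
            "object_id": self.object_id,
            "steps": [
                {
                    "cumulative_clicks": s.cumulative_clicks,
                    "iou": s.iou,
                    "prediction_hash": s.prediction_hash,
                }
                for s in self.steps
            ],
            "clicks_to_target": self.clicks_to_target,
            "reached": self.reached,
            "clicks": self.clicks.to_json(),
            "prior_mode": self.prior_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, d: dict) -> "SessionRecord":
        rec = cls(
            object_id=d["object_id"],
            steps=[
                SessionStep(s["cumulative_clicks"], s["iou"], s["prediction_hash"])
                for s in d["steps"]
            ],
            clicks_to_target=d["clicks_to_target"],
            reached=d["reached"],
            clicks=ClickSet.from_json(d["clicks"]),
            prior_mode=d.get("prior_mode", "with_prior"),
            seed=d.get("seed"),
        )
        return rec


def _mask_hash(mask: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(mask.astype(np.uint8))).hexdigest()[:16]


def object_center(mask: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    """A most-interior pixel of ``mask``: argmax of the interior distance
    transform, drawn uniformly among co-maximal pixels."""
    if not mask.any():
        raise ValueError("empty mask has no center")
    dist = ndimage.distance_transform_edt(mask)
    ys, xs = np.nonzero(dist == dist.max())
    i = int(rng.integers(0, ys.size))
    return int(ys[i]), int(xs[i])


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    return ndimage.binary_dilation(mask, structure=FOUR_CONNECTED, iterations=radius)


def _sample_from(
    candidates: np.ndarray, count: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    ys, xs = np.nonzero(candidates)
    n = min(count, ys.size)
    if n == 0:
        return []
    idx = rng.choice(ys.size, size=n, replace=False)
    return [(int(ys[i]), int(xs[i])) for i in idx]


def sample_initial(
    scene: Scene, object_id: int, cfg: SimConfig, rng: np.random.Generator
) -> ClickSet:
    """Scatter the full click budget over an object and its surroundings.

    Draws n ~ U[1, cap] positives and m = cap - n negatives.  The first
    positive sits at the object centre; later positives keep ``d_step``
    pixels from all earlier ones.  Negatives go first onto nearby/touching
    objects, then into a background ring around the target.  Shortfalls in
    one polarity are reallocated to the other, so the sampler emits exactly
    ``cfg.total_clicks`` clicks whenever enough legal pixels exist.
    """
    if object_id not in scene.object_classes:
        raise ValueError(f"object {object_id} absent from scene")
    target = scene.instance_mask == object_id
    if not target.any():
        raise ValueError(f"object {object_id} has no pixels")

    cap = cfg.total_clicks
    n_pos = int(rng.integers(1, cap + 1))
    clicks = ClickSet()

    # positive clicks: centre first, then d_step-separated object pixels
    positives: list[tuple[int, int]] = [object_center(target, rng)]
    allowed = target.copy()
    for (r, c) in positives:
        rr, cc = np.ogrid[0 : target.shape[0], 0 : target.shape[1]]
        allowed &= (rr - r) ** 2 + (cc - c) ** 2 >= cfg.d_step**2
    while len(positives) < n_pos and allowed.any():
        pick = _sample_from(allowed, 1, rng)[0]
        positives.append(pick)
        rr, cc = np.ogrid[0 : target.shape[0], 0 : target.shape[1]]
        allowed &= (rr - pick[0]) ** 2 + (cc - pick[1]) ** 2 >= cfg.d_step**2

    n_neg = cap - len(positives)  # shortfall reallocated to negatives

    negatives: list[tuple[int, int]] = []
    others = (scene.instance_mask > 0) & ~target
    near = others & _dilate(target, cfg.d_near)
    negatives.extend(_sample_from(near, n_neg, rng))
    if len(negatives) < n_neg:
        ring = _dilate(target, cfg.ring_outer) & ~_dilate(target, cfg.ring_inner)
        ring &= ~target
        taken = np.zeros_like(target)
        for (r, c) in negatives:
            taken[r, c] = True
        negatives.extend(_sample_from(ring & ~taken, n_neg - len(negatives), rng))

    for (r, c) in positives:
        clicks.add(Click(r, c, Polarity.POSITIVE))
    for (r, c) in negatives:
        clicks.add(Click(r, c, Polarity.NEGATIVE))
    return clicks


def find_error_regions(pred_mask: np.ndarray, gt_mask: np.ndarray) -> list[ErrorRegion]:
    """Partition mispredicted pixels into 4-connected error regions.

    False negatives (missed object pixels) and false positives (spurious
    prediction pixels) are labelled separately; together the regions exactly
    tile the symmetric difference of the two masks.
    """
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("prediction and ground truth shapes differ")
    pred = pred_mask.astype(bool)
    gt = gt_mask.astype(bool)
    regions: list[ErrorRegion] = []
    for err, kind in ((gt & ~pred, "false_negative"), (pred & ~gt, "false_positive")):
        labels, n = ndimage.label(err, structure=FOUR_CONNECTED)
        for i in range(1, n + 1):
            ys, xs = np.nonzero(labels == i)
            regions.append(ErrorRegion(np.stack([ys, xs], axis=1), kind))
    return regions


def _region_click(
    region: ErrorRegion,
    shape: tuple[int, int],
    rng: np.random.Generator,
    avoid: set[tuple[int, int]],
) -> tuple[int, int] | None:
    """Most-interior unclicked pixel of the region (ties broken by the rng).

    Interior distance is computed on the full region; pixels already clicked
    are then excluded so a correction never re-spends budget on the same
    spot.  Returns None when every region pixel is already clicked.
    """
    mask = np.zeros(shape, dtype=bool)
    mask[region.pixels[:, 0], region.pixels[:, 1]] = True
    dist = ndimage.distance_transform_edt(mask)
    if avoid:
        rows = [p for p in map(tuple, region.pixels) if p not in avoid]
        if not rows:
            return None
        rows = np.array(rows)
        vals = dist[rows[:, 0], rows[:, 1]]
        best = rows[vals == vals.max()]
    else:
        ys, xs = np.nonzero(dist == dist.max())
        best = np.stack([ys, xs], axis=1)
    i = int(rng.integers(0, best.shape[0]))
    return int(best[i, 0]), int(best[i, 1])


def sample_corrections(
    regions: list[ErrorRegion],
    existing_clicks: ClickSet,
    cfg: SimConfig,
    rng: np.random.Generator,
    shape: tuple[int, int] | None = None,
) -> ClickSet:
    """Place corrective clicks inside size-weighted sampled error regions.

    R <= min(r_max, #regions, remaining budget) regions are drawn without
    replacement with probability proportional to pixel count; K in [R, k_max]
    clicks are placed, at least one per selected region, every click inside
    its region.  Missed-object regions receive positive clicks, spurious
    regions negative ones.  The running total never exceeds the budget.
    """
    if not regions:
        raise ValueError("no error regions to correct")
    budget = cfg.total_clicks - len(existing_clicks)
    if budget <= 0:
        raise ValueError("click budget exhausted")
    if shape is None:
        extent = np.concatenate([r.pixels for r in regions])
        shape = (int(extent[:, 0].max()) + 1, int(extent[:, 1].max()) + 1)

    sizes = np.array([r.size for r in regions], dtype=float)
    n_regions = min(cfg.r_max, len(regions), budget)
    chosen = rng.choice(
        len(regions), size=n_regions, replace=False, p=sizes / sizes.sum()
    )
    k_total = int(rng.integers(n_regions, min(cfg.k_max, budget) + 1)) \
        if min(cfg.k_max, budget) > n_regions else n_regions

    additions = ClickSet()
    polarity = {
        "false_negative": Polarity.POSITIVE,
        "false_positive": Polarity.NEGATIVE,
    }
    used: set[tuple[int, int]] = {(c.row, c.col) for c in existing_clicks}
    # one interior click per selected region
    for idx in chosen:
        region = regions[int(idx)]
        pick = _region_click(region, shape, rng, avoid=used)
        if pick is None:  # region fully clicked already
            continue
        r, c = pick
        additions.add(Click(r, c, polarity[region.kind]))
        used.add((r, c))
    # extra clicks (K > R): size-weighted regions, uniform unused pixels
    extra = k_total - len(chosen)
    for _ in range(extra):
        idx = int(rng.choice(len(chosen), p=sizes[chosen] / sizes[chosen].sum()))
        region = regions[int(chosen[idx])]
        free = [tuple(p) for p in region.pixels if tuple(p) not in used]
        if not free:
            continue
        r, c = free[int(rng.integers(0, len(free)))]
        additions.add(Click(int(r), int(c), polarity[region.kind]))
        used.add((int(r), int(c)))
    return additions


def simulate_session(
    scene: Scene,
    object_id: int,
    backend,
    prior=None,
    prior_mode: str = "with_prior",
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SessionRecord:
    """Run one simulated refinement session on an object.

    Starts from a single positive click at the object centre, predicts,
    then alternates corrective sampling and re-prediction until the IoU
    target is met or the click budget is spent.  ``clicks_to_target`` is the
    first cumulative click count achieving the target, else the cap.
    """
    from .backends import make_backend_input  # late import: circular module pair
    from .evaluation import iou as iou_fn

    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if prior_mode not in ("with_prior", "blank"):
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    gt = scene.object_mask(object_id)

    clicks = ClickSet()
    r, c = object_center(gt, rng)
    clicks.add(Click(r, c, Polarity.POSITIVE))

    record = SessionRecord(object_id=object_id, prior_mode=prior_mode)
    if hasattr(backend, "bind"):
        backend.bind(scene, object_id)

    reached = False
    while True:
        inp = make_backend_input(scene, clicks, prior=prior, prior_mode=prior_mode)
        try:
            pred = backend.predict(inp)
        except Exception as exc:  # annotate failures with session context
            raise RuntimeError(
                f"backend {type(backend).__name__} failed on object {object_id} "
                f"after {len(clicks)} clicks"
            ) from exc
        iou = iou_fn(pred, gt)
        record.steps.append(SessionStep(len(clicks), iou, _mask_hash(pred)))
        if iou >= cfg.iou_target and not reached:
            reached = True
            record.clicks_to_target = len(clicks)
            record.reached = True
        if reached or len(clicks) >= cfg.total_clicks:
            break
        regions = find_error_regions(pred, gt)
        if not regions:  # pred == gt, iou == 1 handled above; defensive
            break
        before = len(clicks)
        clicks.extend(
            sample_corrections(regions, clicks, cfg, rng, shape=scene.shape)
        )
        if len(clicks) == before:
            # every error pixel already clicked: the backend cannot be
            # improved further; the record stays capped at the last IoU
            break
    if not record.reached:
        record.clicks_to_target = cfg.total_clicks
    record.clicks = clicks
    return record
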