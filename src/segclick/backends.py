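"""Segmentation backends.

Every backend honours one contract: given a :class:`BackendInput` — image,
positive guidance, negative guidance, one (possibly blank) semantic-prior
channel, all spatially aligned — ``predict_proba`` returns a per-pixel object
probability and ``predict`` a binary mask at threshold 0.5.  Backends are
sklearn-style estimators (``fit`` / ``predict`` / ``get_params``) behind a
small registry so larger models can be plugged in.

Four backends ship:

* ``oracle``           — returns the ground truth (test double; binds to the
                         session target).
* ``constant``         — returns a constant mask (test double).
* ``prior_threshold``  — training-free baseline: flood-fills the thresholded
                         prior channel from positive clicks, falling back to
                         colour-similarity region growing when the prior is
                         blank or silent at a click; negative clicks carve
                         away colour-similar regions.
* ``pixel_mlp``        — the trainable reference backend: a per-pixel MLP on
                         multi-scale features of the input channels, trained
                         with the iterative click-simulation scheme
                         (corrective clicks refreshed from the current
                         model's errors, random prior reset, bootstrapped
                         cross-entropy, exponentially decaying learning
                         rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .encoding import (
    ClickSet,
    GuidanceMap,
    Window,
    encode_distance,
    encode_gaussian,
)
from .prior import PriorChannel, SemanticPrior, blank_prior, select_channel
from .scene import FOUR_CONNECTED, PriorNoise, Scene, make_prior

__all__ = [
    "BackendInput",
    "TrainConfig",
    "make_backend_input",
    "bootstrapped_ce_loss",
    "learning_rate",
    "InteractiveSegmenter",
    "GroundTruthOracleBackend",
    "ConstantMaskBackend",
    "PriorThresholdBackend",
    "PixelMLPBackend",
    "BACKEND_REGISTRY",
    "make_backend",
]

PROB_CLAMP = 1e-7
DECISION_THRESHOLD = 0.5


@dataclass
class BackendInput:
    """Aligned input channels for one prediction."""

    image: np.ndarray  # H x W x 3 in [0, 1]
    pos_guidance: GuidanceMap
    neg_guidance: GuidanceMap
    prior: PriorChannel
    window: Window | None = None

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        for name, arr in (
            ("pos_guidance", self.pos_guidance.values),
            ("neg_guidance", self.neg_guidance.values),
            ("prior", self.prior.values),
        ):
            if arr.shape != (h, w):
                raise ValueError(f"{name} shape {arr.shape} != image plane {(h, w)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def make_backend_input(
    scene: Scene,
    clicks: ClickSet,
    prior: SemanticPrior | None = None,
    prior_mode: str = "with_prior",
    encoder: str = "gaussian",
    sigma: float | None = None,
    clip: float | None = None,
    window: Window | None = None,
) -> BackendInput:
    """Assemble a :class:`BackendInput` from a scene, clicks and a prior.

    ``prior_mode="blank"`` (or a missing prior) substitutes an all-zero prior
    channel; otherwise the channel scoring highest at the positive clicks is
    selected.  Guidance encoding defaults to Gaussian, under which a blank
    map genuinely means "no clicks".
    """
    shape = scene.shape
    pos, neg = clicks.positives, clicks.negatives
    if encoder == "gaussian":
        kw = {} if sigma is None else {"sigma": sigma}
        pos_g = encode_gaussian(pos, shape, **kw)
        neg_g = encode_gaussian(neg, shape, **kw)
    elif encoder == "distance":
        kw = {} if clip is None else {"clip": clip}
        pos_g = encode_distance(pos, shape, **kw)
        neg_g = encode_distance(neg, shape, **kw)
    else:
        raise ValueError(f"unknown encoder {encoder!r}")
    if prior_mode == "blank" or prior is None:
        channel = blank_prior(shape)
    elif prior_mode == "with_prior":
        channel = select_channel(prior, pos)
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    return BackendInput(
        image=scene.image, pos_guidance=pos_g, neg_guidance=neg_g,
        prior=channel, window=window,
    )


def _pixel_ce(probabilities: np.ndarray, gt: np.ndarray) -> np.ndarray:
    p = np.clip(probabilities, PROB_CLAMP, 1.0 - PROB_CLAMP)
    g = gt.astype(np.float64)
    return -(g * np.log(p) + (1.0 - g) * np.log(1.0 - p))


def bootstrapped_ce_loss(
    probabilities: np.ndarray, gt: np.ndarray, fraction: float
) -> float:
    """Binary cross-entropy averaged over the hardest ``fraction`` of pixels.

    ``fraction=1`` reduces to the plain mean BCE.  Probabilities are clamped
    away from {0, 1} so the loss is always finite.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if probabilities.shape != gt.shape:
        raise ValueError("shape mismatch")
    if probabilities.size == 0:
        raise ValueError("empty mask")
    ce = _pixel_ce(probabilities, gt).ravel()
    k = int(np.ceil(fraction * ce.size))
    top = np.partition(ce, ce.size - k)[ce.size - k:]
    return float(top.mean())


@dataclass(frozen=True)
class TrainConfig:
    """Iterative-training configuration.

    Defaults for the learning-rate schedule follow the reference fine-tuning
    recipe (50 epochs, batch 5, initial lr 1e-4 with decay 0.9 every 5
    epochs, floored at 5e-7).  The bootstrap fraction, prior-reset
    probability and correction rounds are this package's defaults.
    """

    epochs: int = 50
    batch_size: int = 5
    initial_lr: float = 1e-4
    lr_decay_rate: float = 0.9
    decay_interval: int = 5
    lr_floor: float = 5e-7
    prior_reset_prob: float = 0.3
    bootstrap_fraction: float = 0.25
    correction_iterations: int = 3
    initial_budget_max: int = 6  # initial clicks per training sample, U[1, this]
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if not 0 <= self.prior_reset_prob <= 1:
            raise ValueError("prior_reset_prob must be in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Exponentially decayed learning rate at ``epoch``, floored."""
    lr = cfg.initial_lr * cfg.lr_decay_rate ** (epoch // cfg.decay_interval)
    return max(lr, cfg.lr_floor)


class InteractiveSegmenter(BaseEstimator):
    """Base class: the backend contract plus sklearn estimator plumbing."""

    def bind(self, scene: Scene, object_id: int) -> None:
        """Give session-aware test doubles access to the target; no-op here."""

    def fit(self, scenes, y=None):
        return self

    def predict_proba(self, inp: BackendInput) -> np.ndarray:
        raise NotImplementedError

    def predict(self, inp: BackendInput) -> np.ndarray:
        return self.predict_proba(inp) >= DECISION_THRESHOLD


class GroundTruthOracleBackend(InteractiveSegmenter):
    """Always returns the bound object's ground-truth mask (test double)."""

    def bind(self, scene: Scene, object_id: int) -> None:
        self.gt_ = scene.object_mask(object_id)

    def predict_proba(self, inp: BackendInput) -> np.ndarray:
        if not hasattr(self, "gt_"):
            raise RuntimeError("oracle backend not bound to a session")
        if self.gt_.shape != inp.shape:
            raise ValueError("bound ground truth does not match input shape")
        return self.gt_.astype(np.float64)


class ConstantMaskBackend(InteractiveSegmenter):
    """Returns a constant probability everywhere (test double)."""

    def __init__(self, value: float = 0.0):
        self.value = value

    def predict_proba(self, inp: BackendInput) -> np.ndarray:
        return np.full(inp.shape, self.value, dtype=np.float64)


def _color_region(
    blurred: np.ndarray, seed: tuple[int, int], tol: float
) -> np.ndarray:
    """4-connected component of colour-similar pixels containing ``seed``."""
    color = blurred[seed[0], seed[1]]
    similar = np.linalg.norm(blurred - color, axis=2) <= tol
    labels, _ = ndimage.label(similar, structure=FOUR_CONNECTED)
    return labels == labels[seed[0], seed[1]]


class PriorThresholdBackend(InteractiveSegmenter):
    """Training-free baseline: click-seeded flood fill of the prior channel.

    For each positive click, if the prior channel exceeds ``threshold`` at
    the click the 4-connected component of the thresholded prior containing
    it is added; otherwise (including the blank-prior case) a
    colour-similarity region grown from the click on a lightly blurred image
    is added.  Each negative click landing inside the mask carves away the
    colour-similar region around it.  With a noise-free prior and an
    isolated object, one positive click recovers the object exactly.
    """

    def __init__(
        self,
        threshold: float = 0.5,
        color_tol: float = 0.2,
        blur_sigma: float = 1.0,
    ):
        self.threshold = threshold
        self.color_tol = color_tol
        self.blur_sigma = blur_sigma

    def predict_proba(self, inp: BackendInput) -> np.ndarray:
        blurred = np.stack(
            [
                ndimage.gaussian_filter(inp.image[..., c], self.blur_sigma)
                for c in range(inp.image.shape[2])
            ],
            axis=2,
        )
        candidate = None
        labels = None
        if not inp.prior.is_blank:
            candidate = inp.prior.values >= self.threshold
            labels, _ = ndimage.label(candidate, structure=FOUR_CONNECTED)

        mask = np.zeros(inp.shape, dtype=bool)
        for r, c in inp.pos_guidance.click_pixels():
            if candidate is not None and candidate[r, c]:
                mask |= labels == labels[r, c]
            else:
                mask |= _color_region(blurred, (r, c), self.color_tol)
        for r, c in inp.neg_guidance.click_pixels():
            if mask[r, c]:
                mask &= ~_color_region(blurred, (r, c), self.color_tol)
        return mask.astype(np.float64)


def _blur(channel: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(channel, sigma)


class _Adam:
    """Minimal Adam optimiser over a list of numpy parameter arrays."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class PixelMLPBackend(InteractiveSegmenter):
    """Trainable reference backend: per-pixel MLP on multi-scale features.

    The encoder is a fixed Gaussian pyramid over the six input channels
    (RGB, positive guidance, negative guidance, prior channel) plus a few
    prior/colour and prior/guidance interaction products; the decoder is a
    pixelwise one-hidden-layer MLP trained by backpropagation.  Training
    follows the iterative click-simulation scheme: per sample, initial
    clicks are drawn, the current model's errors generate corrective clicks
    for a few rounds, the prior channel is randomly reset to blank, and the
    bootstrapped cross-entropy of the final prediction is minimised with an
    exponentially decaying learning rate.
    """

    def __init__(
        self,
        config: TrainConfig | None = None,
        hidden_units: int = 24,
        feature_sigmas: tuple = (2.0, 4.0, 8.0),
        guidance_sigma: float = 10.0,
        prior_noise: PriorNoise | None = None,
    ):
        self.config = config
        self.hidden_units = hidden_units
        self.feature_sigmas = feature_sigmas
        self.guidance_sigma = guidance_sigma
        self.prior_noise = prior_noise

    # -- features ---------------------------------------------------------

    def _features(self, inp: BackendInput) -> np.ndarray:
        """(H*W, F) feature matrix for one input."""
        h, w = inp.shape
        base = [
            inp.image[..., 0],
            inp.image[..., 1],
            inp.image[..., 2],
            inp.pos_guidance.scaled(),
            inp.neg_guidance.scaled(),
            inp.prior.values,
        ]
        feats = list(base)
        for ch in base:
            for s in self.feature_sigmas:
                feats.append(_blur(ch, s))
        prior_b = _blur(inp.prior.values, self.feature_sigmas[1])
        pos_b = _blur(inp.pos_guidance.scaled(), self.feature_sigmas[-1])
        # interactions: "prior-supported" colour and click evidence
        feats.append(prior_b * inp.image[..., 0])
        feats.append(prior_b * inp.image[..., 1])
        feats.append(prior_b * inp.image[..., 2])
        feats.append(prior_b * pos_b)
        feats.append(inp.prior.values * inp.pos_guidance.scaled())
        return np.stack([f.ravel() for f in feats], axis=1)

    @property
    def n_features(self) -> int:
        return 6 * (1 + len(self.feature_sigmas)) + 5

    # -- forward / backward ----------------------------------------------

    def _forward(self, X: np.ndarray):
        z1 = X @ self.W1_ + self.b1_
        h = np.maximum(z1, 0.0)
        z2 = h @ self.W2_ + self.b2_
        p = 1.0 / (1.0 + np.exp(-z2))
        return p, h, z1

    def _backward(
        self, X: np.ndarray, p: np.ndarray, h: np.ndarray, z1: np.ndarray,
        gt: np.ndarray, fraction: float,
    ):
        """Gradients of the bootstrapped BCE w.r.t. all parameters."""
        n = X.shape[0]
        ce = _pixel_ce(p, gt)
        k = int(np.ceil(fraction * n))
        idx = np.argpartition(ce, n - k)[n - k:]
        sel = np.zeros(n, dtype=bool)
        sel[idx] = True
        # d(mean top-k BCE)/dz2 = (p - g)/k on selected pixels (clamped pixels
        # excluded by the clamp's zero gradient is ignored: clamp is epsilon)
        dz2 = np.where(sel, p - gt.astype(np.float64), 0.0) / k
        gW2 = h.T @ dz2
        gb2 = dz2.sum()
        dh = np.outer(dz2, self.W2_)
        dz1 = dh * (z1 > 0)
        gW1 = X.T @ dz1
        gb1 = dz1.sum(axis=0)
        return [gW1, gb1, gW2, gb2], float(
            np.partition(ce, n - k)[n - k:].mean()
        )

    # -- contract ---------------------------------------------------------

    def predict_proba(self, inp: BackendInput) -> np.ndarray:
        if not hasattr(self, "W1_"):
            raise RuntimeError("PixelMLPBackend is not fitted")
        X = self._features(inp)
        p, _, _ = self._forward(X)
        return p.reshape(inp.shape)

    # -- training ---------------------------------------------------------

    def fit(self, scenes, y=None, priors=None):
        """Train on a list of scenes with the iterative click scheme.

        ``priors`` may supply one :class:`SemanticPrior` per scene; otherwise
        priors are derived from each scene's ground truth with
        ``self.prior_noise`` (moderate corruption by default).
        """
        from .simulate import (
            SimConfig,
            find_error_regions,
            sample_corrections,
            sample_initial,
        )

        cfg = self.config or TrainConfig()
        if not scenes:
            raise ValueError("empty training set")
        rng = np.random.default_rng(cfg.seed)

        noise = self.prior_noise or PriorNoise()
        if priors is None:
            priors = [
                make_prior(
                    s,
                    PriorNoise(
                        softness=noise.softness,
                        jitter_radius=noise.jitter_radius,
                        confusion_rate=noise.confusion_rate,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    ),
                )
                for s in scenes
            ]

        samples = [
            (i, oid) for i, s in enumerate(scenes) for oid in s.object_ids()
        ]
        F, H = self.n_features, self.hidden_units
        self.W1_ = rng.normal(0.0, np.sqrt(2.0 / F), size=(F, H))
        self.b1_ = np.zeros(H)
        self.W2_ = rng.normal(0.0, np.sqrt(1.0 / H), size=H)
        self.b2_ = 0.0
        params = [self.W1_, self.b1_, self.W2_, self.b2_]
        opt = _Adam(params[:3])  # b2_ is a scalar, handled separately
        b2m = b2v = 0.0

        self.history_ = []
        for epoch in range(cfg.epochs):
            lr = learning_rate(epoch, cfg)
            order = rng.permutation(len(samples))
            acc = [np.zeros_like(self.W1_), np.zeros_like(self.b1_),
                   np.zeros_like(self.W2_), 0.0]
            in_batch = 0
            losses = []
            for j in order:
                si, oid = samples[j]
                scene, prior = scenes[si], priors[si]
                gt = scene.object_mask(oid).ravel()
                use_blank = rng.random() < cfg.prior_reset_prob
                prior_mode = "blank" if use_blank else "with_prior"

                init_budget = int(rng.integers(1, cfg.initial_budget_max + 1))
                sim_init = SimConfig(total_clicks=init_budget, seed=0)
                sim_corr = SimConfig(total_clicks=20, r_max=1, k_max=2, seed=0)
                clicks = sample_initial(scene, oid, sim_init, rng)

                inp = make_backend_input(
                    scene, clicks, prior=prior, prior_mode=prior_mode,
                    sigma=self.guidance_sigma,
                )
                for _ in range(cfg.correction_iterations):
                    if len(clicks) >= sim_corr.total_clicks:
                        break
                    pred = self.predict(inp)
                    regions = find_error_regions(pred, gt.reshape(scene.shape))
                    if not regions:
                        break
                    clicks.extend(
                        sample_corrections(
                            regions, clicks, sim_corr, rng, shape=scene.shape
                        )
                    )
                    inp = make_backend_input(
                        scene, clicks, prior=prior, prior_mode=prior_mode,
                        sigma=self.guidance_sigma,
                    )

                X = self._features(inp)
                p, hdn, z1 = self._forward(X)
                grads, loss = self._backward(
                    X, p, hdn, z1, gt, cfg.bootstrap_fraction
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) on scene {si} "
                        f"object {oid}, epoch {epoch}"
                    )
                losses.append(loss)
                for a, g in zip(acc[:3], grads[:3]):
                    a += g
                acc[3] += grads[3]
                in_batch += 1
                if in_batch == cfg.batch_size:
                    opt.step([a / in_batch for a in acc[:3]], lr)
                    g = acc[3] / in_batch
                    b2m = 0.9 * b2m + 0.1 * g
                    b2v = 0.999 * b2v + 0.001 * g * g
                    t = opt.t
                    self.b2_ -= lr * (b2m / (1 - 0.9**t)) / (
                        np.sqrt(b2v / (1 - 0.999**t)) + 1e-8
                    )
                    acc = [np.zeros_like(self.W1_), np.zeros_like(self.b1_),
                           np.zeros_like(self.W2_), 0.0]
                    in_batch = 0
            if in_batch:
                opt.step([a / in_batch for a in acc[:3]], lr)
            self.history_.append(
                {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))}
            )
        self.n_features_ = F
        return self

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights plus config/seed manifest (.npz)."""
        cfg = self.config or TrainConfig()
        np.savez(
            path,
            W1=self.W1_, b1=self.b1_, W2=self.W2_, b2=self.b2_,
            hidden_units=self.hidden_units,
            feature_sigmas=np.asarray(self.feature_sigmas),
            guidance_sigma=self.guidance_sigma,
            seed=cfg.seed, epochs=cfg.epochs, batch_size=cfg.batch_size,
        )

    @classmethod
    def load(cls, path) -> "PixelMLPBackend":
        data = np.load(path)
        model = cls(
            hidden_units=int(data["hidden_units"]),
            feature_sigmas=tuple(float(s) for s in data["feature_sigmas"]),
            guidance_sigma=float(data["guidance_sigma"]),
        )
        model.W1_ = data["W1"]
        model.b1_ = data["b1"]
        model.W2_ = data["W2"]
        model.b2_ = float(data["b2"])
        model.n_features_ = model.W1_.shape[0]
        return model


BACKEND_REGISTRY: dict[str, type] = {
    "oracle": GroundTruthOracleBackend,
    "constant": ConstantMaskBackend,
    "prior_threshold": PriorThresholdBackend,
    "pixel_mlp": PixelMLPBackend,
}


def make_backend(name: str, **kwargs) -> InteractiveSegmenter:
    try:
        cls = BACKEND_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown backend {name!r}; known: {sorted(BACKEND_REGISTRY)}"
        ) from None
    return cls(**kwargs)
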