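"""Backend contract, bootstrapped loss, lr schedule, and training behaviour."""

import numpy as np
import pytest
from scipy import ndimage

from segclick import (
    Click,
    ClickSet,
    GroundTruthOracleBackend,
    PixelMLPBackend,
    Polarity,
    PriorNoise,
    PriorThresholdBackend,
    SceneConfig,
    TrainConfig,
    bootstrapped_ce_loss,
    generate_scenes,
    learning_rate,
    make_backend,
    make_backend_input,
    make_prior,
    select_channel,
)
from segclick.scene import FOUR_CONNECTED


def pos(r, c):
    return Click(r, c, Polarity.POSITIVE)


def neg(r, c):
    return Click(r, c, Polarity.NEGATIVE)


class TestBootstrappedLoss:
    def test_full_fraction_equals_plain_mean_bce(self, rng):
        p = rng.uniform(0.05, 0.95, size=(8, 8))
        g = rng.random((8, 8)) > 0.5
        expected = np.mean(
            -(g * np.log(p) + (~g) * np.log(1 - p))
        )
        assert bootstrapped_ce_loss(p, g, 1.0) == pytest.approx(expected)

    def test_perfect_prediction_is_at_clamp_floor(self):
        g = np.zeros((4, 4), dtype=bool)
        g[1:3, 1:3] = True
        assert bootstrapped_ce_loss(g.astype(float), g, 0.5) < 1e-6

    def test_hand_computed_top_half_mean(self):
        # per-pixel CE values {0.1, 0.2, 0.7, 1.4}; top half -> (0.7+1.4)/2
        ce = np.array([0.1, 0.2, 0.7, 1.4])
        p = np.exp(-ce).reshape(2, 2)  # gt = 1 everywhere => CE = -log(p)
        g = np.ones((2, 2), dtype=bool)
        assert bootstrapped_ce_loss(p, g, 0.5) == pytest.approx(1.05, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrapped_ce_loss(np.zeros((2, 2)), np.zeros((2, 2)), 0.0)
        with pytest.raises(ValueError):
            bootstrapped_ce_loss(np.zeros((2, 2)), np.zeros((3, 3)), 0.5)


class TestLearningRateSchedule:
    def test_reference_schedule_values(self):
        cfg = TrainConfig()
        assert learning_rate(0, cfg) == pytest.approx(1e-4)
        assert learning_rate(5, cfg) == pytest.approx(9e-5)
        assert learning_rate(10, cfg) == pytest.approx(8.1e-5)

    def test_floor_is_respected(self):
        cfg = TrainConfig()
        assert learning_rate(10_000, cfg) == 5e-7
        # and the floor binds exactly where decay would undershoot it
        assert all(learning_rate(e, cfg) >= 5e-7 for e in range(0, 2000, 50))


class TestContractBackends:
    def test_oracle_returns_ground_truth_exactly(self, small_scene, clean_prior):
        backend = GroundTruthOracleBackend()
        backend.bind(small_scene, 2)
        clicks = ClickSet([pos(*np.argwhere(small_scene.instance_mask == 2)[0])])
        inp = make_backend_input(small_scene, clicks, prior=clean_prior)
        np.testing.assert_array_equal(
            backend.predict(inp), small_scene.instance_mask == 2
        )

    def test_registry_round_trip_and_unknown_name(self):
        assert isinstance(make_backend("prior_threshold"), PriorThresholdBackend)
        with pytest.raises(ValueError):
            make_backend("nope")

    def test_estimator_params_round_trip(self):
        be = PriorThresholdBackend(color_tol=0.3)
        params = be.get_params()
        assert params["color_tol"] == 0.3
        be.set_params(color_tol=0.1)
        assert be.color_tol == 0.1


class TestPriorThresholdBackend:
    def test_zero_noise_prior_component_matches_flood_fill_oracle(
        self, small_scene, clean_prior
    ):
        """Mask = the 4-connected component of selected-channel pixels that
        contains the positive click (hand-composed oracle), and a component
        holding only a negative click stays out."""
        target, other = 1, 2
        click_pt = tuple(np.argwhere(small_scene.instance_mask == target)[0])
        neg_pt = tuple(np.argwhere(small_scene.instance_mask == other)[0])
        clicks = ClickSet([pos(*click_pt), neg(*neg_pt)])
        inp = make_backend_input(small_scene, clicks, prior=clean_prior)
        mask = PriorThresholdBackend().predict(inp)

        sel = select_channel(clean_prior, clicks.positives)
        candidate = sel.values >= 0.5
        labels, _ = ndimage.label(candidate, structure=FOUR_CONNECTED)
        expected = labels == labels[click_pt]
        np.testing.assert_array_equal(mask, expected)
        assert not mask[neg_pt]

    def test_perfect_prior_single_click_recovers_isolated_object(
        self, small_scene, clean_prior
    ):
        from segclick import iou

        for oid in small_scene.object_ids():
            click_pt = tuple(np.argwhere(small_scene.instance_mask == oid)[0])
            inp = make_backend_input(
                small_scene, ClickSet([pos(*click_pt)]), prior=clean_prior
            )
            mask = PriorThresholdBackend().predict(inp)
            assert iou(mask, small_scene.instance_mask == oid) == 1.0

    def test_blank_prior_falls_back_to_click_seeded_region_growing(
        self, small_scene
    ):
        click_pt = tuple(np.argwhere(small_scene.instance_mask == 3)[10])
        inp = make_backend_input(
            small_scene, ClickSet([pos(*click_pt)]), prior_mode="blank"
        )
        mask = PriorThresholdBackend().predict(inp)
        assert mask[click_pt]  # grown region contains its seed
        # clicks-only prediction overlaps the clicked object, not the others
        gt = small_scene.instance_mask == 3
        assert (mask & gt).sum() > 0.5 * gt.sum()
        for other in (1, 2):
            other_mask = small_scene.instance_mask == other
            assert (mask & other_mask).sum() < 0.5 * other_mask.sum()


@pytest.fixture(scope="module")
def tiny_trained_model():
    scenes = generate_scenes(
        12, SceneConfig(height=64, width=64, min_object_area=48), seed=21
    )
    cfg = TrainConfig(epochs=2, initial_lr=0.02, seed=21)
    return PixelMLPBackend(config=cfg).fit(scenes), scenes


class TestPixelMLPTraining:
    def test_loss_decreases_and_history_is_logged(self, tiny_trained_model):
        model, _ = tiny_trained_model
        assert len(model.history_) == 2
        assert model.history_[-1]["loss"] < model.history_[0]["loss"]
        assert model.history_[0]["lr"] == 0.02

    def test_training_is_deterministic_for_fixed_seed(self):
        scenes = generate_scenes(
            4, SceneConfig(height=64, width=64, min_object_area=48), seed=5
        )
        cfg = TrainConfig(epochs=1, initial_lr=0.02, seed=5)
        a = PixelMLPBackend(config=cfg).fit(scenes)
        b = PixelMLPBackend(config=cfg).fit(scenes)
        np.testing.assert_array_equal(a.W1_, b.W1_)
        np.testing.assert_array_equal(a.W2_, b.W2_)
        assert a.history_ == b.history_

    def test_prior_reset_probability_one_blanks_every_prior(self):
        scenes = generate_scenes(
            2, SceneConfig(height=64, width=64, min_object_area=48), seed=6
        )
        seen_blank = []

        class Instrumented(PixelMLPBackend):
            def _features(self, inp):
                seen_blank.append(inp.prior.is_blank)
                return super()._features(inp)

        cfg = TrainConfig(epochs=1, prior_reset_prob=1.0, initial_lr=0.02, seed=6)
        Instrumented(config=cfg).fit(scenes)
        assert seen_blank and all(seen_blank)

    def test_prediction_deterministic_and_probabilities_bounded(
        self, tiny_trained_model, clean_prior, small_scene
    ):
        model, _ = tiny_trained_model
        click_pt = tuple(np.argwhere(small_scene.instance_mask == 1)[0])
        inp = make_backend_input(
            small_scene, ClickSet([pos(*click_pt)]), prior=clean_prior
        )
        p1 = model.predict_proba(inp)
        p2 = model.predict_proba(inp)
        np.testing.assert_array_equal(p1, p2)
        assert p1.min() >= 0 and p1.max() <= 1

    def test_checkpoint_round_trip_preserves_predictions(
        self, tiny_trained_model, small_scene, clean_prior, tmp_path
    ):
        model, _ = tiny_trained_model
        path = tmp_path / "model.npz"
        model.save(path)
        clone = PixelMLPBackend.load(path)
        click_pt = tuple(np.argwhere(small_scene.instance_mask == 2)[0])
        inp = make_backend_input(
            small_scene, ClickSet([pos(*click_pt)]), prior=clean_prior
        )
        np.testing.assert_array_equal(
            model.predict_proba(inp), clone.predict_proba(inp)
        )

    def test_unfitted_model_refuses_to_predict(self, small_scene, clean_prior):
        click_pt = tuple(np.argwhere(small_scene.instance_mask == 1)[0])
        inp = make_backend_input(
            small_scene, ClickSet([pos(*click_pt)]), prior=clean_prior
        )
        with pytest.raises(RuntimeError):
            PixelMLPBackend().predict(inp)

    def test_trained_model_prefers_prior_over_blank(self, tiny_trained_model):
        """Directional check: clean prior needs no more clicks than blank."""
        from segclick import SimConfig, compare_prior_modes

        model, _ = tiny_trained_model
        held = generate_scenes(
            6, SceneConfig(height=64, width=64, min_object_area=48), seed=99
        )
        priors = [make_prior(s, PriorNoise.none()) for s in held]
        rep = compare_prior_modes(held, model, priors, cfg=SimConfig(), seed=99)
        assert rep.mean_clicks_with_prior <= rep.mean_clicks_blank
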