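"""Click simulation: initial sampling, error regions, corrections, sessions."""

import numpy as np
import pytest

from segclick import (
    Click,
    ConstantMaskBackend,
    ErrorRegion,
    GroundTruthOracleBackend,
    Polarity,
    SimConfig,
    encode_gaussian,
    find_error_regions,
    sample_corrections,
    sample_initial,
    simulate_session,
)
from segclick.encoding import ClickSet


def flood_fill_components(mask):
    """Independent 4-connected component oracle (iterative flood fill)."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    components = []
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                stack = [(y, x)]
                seen[y, x] = True
                pixels = []
                while stack:
                    r, c = stack.pop()
                    pixels.append((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                components.append(frozenset(pixels))
    return components


class TestSampleInitial:
    def test_emits_exactly_the_click_budget(self, small_scene, rng):
        clicks = sample_initial(small_scene, 1, SimConfig(), rng)
        assert len(clicks) == 20

    def test_every_positive_click_is_on_the_object(self, small_scene, rng):
        for oid in small_scene.object_ids():
            clicks = sample_initial(small_scene, oid, SimConfig(), rng)
            for c in clicks.positives:
                assert small_scene.instance_mask[c.row, c.col] == oid

    def test_first_positive_is_a_most_interior_pixel(self, small_scene, rng):
        from scipy import ndimage

        oid = 1
        clicks = sample_initial(small_scene, oid, SimConfig(), rng)
        first = clicks.positives[0]
        dist = ndimage.distance_transform_edt(small_scene.instance_mask == oid)
        assert dist[first.row, first.col] == dist.max()

    def test_positive_spacing_at_least_d_step(self, small_scene, rng):
        cfg = SimConfig(d_step=6)
        clicks = sample_initial(small_scene, 2, cfg, rng)
        pts = clicks.positives.coords()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert np.hypot(*(pts[i] - pts[j])) >= cfg.d_step

    def test_negatives_avoid_the_target_object(self, small_scene, rng):
        clicks = sample_initial(small_scene, 3, SimConfig(), rng)
        for c in clicks.negatives:
            assert small_scene.instance_mask[c.row, c.col] != 3

    def test_zero_negatives_encode_as_blank_mask(self, small_scene, rng):
        clicks = sample_initial(small_scene, 1, SimConfig(total_clicks=1), rng)
        assert len(clicks.negatives) == 0
        gmap = encode_gaussian(clicks.negatives, small_scene.shape)
        assert gmap.empty_flag and not gmap.values.any()

    def test_absent_object_rejected(self, small_scene, rng):
        with pytest.raises(ValueError):
            sample_initial(small_scene, 99, SimConfig(), rng)


class TestErrorRegions:
    def test_perfect_prediction_has_no_regions(self, rng):
        mask = rng.random((16, 16)) > 0.5
        assert find_error_regions(mask, mask) == []

    def test_two_missing_corners_give_two_unit_false_negatives(self):
        gt = np.zeros((8, 8), dtype=bool)
        gt[1:6, 1:6] = True
        pred = gt.copy()
        pred[1, 1] = False
        pred[5, 5] = False
        regions = find_error_regions(pred, gt)
        assert len(regions) == 2
        assert all(r.kind == "false_negative" and r.size == 1 for r in regions)

    def test_partition_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            pred = rng.random((32, 32)) > 0.6
            gt = rng.random((32, 32)) > 0.6
            regions = find_error_regions(pred, gt)
            got_fn = {frozenset(map(tuple, r.pixels)) for r in regions
                      if r.kind == "false_negative"}
            got_fp = {frozenset(map(tuple, r.pixels)) for r in regions
                      if r.kind == "false_positive"}
            assert got_fn == set(flood_fill_components(gt & ~pred))
            assert got_fp == set(flood_fill_components(pred & ~gt))

    def test_regions_conserve_the_symmetric_difference(self, rng):
        pred = rng.random((24, 24)) > 0.5
        gt = rng.random((24, 24)) > 0.5
        regions = find_error_regions(pred, gt)
        assert sum(r.size for r in regions) == np.count_nonzero(pred ^ gt)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            find_error_regions(np.zeros((4, 4)), np.zeros((5, 5)))


def region_from_pixels(pixels, kind):
    return ErrorRegion(np.array(sorted(pixels)), kind)


class TestSampleCorrections:
    def test_single_region_budget_one_forces_one_positive_inside(self, rng):
        region = region_from_pixels([(2, 2), (2, 3), (3, 2)], "false_negative")
        existing = ClickSet()
        cfg = SimConfig(total_clicks=1)
        added = sample_corrections([region], existing, cfg, rng, shape=(8, 8))
        assert len(added) == 1
        click = added[0]
        assert click.polarity == Polarity.POSITIVE
        assert (click.row, click.col) in {(2, 2), (2, 3), (3, 2)}

    def test_false_positive_regions_get_negative_clicks(self, rng):
        region = region_from_pixels([(1, 1), (1, 2)], "false_positive")
        added = sample_corrections([region], ClickSet(), SimConfig(), rng,
                                   shape=(4, 4))
        assert all(c.polarity == Polarity.NEGATIVE for c in added)

    def test_region_sampling_is_size_proportional(self):
        """Monte-Carlo check: a 90-pixel region beats a 10-pixel region ~90%."""
        big = region_from_pixels([(0, i) for i in range(90)], "false_negative")
        small = region_from_pixels([(5, i) for i in range(10)], "false_negative")
        rng = np.random.default_rng(42)
        cfg = SimConfig(r_max=1, k_max=1)
        hits = 0
        n_draws = 10_000
        for _ in range(n_draws):
            added = sample_corrections([big, small], ClickSet(), cfg, rng,
                                       shape=(6, 90))
            if added[0].row == 0:
                hits += 1
        # binomial(10000, 0.9): sd ~ 0.003, allow 5 sd plus slack
        assert abs(hits / n_draws - 0.9) < 0.02

    def test_k_at_least_r_and_cap_respected_under_fuzzing(self, rng):
        for _ in range(50):
            n_regions = int(rng.integers(1, 5))
            regions = []
            taken = set()
            for k in range(n_regions):
                base = (int(rng.integers(0, 20)) , int(rng.integers(0, 20)))
                pixels = {(base[0], base[1] + i) for i in range(int(rng.integers(1, 6)))}
                pixels -= taken
                if not pixels:
                    continue
                taken |= pixels
                regions.append(region_from_pixels(pixels, "false_negative"))
            if not regions:
                continue
            n_existing = int(rng.integers(0, 19))
            existing = ClickSet(
                [Click(30 + i, 0, Polarity.NEGATIVE) for i in range(n_existing)]
            )
            cfg = SimConfig(r_max=int(rng.integers(1, 4)), k_max=int(rng.integers(4, 7)))
            added = sample_corrections(regions, existing, cfg, rng, shape=(40, 40))
            r_used = min(cfg.r_max, len(regions), 20 - n_existing)
            assert len(added) >= r_used
            assert n_existing + len(added) <= cfg.total_clicks
            pixel_union = {tuple(p) for r in regions for p in r.pixels}
            assert all((c.row, c.col) in pixel_union for c in added)

    def test_exhausted_budget_rejected(self, rng):
        region = region_from_pixels([(0, 0)], "false_negative")
        full = ClickSet(
            [Click(i, 0, Polarity.POSITIVE) for i in range(20)]
        )
        with pytest.raises(ValueError):
            sample_corrections([region], full, SimConfig(), rng, shape=(30, 1))


class TestSimulateSession:
    def test_oracle_backend_needs_exactly_one_click(self, small_scene):
        rec = simulate_session(
            small_scene, 1, GroundTruthOracleBackend(),
            rng=np.random.default_rng(1),
        )
        assert rec.reached and rec.clicks_to_target == 1
        assert rec.steps[0].iou == 1.0

    def test_constant_empty_backend_caps_at_twenty(self, small_scene):
        rec = simulate_session(
            small_scene, 1, ConstantMaskBackend(0.0),
            rng=np.random.default_rng(1),
        )
        assert not rec.reached
        assert rec.clicks_to_target == 20
        assert rec.steps[-1].cumulative_clicks == 20

    def test_fixed_seed_sessions_are_identical(self, small_scene, clean_prior):
        from segclick import PriorThresholdBackend

        runs = [
            simulate_session(
                small_scene, 2, PriorThresholdBackend(), prior=clean_prior,
                prior_mode="with_prior", rng=np.random.default_rng(5),
            ).to_json()
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_corrective_clicks_lie_in_error_regions(self, small_scene):
        """With a constant-empty backend every error region is part of the
        missed object, so all corrective clicks must be positive and on it."""
        rec = simulate_session(
            small_scene, 2, ConstantMaskBackend(0.0),
            rng=np.random.default_rng(3),
        )
        gt = small_scene.instance_mask == 2
        for c in rec.clicks:
            assert c.polarity == Polarity.POSITIVE
            assert gt[c.row, c.col]

    def test_click_counts_strictly_increase_within_cap(self, small_scene):
        rec = simulate_session(
            small_scene, 1, ConstantMaskBackend(0.0),
            rng=np.random.default_rng(2),
        )
        counts = [s.cumulative_clicks for s in rec.steps]
        assert counts == sorted(set(counts))
        assert counts[-1] <= 20
        assert 1 <= rec.clicks_to_target <= 20

    def test_session_round_trips_through_json(self, small_scene):
        from segclick.simulate import SessionRecord

        rec = simulate_session(
            small_scene, 1, GroundTruthOracleBackend(),
            rng=np.random.default_rng(1),
        )
        clone = SessionRecord.from_json(rec.to_json())
        assert clone.to_json() == rec.to_json()
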