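"""Crossing detection, patch extraction and candidate matching."""

import numpy as np
import pytest

import avgrade as ag
from avgrade.scene import AV_ARTERY, AV_VEIN, VesselScene
from avgrade.synthetic import GroundTruthRecord


def tube_scene(artery_spans=(), vein_spans=(), shape=(200, 200), cup=None):
    """Scenes from axis-aligned tube spans: (r0, r1, c0, c1) rectangles.

    The artery is drawn last (over the vein), as at a diagnostic crossing.
    """
    av = np.zeros(shape, dtype=np.uint8)
    for r0, r1, c0, c1 in vein_spans:
        av[r0:r1, c0:c1] = AV_VEIN
    for r0, r1, c0, c1 in artery_spans:
        av[r0:r1, c0:c1] = AV_ARTERY
    cup_mask = None
    if cup is not None:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cup_mask = np.hypot(yy - cup[0], xx - cup[1]) <= cup[2]
    fundus = np.zeros(shape + (3,), dtype=np.uint8)
    return VesselScene(fundus=fundus, vessel_mask=av != 0, av_map=av, cup_mask=cup_mask)


PLUS_ARTERY = [(97, 104, 0, 200)]  # horizontal, through (100, 100)
PLUS_VEIN = [(0, 200, 97, 104)]  # vertical


class TestDetectCandidates:
    def test_single_plus_sign_crossing(self):
        scene = tube_scene(PLUS_ARTERY, PLUS_VEIN)
        cands = ag.detect_candidates(scene)
        assert len(cands) == 1
        assert np.hypot(cands[0].xy[0] - 100, cands[0].xy[1] - 100) <= 5

    def test_parallel_tubes_yield_nothing(self):
        scene = tube_scene([(50, 57, 0, 200)], [(67, 74, 0, 200)])
        assert ag.detect_candidates(scene) == []

    def test_crossing_inside_cup_is_suppressed(self):
        scene = tube_scene(PLUS_ARTERY, PLUS_VEIN, cup=(100, 100, 30))
        assert ag.detect_candidates(scene) == []

    def test_t_junction_is_rejected(self):
        # artery terminates ON the vein: its skeleton does not traverse the disc
        scene = tube_scene([(97, 104, 0, 100)], [(0, 200, 100, 107)])
        assert ag.detect_candidates(scene) == []

    def test_unrefined_scene_raises(self):
        scene = tube_scene(PLUS_ARTERY, PLUS_VEIN)
        av = scene.av_map.copy()
        av[10, 10] = AV_VEIN  # label off the vessel mask
        bad = VesselScene(fundus=scene.fundus, vessel_mask=scene.vessel_mask, av_map=av)
        with pytest.raises(ValueError, match="refine"):
            ag.detect_candidates(bad)

    def test_flip_equivariance(self):
        scene, _ = ag.generate_scene(
            ag.SceneSpec(image_size=(400, 400), n_crossings=2, noise_level=0.0, seed=13)
        )
        scene = ag.refine_av_labels(scene)
        cands = ag.detect_candidates(scene)
        h = scene.shape[0]
        flipped = VesselScene(
            fundus=scene.fundus[::-1].copy(),
            vessel_mask=scene.vessel_mask[::-1].copy(),
            av_map=scene.av_map[::-1].copy(),
        )
        flipped_cands = ag.detect_candidates(flipped)
        assert len(cands) == len(flipped_cands)
        expected = sorted((h - 1 - r, c) for (r, c) in (cand.xy for cand in cands))
        got = sorted(cand.xy for cand in flipped_cands)
        for (er, ec), (gr, gc) in zip(expected, got):
            assert abs(er - gr) <= 1 and abs(ec - gc) <= 1

    def test_merging_conserves_score(self):
        scene = tube_scene(PLUS_ARTERY, PLUS_VEIN)
        fine = ag.detect_candidates(scene, merge_radius_px=1e-6)
        merged = ag.detect_candidates(scene, merge_radius_px=50.0)
        assert sum(c.score for c in fine) == pytest.approx(sum(c.score for c in merged))
        for cand in fine + merged:
            assert cand.score > 0 and cand.score == int(cand.score)


class TestExtractPatch:
    def test_centered_crop_arithmetic(self):
        rng = np.random.default_rng(0)
        fundus = rng.integers(0, 255, (600, 600, 3), dtype=np.uint8)
        scene = VesselScene(
            fundus=fundus,
            vessel_mask=np.zeros((600, 600), bool),
            av_map=np.zeros((600, 600), np.uint8),
        )
        patch = ag.extract_patch(scene, (300, 300), size_px=150)
        assert np.array_equal(patch.pixels, fundus[225:375, 225:375])

    def test_near_corner_patch_is_reflect_padded(self):
        rng = np.random.default_rng(1)
        fundus = rng.integers(0, 255, (200, 200, 3), dtype=np.uint8)
        scene = VesselScene(
            fundus=fundus,
            vessel_mask=np.zeros((200, 200), bool),
            av_map=np.zeros((200, 200), np.uint8),
        )
        patch = ag.extract_patch(scene, (10, 10), size_px=150)
        assert patch.pixels.shape == (150, 150, 3)
        # the in-bounds region is copied verbatim
        assert np.array_equal(patch.pixels[65:, 65:], fundus[0:85, 0:85])

    def test_exact_size_scene_round_trips(self):
        rng = np.random.default_rng(2)
        fundus = rng.integers(0, 255, (150, 150, 3), dtype=np.uint8)
        scene = VesselScene(
            fundus=fundus,
            vessel_mask=np.zeros((150, 150), bool),
            av_map=np.zeros((150, 150), np.uint8),
        )
        patch = ag.extract_patch(scene, (75, 75), size_px=150)
        assert np.array_equal(patch.pixels, fundus)

    def test_rejects_bad_inputs(self):
        scene = tube_scene(PLUS_ARTERY, PLUS_VEIN)
        with pytest.raises(ValueError):
            ag.extract_patch(scene, (100, 100), size_px=0)
        with pytest.raises(ValueError):
            ag.extract_patch(scene, (500, 100))


def truth_at(*coords):
    return [
        GroundTruthRecord(crossing_xy=c, is_valid=True, grade="none") for c in coords
    ]


class TestMatchCandidates:
    def cand(self, *coords):
        return [ag.CrossingCandidate(xy=c, score=1.0) for c in coords]

    def test_perfect_match(self):
        truth = truth_at((10, 10), (50, 50), (90, 90))
        tp, fp, fn = ag.match_candidates(self.cand((10, 10), (50, 50), (90, 90)), truth, 5.0)
        assert (tp, fp, fn) == (3, 0, 0)

    def test_empty_candidates_all_missed(self):
        tp, fp, fn = ag.match_candidates([], truth_at((1, 1), (2, 2), (3, 3)), 5.0)
        assert (tp, fp, fn) == (0, 0, 3)

    def test_one_to_one_matching(self):
        truth = truth_at((100, 100))
        tp, fp, fn = ag.match_candidates(self.cand((99, 100), (101, 100)), truth, 5.0)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_distance_beyond_tolerance_not_matched(self):
        tp, fp, fn = ag.match_candidates(self.cand((20, 20)), truth_at((30, 30)), 5.0)
        assert (tp, fp, fn) == (0, 1, 1)
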