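"""Generator contracts: determinism, planted truth, grade morphology."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import avgrade as ag
from avgrade.scene import AV_ARTERY, AV_VEIN
from avgrade.synthetic import DEFAULT_GRADE_COUNTS

from conftest import STRONG_NARROWING


def small_spec(**kw):
    defaults = dict(image_size=(400, 400), n_crossings=2, seed=5)
    defaults.update(kw)
    return ag.SceneSpec(**defaults)


class TestGenerateScene:
    def test_seeded_determinism_is_byte_identical(self):
        spec = small_spec(seed=9)
        scene_a, recs_a = ag.generate_scene(spec)
        scene_b, recs_b = ag.generate_scene(small_spec(seed=9))
        for layer in ("fundus", "vessel_mask", "av_map"):
            assert np.array_equal(getattr(scene_a, layer), getattr(scene_b, layer))
        assert recs_a == recs_b

    def test_planted_crossing_count(self):
        _, recs = ag.generate_scene(small_spec(n_crossings=3, image_size=(512, 512)))
        assert len(recs) == 3

    def test_av_labels_subset_of_vessel_mask(self):
        scene, _ = ag.generate_scene(small_spec())
        assert not np.any((scene.av_map != 0) & ~scene.vessel_mask)

    def test_z_order_controls_overlap_ownership(self):
        """The over-vessel's label owns the overlap: valid scenes keep an
        unbroken artery through each crossing, invalid scenes an unbroken vein."""
        for prob, over_code in ((1.0, AV_ARTERY), (0.0, AV_VEIN)):
            scene, recs = ag.generate_scene(small_spec(z_order_artery_over_prob=prob, seed=3))
            for rec in recs:
                r, c = rec.crossing_xy
                window = scene.av_map[r - 1 : r + 2, c - 1 : c + 2]
                assert (window == over_code).all()

    def test_crossings_recoverable_near_both_vessels(self):
        scene, recs = ag.generate_scene(small_spec(seed=21))
        for rec in recs:
            r, c = rec.crossing_xy
            window = scene.av_map[max(r - 8, 0) : r + 9, max(c - 8, 0) : c + 9]
            assert (window == AV_ARTERY).any() and (window == AV_VEIN).any()

    def test_overcrowded_spec_raises(self):
        with pytest.raises(ValueError, match="crossings"):
            ag.generate_scene(small_spec(n_crossings=30, image_size=(300, 300)))

    def test_cup_mask_rendered_as_disc(self):
        scene, _ = ag.generate_scene(
            small_spec(cup_center=(80, 90), cup_radius=30.0, n_crossings=1, image_size=(512, 512))
        )
        assert scene.cup_mask[80, 90]
        assert not scene.cup_mask[80, 125]
        area = scene.cup_mask.sum()
        assert abs(area - np.pi * 30.0**2) < 120

    @pytest.mark.parametrize("bad", [
        dict(grade_distribution=(0.5, 0.5, 0.1, 0.0)),
        dict(artery_caliber_px=1.0),
        dict(narrowing_profile={**STRONG_NARROWING, "mild": (0.0, 1.0)}),
        dict(z_order_artery_over_prob=1.5),
        dict(noise_level=-1.0),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            ag.generate_scene(small_spec(**bad))


class TestGradeMorphology:
    def _measure(self, grade, dist, seeds=range(4)):
        out = []
        for seed in seeds:
            spec = small_spec(
                seed=20 + seed,
                noise_level=0.0,
                z_order_artery_over_prob=1.0,
                grade_distribution=dist,
                narrowing_profile=dict(STRONG_NARROWING),
            )
            scene, recs = ag.generate_scene(spec)
            for rec in recs:
                assert rec.grade == grade
                out.extend(ag.measure_vein_caliber(scene, rec.crossing_xy, offset_px=20))
        return out, spec.vein_caliber_px

    def test_grade_none_keeps_nominal_caliber(self):
        calibers, nominal = self._measure("none", (1, 0, 0, 0))
        assert calibers, "no vein arcs found"
        assert all(abs(c - nominal) <= 1.0 for c in calibers)

    def test_grade_severe_halves_caliber_both_sides(self):
        calibers, nominal = self._measure("severe", (0, 0, 0, 1))
        assert calibers
        assert all(abs(c - 0.5 * nominal) <= 1.0 for c in calibers)


class TestGenerateDataset:
    def test_round_robin_subject_assignment(self):
        ds = ag.generate_dataset(small_spec(n_crossings=1), n_scenes=10, subjects=5)
        images = ds.manifest.drop_duplicates("image_id")
        per_subject = images.groupby("subject_id")["image_id"].count()
        assert len(per_subject) == 5
        assert (per_subject == 2).all()
        assert images.groupby("image_id")["subject_id"].nunique().eq(1).all()

    def test_all_invalid_when_z_order_prob_zero(self):
        ds = ag.generate_dataset(
            small_spec(n_crossings=1, z_order_artery_over_prob=0.0), n_scenes=8, subjects=4
        )
        assert not ds.manifest["is_valid"].any()
        assert (ds.manifest["grade"] == "").all()

    def test_patches_are_150_square(self):
        ds = ag.generate_dataset(small_spec(n_crossings=1), n_scenes=4, subjects=2)
        for patch in ds.patches:
            assert patch.pixels.shape == (150, 150, 3)

    def test_grade_frequencies_match_study_distribution(self):
        """2000 valid crossings drawn from the study's empirical grade
        frequencies land within 3 sigma of the multinomial expectation and
        pass a chi-square goodness-of-fit test at alpha = 0.01."""
        n_target = 2000
        spec = small_spec(
            image_size=(180, 180),
            n_crossings=1,
            tube_half_length_px=35.0,
            z_order_artery_over_prob=1.0,
            noise_level=0.0,
            seed=77,
        )
        ds = ag.generate_dataset(spec, n_scenes=n_target, subjects=50)
        counts = ds.manifest["grade"].value_counts()
        n = len(ds.manifest)
        p = np.array(DEFAULT_GRADE_COUNTS) / sum(DEFAULT_GRADE_COUNTS)
        observed = np.array([counts.get(g, 0) for g in ag.GRADES])
        expected = n * p
        sigma = np.sqrt(n * p * (1 - p))
        assert (np.abs(observed - expected) <= 3 * sigma).all(), (observed, expected)
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01

    def test_requires_enough_scenes_for_subjects(self):
        with pytest.raises(ValueError):
            ag.generate_dataset(small_spec(), n_scenes=2, subjects=5)
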