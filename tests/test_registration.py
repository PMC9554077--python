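import numpy as np
import pytest

from bdseg.dictionary import TemplateDictionary, TemplatePair
from bdseg.phantom import make_dictionary, make_phantom
from bdseg.preprocess import preprocess_pipeline
from bdseg.registration import (
    DeformationField,
    RegistrationConfig,
    nmi,
    register_nonrigid,
    segment_registration,
    select_templates,
    vote_fusion,
    warp_mask,
)
from bdseg.volumes import SegmentationMask, SingleBreastVolume

from conftest import dice, small_spec


class TestNMI:
    def test_self_similarity_is_two(self, rng):
        a = rng.random((10, 10, 10))
        assert abs(nmi(a, a) - 2.0) < 1e-12

    def test_independent_noise_near_one(self):
        rng = np.random.default_rng(0)
        a = rng.random((40, 40, 40))
        b = rng.random((40, 40, 40))
        assert abs(nmi(a, b, bins=32) - 1.0) < 0.02

    def test_permutation_invariance(self, rng):
        a = rng.random((8, 8, 8))
        b = rng.random((8, 8, 8))
        perm = rng.permutation(a.size)
        v1 = nmi(a, b)
        v2 = nmi(a.ravel()[perm].reshape(a.shape),
                 b.ravel()[perm].reshape(b.shape))
        assert abs(v1 - v2) < 1e-12

    def test_constant_array_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            nmi(np.zeros((4, 4, 4)), rng.random((4, 4, 4)))

    def test_range(self, rng):
        for _ in range(5):
            a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
            v = nmi(a, b, bins=16)
            assert 1.0 - 1e-9 <= v <= 2.0 + 1e-9


@pytest.fixture(scope="module")
def small_dict():
    return make_dictionary(10, small_spec(seed=50))


@pytest.fixture(scope="module")
def small_target():
    fw, truth = make_phantom(small_spec(seed=77))
    right, left = preprocess_pipeline(fw)
    return fw, truth, right, left


class TestSelectTemplates:
    def test_whole_dictionary_when_k_equals_size(self, small_dict, small_target):
        _, _, right, _ = small_target
        d5 = TemplateDictionary(list(small_dict)[:5])
        ids = select_templates(right, d5, k=5)
        assert sorted(ids) == sorted(d5.ids)

    def test_identical_template_ranked_first(self, small_dict):
        tpl = small_dict.get(small_dict.ids[3])
        ids = select_templates(tpl.image, small_dict, k=5)
        assert ids[0] == tpl.id

    def test_matches_bruteforce_sort(self, small_dict, small_target):
        _, _, right, _ = small_target
        ids, scores = select_templates(right, small_dict, k=5,
                                       return_scores=True)
        brute = sorted(
            ((nmi(right.image, p.image.image, bins=64), -i, p.id)
             for i, p in enumerate(small_dict)), reverse=True)
        assert ids == [tid for _, _, tid in brute[:5]]
        np.testing.assert_allclose(scores, [v for v, _, _ in brute[:5]])

    def test_small_dictionary_errors(self, small_dict, small_target):
        _, _, right, _ = small_target
        d3 = TemplateDictionary(list(small_dict)[:3])
        with pytest.raises(ValueError, match="need >= 5"):
            select_templates(right, d3, k=5)


class TestRegisterNonrigid:
    def test_identity_recovery(self, small_target):
        _, _, right, _ = small_target
        field = register_nonrigid(right, right)
        mag = np.sqrt((field.displacement ** 2).sum(axis=0))
        assert np.median(mag) < 0.5

    def test_known_shift_recovery(self, small_target):
        _, _, right, _ = small_target
        shifted = np.roll(right.image, 3, axis=0)
        target = SingleBreastVolume(image=shifted,
                                    body_mask=(shifted > 0).astype(np.uint8),
                                    side="right", flipped=False,
                                    spacing=right.spacing)
        field = register_nonrigid(right, target)
        med = np.array([np.median(field.displacement[d]) for d in range(3)])
        # pull convention: target(x) = template(x + u) => u ~ (-3, 0, 0)
        np.testing.assert_allclose(med, [-3.0, 0.0, 0.0], atol=0.5)

    def test_never_decreases_registration_metric(self, small_dict, small_target):
        # the improvement guarantee is stated with the estimator the
        # backend optimizes (smoothed Parzen NMI); raw hard-binned NMI
        # drops under any interpolating warp of piecewise-constant images
        _, _, right, _ = small_target
        cfg = RegistrationConfig()
        from bdseg.registration import (_resample_to, _warp_image,
                                        registration_metric)
        for tid in small_dict.ids[:3]:
            tpl = small_dict.get(tid)
            field = register_nonrigid(tpl.image, right, cfg)
            moving = _resample_to(tpl.image.image, right.shape)
            before = registration_metric(right.image, moving, cfg)
            after = registration_metric(
                right.image, _warp_image(moving, field.displacement), cfg)
            assert after >= before - 1e-12

    def test_constant_image_errors(self, small_target):
        _, _, right, _ = small_target
        flat = SingleBreastVolume(image=np.zeros(right.shape),
                                  body_mask=np.zeros(right.shape, np.uint8),
                                  side="right", flipped=False)
        with pytest.raises(ValueError, match="degenerate"):
            register_nonrigid(flat, right)


class TestWarpMask:
    def test_identity_field(self, rng):
        mask = SegmentationMask((rng.random((8, 8, 8)) > 0.5).astype(np.uint8))
        field = DeformationField(np.zeros((3, 8, 8, 8)))
        np.testing.assert_array_equal(warp_mask(mask, field).data, mask.data)

    def test_integer_translation(self):
        data = np.zeros((8, 8, 8), dtype=np.uint8)
        data[3:5, 3:5, 3:5] = 1
        mask = SegmentationMask(data)
        disp = np.zeros((3, 8, 8, 8))
        disp[0] = 2.0  # pull from z+2: shifts content toward -z
        warped = warp_mask(mask, DeformationField(disp))
        np.testing.assert_array_equal(warped.data[1:3, 3:5, 3:5],
                                      np.ones((2, 2, 2), np.uint8))
        assert warped.data.sum() == mask.data.sum()

    def test_output_binary(self, rng):
        mask = SegmentationMask((rng.random((8, 8, 8)) > 0.3).astype(np.uint8))
        disp = rng.normal(0, 1.5, (3, 8, 8, 8))
        warped = warp_mask(mask, DeformationField(disp))
        assert set(np.unique(warped.data)) <= {0, 1}

    def test_grid_mismatch_errors(self):
        mask = SegmentationMask(np.ones((8, 8, 8), np.uint8))
        with pytest.raises(ValueError, match="incompatible"):
            warp_mask(mask, DeformationField(np.zeros((3, 4, 4, 4))))


class TestVoteFusion:
    @staticmethod
    def _random_masks(rng, n=5, shape=(4, 4, 4)):
        return [SegmentationMask((rng.random(shape) > 0.5).astype(np.uint8))
                for _ in range(n)]

    def test_identical_masks_pass_through(self, rng):
        m = SegmentationMask((rng.random((4, 4, 4)) > 0.5).astype(np.uint8))
        out = vote_fusion([m] * 5, min_votes=4)
        np.testing.assert_array_equal(out.data, m.data)

    def test_four_of_five_included_three_excluded(self):
        shape = (2, 2, 2)
        base = np.zeros(shape, dtype=np.uint8)
        m4 = base.copy()
        m4[0, 0, 0] = 1  # present in 4 masks
        m3 = base.copy()
        m3[1, 1, 1] = 1  # present in 3 masks
        masks = ([SegmentationMask(np.maximum(m4, m3))] * 3
                 + [SegmentationMask(m4)] + [SegmentationMask(base)])
        out = vote_fusion(masks, min_votes=4)
        assert out.data[0, 0, 0] == 1
        assert out.data[1, 1, 1] == 0

    def test_counting_oracle(self, rng):
        masks = self._random_masks(rng)
        for mv in (1, 2, 3, 4, 5):
            out = vote_fusion(masks, min_votes=mv)
            counts = sum(m.data.astype(int) for m in masks)
            np.testing.assert_array_equal(out.data, (counts >= mv).astype(np.uint8))

    def test_bounded_by_union_and_intersection(self, rng):
        masks = self._random_masks(rng)
        union = np.maximum.reduce([m.data for m in masks])
        inter = np.minimum.reduce([m.data for m in masks])
        for mv in (1, 3, 5):
            out = vote_fusion(masks, min_votes=mv).data
            assert np.all(out <= union)
            assert np.all(out >= inter)

    def test_monotone_in_added_mask(self, rng):
        masks = self._random_masks(rng, n=4)
        before = vote_fusion(masks, min_votes=2).data
        extra = SegmentationMask((rng.random((4, 4, 4)) > 0.5).astype(np.uint8))
        after = vote_fusion(masks + [extra], min_votes=2).data
        assert np.all(after >= before)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            vote_fusion([])

    def test_grid_mismatch_errors(self, rng):
        a = SegmentationMask(np.ones((4, 4, 4), np.uint8))
        b = SegmentationMask(np.ones((5, 5, 5), np.uint8))
        with pytest.raises(ValueError, match="share a grid"):
            vote_fusion([a, b], min_votes=1)


class TestSegmentRegistration:
    def test_phantom_recovery(self, small_dict):
        fw, truth = make_phantom(small_spec(seed=201))
        rm, lm = segment_registration(fw, small_dict)
        pred = np.maximum(rm.data, lm.data)
        assert dice(pred, truth.breast_mask) >= 0.80

    def test_self_segmentation(self, small_dict):
        # target identical to a dictionary template: pad the template's
        # canonical half back into a bilateral frame is involved; instead
        # use a dictionary whose five best entries are the same template
        tpl = small_dict.get(small_dict.ids[0])
        d = TemplateDictionary()
        for i in range(5):
            d.add(TemplatePair(id=f"c{i}", image=tpl.image, mask=tpl.mask,
                               meta={}))
        from bdseg.registration import _segment_side, RegistrationConfig
        fused, report = _segment_side(tpl.image, d, RegistrationConfig(), 5, 4)
        assert dice(fused.data, tpl.mask.data) >= 0.99

    def test_masks_inside_body(self, small_dict):
        fw, truth = make_phantom(small_spec(seed=202))
        right, left = preprocess_pipeline(fw)
        rm, lm = segment_registration(fw, small_dict)
        from bdseg.volumes import merge_halves
        body = merge_halves(right.body_mask, left.body_mask)
        pred = np.maximum(rm.data, lm.data)
        assert np.all(body[pred.astype(bool)] == 1)
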