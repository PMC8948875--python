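"""Competition metric against an exhaustive-matching oracle, plus TTA merging."""

import itertools

import numpy as np
import pytest

import nucstyle as ns
from nucstyle.metrics import (
    KAGGLE_THRESHOLDS,
    PAPER_THRESHOLDS,
    ColorJitter,
    HFlip,
    Identity,
    Rescale,
    Rot90,
    VFlip,
)


def optimal_tp(iou_mat: np.ndarray, t: float) -> int:
    """Oracle: maximum one-to-one matching with IoU > t, by exhaustive
    enumeration of injective assignments (feasible for <= 6 instances)."""
    n_pred, n_gt = iou_mat.shape
    if n_pred == 0 or n_gt == 0:
        return 0
    small, large, mat = (
        (n_pred, n_gt, iou_mat) if n_pred <= n_gt else (n_gt, n_pred, iou_mat.T)
    )
    best = 0
    for perm in itertools.permutations(range(large), small):
        best = max(best, sum(mat[i, j] > t for i, j in enumerate(perm)))
    return best


def random_instance_set(rng, n_max=6, side=32):
    """Disjoint random rectangles as an instance set."""
    masks = []
    occupied = np.zeros((side, side), bool)
    for _ in range(rng.integers(0, n_max + 1)):
        h, w = rng.integers(3, 10, size=2)
        y, x = rng.integers(0, side - 10, size=2)
        m = np.zeros((side, side), bool)
        m[y : y + h, x : x + w] = True
        m &= ~occupied
        if m.sum() >= 3:
            occupied |= m
            masks.append(m)
    return masks


class TestIou:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8), bool)
        a[:4] = True
        b = np.zeros((8, 8), bool)
        b[4:] = True
        assert ns.iou(a, a) == 1.0
        assert ns.iou(a, b) == 0.0

    def test_counted_overlap(self):
        a = np.zeros((4, 4), bool)
        a[0:2, 0:2] = True
        b = np.zeros((4, 4), bool)
        b[0:2, 1:3] = True  # overlap 2, union 6
        assert ns.iou(a, b) == pytest.approx(1 / 3)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ns.iou(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMatching:
    def test_exact_prediction_matches_everywhere(self):
        mat = np.array([[1.0]])
        for t in PAPER_THRESHOLDS:
            assert ns.match_at_threshold(mat, t) == (1, 0, 0)

    def test_no_predictions(self):
        assert ns.match_at_threshold(np.zeros((0, 3)), 0.5) == (0, 0, 3)

    def test_strict_inequality_at_threshold(self):
        mat = np.array([[0.5]])
        assert ns.match_at_threshold(mat, 0.5) == (0, 1, 1)
        assert ns.match_at_threshold(mat, 0.45) == (1, 0, 0)

    def test_matching_equals_exhaustive_optimal_on_random_sets(self):
        """500 random small instance sets: the metric's TP equals the TP of
        an exhaustive enumeration over all injective assignments, at every
        threshold in the ladder."""
        rng = np.random.default_rng(2024)
        discrepancies = 0
        for _ in range(500):
            preds = random_instance_set(rng)
            gts = random_instance_set(rng)
            mat = ns.iou_matrix(preds, gts)
            for t in PAPER_THRESHOLDS:
                tp_greedy, _, _ = ns.match_at_threshold(mat, t)
                if tp_greedy != optimal_tp(np.atleast_2d(mat), t):
                    discrepancies += 1
        assert discrepancies == 0

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mat = ns.iou_matrix(random_instance_set(rng), random_instance_set(rng))
            tps = [ns.match_at_threshold(mat, t)[0] for t in PAPER_THRESHOLDS]
            fps = [ns.match_at_threshold(mat, t)[1] for t in PAPER_THRESHOLDS]
            fns = [ns.match_at_threshold(mat, t)[2] for t in PAPER_THRESHOLDS]
            assert all(a >= b for a, b in zip(tps, tps[1:]))
            assert all(a <= b for a, b in zip(fps, fps[1:]))
            assert all(a <= b for a, b in zip(fns, fns[1:]))


class TestImageScore:
    def test_threshold_ladders(self):
        assert len(PAPER_THRESHOLDS) == 18
        assert PAPER_THRESHOLDS[0] == 0.10 and PAPER_THRESHOLDS[-1] == 0.95
        assert len(KAGGLE_THRESHOLDS) == 10
        assert KAGGLE_THRESHOLDS[0] == 0.50

    def test_perfect_and_empty_predictions(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert ns.image_score([m], [m]) == 1.0
        assert ns.image_score([], [m]) == 0.0
        assert ns.image_score([], []) == 1.0

    def test_single_pair_iou_point_six(self):
        """A pred/GT pair at IoU exactly 0.6 passes the 10 thresholds below
        0.6 (strict inequality) out of 18, so S = 10/18."""
        gt = np.zeros((30, 30), bool)
        gt[0:5, 0:20] = True
        pr = np.zeros((30, 30), bool)
        pr[0:5, 5:25] = True  # intersection 75, union 125
        assert ns.iou(pr, gt) == 0.6
        assert ns.image_score([pr], [gt]) == pytest.approx(10 / 18)

    def test_symmetric_under_instance_relabeling(self):
        rng = np.random.default_rng(9)
        preds = random_instance_set(rng, n_max=5)
        gts = random_instance_set(rng, n_max=5)
        s = ns.image_score(preds, gts)
        assert ns.image_score(preds[::-1], gts[::-1]) == pytest.approx(s)

    def test_invariant_to_rigid_transform_of_both(self):
        rng = np.random.default_rng(11)
        preds = random_instance_set(rng, n_max=4)
        gts = random_instance_set(rng, n_max=4)
        s = ns.image_score(preds, gts)
        rot = lambda ms: [np.rot90(m) for m in ms]
        assert ns.image_score(rot(preds), rot(gts)) == pytest.approx(s)


class TestDatasetScore:
    def _pair(self, s_target):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        return ([m], [m]) if s_target == 1.0 else ([], [m])

    def test_mean_of_extremes(self):
        report = ns.dataset_score([self._pair(1.0), self._pair(0.0)])
        assert report.mean_score == 0.5
        assert len(report.per_image) == 2

    def test_single_image_and_permutation_invariance(self):
        pairs = [self._pair(1.0), self._pair(0.0), self._pair(1.0)]
        a = ns.dataset_score(pairs).mean_score
        b = ns.dataset_score(pairs[::-1]).mean_score
        assert a == b
        assert ns.dataset_score([pairs[0]]).mean_score == 1.0

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            ns.dataset_score([])

    def test_summary_mentions_mean(self):
        rep = ns.dataset_score([self._pair(1.0)])
        assert "mean score" in rep.summary()


class _StubSegmenter:
    """Returns a fixed instance, optionally only for the untransformed view."""

    def __init__(self, mask, only_identity=False, reference=None):
        self.mask = mask
        self.only_identity = only_identity
        self.reference = reference if reference is not None else mask

    def predict(self, image):
        if self.only_identity and image.shape[:2] != self.reference.shape:
            return []
        if self.only_identity and not np.array_equal(
            image, getattr(self, "_id_image", image)
        ):
            return []
        return [self.mask.copy()]


class TestTta:
    def _mask(self):
        m = np.zeros((16, 16), bool)
        m[4:9, 6:11] = True
        return m

    def test_identity_only_equals_plain_prediction(self, rng):
        img = rng.random((16, 16, 3))
        seg = _StubSegmenter(self._mask())
        out = ns.tta_predict(seg, img, [Identity()])
        assert len(out) == 1
        assert (out[0] == self._mask()).all()

    def test_equivariant_segmenter_with_flip_keeps_instances(self, rng):
        """A segmenter that always returns the same absolute region is
        flip-equivariant for a symmetric mask-through-flip round trip."""
        img = rng.random((16, 16, 3))

        class _Equivariant:
            def __init__(self, mask):
                self.mask = mask

            def predict(self, image):
                # responds in the view's frame so inversion maps it back
                if image[0, 0, 0] != img[0, 0, 0]:  # flipped view
                    return [self.mask[:, ::-1].copy()]
                return [self.mask.copy()]

        seg = _Equivariant(self._mask())
        out = ns.tta_predict(seg, img, [Identity(), HFlip()])
        assert len(out) == 1
        assert (out[0] == self._mask()).all()

    def test_low_support_instance_dropped(self, rng):
        img = rng.random((16, 16, 3))

        class _OnlyIdentity:
            def predict(self, image):
                if np.array_equal(image, img):
                    return [np.pad(np.ones((3, 3), bool), ((4, 9), (4, 9)))]
                return []

        out = ns.tta_predict(
            seg := _OnlyIdentity(), img,
            [Identity(), HFlip(), VFlip(), Rot90(1)],
        )
        assert out == []  # support 1 of 4 < half

    def test_photometric_transforms_do_not_move_masks(self, rng):
        img = rng.random((16, 16, 3))
        seg = _StubSegmenter(self._mask())
        out = ns.tta_predict(
            seg, img, [Identity(), ColorJitter(1.05, 0.95)]
        )
        assert len(out) == 1
        assert (out[0] == self._mask()).all()

    def test_rescale_transform_roundtrip(self, rng):
        tr = Rescale(1.25)
        img = rng.random((16, 16, 3))
        up = tr.apply(img)
        assert up.shape[0] == 20
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        back = tr.invert_mask(mask)
        assert back.shape == (16, 16)

    def test_non_transform_rejected(self, rng):
        with pytest.raises(ValueError):
            ns.tta_predict(_StubSegmenter(self._mask()), rng.random((8, 8, 3)),
                           ["hflip"])
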