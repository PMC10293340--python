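import itertools

import numpy as np
import pytest

from fetalvol.image_model import ClassProbabilities, LabelMap, VolumeImage
from fetalvol.nets import UNet2D
from fetalvol.segmentation import (
    FoldAssignment,
    NetConfig,
    extract_slices,
    fuse_votes,
    keep_largest_fetal_component,
    make_folds,
    predict_plane,
    restack,
    segment_volume,
    train,
)


class TestFolds:
    def test_twenty_cases_four_folds_gives_15_5(self):
        fa = make_folds(list(range(20)), 4, seed=0)
        assert len(fa.folds) == 4
        for tr, va in fa.folds:
            assert len(tr) == 15 and len(va) == 5

    def test_val_sets_cover_all_ids_once(self):
        ids = [f"case{i}" for i in range(11)]
        fa = make_folds(ids, 3, seed=5)
        all_val = [i for _, va in fa.folds for i in va]
        assert sorted(all_val) == sorted(ids)

    def test_k_equal_n_gives_singleton_val_sets(self):
        fa = make_folds(list(range(4)), 4, seed=0)
        assert all(len(va) == 1 for _, va in fa.folds)

    def test_deterministic_given_seed(self):
        a = make_folds(list(range(20)), 4, seed=9)
        b = make_folds(list(range(20)), 4, seed=9)
        assert a.folds == b.folds

    def test_no_leakage_enforced(self):
        with pytest.raises(ValueError):
            FoldAssignment([(["a", "b"], ["b"])])

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(list(range(3)), 4)


class TestSlicing:
    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_restack_is_inverse(self, axis, rng):
        v = VolumeImage(rng.normal(size=(6, 7, 8)), spacing=(1, 1, 1))
        np.testing.assert_array_equal(restack(extract_slices(v, axis), axis), v.voxels)

    def test_shape_bookkeeping(self, rng):
        v = VolumeImage(rng.normal(size=(10, 12, 14)), spacing=(1, 1, 1))
        s = extract_slices(v, 2)
        assert s.shape == (14, 10, 12)
        np.testing.assert_array_equal(s[3], v.voxels[:, :, 3])

    def test_bad_axis_rejected(self, rng):
        v = VolumeImage(rng.normal(size=(4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            extract_slices(v, 3)


def oracle_fuse_single(probs):
    """Literal restatement of the voting rule for one voxel.

    probs: (3, n_classes).  Each direction votes its argmax; ≥ 2 agreeing
    votes win; a 3-way split goes to the tied class with the largest summed
    probability, then lowest index.
    """
    votes = [int(np.argmax(p)) for p in probs]
    for v in votes:
        if votes.count(v) >= 2:
            return v
    total = probs.sum(axis=0)
    best, best_score = None, -1.0
    for v in sorted(votes):
        if total[v] > best_score:
            best, best_score = v, total[v]
    return best


class TestVoteFusion:
    def _probs_for_vote(self, vote, rng, n_classes=5):
        p = rng.uniform(0.01, 0.5, size=n_classes)
        p[vote] = p.max() + rng.uniform(0.1, 0.5)
        return p / p.sum()

    def test_exhaustive_equivalence_with_oracle(self):
        # every one of the 5³ per-voxel vote patterns, random soft outputs
        rng = np.random.default_rng(7)
        patterns = list(itertools.product(range(5), repeat=3))
        planes = np.zeros((3, len(patterns), 1, 1, 5), dtype=np.float32)
        for j, pat in enumerate(patterns):
            for d in range(3):
                planes[d, j, 0, 0] = self._probs_for_vote(pat[d], rng)
        fused = fuse_votes(*[ClassProbabilities(planes[d]) for d in range(3)])
        for j in range(len(patterns)):
            expected = oracle_fuse_single(planes[:, j, 0, 0, :])
            assert fused.labels[j, 0, 0] == expected, patterns[j]

    def test_majority_beats_probabilities(self):
        # two agreeing low-confidence votes beat one confident dissenter
        p_agree = np.array([0.0, 0.4, 0.35, 0.25, 0.0], dtype=np.float32)
        p_dissent = np.array([0.0, 0.0, 0.99, 0.01, 0.0], dtype=np.float32)
        planes = [
            ClassProbabilities(p[None, None, None]) for p in (p_agree, p_agree, p_dissent)
        ]
        assert fuse_votes(*planes).labels[0, 0, 0] == 1

    def test_unanimity_preserved(self, rng):
        shape = (4, 5, 6)
        lab = rng.integers(0, 5, size=shape)
        planes = []
        for _ in range(3):
            p = rng.uniform(0.01, 0.3, size=shape + (5,)).astype(np.float32)
            np.put_along_axis(p, lab[..., None], 0.9, axis=-1)
            p /= p.sum(axis=-1, keepdims=True)
            planes.append(ClassProbabilities(p))
        np.testing.assert_array_equal(fuse_votes(*planes).labels, lab)

    def test_three_way_tie_lowest_index_on_equal_sums(self):
        planes = []
        for vote in (0, 1, 2):
            p = np.full(5, 0.1, dtype=np.float32)
            p[vote] = 0.6  # symmetric: summed scores for 0,1,2 all equal
            planes.append(ClassProbabilities(p[None, None, None]))
        assert fuse_votes(*planes).labels[0, 0, 0] == 0

    def test_shape_mismatch_rejected(self, rng):
        a = ClassProbabilities(rng.random((2, 2, 2, 5)))
        b = ClassProbabilities(rng.random((2, 2, 3, 5)))
        with pytest.raises(ValueError):
            fuse_votes(a, a, b)


@pytest.fixture(scope="module")
def model():
    return UNet2D(depth=2, base_channels=4, seed=0)


class TestPredictPlane:

    def test_output_normalized(self, model, rng):
        v = VolumeImage(rng.normal(size=(10, 12, 9)), spacing=(1, 1, 1))
        probs = predict_plane(model, v, 0)
        assert probs.spatial_shape == v.shape
        assert probs.check_normalized(tol=1e-5)

    def test_constant_volume_gives_identical_slices(self, model):
        v = VolumeImage(np.full((8, 8, 6), 2.0), spacing=(1, 1, 1))
        probs = predict_plane(model, v, 2)
        for k in range(1, 6):
            np.testing.assert_allclose(
                probs.probs[:, :, k], probs.probs[:, :, 0], atol=1e-6
            )

    def test_three_axes_same_spatial_shape(self, model, rng):
        v = VolumeImage(rng.normal(size=(9, 10, 11)), spacing=(1, 1, 1))
        shapes = {predict_plane(model, v, a).spatial_shape for a in range(3)}
        assert shapes == {(9, 10, 11)}


class TestTraining:
    def test_deterministic_and_learning(self, tiny_training_set):
        cases, _ = tiny_training_set
        data = [(v, l) for v, l, _ in cases]
        cfg = NetConfig(
            seed=5, epochs=2, iso_mm=3.0, slices_per_epoch=60, val_slices=20
        )
        folds = make_folds(list(range(4)), 2, seed=1)
        _, m1 = train(cfg, data, folds)
        _, m2 = train(cfg, data, folds)
        v1 = m1[m1.split == "val"].loss.to_numpy()
        v2 = m2[m2.split == "val"].loss.to_numpy()
        np.testing.assert_array_equal(v1, v2)
        # best-so-far training loss must improve on the first epoch
        for f in (0, 1):
            tr = m1[(m1.split == "train") & (m1.fold == f)].sort_values("epoch").loss
            assert tr.min() <= tr.iloc[0]

    def test_fold_bookkeeping_no_leakage(self):
        folds = make_folds(list(range(8)), 2, seed=3)
        for tr, va in folds.folds:
            assert not set(tr) & set(va)

    def test_empty_dataset_rejected(self):
        cfg = NetConfig(epochs=1)
        with pytest.raises(ValueError):
            train(cfg, [], FoldAssignment([([0, 1], [2])]))


class TestSegmentVolume:
    def test_output_grid_matches_input(self, rng):
        model = UNet2D(depth=2, base_channels=4, seed=0)
        v = VolumeImage(
            rng.normal(size=(11, 13, 9)), spacing=(1.8, 1.4, 2.5)
        )
        seg = segment_volume(model, v, iso_mm=3.0)
        assert seg.shape == v.shape
        assert seg.spacing == v.spacing

    def test_spurious_fetal_island_removed(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[2:5, 2:5, 2:5] = 1  # main fetal body
        labels[7, 7, 7] = 1  # disconnected single voxel
        cleaned = keep_largest_fetal_component(LabelMap(labels, spacing=(1, 1, 1)))
        assert cleaned.labels[7, 7, 7] == 0
        assert np.count_nonzero(cleaned.labels == 1) == 27

    def test_postprocess_leaves_other_classes_alone(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[0:2, 0:2, 0:2] = 1
        labels[4, 4, 4] = 1
        labels[5, 5, 5] = 2
        cleaned = keep_largest_fetal_component(LabelMap(labels, spacing=(1, 1, 1)))
        assert cleaned.labels[5, 5, 5] == 2
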