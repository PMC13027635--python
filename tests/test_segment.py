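import numpy as np
import pytest

from orbifab import phantom, segment
from orbifab.phantom import PhantomSpec
from orbifab.segment import (
    best_threshold_dice,
    classify,
    crossval_dice,
    dice,
    estimate_isovalue,
    extract_features,
    sample_annotations,
    train_rf,
)
from orbifab.volume import AnnotationSet, LabelVolume, VoxelVolume

SMALL = dict(grid_shape=(20, 20, 16), shell_radius_mm=3.0, shell_thickness_mm=0.8)


def small_phantom(seed, **kw):
    return phantom.make_orbital_phantom(PhantomSpec(seed=seed, **SMALL, **kw))


class TestFeatures:
    def test_constant_volume_zero_gradient(self):
        vol = VoxelVolume(np.full((8, 8, 8), 7.0), (1, 1, 1))
        f = extract_features(vol)
        assert np.all(f.data[..., 3] == 0)  # gradient magnitude
        assert np.all(f.data[..., 4] == 0)  # local variance

    def test_single_bright_voxel_maximises_variance(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 100.0
        f = extract_features(VoxelVolume(data, (1, 1, 1)))
        var = f.data[..., 4]
        # every 3^3 window containing the spike ties for the maximum
        peaks = np.argwhere(var == var.max())
        assert [4, 4, 4] in peaks.tolist()
        assert np.abs(peaks - 4).max() <= 1

    def test_boundary_gradient_exceeds_interior(self, default_phantom):
        vol, truth, _ = default_phantom
        f = extract_features(vol)
        grad = f.data[..., 3]
        m = truth.data.astype(bool)
        padded = np.pad(m, 1)
        core = padded[1:-1, 1:-1, 1:-1]
        boundary = np.zeros_like(m)
        for ax in range(3):
            for off in (-1, 1):
                boundary |= core & ~np.roll(padded, off, axis=ax)[1:-1, 1:-1, 1:-1]
        interior = m & ~boundary
        if interior.any():
            assert grad[boundary].mean() > grad[interior].mean()

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            extract_features(VoxelVolume(np.zeros((3, 8, 8)), (1, 1, 1)))


class TestTrainClassify:
    def test_separable_clusters_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        data = np.where(rng.random((12, 12, 12)) < 0.5, 40.0, 700.0)
        data += rng.normal(0, 5, data.shape)
        vol = VoxelVolume(data, (1, 1, 1))
        truth = LabelVolume((data > 370).astype(np.uint8), (1, 1, 1))
        f = extract_features(vol)
        ann = sample_annotations(truth, 300, seed=1)
        model = train_rf(f, ann, seed=0)
        pred = model.forest.predict(f.at(ann.indices()))
        assert np.mean(pred == ann.labels()) == 1.0

    def test_single_class_annotations_rejected(self, default_phantom):
        vol, _, _ = default_phantom
        f = extract_features(vol)
        with pytest.raises(ValueError):
            AnnotationSet([((0, 0, 0), 0), ((1, 1, 1), 0)])

    def test_6300_voxel_protocol_accepted(self):
        """21 datasets x 300 points pooled into one training set of 6300."""
        vol, truth = small_phantom(0)
        f = extract_features(vol)
        pts = []
        for i in range(21):
            pts += sample_annotations(truth, 300, seed=i).points
        pooled = AnnotationSet(pts)
        assert len(pooled.points) == 6300
        model = train_rf(f, pooled, n_trees=10, seed=0)
        assert model.n_trees == 10

    def test_classify_schema_mismatch(self, default_phantom):
        vol, truth, _ = default_phantom
        f = extract_features(vol)
        model = train_rf(f, sample_annotations(truth, 100, seed=0), n_trees=10, seed=0)
        model.schema = "other"
        with pytest.raises(ValueError, match="schema"):
            classify(model, f)

    def test_noise_free_phantom_dice_one(self):
        # supersample=1 makes intensity a perfect predictor of the mask
        vol, truth = phantom.make_orbital_phantom(
            PhantomSpec(seed=1, noise_sd=0, supersample=1)
        )
        f = extract_features(vol)
        model = train_rf(f, sample_annotations(truth, 300, seed=0), seed=0)
        pred = classify(model, f, spacing_mm=vol.spacing_mm)
        truth_l = LabelVolume(truth.data, vol.spacing_mm)
        assert dice(pred, truth_l) == 1.0

    def test_model_save_load_identical_predictions(self, tmp_path, default_phantom):
        vol, truth, _ = default_phantom
        f = extract_features(vol)
        model = train_rf(f, sample_annotations(truth, 100, seed=0), n_trees=10, seed=0)
        model.save(tmp_path / "m.pkl")
        back = segment.RFModel.load(tmp_path / "m.pkl")
        p1 = classify(model, f)
        p2 = classify(back, f)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_intensity_shift_invariance(self):
        """Adding a constant to all intensities leaves predictions unchanged
        when features are recomputed (translation-covariant schema)."""
        vol, truth = small_phantom(2)
        shifted = VoxelVolume(vol.data + 123.0, vol.spacing_mm)
        ann = sample_annotations(truth, 300, seed=0)
        m1 = train_rf(extract_features(vol), ann, n_trees=30, seed=0)
        m2 = train_rf(extract_features(shifted), ann, n_trees=30, seed=0)
        p1 = classify(m1, extract_features(vol))
        p2 = classify(m2, extract_features(shifted))
        assert np.mean(p1.data == p2.data) > 0.999


class TestIsoValue:
    def test_symmetric_classes_midpoint(self):
        rng = np.random.default_rng(0)
        data = np.concatenate([rng.normal(40, 20, 4000), rng.normal(700, 20, 4000)])
        vol = VoxelVolume(data.reshape(20, 20, 20), (1, 1, 1))
        labels = LabelVolume((vol.data > 370).astype(np.uint8), (1, 1, 1))
        iso = estimate_isovalue(vol, labels)
        assert iso == pytest.approx(370, abs=30)

    def test_unequal_variances_shift_toward_tight_class(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(40, 20, 4000)  # tight class
        hi = rng.normal(300, 150, 4000)  # overlaps the low class
        data = np.concatenate([lo, hi]).reshape(20, 20, 20)
        vol = VoxelVolume(data, (1, 1, 1))
        labels = LabelVolume(
            (np.arange(8000) >= 4000).astype(np.uint8).reshape(20, 20, 20), (1, 1, 1)
        )
        iso = estimate_isovalue(vol, labels)
        # brute-force sweep oracle: midpoint of the minimum-error interval
        grid = np.linspace(data.min(), data.max(), 5000)
        flat = data.ravel()
        lab = labels.data.ravel()
        errs = np.array(
            [(np.sum(flat[lab == 1] < t) + np.sum(flat[lab == 0] >= t)) for t in grid]
        )
        ties = np.nonzero(errs == errs.min())[0]
        t_opt = (grid[ties[0]] + grid[ties[-1]]) / 2
        assert abs(iso - t_opt) < 5
        assert iso < (40 + 300) / 2  # shifted toward the low-variance class

    def test_single_class_rejected(self):
        vol = VoxelVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        labels = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            estimate_isovalue(vol, labels)


class TestDice:
    def test_reference_cases(self):
        shape = (10, 10, 2)
        a = np.zeros(shape, dtype=np.uint8)
        b = np.zeros(shape, dtype=np.uint8)
        a.ravel()[:100] = 1
        b.ravel()[:100] = 1
        mk = lambda m: LabelVolume(m, (1, 1, 1))
        assert dice(mk(a), mk(b)) == 1.0
        b = np.zeros(shape, dtype=np.uint8)
        b.ravel()[100:200] = 1
        assert dice(mk(a), mk(b)) == 0.0
        b = np.zeros(shape, dtype=np.uint8)
        b.ravel()[50:150] = 1
        assert dice(mk(a), mk(b)) == 0.5
        empty = np.zeros(shape, dtype=np.uint8)
        assert dice(mk(empty), mk(empty)) == 1.0

    def test_symmetry_and_shape_mismatch(self):
        rng = np.random.default_rng(0)
        a = LabelVolume((rng.random((5, 5, 5)) > 0.5).astype(np.uint8), (1, 1, 1))
        b = LabelVolume((rng.random((5, 5, 5)) > 0.5).astype(np.uint8), (1, 1, 1))
        assert dice(a, b) == dice(b, a)
        c = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            dice(a, c)


class TestCrossval:
    def test_fold_sizes_for_21_cases(self):
        vols, truths = zip(*[small_phantom(s) for s in range(6)])
        # fold partition logic checked at n=21 via a cheap direct call
        rng = np.random.default_rng(0)
        perm = rng.permutation(21)
        folds = [sorted(perm[i::5].tolist()) for i in range(5)]
        assert sorted(len(f) for f in folds) == [4, 4, 4, 4, 5]
        assert sorted(sum(folds, [])) == list(range(21))

    def test_separable_phantoms_high_mean_dice(self):
        pairs = [small_phantom(s, noise_sd=0) for s in range(5)]
        vols = [p[0] for p in pairs]
        truths = [p[1] for p in pairs]
        res = crossval_dice(vols, truths, k=5, n_trees=30, seed=0)
        assert res.fold_sizes == [1, 1, 1, 1, 1]
        assert res.mean > 0.95

    def test_k_larger_than_n_rejected(self):
        vol, truth = small_phantom(0)
        with pytest.raises(ValueError):
            crossval_dice([vol], [truth], k=5)
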