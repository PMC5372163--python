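"""Cascade training/prediction, restriction invariant and evaluation metrics."""

import itertools

import numpy as np
import pytest

from ftirlcm import classify as clf
from ftirlcm import preprocess as pp
from ftirlcm import synthetic as syn
from ftirlcm.errors import StructuralError, ValidationError
from ftirlcm.hyperspec_io import LabelMap, SpectralImage, WavenumberAxis

from conftest import leaf_accuracy, preprocess_phantom, train_on_phantom


class TestExtractFeatures:
    def test_fingerprint_region_has_213_bands(self, axis):
        # axis points of the 2700->952 grid inside [950, 1800]
        image = SpectralImage(cube=np.random.default_rng(0).random((3, 3, len(axis))), axis=axis)
        features, back_map = clf.extract_features(image)
        assert features.shape == (9, 213)

    def test_all_pixels_failed_is_error(self, axis):
        image = SpectralImage(
            cube=np.ones((2, 2, len(axis))),
            axis=axis,
            qc_mask=np.zeros((2, 2), dtype=bool),
        )
        with pytest.raises(ValidationError, match="no usable pixels"):
            clf.extract_features(image)

    def test_back_map_round_trip(self, axis):
        rng = np.random.default_rng(1)
        mask = rng.random((4, 5)) > 0.3
        mask[0, 0] = True
        image = SpectralImage(cube=rng.random((4, 5, len(axis))), axis=axis, qc_mask=mask)
        features, back_map = clf.extract_features(image)
        flat = image.cube.reshape(-1, len(axis))
        idx = axis.window_indices(*clf.FINGERPRINT_RANGE)
        for k in range(features.shape[0]):
            r, c = divmod(int(back_map[k]), 5)
            assert mask[r, c]
            np.testing.assert_array_equal(features[k], flat[back_map[k]][idx])


class TestCascadeSpec:
    def test_unknown_parent_rejected(self):
        with pytest.raises(Exception):
            clf.CascadeSpec(
                levels=(
                    clf.CascadeLevel("l1", ("a", "b")),
                    clf.CascadeLevel("l2", ("c",), parents={"c": "nope"}),
                )
            )

    def test_leaf_classes_of_dmm_hierarchy(self):
        spec = clf.dmm_cascade_spec()
        assert spec.leaf_classes() == ["normal", "other-neoplasm", "epithelioid", "sarcomatoid"]

    def test_label_missing_from_spec_rejected(self, axis):
        spec = clf.CascadeSpec(
            levels=(clf.CascadeLevel("l1", ("a", "b")),), min_train_pixels=1
        )
        rng = np.random.default_rng(0)
        features = rng.random((10, 213))
        labels = np.array(["a"] * 5 + ["zzz"] * 5, dtype=object)
        with pytest.raises(ValidationError, match="zzz"):
            clf.train_cascade([(features, labels)], spec, np.arange(213.0), seed=0)


class TestTrainPredict:
    def test_separable_classes_high_oob(self):
        """Two disjoint-band signatures are near-perfectly separable."""
        rng = np.random.default_rng(0)
        n = 300
        grid = np.arange(213.0)
        a = np.exp(-0.5 * ((grid - 60) / 8) ** 2)
        b = np.exp(-0.5 * ((grid - 150) / 8) ** 2)
        features = np.vstack(
            [a + rng.normal(0, 0.05, (n, 213)), b + rng.normal(0, 0.05, (n, 213))]
        )
        labels = np.array(["a"] * n + ["b"] * n, dtype=object)
        spec = clf.CascadeSpec(levels=(clf.CascadeLevel("l1", ("a", "b"), n_trees=100),))
        cascade = clf.train_cascade([(features, labels)], spec, grid, seed=0)
        assert cascade.forests[0].oob_score_ >= 0.99

    def test_deterministic_given_seed(self, trained_phantom_cascade):
        cascade, held_out, truth = trained_phantom_cascade
        corrected, train_truth, _ = preprocess_phantom(seed=1)
        again = train_on_phantom(corrected, train_truth, seed=7)
        map1 = clf.predict_cascade(held_out, cascade)
        map2 = clf.predict_cascade(held_out, again)
        np.testing.assert_array_equal(map1.labels, map2.labels)

    def test_too_few_examples_named_error(self):
        spec = clf.CascadeSpec(levels=(clf.CascadeLevel("l1", ("a", "b")),))
        rng = np.random.default_rng(0)
        features = rng.random((150, 213))
        labels = np.array(["a"] * 140 + ["b"] * 10, dtype=object)
        with pytest.raises(ValidationError, match="'b'"):
            clf.train_cascade([(features, labels)], spec, np.arange(213.0), seed=0)

    def test_held_out_phantom_accuracy(self, trained_phantom_cascade):
        cascade, held_out, truth = trained_phantom_cascade
        pred = clf.predict_cascade(held_out, cascade)
        assert leaf_accuracy(pred, truth) >= 0.95
        # QC-failed pixels stay unclassified
        assert np.all(pred.labels[~held_out.qc_mask] == 0)

    def test_shifted_axis_rejected(self, trained_phantom_cascade):
        cascade, held_out, _ = trained_phantom_cascade
        shifted = SpectralImage(
            cube=held_out.cube,
            axis=WavenumberAxis(held_out.axis.values + 2.0),
            qc_mask=held_out.qc_mask,
        )
        with pytest.raises(StructuralError):
            clf.predict_cascade(shifted, cascade)


class TestCascadeRestriction:
    def test_no_leaf_without_assigned_parent(self):
        """Two-level cascade: subtype labels only inside 'pathologic' pixels."""
        rng = np.random.default_rng(5)
        grid = np.arange(50.0)
        protos = {
            "normal": np.exp(-0.5 * ((grid - 10) / 4) ** 2),
            "epi": np.exp(-0.5 * ((grid - 25) / 4) ** 2),
            "sarc": np.exp(-0.5 * ((grid - 40) / 4) ** 2),
        }
        n = 200
        features = np.vstack(
            [protos[k] + rng.normal(0, 0.05, (n, 50)) for k in ("normal", "epi", "sarc")]
        )
        labels = np.array(
            ["normal"] * n + ["epi"] * n + ["sarc"] * n, dtype=object
        )
        spec = clf.CascadeSpec(
            levels=(
                clf.CascadeLevel("region", ("normal", "pathologic"), n_trees=50),
                clf.CascadeLevel(
                    "subtype",
                    ("epi", "sarc"),
                    parents={"epi": "pathologic", "sarc": "pathologic"},
                    n_trees=50,
                ),
            ),
            min_train_pixels=50,
        )
        cascade = clf.train_cascade([(features, labels)], spec, grid, seed=0)
        axis = WavenumberAxis(1800.0 - 4.0 * np.arange(50), nominal_resolution=4.0)
        test_img = SpectralImage(
            cube=features[::7].reshape(-1, 1, 50), axis=axis
        )
        grid_axis = axis.values[axis.window_indices(*spec.feature_range)]
        cascade.feature_wavenumbers = grid_axis
        pred = clf.predict_cascade(test_img, cascade)
        level1 = cascade.forests[0].predict(
            clf.extract_features(test_img, spec.feature_range)[0]
        )
        names = {lbl: name for lbl, (name, _) in pred.legend.items()}
        flat = pred.labels.reshape(-1)
        for k, lvl1 in enumerate(level1):
            leaf = names[flat[k]]
            if leaf in ("epi", "sarc"):
                assert lvl1 == "pathologic"
            else:
                assert leaf == lvl1 == "normal"

    def test_single_class_phantom_uniform_labels(self):
        spec_p = syn.PhantomSpec(
            shape=(24, 24), seed=9, blob_classes={}, background_class="stroma",
            n_blank=4, n_saturated=2,
        )
        image, truth, *_ = syn.generate_phantom(spec_p)
        pp.quality_control(image)
        corrected, train_truth, _ = preprocess_phantom(seed=1)
        cascade = train_on_phantom(corrected, train_truth, seed=7)
        flat = image.cube.reshape(-1, image.cube.shape[2])
        reference = flat[image.qc_mask.reshape(-1)].mean(axis=0)
        model = pp.EMSCModel(
            reference=reference, axis=image.axis, mie_basis=pp.build_mie_basis(image.axis)
        )
        corr_img, _ = pp.emsc_correct_image(image, model)
        pred = clf.predict_cascade(corr_img, cascade)
        names = {lbl: name for lbl, (name, _) in pred.legend.items()}
        passing = pred.labels[corr_img.qc_mask]
        assert passing.min() > 0
        assert {names[l] for l in np.unique(passing)} == {"stroma"}
        assert np.all(pred.labels[~corr_img.qc_mask] == 0)


class TestNoiseDegradation:
    def test_mean_accuracy_non_increasing_as_noise_doubles(self):
        """Held-out accuracy degrades monotonically over sigma doublings."""
        from scipy.stats import spearmanr

        sigmas = (0.005, 0.01, 0.02, 0.04)
        means = []
        for sigma in sigmas:
            accs = []
            for seed in range(10):
                corrected, truth, _ = preprocess_phantom(
                    seed=seed, size=32, noise_sigma=sigma, n_blank=0, n_saturated=0
                )
                cascade = train_on_phantom(corrected, truth, seed=seed, n_trees=100)
                held, held_truth, _ = preprocess_phantom(
                    seed=seed + 1000, size=32, noise_sigma=sigma,
                    n_blank=0, n_saturated=0,
                )
                pred = clf.predict_cascade(held, cascade)
                accs.append(leaf_accuracy(pred, held_truth))
            means.append(float(np.mean(accs)))
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))
        rho = spearmanr(range(len(sigmas)), means).statistic
        assert rho < 0


class TestEvaluate:
    def test_seventeen_sample_worked_example(self):
        """The only 17-sample confusion matrix with sensitivity exactly 100%
        and specificity exactly 75% gives accuracy 88% after rounding."""
        # brute-force oracle: enumerate all (P, N) splits and error counts
        matches = []
        for n_pos in range(1, 17):
            n_neg = 17 - n_pos
            for fn, fp in itertools.product(range(n_pos + 1), range(n_neg + 1)):
                tp, tn = n_pos - fn, n_neg - fp
                if (
                    tp / n_pos == 1.0
                    and tn / n_neg == 0.75
                    and round(100 * (tp + tn) / 17) == 88
                ):
                    matches.append((tp, tn, fp, fn))
        assert matches == [(9, 6, 2, 0)]
        predicted = ["pos"] * 9 + ["pos"] * 2 + ["neg"] * 6
        truth = ["pos"] * 9 + ["neg"] * 8
        report = clf.evaluate(predicted, truth, positive_class="pos")
        assert report.sensitivity == 100.0
        assert report.specificity == 75.0
        assert round(report.accuracy) == 88
        assert report.accuracy == pytest.approx(100 * 15 / 17)

    def test_perfect_and_all_wrong(self):
        perfect = clf.evaluate(["a", "b"], ["a", "b"], positive_class="a")
        assert (perfect.accuracy, perfect.sensitivity, perfect.specificity) == (100.0, 100.0, 100.0)
        wrong = clf.evaluate(["b", "a"], ["a", "b"], positive_class="a")
        assert wrong.accuracy == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            clf.evaluate([], [], positive_class="a")


class TestMajoritySampleCall:
    def _map(self, n_epi, n_sarc):
        labels = np.array([1] * n_epi + [2] * n_sarc, dtype=np.int32).reshape(1, -1)
        return LabelMap(labels, {1: ("epithelioid", "#00f"), 2: ("sarcomatoid", "#0f0")})

    def test_mixed_sample_called_biphasic_with_sarcomatoid_majority(self):
        call = clf.majority_sample_call(self._map(30, 70))
        assert call.call == "biphasic"
        assert call.majority_class == "sarcomatoid"
        assert call.majority_fraction == pytest.approx(0.70)

    def test_pure_sample(self):
        call = clf.majority_sample_call(self._map(50, 0))
        assert call.call == "epithelioid"
        assert call.majority_fraction == 1.0

    def test_ninety_ten_split_below_threshold_not_biphasic(self):
        call = clf.majority_sample_call(self._map(90, 10))
        assert call.call == "epithelioid"

    def test_no_candidate_pixels_rejected(self):
        labels = np.zeros((2, 2), dtype=np.int32)
        lm = LabelMap(labels, {})
        with pytest.raises(ValidationError):
            clf.majority_sample_call(lm)
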