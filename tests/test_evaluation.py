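"""Evaluation semantics: accuracy under the tie-break convention, sweep
consistency, the left-right flank correlation, and misclassification
histograms."""

import numpy as np
import pytest

from mirrornet.estimators import ConvLSTMClassifier
from mirrornet.evaluation import (
    cross_dataset_eval,
    degree_of_nonsymmetry,
    degrees_of_nonsymmetry,
    evaluate,
    misclassification_analysis,
    timestep_sweep,
)
from mirrornet.exceptions import InvalidSpecError, UndefinedStatisticError
from mirrornet.fixtures import make_ideal_predictor
from mirrornet.stimuli import (
    FamilySpec,
    generate_family,
    make_band_image,
    mirror_image,
)


@pytest.fixture(scope="module")
def band4_family():
    return generate_family(FamilySpec("band", band_size=4), 200, seed=11)


class TestEvaluate:
    def test_oracle_predictor_is_perfect(self, band4_family):
        assert evaluate(make_ideal_predictor("oracle", 4), band4_family) == 1.0

    def test_chance_predictor_scores_symmetric_fraction(self, band4_family):
        # p = 0.5 everywhere; ties predict non-symmetric, so accuracy equals
        # the non-symmetric fraction = 0.5 on a balanced family
        assert evaluate(make_ideal_predictor("chance"), band4_family) == 0.5

    def test_label_flip_complements_accuracy(self, band4_family):
        model = make_ideal_predictor("band_detector")
        a = evaluate(model, band4_family)
        flipped = generate_family(FamilySpec("band", band_size=4), 200, seed=11)
        flipped.labels = 1 - flipped.labels
        assert evaluate(model, flipped) == pytest.approx(1.0 - a)

    def test_order_invariance(self, band4_family):
        model = make_ideal_predictor("band_detector")
        a = evaluate(model, band4_family)
        perm = np.random.default_rng(0).permutation(len(band4_family))
        shuffled = generate_family(FamilySpec("band", band_size=4), 200, seed=11)
        shuffled.images, shuffled.labels = shuffled.images[perm], shuffled.labels[perm]
        assert evaluate(model, shuffled) == a


class TestCrossDatasetEval:
    def test_one_row_per_family_and_consistency(self, band4_family):
        other = generate_family(FamilySpec("band", band_size=14), 100, seed=12)
        model = make_ideal_predictor("oracle", 0)  # wrong band size on purpose
        oracle4 = make_ideal_predictor("oracle", 4)
        df = cross_dataset_eval(oracle4, [band4_family])
        assert len(df) == 1
        assert df.accuracy.iloc[0] == evaluate(oracle4, band4_family)
        df2 = cross_dataset_eval(model, [band4_family, other])
        assert list(df2.family) == ["band4", "band14"]


class TestTimestepSweep:
    def test_requires_recurrent_model(self, band4_family):
        with pytest.raises(InvalidSpecError):
            timestep_sweep(make_ideal_predictor("oracle", 4), band4_family, [1, 2])

    def test_random_weight_model_near_chance(self):
        est = ConvLSTMClassifier(n_channels=3, unroll_steps=4, random_state=0)
        est.classes_ = np.array([0, 1])
        est.params_ = est._init_params(np.random.default_rng(0))
        est.history_ = {}
        fam = generate_family(FamilySpec("band", band_size=4), 400, seed=5)
        sw = timestep_sweep(est, fam, [1, 4])
        # an untrained readout carries no label information
        assert np.all(np.abs(sw.accuracy.values - 0.5) < 0.1)

    def test_sweep_final_step_matches_plain_evaluation(self):
        est = ConvLSTMClassifier(n_channels=3, unroll_steps=4, random_state=0)
        est.classes_ = np.array([0, 1])
        est.params_ = est._init_params(np.random.default_rng(1))
        est.history_ = {}
        fam = generate_family(FamilySpec("stripe", stripe_x=6), 60, seed=6)
        sw = timestep_sweep(est, fam, [2, 4])
        assert sw.accuracy.iloc[-1] == evaluate(est, fam)


class TestDegreeOfNonsymmetry:
    def test_symmetric_image_scores_one(self, rng):
        img = make_band_image(4, True, "normal", rng)
        assert degree_of_nonsymmetry(img, 4) == pytest.approx(1.0)

    def test_mirrored_image_scores_one(self, rng):
        img = mirror_image(rng.integers(0, 256, (20, 20)).astype(np.uint8))
        assert degree_of_nonsymmetry(img, 0) == pytest.approx(1.0)

    def test_swap_and_flip_invariance(self, rng):
        img = make_band_image(4, False, "normal", rng)
        swapped = img[:, ::-1].copy()  # swaps the flanks and flips both
        assert degree_of_nonsymmetry(swapped, 4) == pytest.approx(
            degree_of_nonsymmetry(img, 4)
        )

    def test_zero_variance_flank_rejected(self):
        img = np.full((20, 20), 100, np.uint8)
        with pytest.raises(UndefinedStatisticError):
            degree_of_nonsymmetry(img, 0)

    def test_batch_matches_scalar(self, rng):
        fam = generate_family(FamilySpec("band", band_size=6), 20, seed=3)
        batch = degrees_of_nonsymmetry(fam.images, 6)
        scalar = [degree_of_nonsymmetry(im, 6) for im in fam.images]
        np.testing.assert_allclose(batch, scalar, atol=1e-12)


class _CorrelationThresholdPredictor:
    """Predicts symmetric iff the flank correlation exceeds a threshold."""

    is_recurrent = False

    def __init__(self, band_size, thr=0.2):
        self.band_size, self.thr = band_size, thr

    def predict_proba(self, images):
        r = degrees_of_nonsymmetry(np.asarray(images), self.band_size)
        p1 = (r > self.thr).astype(float)
        return np.column_stack([1 - p1, p1])


class TestMisclassificationAnalysis:
    def test_counts_conserved_and_perfect_predictor(self, band4_family):
        hist = misclassification_analysis(
            make_ideal_predictor("oracle", 4), band4_family, which_class=0
        )
        assert hist.n_total == 100
        assert hist.incorrect.sum() == 0

    def test_histogram_frame_shape(self, band4_family):
        hist = misclassification_analysis(
            make_ideal_predictor("chance"), band4_family, which_class=1, bins=10
        )
        df = hist.to_frame()
        assert len(df) == 10
        assert hist.n_total == 100

    def test_threshold_predictor_errors_concentrate_above_threshold(self):
        """A predictor thresholding the correlation itself misclassifies
        exactly the non-symmetric images whose correlation falls above the
        threshold."""
        fam = generate_family(FamilySpec("band", band_size=4), 2000, seed=21)
        model = _CorrelationThresholdPredictor(4, thr=0.05)
        hist = misclassification_analysis(model, fam, which_class=0)
        centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
        wrong_bins = centers[hist.incorrect > 0]
        if wrong_bins.size:  # every error lies above the threshold
            assert wrong_bins.min() > 0.0
        right_bins = centers[hist.correct > 0]
        assert right_bins.max() <= 0.15  # correct ones below it
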