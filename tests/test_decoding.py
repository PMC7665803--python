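import numpy as np
import pandas as pd
import pytest

import whisklocate as wl
from whisklocate import decoding, tuning


def _population_curves(n_neurons=10, sd=1.0, peak=2.0, seed=0,
                       n_touches=400):
    rng = np.random.default_rng(seed)
    curves = []
    for i in range(n_neurons):
        neuron = wl.GroundTruthNeuron(
            baseline_rate=2.0, location_pref=rng.uniform(0, 10),
            location_sd=sd, peak_touch_spikes=peak, count_dispersion=1.0)
        locs, counts = wl.simulate_touch_counts(neuron, n_touches, (0, 10), rng)
        tc = tuning.build_tuning_curve(locs, counts.astype(float), "loc")
        curves.append((f"n{i}", tc.bin_stimulus, tc.bin_response))
    return curves


@pytest.fixture(scope="module")
def small_model():
    """A fitted 10-neuron decoder (single regularization value for speed)."""
    design = decoding.build_design(_population_curves(10, seed=2), seed=3)
    model = decoding.fit_decoder(design, seed=4, c_grid=(5.0,))
    return design, model


class TestBuildDesign:
    def test_shape_and_dtype(self):
        design = decoding.build_design(_population_curves(5), seed=0)
        assert design.design_matrix.shape == (40 * 50, 5)
        assert design.labels.shape == (2000,)
        assert np.issubdtype(design.design_matrix.dtype, np.integer)
        assert design.design_matrix.min() >= 0
        assert np.all(design.lambda_matrix >= 0)

    def test_constant_lambda_poisson_moments(self):
        c = 2.5
        x = np.linspace(0.25, 9.75, 20)
        design = decoding.build_design([("n0", x, np.full(20, c))], seed=1)
        col = design.design_matrix[:, 0]
        assert abs(col.mean() - c) < 0.15
        assert abs(col.var() - c) < 0.3

    def test_zero_lambda_gives_zero_column(self):
        x = np.linspace(0.25, 9.75, 20)
        design = decoding.build_design([("n0", x, np.zeros(20))], seed=1)
        assert not design.design_matrix.any()

    def test_inclusion_rule(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0.25, 9.75, 20)
        curves = [("few", x, np.ones(20)), ("narrow", x, np.ones(20)),
                  ("good", x, np.ones(20))]
        touch_locations = {
            "few": rng.uniform(0, 10, 50),            # < 75 touches
            "narrow": rng.uniform(0, 3, 200),         # < 80% coverage
            "good": rng.uniform(0, 10, 200),
        }
        design = decoding.build_design(curves, touch_locations, seed=0)
        assert design.neuron_ids == ["good"]

    def test_all_excluded_is_error(self):
        x = np.linspace(0.25, 9.75, 20)
        with pytest.raises(ValueError):
            decoding.build_design([("n", x, np.ones(20))],
                                  {"n": np.array([1.0, 2.0])}, seed=0)


class TestFitDecoder:
    def test_informative_population_beats_chance(self, small_model):
        design, model = small_model
        assert model.accuracy > 5 * (1 / 40)
        assert model.ensemble_accuracy >= model.accuracy - 0.05

    def test_confusion_rows_normalized(self, small_model):
        _, model = small_model
        sums = model.confusion.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)

    def test_single_flat_neuron_is_chance(self):
        x = np.linspace(0.25, 9.75, 20)
        design = decoding.build_design([("flat", x, np.full(20, 2.0))], seed=5)
        model = decoding.fit_decoder(design, seed=6, n_iterations=3,
                                     c_grid=(1.0,))
        assert model.accuracy < 0.08  # chance = 0.025

    def test_column_order_invariance(self, small_model):
        """Accuracy of the fitted coefficients is invariant to relabeling
        neuron columns (predictions permute coherently)."""
        design, model = small_model
        perm = np.random.default_rng(0).permutation(design.n_neurons)
        base = decoding.predict_from_columns(model, model.eval_X)
        swapped = model.eval_X[:, perm] @ model.coefficients[:, perm].T \
            + model.intercepts
        assert np.array_equal(base, np.argmax(swapped, axis=1))


class TestBayesOracle:
    def test_oracle_identifies_obvious_class(self):
        lam = np.ones((2, 40))
        lam[:, 7] = 10.0
        X = np.full((5, 2), 10)
        assert np.all(decoding.bayes_predict(lam, X) == 7)

    def test_ties_break_to_lower_bin(self):
        lam = np.ones((2, 40))
        X = np.zeros((3, 2), dtype=int)
        assert np.all(decoding.bayes_predict(lam, X) == 0)


class TestSubsample:
    def test_full_pool_without_duplication_matches_model(self, small_model):
        design, model = small_model
        pred = decoding.predict_from_columns(
            model, model.eval_X, np.arange(design.n_neurons))
        full = decoding.predict_from_columns(model, model.eval_X)
        assert np.array_equal(pred, full)
        assert (pred == model.eval_y).mean() == pytest.approx(
            model.ensemble_accuracy)

    def test_accuracy_grows_with_pool(self, small_model):
        design, model = small_model
        sub = decoding.subsample_population(model, design, [1, 10],
                                            n_draws=100, seed=0)
        assert sub.mean_accuracy[1] >= sub.mean_accuracy[0]

    def test_reproducible_with_seed(self, small_model):
        design, model = small_model
        a = decoding.subsample_population(model, design, [3], n_draws=50, seed=1)
        b = decoding.subsample_population(model, design, [3], n_draws=50, seed=1)
        assert np.array_equal(a.mean_accuracy, b.mean_accuracy)

    def test_zero_pool_rejected(self, small_model):
        design, model = small_model
        with pytest.raises(ValueError):
            decoding.subsample_population(model, design, [0], n_draws=5, seed=0)


class TestResolutionNeurometric:
    def test_perfect_predictions(self):
        y = np.repeat(np.arange(40), 3)
        res = decoding.resolution_curve(y, y)
        assert res[0] == 1.0 and res[-1] == 1.0
        neuro = decoding.neurometric_curve(y, y)
        assert np.all(neuro[:20] == 1.0) and np.all(neuro[20:] == 0.0)

    def test_uniform_predictions_closed_form(self):
        """For a true interior bin with uniform predictions,
        resolution(n) = (2n+1)/40."""
        y_pred = np.tile(np.arange(40), 25)
        y_true = np.full(1000, 20)
        res = decoding.resolution_curve(y_true, y_pred)
        for n in (0, 2, 5):
            assert res[n] == pytest.approx((2 * n + 1) / 40)

    def test_resolution_nondecreasing_and_saturates(self, small_model):
        _, model = small_model
        res, neuro, choices = decoding.resolution_and_neurometric(model)
        assert np.all(np.diff(res) >= 0)
        assert res[39] == 1.0
        assert choices.dtype == bool


class TestPsychometricComparison:
    def _table(self, probs, sd=0.05):
        # synthetic psychometric reference (stand-in for behavioral data)
        return pd.DataFrame(dict(location_mm=np.linspace(0.125, 9.875, 40),
                                 mean_lick_prob=probs, sd=sd, n=15))

    def test_identical_curves_not_significant(self):
        locs = np.linspace(0.125, 9.875, 40)
        probs = 1 / (1 + np.exp(locs - 5))
        draws = np.tile(probs, (30, 1)) \
            + np.random.default_rng(0).normal(0, 0.05, (30, 40))
        out = decoding.compare_to_psychometric(draws, locs, self._table(probs))
        assert out["significant"].sum() <= 4  # ~5% false positives at alpha .05

    def test_shifted_curve_all_significant(self):
        locs = np.linspace(0.125, 9.875, 40)
        probs = np.full(40, 0.5)
        draws = np.tile(probs + 0.3, (30, 1)) \
            + np.random.default_rng(1).normal(0, 0.02, (30, 40))
        out = decoding.compare_to_psychometric(draws, locs,
                                               self._table(probs, sd=0.02))
        assert out["significant"].all()
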