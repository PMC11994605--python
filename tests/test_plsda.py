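import numpy as np
import pytest

from scapstab.landmarks import template_coords
from scapstab.plsda import (
    classify,
    fit_pls,
    group_shape,
    loocv_mode_selection,
    n_modes_for_variance,
    null_model_comparison,
    performance_metrics,
    predict_response,
)
from scapstab.procrustes import _optimal_rotation, centroid_size, gpa
from scapstab.synthgen import SynthConfig, default_effect_vector, generate_landmark_sample


def _random_xy(rng, n=20, p=12):
    X = rng.normal(size=(n, p))
    y = np.zeros(n)
    y[: n // 2] = 1.0
    return X, rng.permutation(y)


class TestFit:
    def test_first_weight_parallel_to_group_mean_difference(self, rng):
        X, y = _random_xy(rng)
        model = fit_pls(X, y, 1)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        expected = Xc.T @ yc
        expected /= np.linalg.norm(expected)
        cos = abs(np.dot(model.W[:, 0], expected))
        assert cos > 1.0 - 1e-10

    def test_scores_mutually_orthogonal(self, rng):
        X, y = _random_xy(rng, n=25, p=15)
        model = fit_pls(X, y, 6)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="classes"):
            fit_pls(X, np.ones(6), 1)

    def test_m_too_large_rejected(self, rng):
        X, y = _random_xy(rng, n=6, p=4)
        with pytest.raises(ValueError, match="m must be"):
            fit_pls(X, y, 6)

    def test_matches_reference_pls_implementation(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_xy(rng, n=30, p=20)
        model = fit_pls(X, y, 1)
        ref = PLSRegression(n_components=1, scale=False).fit(X, y)
        ours = predict_response(model, X, 1)
        assert np.max(np.abs(ref.predict(X).ravel() - ours)) < 1e-6

    def test_centering_invariance(self, rng):
        X, y = _random_xy(rng)
        model_a = fit_pls(X, y, 3)
        model_b = fit_pls(X + 7.3, y, 3)
        xq = rng.normal(size=X.shape[1])
        assert abs(
            predict_response(model_a, xq, 3) - predict_response(model_b, xq + 7.3, 3)
        ) < 1e-8


class TestPredict:
    def test_mean_predicts_class_proportion(self, rng):
        X, y = _random_xy(rng)
        model = fit_pls(X, y, 2)
        assert abs(predict_response(model, model.x_mean, 2) - y.mean()) < 1e-12

    def test_zero_modes_is_constant_null_model(self, rng):
        X, y = _random_xy(rng)
        model = fit_pls(X, y, 2)
        preds = predict_response(model, X, 0)
        np.testing.assert_allclose(preds, y.mean())

    def test_separable_training_data_classified_correctly(self, rng):
        X, y = _random_xy(rng, n=16, p=8)
        X = X + 10.0 * np.outer(y, np.ones(8))  # huge class offset, noise-free axis
        model = fit_pls(X, y, 1)
        np.testing.assert_array_equal(classify(predict_response(model, X, 1)), y)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _random_xy(rng)
        model = fit_pls(X, y, 1)
        with pytest.raises(ValueError, match="features"):
            predict_response(model, np.zeros(5), 1)


class TestModeCount:
    def test_rank_one_x_needs_one_mode(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, rng.normal(size=10))
        y = (t > 0).astype(float)
        assert n_modes_for_variance(X, y, 0.70) == 1
        assert n_modes_for_variance(X, y, 1.0) == 1

    def test_matches_bruteforce_cumulative_sum(self, rng):
        X, y = _random_xy(rng, n=25, p=10)
        model = fit_pls(X, y, min(24, 10))
        cum = np.cumsum(model.x_variance_explained)
        brute = int(np.argmax(cum >= 0.70)) + 1
        assert n_modes_for_variance(X, y, 0.70) == brute
        # isotropic X: modes each carry roughly 1/rank of the variance
        assert abs(brute - 0.70 * model.n_modes) <= 2

    def test_full_fraction_reaches_rank(self, rng):
        X, y = _random_xy(rng, n=12, p=5)
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        assert n_modes_for_variance(X, y, 1.0) == rank

    def test_invalid_fraction_rejected(self, rng):
        X, y = _random_xy(rng)
        with pytest.raises(ValueError):
            n_modes_for_variance(X, y, 0.0)


class TestPerformanceMetrics:
    def test_printed_arithmetic_example(self):
        y_true = [1] * 3 + [1] + [0] * 8 + [0] * 2
        y_pred = [1] * 3 + [0] + [0] * 8 + [1] * 2  # TP=3 FN=1 TN=8 FP=2
        rep = performance_metrics(y_true, y_pred)
        assert rep.sensitivity == 0.75
        assert rep.specificity == 0.8
        assert rep.balanced_accuracy == 0.775
        assert rep.precision == 0.6
        assert abs(rep.f1 - 2.0 / 3.0) < 1e-12
        assert abs(rep.g_mean - np.sqrt(0.45)) < 1e-12

    def test_perfect_prediction(self):
        rep = performance_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert all(v == 1.0 for v in rep.as_dict().values())

    def test_all_predicted_control(self):
        rep = performance_metrics([0, 0, 1, 1], [0, 0, 0, 0])
        assert rep.sensitivity == 0.0
        assert rep.balanced_accuracy == 0.5
        assert rep.precision == 0.0 and rep.precision_undefined

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            performance_metrics([], [])


class TestLOOCV:
    def test_perfectly_separable_reaches_full_accuracy(self):
        cfg = SynthConfig(n_control=10, n_ftt=10, effect_scale=2.0, noise_sd=0.05, seed=2)
        aligned = gpa(generate_landmark_sample(cfg))
        X, y = aligned.flat(), aligned.groups.astype(float)
        _, best, reports = loocv_mode_selection(X, y, 3)
        assert reports[best].balanced_accuracy == 1.0

    def test_single_mode_table(self, rng):
        X, y = _random_xy(rng, n=10, p=6)
        table, best, _ = loocv_mode_selection(X, y, 1)
        assert len(table) == 1 and best == 1

    def test_balanced_accuracy_monotone_in_effect_scale(self):
        # allow one inversion within Monte-Carlo noise per seed
        scales = [0.0, 0.5, 1.5, 3.0]
        for seed in range(5):
            bas = []
            for s in scales:
                cfg = SynthConfig(n_control=12, n_ftt=12, effect_scale=s,
                                  noise_sd=1.0, seed=seed)
                aligned = gpa(generate_landmark_sample(cfg))
                X, y = aligned.flat(), aligned.groups.astype(float)
                _, best, reports = loocv_mode_selection(X, y, 4)
                bas.append(reports[best].balanced_accuracy)
            inversions = sum(b < a - 1e-12 for a, b in zip(bas, bas[1:]))
            assert inversions <= 1, (seed, bas)


class TestNullComparison:
    def test_fixed_seed_reproducible_and_separable_data_significant(self):
        cfg = SynthConfig(n_control=24, n_ftt=16, effect_scale=2.0, noise_sd=0.3, seed=4)
        aligned = gpa(generate_landmark_sample(cfg))
        X, y = aligned.flat(), aligned.groups.astype(float)
        a = null_model_comparison(X, y, n_null=20, seed=11, m_cap=6)
        b = null_model_comparison(X, y, n_null=20, seed=11, m_cap=6)
        assert a.null_table.equals(b.null_table)
        assert a.z_scores == b.z_scores
        assert a.z_scores["balanced_accuracy"] > 3.0
        assert all(p < 0.01 for p in a.p_values.values())
        # permutation preserves group proportions by construction
        assert (a.null_table["m"] >= 1).all()


class TestGroupShape:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = SynthConfig(n_control=14, n_ftt=10, effect_scale=1.0, noise_sd=0.8, seed=6)
        aligned = gpa(generate_landmark_sample(cfg))
        X, y = aligned.flat(), aligned.groups.astype(float)
        return fit_pls(X, y, 4), X, y

    def test_group_weighted_average_is_grand_mean(self, fitted):
        model, X, y = fitted
        g0 = group_shape(model, 0).reshape(-1)
        g1 = group_shape(model, 1).reshape(-1)
        n0, n1 = np.sum(y == 0), np.sum(y == 1)
        avg = (n0 * g0 + n1 * g1) / (n0 + n1)
        np.testing.assert_allclose(avg, model.x_mean, atol=1e-8)

    def test_equals_group_mean_projected_onto_modes(self, fitted):
        model, X, y = fitted
        # independent projection: oblique PLS projector applied to the group mean
        Rmat = model.W @ np.linalg.inv(model.P.T @ model.W)
        for g in (0, 1):
            xbar = X[y == g].mean(axis=0)
            proj = model.x_mean + model.P @ (Rmat.T @ (xbar - model.x_mean))
            np.testing.assert_allclose(group_shape(model, g).reshape(-1), proj, atol=1e-8)

    def test_full_rank_two_specimen_dataset_recovers_inputs(self, rng):
        base = template_coords()
        eff = default_effect_vector()
        X = np.stack([base.reshape(-1), (base + eff).reshape(-1), base.reshape(-1),
                      (base + eff).reshape(-1)])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        model = fit_pls(X, y, 1)  # two distinct points: rank-1 centred X
        np.testing.assert_allclose(group_shape(model, 0), base, atol=1e-8)
        np.testing.assert_allclose(group_shape(model, 1), base + eff, atol=1e-8)


def test_first_direction_recovers_injected_effect():
    scale, noise = 2.0, 0.2
    cfg = SynthConfig(n_control=20, n_ftt=20, effect_scale=scale, noise_sd=noise, seed=5)
    aligned = gpa(generate_landmark_sample(cfg))
    model = fit_pls(aligned.flat(), aligned.groups.astype(float), 1)

    def to_shape_space(coords):
        c = coords - coords.mean(axis=0)
        c = c / centroid_size(c)
        return c @ _optimal_rotation(c, aligned.mean_shape)

    tpl = template_coords()
    v = (to_shape_space(tpl + scale * default_effect_vector()) - to_shape_space(tpl))
    v = v.reshape(-1)
    v /= np.linalg.norm(v)
    cos = abs(float(model.W[:, 0] @ v))
    assert np.degrees(np.arccos(min(1.0, cos))) < 5.0
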