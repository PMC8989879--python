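"""GMLVQ core: metric distances, cost, gradients, training behavior."""

import numpy as np
import pandas as pd
import pytest

from tautraj.gmlvq import (GMLVQ, GMLVQResults, glvq_cost,
                           glvq_cost_gradients, metric_distance)

STABLE, DECLINING = "ClinicallyStable", "ClinicallyDeclining"


def _random_psd(rng, d):
    omega = rng.standard_normal((d, d))
    lam = omega.T @ omega
    return lam / np.trace(lam), omega


class TestMetricDistance:
    def test_zero_at_prototype(self, rng):
        x = rng.standard_normal(4)
        lam, _ = _random_psd(rng, 4)
        assert metric_distance(x, x, lam) == 0.0

    def test_scaled_euclidean_special_case(self):
        assert metric_distance([3.0, 0, 0], [0.0, 0, 0], np.eye(3) / 3) \
            == pytest.approx(3.0)

    def test_matches_omega_factorization(self, rng):
        # oracle: d = ||Omega (x - w)||^2 for Lambda = Omega' Omega
        for _ in range(10):
            d = rng.integers(2, 6)
            omega = rng.standard_normal((d, d))
            x, w = rng.standard_normal(d), rng.standard_normal(d)
            expect = float(np.sum((omega @ (x - w)) ** 2))
            assert metric_distance(x, w, omega.T @ omega) \
                == pytest.approx(expect, rel=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            metric_distance([1.0, 2.0], [1.0, 2.0, 3.0], np.eye(3))


class TestCost:
    def test_sample_on_own_prototype_gives_mu_minus_one(self):
        Z = np.array([[0.0, 0.0]])
        protos = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert glvq_cost(Z, [0], protos, np.eye(2)) == pytest.approx(-1.0)

    def test_equidistant_sample_gives_zero(self):
        Z = np.array([[0.5, 0.7]])
        protos = np.array([[0.0, 0.7], [1.0, 0.7]])
        assert glvq_cost(Z, [0], protos, np.eye(2)) == pytest.approx(0.0)

    def test_four_point_toy_matches_hand_computation(self):
        protos = np.array([[0.0, 0.0], [2.0, 0.0]])
        Z = np.array([[0.5, 0.0], [-0.5, 0.5], [1.5, 0.0], [2.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        omega = np.eye(2)
        # hand: mu = (dJ - dK)/(dJ + dK) with squared Euclidean distances
        total = 0.0
        for zi, yi in zip(Z, y):
            dj = float(np.sum((zi - protos[yi]) ** 2))
            dk = float(np.sum((zi - protos[1 - yi]) ** 2))
            total += (dj - dk) / (dj + dk)
        assert glvq_cost(Z, y, protos, omega) == pytest.approx(total, rel=1e-12)

    def test_degenerate_coincident_everything_is_zero(self):
        Z = np.zeros((1, 2))
        protos = np.zeros((2, 2))
        assert glvq_cost(Z, [0], protos, np.eye(2)) == 0.0


class TestGradients:
    @pytest.mark.parametrize("link", ["identity", "sigmoid"])
    def test_match_central_finite_differences(self, link, rng):
        """Analytic gradients agree with numerical differentiation."""
        eps = 1e-6
        for _ in range(20):
            n, d = int(rng.integers(3, 8)), int(rng.integers(2, 5))
            Z = rng.standard_normal((n, d))
            y = rng.integers(0, 2, n)
            protos = rng.standard_normal((2, d))
            omega = rng.standard_normal((d, d))
            gw, go = glvq_cost_gradients(Z, y, protos, omega, link)

            def cost(p, o):
                return glvq_cost(Z, y, p, o, link)

            for k in range(2):
                for j in range(d):
                    pp, pm = protos.copy(), protos.copy()
                    pp[k, j] += eps
                    pm[k, j] -= eps
                    num = (cost(pp, omega) - cost(pm, omega)) / (2 * eps)
                    assert gw[k, j] == pytest.approx(
                        num, rel=1e-5, abs=1e-7), (k, j)
            for i in range(d):
                for j in range(d):
                    op, om = omega.copy(), omega.copy()
                    op[i, j] += eps
                    om[i, j] -= eps
                    num = (cost(protos, op) - cost(protos, om)) / (2 * eps)
                    assert go[i, j] == pytest.approx(num, rel=1e-5, abs=1e-7)


def _toy_frame(X, y):
    return pd.DataFrame({"amyloid_centiloid": X[:, 0], "mtl_gm_density": X[:, 1],
                         "apoe4": X[:, 2] if X.shape[1] > 2 else 0.0,
                         "class_label": y})


class TestTraining:
    def test_separable_point_masses(self, rng):
        """Two tight clusters: perfect accuracy, prototypes at the clusters."""
        X = np.vstack([rng.normal([0, 0], 1e-4, (20, 2)),
                       rng.normal([3, 1], 1e-4, (20, 2))])
        y = np.array([STABLE] * 20 + [DECLINING] * 20)
        res = GMLVQ(X, y).fit()
        assert (res.classify(X) == y).all()
        Z = (X - res.scaler_mean) / res.scaler_sd
        for k in (0, 1):
            centre = Z[y == res.class_names[k]].mean(axis=0)
            assert np.linalg.norm(res.prototypes[k] - centre) < 1e-3

    def test_relevance_learning_concentrates_on_informative_feature(self, rng):
        # only feature 0 separates; its diagonal relevance should dominate
        X = np.column_stack([
            np.concatenate([rng.normal(0, .3, 100), rng.normal(3, .3, 100)]),
            rng.standard_normal(200)])
        y = np.array([STABLE] * 100 + [DECLINING] * 100)
        res = GMLVQ(X, y).fit()
        assert res.lambda_[0, 0] > 0.8 * np.trace(res.lambda_)

    def test_permutation_null_training_accuracy_near_chance(self):
        """Shuffled labels: balanced training accuracy hovers at 0.5."""
        accs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = r.standard_normal((500, 3))
            y = np.array([STABLE, DECLINING] * 250)
            r.shuffle(y)
            res = GMLVQ(X, y).fit(epochs=100, seed=seed)
            pred = res.classify(X)
            tpr = np.mean(pred[y == DECLINING] == DECLINING)
            tnr = np.mean(pred[y == STABLE] == STABLE)
            accs.append((tpr + tnr) / 2)
        assert 0.4 < float(np.mean(accs)) < 0.6

    def test_cost_non_increasing_and_metric_valid(self, small_cohort):
        res = GMLVQ.from_dataframe(small_cohort.cohort_table).fit()
        lam = res.lambda_
        assert np.allclose(lam, lam.T)
        assert np.trace(lam) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.eigvalsh(lam).min() >= -1e-10
        assert res.meta["converged"]

    def test_classification_boundary_matches_bruteforce_bisector(self, rng):
        X = np.vstack([rng.normal([0, 0], .5, (30, 2)),
                       rng.normal([2, 2], .5, (30, 2))])
        y = np.array([STABLE] * 30 + [DECLINING] * 30)
        res = GMLVQ(X, y).fit()
        grid = np.array(np.meshgrid(np.linspace(-2, 4, 25),
                                    np.linspace(-2, 4, 25))).reshape(2, -1).T
        pred = res.classify(grid)
        Z = (grid - res.scaler_mean) / res.scaler_sd
        expected = []
        for z in Z:
            d = [float((z - w) @ res.lambda_ @ (z - w)) for w in res.prototypes]
            expected.append(res.class_names[int(np.argmin(d))])
        assert (pred == np.array(expected)).all()

    def test_scale_equivariance_of_classifications(self, rng):
        X = np.vstack([rng.normal([0, 0, 0], 1, (40, 3)),
                       rng.normal([2, 1, 1], 1, (40, 3))])
        y = np.array([STABLE] * 40 + [DECLINING] * 40)
        base = GMLVQ(X, y).fit().classify(X)
        Xs = X.copy()
        Xs[:, 1] *= 1000.0
        scaled = GMLVQ(Xs, y).fit().classify(Xs)
        assert (base == scaled).all()

    def test_seeded_determinism(self, small_cohort):
        r1 = GMLVQ.from_dataframe(small_cohort.cohort_table).fit(seed=5)
        r2 = GMLVQ.from_dataframe(small_cohort.cohort_table).fit(seed=5)
        assert np.array_equal(r1.prototypes, r2.prototypes)
        assert np.array_equal(r1.omega, r2.omega)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            GMLVQ(X, np.array([STABLE] * 10))

    def test_prototypes_classify_to_own_class(self, trained_model):
        m = trained_model
        assert m.classify(m.prototype_raw(STABLE))[0] == STABLE
        assert m.classify(m.prototype_raw(DECLINING))[0] == DECLINING


class TestPersistence:
    def test_save_load_round_trip(self, trained_model, tmp_path, rng):
        path = tmp_path / "model.yaml"
        trained_model.save(path)
        back = GMLVQResults.load(path)
        X = rng.normal([30, 0.5, 0.5], [30, 0.1, 0.5], size=(20, 3))
        assert np.allclose(back.scalar_projection(X),
                           trained_model.scalar_projection(X), atol=1e-9)
        assert (back.classify(X) == trained_model.classify(X)).all()

    def test_summary_mentions_classes_and_features(self, trained_model):
        text = trained_model.summary()
        assert "ClinicallyStable" in text and "amyloid_centiloid" in text
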