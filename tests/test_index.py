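"""Scalar-projection index, threshold fitting, stratification and CV."""

import numpy as np
import pandas as pd
import pytest

from tautraj import index as idx
from tautraj.gmlvq import GMLVQResults
from tautraj.tables import CLASS_ACS, CLASS_DECLINING, CLASS_STABLE


class TestMetricSpaceTransform:
    def test_identity_metric_leaves_input(self, rng):
        x = rng.standard_normal((5, 3))
        assert np.allclose(idx.transform_to_metric_space(x, np.eye(3)), x)

    def test_diagonal_square_root(self):
        out = idx.transform_to_metric_space(np.array([1.0, 1.0]),
                                            np.diag([4.0, 1.0]))
        assert np.allclose(out, [2.0, 1.0])

    def test_quadratic_form_consistency(self, rng):
        for _ in range(10):
            d = int(rng.integers(2, 6))
            omega = rng.standard_normal((d, d))
            lam = omega.T @ omega
            x = rng.standard_normal(d)
            y = idx.transform_to_metric_space(x, lam)
            assert float(y @ y) == pytest.approx(float(x @ lam @ x), abs=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            idx.sqrt_psd(np.array([[1.0, 0.5], [0.0, 1.0]]))


def _manual_results():
    """Hand-built fitted model with invertible metric for geometry tests."""
    lam = np.diag([0.5, 0.3, 0.2])
    protos = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, -1.0]])
    return GMLVQResults((CLASS_STABLE, CLASS_DECLINING),
                        ["f1", "f2", "f3"], protos, idx.sqrt_psd(lam), lam,
                        np.zeros(3), np.ones(3), {"epochs_run": 0,
                        "final_cost": 0.0, "converged": True})


class TestScalarProjection:
    def test_anchors_at_prototypes(self, trained_model):
        m = trained_model
        assert m.scalar_projection(m.prototype_raw(CLASS_STABLE)) \
            == pytest.approx(0.0, abs=1e-12)
        assert m.scalar_projection(m.prototype_raw(CLASS_DECLINING)) \
            == pytest.approx(1.0, abs=1e-12)

    def test_linear_along_prototype_axis(self):
        res = _manual_results()
        w_s, w_d = res.prototypes
        for t in (-0.5, 0.0, 0.25, 0.5, 1.0, 2.0):
            x = w_s + t * (w_d - w_s)  # scaler is identity here
            assert res.scalar_projection(x) == pytest.approx(t, abs=1e-10)

    def test_orthogonal_components_do_not_move_the_index(self, rng):
        res = _manual_results()
        root = idx.sqrt_psd(res.lambda_)
        inv_root = np.linalg.inv(root)
        axis = root @ (res.prototypes[1] - res.prototypes[0])
        for _ in range(5):
            v = rng.standard_normal(3)
            v_perp = v - (v @ axis) / (axis @ axis) * axis  # metric-space
            x = res.prototypes[0] + 0.3 * (res.prototypes[1] - res.prototypes[0])
            s0 = res.scalar_projection(x)
            s1 = res.scalar_projection(x + inv_root @ v_perp)
            assert abs(s1 - s0) < 1e-10

    def test_coincident_prototypes_invalid(self):
        res = _manual_results()
        res.prototypes = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            res.scalar_projection(np.ones(3))


class TestThreshold:
    def _scores(self, rng, n=200, sds=(0.1, 0.1, 0.1)):
        s = np.concatenate([rng.normal(0, sds[0], n), rng.normal(1, sds[1], n),
                            rng.normal(2, sds[2], n)])
        labels = np.array([CLASS_STABLE] * n + [CLASS_DECLINING] * n
                          + [CLASS_ACS] * n)
        return s, labels

    def test_threshold_lands_between_stable_and_declining(self, rng):
        # tight classes may be completely separated; either way the
        # boundary must fall between the Stable and Declining centres
        import warnings as _w
        s, labels = self._scores(rng)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            model = idx.fit_threshold(s, labels)
        assert 0.3 < model.threshold_s < 0.7

    def test_defining_property_probability_half(self, rng):
        s, labels = self._scores(rng, sds=(0.25, 0.25, 0.25))
        model = idx.fit_threshold(s, labels)
        assert model.stable_probability(model.threshold_s) \
            == pytest.approx(0.5, abs=1e-6)

    def test_stable_probability_decreasing(self, rng):
        s, labels = self._scores(rng, sds=(0.3, 0.3, 0.3))
        model = idx.fit_threshold(s, labels)
        grid = np.linspace(s.min(), s.max(), 50)
        p = model.stable_probability(grid)
        assert np.all(np.diff(p) < 0)

    def test_complete_separation_flagged_with_gap_midpoint(self, rng):
        s = np.concatenate([rng.uniform(-1, 0.0, 50), rng.uniform(0.6, 1.5, 50),
                            rng.uniform(1.6, 2.5, 50)])
        labels = np.array([CLASS_STABLE] * 50 + [CLASS_DECLINING] * 50
                          + [CLASS_ACS] * 50)
        with pytest.warns(UserWarning, match="separation"):
            model = idx.fit_threshold(s, labels)
        assert model.separated
        assert s[:50].max() < model.threshold_s < s[50:].min()

    def test_missing_class_rejected(self, rng):
        s = rng.standard_normal(20)
        labels = np.array([CLASS_STABLE] * 10 + [CLASS_DECLINING] * 10)
        with pytest.raises(ValueError, match="ACS"):
            idx.fit_threshold(s, labels)


class TestStratify:
    def test_boundary_is_strictly_greater(self):
        out = idx.stratify(np.array([0.34, 0.34 + 1e-9, 0.1]), 0.34)
        assert list(out) == [CLASS_STABLE, CLASS_DECLINING, CLASS_STABLE]

    def test_all_zero_scores_are_stable(self):
        assert (idx.stratify(np.zeros(5), 0.34) == CLASS_STABLE).all()

    def test_agreement_with_generating_class(self, small_cohort, trained_model):
        table = small_cohort.cohort_table
        two = table[table.class_label != CLASS_ACS]
        s = trained_model.scalar_projection(
            two[["amyloid_centiloid", "mtl_gm_density", "apoe4"]].to_numpy())
        assigned = idx.stratify(s, 0.5)
        assert np.mean(assigned == two.class_label.to_numpy()) >= 0.9


class TestBalancedResamplingCV:
    def test_balanced_accuracy_arithmetic(self):
        # one resample with confusion counts TP=87 FN=13 TN=91 FP=9
        res = idx.CVResult(np.array([87 / 100]), np.array([91 / 100]), 1)
        assert res.balanced_accuracy == pytest.approx(0.89)

    def test_separable_classes_score_perfectly(self, rng):
        n = 30
        df = pd.DataFrame({
            "amyloid_centiloid": np.r_[rng.normal(0, 1e-3, n),
                                       rng.normal(100, 1e-3, n)],
            "mtl_gm_density": np.r_[rng.normal(1, 1e-3, n),
                                    rng.normal(0, 1e-3, n)],
            "apoe4": np.r_[np.zeros(n), np.ones(n)],
            "class_label": [CLASS_STABLE] * n + [CLASS_DECLINING] * n})
        res = idx.balanced_resampling_cv(df, n_resamples=20, seed=1, epochs=100)
        assert res.balanced_accuracy == pytest.approx(1.0)

    def test_permutation_null_near_half(self, rng):
        n = 30
        df = pd.DataFrame({
            "amyloid_centiloid": rng.standard_normal(2 * n),
            "mtl_gm_density": rng.standard_normal(2 * n),
            "apoe4": rng.integers(0, 2, 2 * n).astype(float),
            "class_label": rng.permutation([CLASS_STABLE] * n
                                           + [CLASS_DECLINING] * n)})
        res = idx.balanced_resampling_cv(df, n_resamples=400, seed=7, epochs=60)
        assert 0.45 < res.balanced_accuracy < 0.55

    def test_tiny_minority_rejected(self, rng):
        df = pd.DataFrame({
            "amyloid_centiloid": rng.standard_normal(13),
            "mtl_gm_density": rng.standard_normal(13),
            "apoe4": 0.0,
            "class_label": [CLASS_STABLE] * 3 + [CLASS_DECLINING] * 10})
        with pytest.raises(ValueError, match="minority"):
            idx.balanced_resampling_cv(df, n_resamples=5, seed=0)
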