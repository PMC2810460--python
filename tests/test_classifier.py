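"""Gaussian Bayes decision function, parameter estimation, training sets."""

import numpy as np
import pytest

from mcdetect.classifier import (
    ClassParams,
    DegenerateFeatureError,
    GaussianBayesClassifier,
    classify,
    decision_value,
    decision_values,
    estimate_params,
    mean_difference_diagnostic,
    select_training_samples,
)
from mcdetect.features import FeatureStack, stack_features
from mcdetect.imagery import GrayImage
from mcdetect.synthesis import ClusterSpec, MCModel, blend, make_std_model


def random_spd(rng, d=4):
    a = rng.normal(size=(d, d))
    return a @ a.T + d * np.eye(d)


def params_from(mean, cov, n=100):
    sign, log_det = np.linalg.slogdet(cov)
    return ClassParams(mean=np.asarray(mean, float), cov=np.asarray(cov, float),
                       log_det=float(log_det), inv_cov=np.linalg.inv(cov), n_samples=n)


class TestDecisionValue:
    def test_at_mean_with_identity_cov(self):
        p = params_from(np.zeros(4), np.eye(4))
        assert decision_value(np.zeros(4), p) == pytest.approx(0.0)

    def test_unit_cov_offset(self):
        p = params_from(np.zeros(4), np.eye(4))
        x = np.array([2.0, 0.0, 0.0, 0.0])
        assert decision_value(x, p) == pytest.approx(-2.0)

    def test_oracle_equivalence_on_random_spd(self):
        """Score matches -0.5 ln|C| - 0.5 (x-m)' C^-1 (x-m) via linear solve."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            cov = random_spd(rng)
            mean = rng.normal(size=4)
            x = rng.normal(size=4)
            p = params_from(mean, cov)
            expected = -0.5 * np.linalg.slogdet(cov)[1] - 0.5 * (
                (x - mean) @ np.linalg.solve(cov, x - mean)
            )
            assert decision_value(x, p) == pytest.approx(expected, abs=1e-9)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(8)
        cov = random_spd(rng)
        p = params_from(rng.normal(size=4), cov)
        X = rng.normal(size=(50, 4))
        np.testing.assert_allclose(
            decision_values(X, p), [decision_value(x, p) for x in X], atol=1e-12
        )

    def test_nonfinite_input_rejected(self):
        p = params_from(np.zeros(4), np.eye(4))
        with pytest.raises(ValueError):
            decision_value(np.array([np.inf, 0, 0, 0]), p)


class TestEstimateParams:
    def test_identical_samples_degenerate(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        with pytest.raises((DegenerateFeatureError, ValueError)):
            ClassParams.from_samples(X)

    def test_constant_channel_named(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 4))
        X[:, 2] = 5.0  # wavelet channel constant
        with pytest.raises(DegenerateFeatureError, match="wavelet"):
            ClassParams.from_samples(X)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ClassParams.from_samples(np.zeros((3, 4)))

    def test_monte_carlo_recovery(self):
        """n=1e5 draws from a known 4-D Gaussian: mean within 3 sigma/sqrt(n),
        covariance within 5% Frobenius."""
        rng = np.random.default_rng(12345)
        true_mean = np.array([10.0, -3.0, 0.5, 100.0])
        a = rng.normal(size=(4, 4))
        true_cov = a @ a.T + 2 * np.eye(4)
        n = 100_000
        X = rng.multivariate_normal(true_mean, true_cov, size=n)
        p = ClassParams.from_samples(X)
        tol = 3.0 * np.sqrt(np.diag(true_cov)) / np.sqrt(n)
        assert np.all(np.abs(p.mean - true_mean) <= tol)
        rel = np.linalg.norm(p.cov - true_cov) / np.linalg.norm(true_cov)
        assert rel < 0.05

    def test_roi_covariance_is_near_diagonal_for_independent_channels(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5000, 4)) * np.array([1.0, 2.0, 3.0, 4.0])
        p = ClassParams.from_samples(X)
        np.testing.assert_allclose(np.diag(p.cov), [1, 4, 9, 16], rtol=0.15)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(11)
        p = ClassParams.from_samples(rng.normal(size=(100, 4)))
        q = ClassParams.from_dict(p.to_dict())
        np.testing.assert_allclose(q.mean, p.mean)
        np.testing.assert_allclose(q.cov, p.cov)
        assert q.log_det == pytest.approx(p.log_det)


class TestClassify:
    @staticmethod
    def _stack_from_matrix(X, shape):
        return FeatureStack(X.reshape(*shape, 4))

    def test_identical_params_all_healthy(self):
        rng = np.random.default_rng(12)
        p = ClassParams.from_samples(rng.normal(size=(100, 4)))
        stack = self._stack_from_matrix(rng.normal(size=(8, 8, 4)), (8, 8))
        mask = classify(stack, p, p)
        assert mask.labels.sum() == 0  # exact ties go to healthy

    def test_pixel_at_mc_mean_labeled_one(self):
        mc = params_from(np.array([10.0, 10, 10, 10]), np.eye(4))
        bg = params_from(np.zeros(4), np.eye(4))
        stack = self._stack_from_matrix(np.tile([10.0, 10, 10, 10], (1, 1, 1)), (1, 1))
        assert classify(stack, mc, bg).labels[0, 0] == 1

    def test_well_separated_classes_low_error(self):
        """Mean gap 10 sigma with identity covariances: the Bayes error is
        Phi(-5) ~ 3e-7, so the empirical error over 2e4 draws is < 1%."""
        rng = np.random.default_rng(13)
        m1 = np.zeros(4)
        m2 = np.full(4, 10.0 / np.sqrt(4))  # ||m2 - m1|| = 10
        n = 10_000
        X = np.vstack([rng.normal(size=(n, 4)) + m1, rng.normal(size=(n, 4)) + m2])
        y = np.repeat([0, 1], n)
        bg = ClassParams.from_samples(X[:n])
        mc = ClassParams.from_samples(X[n:])
        stack = self._stack_from_matrix(X.reshape(2 * n, 1, 4), (2 * n, 1))
        pred = classify(stack, mc, bg).labels.ravel()
        assert (pred != y).mean() < 0.01

    def test_affine_invariance_per_channel(self):
        """Scaling/shifting each channel identically in training and test
        leaves the decision unchanged (Mahalanobis affine invariance)."""
        rng = np.random.default_rng(14)
        Xmc = rng.normal(size=(300, 4)) + 2.0
        Xbg = rng.normal(size=(300, 4))
        T = rng.normal(size=(64, 4))
        scale = np.array([2.0, 0.5, 10.0, 100.0])
        shift = np.array([-5.0, 3.0, 0.0, 42.0])
        base = classify(
            FeatureStack(T.reshape(8, 8, 4)),
            ClassParams.from_samples(Xmc),
            ClassParams.from_samples(Xbg),
        )
        mapped = classify(
            FeatureStack((T * scale + shift).reshape(8, 8, 4)),
            ClassParams.from_samples(Xmc * scale + shift),
            ClassParams.from_samples(Xbg * scale + shift),
        )
        np.testing.assert_array_equal(base.labels, mapped.labels)

    def test_agrees_with_sklearn_qda(self):
        """Independent route: sklearn's QDA with equal priors implements the
        same Gaussian log-posterior rule (up to tie handling)."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(15)
        L = np.linalg.cholesky(random_spd(rng))
        Xmc = rng.normal(size=(500, 4)) @ L.T + 1.5
        Xbg = rng.normal(size=(500, 4))
        X = np.vstack([Xbg, Xmc])
        y = np.repeat([0, 1], 500)
        qda = QuadraticDiscriminantAnalysis(priors=[0.5, 0.5], store_covariance=True)
        qda.fit(X, y)
        T = rng.normal(size=(2000, 4)) + 0.75
        ours = classify(
            FeatureStack(T.reshape(50, 40, 4)),
            ClassParams.from_samples(Xmc),
            ClassParams.from_samples(Xbg),
        ).labels.ravel()
        theirs = qda.predict(T)
        assert (ours == theirs).mean() > 0.999


class TestGaussianBayesEstimator:
    def test_fit_predict_sklearn_interface(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(size=(200, 4)), rng.normal(size=(200, 4)) + 4.0])
        y = np.repeat([0, 1], 200)
        clf = GaussianBayesClassifier().fit(X, y)
        assert set(clf.classes_) == {0, 1}
        acc = (clf.predict(X) == y).mean()
        assert acc > 0.95
        assert clf.get_params() == {}

    def test_decision_function_sign_convention(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(size=(100, 4)), rng.normal(size=(100, 4)) + 6.0])
        y = np.repeat([0, 1], 100)
        clf = GaussianBayesClassifier().fit(X, y)
        assert np.all(clf.decision_function(X[y == 1]) > 0)


class TestSelectTrainingSamples:
    def _mask(self, shape=(512, 512), n=86, seed=0):
        rng = np.random.default_rng(seed)
        mask = np.zeros(shape, np.uint8)
        idx = rng.choice(shape[0] * shape[1], size=n, replace=False)
        mask.ravel()[idx] = 1
        return mask

    def test_background_to_lesion_ratio_about_fifty(self):
        mask = self._mask(n=86)
        ts = select_training_samples(mask, (512, 512), bg_total=4300, seed=1)
        ratio = len(ts.bg_coords) / len(ts.mc_coords)
        # two 47x47 ROIs give 4418 samples ~ 51x the 86 lesion pixels
        assert 45 <= ratio <= 55
        assert len(ts.bg_coords) == 2 * 47 * 47

    def test_deterministic_roi_boxes(self):
        mask = self._mask()
        a = select_training_samples(mask, (512, 512), seed=3)
        b = select_training_samples(mask, (512, 512), seed=3)
        assert a.bg_roi_boxes == b.bg_roi_boxes

    def test_ratio_violation_raises(self):
        mask = self._mask(n=86)
        with pytest.raises(ValueError):
            select_training_samples(mask, (512, 512), bg_total=100, seed=0)

    def test_rois_avoid_model_and_exclusions(self):
        mask = np.zeros((256, 256), np.uint8)
        mask[100:110, 100:110] = 1
        ts = select_training_samples(
            mask, (256, 256), bg_total=800, seed=5,
            exclusion=[(200, 200, 30.0)],
        )
        bg = set(map(tuple, ts.bg_coords))
        mc = set(map(tuple, ts.mc_coords))
        assert not bg & mc
        for r, c in ts.bg_coords:
            assert (r - 200) ** 2 + (c - 200) ** 2 > 30**2

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            select_training_samples(np.zeros((64, 64), np.uint8), (64, 64), seed=0)


class TestMeanDifferenceDiagnostic:
    def test_identical_distributions_zero(self):
        rng = np.random.default_rng(18)
        p = ClassParams.from_samples(rng.normal(size=(100, 4)))
        img = GrayImage(np.full((32, 32), 100.0))
        masks = np.ones((32, 32), bool)
        d = mean_difference_diagnostic(p, p, img, masks, masks)
        np.testing.assert_allclose(d.mean_difference, 0.0)
        np.testing.assert_allclose(d.variance_ratio, 1.0)
        assert d.nmd == pytest.approx(0.0)

    def test_nmd_formula(self):
        img = GrayImage(np.full((10, 10), 188.0))
        model = np.zeros((10, 10), bool)
        model[0, 0] = True
        img.pixels[0, 0] = 200.75
        breast = ~model
        rng = np.random.default_rng(19)
        p = ClassParams.from_samples(rng.normal(size=(100, 4)))
        d = mean_difference_diagnostic(p, p, img, breast, model)
        assert d.nmd == pytest.approx((200.75 - 188.0) / 255.0)

    def test_graylevel_gap_grows_with_k(self):
        """Blending with larger K raises the lesion-class graylevel mean."""
        rng = np.random.default_rng(20)
        img = GrayImage(np.clip(rng.normal(120, 10, (128, 128)), 0, 255))
        mask = make_std_model(
            (128, 128), [ClusterSpec(center=(64, 64), n_mcs=5, cluster_radius_px=15.0)],
            seed=21,
        )
        gaps = []
        for k in (0.2, 0.5, 1.0):
            hybrid = blend(img, MCModel(std_model=mask, K=k))
            feats = stack_features(hybrid.pixels)
            ts = select_training_samples(mask, (128, 128), bg_total=900, seed=22)
            mc = estimate_params(feats, ts.mc_coords)
            bg = estimate_params(feats, ts.bg_coords)
            gaps.append(mc.mean[0] - bg.mean[0])
        assert gaps[0] < gaps[1] < gaps[2]
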