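import numpy as np
import pytest

from conftest import random_dna
from wdsvr import svr_engine as se
from wdsvr import wdkernel as wk
from wdsvr.wdkernel import KernelConfig


def _model_on(seqs, y, cfg, C=5.0, epsilon=0.01):
    K = wk.kernel_matrix(seqs, cfg)
    model = se.fit(K, y, C=C, epsilon=epsilon)
    model.kernel_config = cfg
    model.training_sequences = list(seqs)
    return model


class TestFit:
    def test_single_point_within_tube(self):
        model = se.fit(np.array([[1.0]]), [5.0], C=10.0, epsilon=0.1)
        pred = se.predict(model, np.array([[1.0]]))
        assert abs(pred[0] - 5.0) <= 0.1 + 1e-9

    def test_zero_noise_linear_target_is_interpolated(self, rng):
        # y constructed from a known weight vector over positional k-mer
        # indicators lies in the WD kernel's function space
        seqs = [random_dna(rng, 10) for _ in range(30)]
        cfg = KernelConfig(d=2, s=0, m=0, normalize=False)
        nprng = np.random.default_rng(5)
        arrays = {
            1: nprng.normal(size=(4, 10)) * 0.5,
            2: nprng.normal(size=(16, 9)) * 0.5,
        }
        truth = se.LinearWeights(arrays, 1.0, 10, cfg)
        y = truth.evaluate(seqs)
        model = _model_on(seqs, y, cfg, C=1e4, epsilon=0.01)
        resid = model.fitted_values - y
        assert np.sqrt(np.mean(resid**2)) <= 0.05

    def test_identical_sequences_get_identical_fits(self, rng):
        s = random_dna(rng, 8)
        seqs = [s, s] + [random_dna(rng, 8) for _ in range(6)]
        cfg = KernelConfig(d=3, normalize=False)
        y = np.random.default_rng(0).normal(size=8)
        model = _model_on(seqs, y, cfg)
        assert model.fitted_values[0] == pytest.approx(model.fitted_values[1], abs=1e-9)

    def test_asymmetric_kernel_rejected(self):
        K = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            se.fit(K, [1.0, 2.0])

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError, match="square"):
            se.fit(np.ones((2, 3)), [1.0, 2.0])

    def test_dual_coefficients_sum_to_zero(self, rng):
        seqs = [random_dna(rng, 10) for _ in range(25)]
        y = np.random.default_rng(1).normal(size=25)
        model = _model_on(seqs, y, KernelConfig(d=4, s=1, m=1, normalize=True), C=2.0)
        assert abs(model.dual_coef.sum()) < 1e-6
        assert np.all(np.abs(model.dual_coef) <= model.C + 1e-9)

    def test_vanishing_C_gives_constant_predictions(self, rng):
        seqs = [random_dna(rng, 10) for _ in range(15)]
        y = np.random.default_rng(2).normal(3.0, 1.0, size=15)
        model = _model_on(seqs, y, KernelConfig(d=3, normalize=True), C=1e-8, epsilon=0.01)
        assert np.abs(model.dual_coef).max() <= 1e-8 + 1e-15
        assert np.ptp(model.fitted_values) < 1e-6


class TestPredict:
    def test_training_row_reproduces_fitted_value(self, rng):
        seqs = [random_dna(rng, 10) for _ in range(12)]
        cfg = KernelConfig(d=3, normalize=False)
        K = wk.kernel_matrix(seqs, cfg)
        y = np.random.default_rng(3).normal(size=12)
        model = se.fit(K, y, C=2.0, epsilon=0.05)
        np.testing.assert_allclose(se.predict(model, K[4:5]), model.fitted_values[4])

    def test_zero_row_predicts_intercept(self):
        model = se.fit(np.eye(3), [1.0, 2.0, 3.0], C=1.0, epsilon=0.01)
        assert se.predict(model, np.zeros((1, 3)))[0] == pytest.approx(model.intercept)

    def test_dimension_mismatch(self):
        model = se.fit(np.eye(3), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="columns"):
            se.predict(model, np.ones((1, 4)))

    def test_matches_termwise_dual_expansion(self, rng):
        seqs = [random_dna(rng, 10) for _ in range(15)]
        cfg = KernelConfig(d=3, s=1, m=1, normalize=False)
        model = _model_on(seqs, np.random.default_rng(4).normal(size=15), cfg)
        tests = [random_dna(rng, 10) for _ in range(10)]
        # independent summation: explicit sum over support vectors
        expected = [
            sum(
                c * wk.wds_kernel(sv, x, cfg)
                for c, sv in zip(model.dual_coef, seqs)
                if c != 0
            )
            + model.intercept
            for x in tests
        ]
        got = se.predict(model, wk.cross_kernel_matrix(tests, seqs, cfg))
        np.testing.assert_allclose(got, expected, atol=1e-9)


class TestLinearWeights:
    def test_zero_coefficients_give_intercept_everywhere(self, rng):
        seqs = [random_dna(rng, 8) for _ in range(5)]
        cfg = KernelConfig(d=2, normalize=False)
        model = se.SVRModel(
            dual_coef=np.zeros(5), intercept=2.5, C=1.0, epsilon=0.1,
            kernel_config=cfg, training_sequences=seqs,
        )
        lw = se.linear_weights(model)
        assert all(not W.any() for W in lw.arrays.values())
        np.testing.assert_allclose(lw.evaluate([random_dna(rng, 8)]), 2.5)

    def test_single_support_vector_d1_closed_form(self):
        cfg = KernelConfig(d=1, beta_scheme="uniform", normalize=False)
        model = se.SVRModel(
            dual_coef=np.array([3.0]), intercept=0.0, C=10.0, epsilon=0.1,
            kernel_config=cfg, training_sequences=["ACGT"],
        )
        lw = se.linear_weights(model)
        # the mu term counts both directions at s'=0, omega_0 = 1/2 cancels it
        assert lw.weight(1, "A", 1) == pytest.approx(3.0)
        assert lw.weight(1, "C", 2) == pytest.approx(3.0)
        assert lw.weight(1, "A", 2) == 0.0

    @pytest.mark.parametrize("d,s,m", [(2, 0, 0), (3, 0, 0), (3, 1, 1), (2, 2, 2)])
    def test_round_trip_exactness_raw_kernels(self, rng, d, s, m):
        seqs = [random_dna(rng, 12) for _ in range(20)]
        cfg = KernelConfig(d=d, s=s, m=m, normalize=False)
        model = _model_on(seqs, np.random.default_rng(6).normal(size=20), cfg)
        lw = se.linear_weights(model)
        tests = [random_dna(rng, 12) for _ in range(20)]
        pred_kernel = se.predict(model, wk.cross_kernel_matrix(tests, seqs, cfg))
        pred_features = lw.evaluate(tests)
        np.testing.assert_allclose(pred_features, pred_kernel, atol=1e-10)

    def test_restricted_model_round_trip(self, rng):
        seqs = [random_dna(rng, 10) for _ in range(20)]
        sel = frozenset(
            wk.SelectedAnchor(k, random_dna(rng, k), rng.randint(1, 10 - k + 1))
            for k in (1, 2) for _ in range(5)
        )
        cfg = KernelConfig(d=2, s=1, normalize=False, restriction=sel)
        model = _model_on(seqs, np.random.default_rng(7).normal(size=20), cfg, C=2.0)
        lw = se.linear_weights(model)
        tests = [random_dna(rng, 10) for _ in range(10)]
        np.testing.assert_allclose(
            lw.evaluate(tests),
            se.predict(model, wk.cross_kernel_matrix(tests, seqs, cfg)),
            atol=1e-10,
        )

    def test_normalized_model_refused_without_flag(self, rng):
        seqs = [random_dna(rng, 8) for _ in range(10)]
        cfg = KernelConfig(d=2, normalize=True)
        model = _model_on(seqs, np.random.default_rng(8).normal(size=10), cfg)
        with pytest.raises(ValueError, match="approximate"):
            se.linear_weights(model)
        se.linear_weights(model, approximate=True)  # accepted with the flag


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        seqs = [random_dna(rng, 10) for _ in range(12)]
        cfg = KernelConfig(d=3, s=1, normalize=True)
        model = _model_on(seqs, np.random.default_rng(9).normal(size=12), cfg)
        p = tmp_path / "model.json"
        model.save(p)
        model2 = se.SVRModel.load(p)
        tests = [random_dna(rng, 10) for _ in range(5)]
        Kc = wk.cross_kernel_matrix(tests, seqs, cfg)
        np.testing.assert_array_equal(se.predict(model, Kc), se.predict(model2, Kc))
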