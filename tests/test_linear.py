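"""Linear lead transforms: OLS/SGD fitting, prediction, limb-lead identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import P2_INPUTS, P2_OUTPUTS, stack_leads
from ecgrecon import (
    PipelineConfig,
    SGDConfig,
    derive_limb_leads,
    fit_ols,
    fit_sgd,
    load_model,
    make_pipeline,
    predict,
    save_model,
)
from ecgrecon.linear import standardized_coefficients
from ecgrecon.masking import CHANNEL_NAMES


def toy_xy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 1))
    return X, 2.0 * X + 1.0


class TestFitOLS:
    def test_exact_linear_relation(self):
        X, Y = toy_xy()
        m = fit_ols(X, Y)
        assert abs(m.A[0, 0] - 2.0) < 1e-10
        assert abs(m.C[0] - 1.0) < 1e-10

    def test_recovers_generator_truth(self, global_cohort):
        A_true, C_true = global_cohort.mixing.truth_linear_map(P2_INPUTS, P2_OUTPUTS)
        m = fit_ols(stack_leads(global_cohort, P2_INPUTS), stack_leads(global_cohort, P2_OUTPUTS))
        assert np.max(np.abs(m.A - A_true)) < 1e-6
        assert np.max(np.abs(m.C - C_true)) < 1e-6

    def test_rank_deficiency_min_norm(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 1))
        X = np.hstack([x, x])  # duplicated column
        Y = 3.0 * x + 0.5
        with pytest.warns(UserWarning, match="rank-deficient"):
            m = fit_ols(X, Y)
        # minimum-norm pseudoinverse oracle splits the weight evenly
        coef_oracle = np.linalg.pinv(X - X.mean(0)) @ (Y - Y.mean(0))
        assert np.max(np.abs(m.A - coef_oracle.T)) < 1e-9
        with pytest.warns(UserWarning, match="rank-deficient"):
            m2 = fit_ols(X, Y)
        assert np.max(np.abs(predict(m, X) - predict(m2, X))) < 1e-9

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_ols(np.zeros((2, 3)), np.zeros((2, 1)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fit_ols(np.zeros((10, 2)), np.zeros((8, 1)))


class TestFitSGD:
    def test_toy_matches_ols(self):
        X, Y = toy_xy(2000)
        m = fit_sgd(X, Y)
        assert np.abs(m.A[0, 0] - 2.0) < 1e-2

    def test_deterministic_given_seed(self):
        X, Y = toy_xy(2000, seed=3)
        m1 = fit_sgd(X, Y, SGDConfig(seed=7))
        m2 = fit_sgd(X, Y, SGDConfig(seed=7))
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.C, m2.C)

    def test_equivalence_on_cohort(self, global_cohort):
        """SGD converges to the closed-form least-squares transform."""
        train = global_cohort.items[:16]
        test = global_cohort.items[16:]
        Xtr = np.vstack([it.record.subset(P2_INPUTS) for it in train])
        Ytr = np.vstack([it.record.subset(P2_OUTPUTS) for it in train])
        Xte = np.vstack([it.record.subset(P2_INPUTS) for it in test])
        Yte = np.vstack([it.record.subset(P2_OUTPUTS) for it in test])
        mo = fit_ols(Xtr, Ytr)
        ms = fit_sgd(Xtr, Ytr)
        s = ms.scaling
        ols_std = mo.A * s.x_scale[None, :] / s.y_scale[:, None]
        assert np.max(np.abs(standardized_coefficients(ms) - ols_std)) <= 1e-2
        rmse_o = np.sqrt(np.mean((predict(mo, Xte) - Yte) ** 2))
        rmse_s = np.sqrt(np.mean((predict(ms, Xte) - Yte) ** 2))
        assert abs(rmse_s - rmse_o) <= 1e-3

    def test_divergence_error(self):
        X, Y = toy_xy(500)
        with pytest.raises(FloatingPointError, match="epoch"):
            fit_sgd(X, Y, SGDConfig(learning_rate=1e6, momentum=0.99))

    def test_scaling_invariance(self, global_cohort):
        """Predictions are expressed in raw mV regardless of internal scaling."""
        X = stack_leads(global_cohort, P2_INPUTS)[:5000]
        Y = stack_leads(global_cohort, P2_OUTPUTS)[:5000]
        m = fit_sgd(X, Y, SGDConfig(seed=1))
        s = m.scaling
        W = standardized_coefficients(m)
        via_std = (
            ((X - s.x_mean) / s.x_scale) @ W.T
            + (m.C - s.y_mean + m.A @ s.x_mean) / s.y_scale
        ) * s.y_scale + s.y_mean
        assert np.max(np.abs(via_std - predict(m, X))) < 1e-9


class TestPredict:
    def test_identity_and_constant(self):
        from ecgrecon.linear import LinearLeadModel

        X = np.random.default_rng(0).normal(size=(50, 2))
        ident = LinearLeadModel(np.eye(2), np.zeros(2), ("a", "b"), ("u", "v"))
        np.testing.assert_array_equal(predict(ident, X), X)
        const = LinearLeadModel(np.zeros((2, 2)), np.array([1.5, -2.0]), ("a", "b"), ("u", "v"))
        assert np.all(predict(const, X) == np.array([1.5, -2.0]))

    def test_matches_direct_matrix_evaluation(self):
        X, Y = toy_xy(300, seed=5)
        m = fit_ols(X, Y)
        np.testing.assert_allclose(predict(m, X), X @ m.A.T + m.C, atol=1e-12)

    def test_channel_name_mismatch_rejected(self):
        X, Y = toy_xy()
        m = fit_ols(X, Y, input_names=("I",), output_names=("V1",))
        with pytest.raises(ValueError, match="reordering"):
            predict(m, X, input_names=("II",))
        with pytest.raises(ValueError):
            predict(m, np.zeros((10, 2)))


class TestLimbLeads:
    def test_zero_and_constant_inputs(self):
        zeros = np.zeros(10)
        out = derive_limb_leads(zeros, zeros)
        for lead in ("III", "aVR", "aVL", "aVF"):
            np.testing.assert_array_equal(out[lead], zeros)
        ones = np.ones(4)
        out = derive_limb_leads(ones, ones)
        np.testing.assert_array_equal(out["III"], np.zeros(4))
        np.testing.assert_array_equal(out["aVR"], -np.ones(4))
        np.testing.assert_array_equal(out["aVL"], 0.5 * np.ones(4))
        np.testing.assert_array_equal(out["aVF"], 0.5 * np.ones(4))

    @given(
        hnp.arrays(np.float64, (2, 32), elements=st.floats(-5, 5, allow_nan=False))
    )
    def test_einthoven_and_goldberger_identities(self, leads):
        i, ii = leads
        out = derive_limb_leads(i, ii)
        np.testing.assert_allclose(i + out["III"], ii, rtol=0, atol=1e-12)  # Einthoven
        assert np.max(np.abs(out["aVR"] + out["aVL"] + out["aVF"])) < 1e-12
        np.testing.assert_allclose(out["aVL"] - out["aVR"], 1.5 * i, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            derive_limb_leads(np.zeros(5), np.zeros(6))


class TestPipelines:
    def test_variant_channel_lists(self):
        p2 = make_pipeline(PipelineConfig(variant="p2"))
        assert p2.output_names == ("V1", "V2", "V4", "V5", "V6")
        assert p2.input_names == ("I", "II", "V3")
        p1 = make_pipeline(PipelineConfig(variant="p1"))
        assert p1.output_names == ("V1", "V3", "V4", "V5", "V6")
        assert p1.input_names == ("I", "II", "V2")
        wmlr = make_pipeline(PipelineConfig(variant="wmlr"))
        assert wmlr.input_names == CHANNEL_NAMES
        assert len(wmlr.input_names) == 6

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            PipelineConfig(variant="p9")

    def test_fit_predict_round(self, global_cohort):
        pipe = make_pipeline(PipelineConfig(variant="p2")).fit(global_cohort.items[:10])
        item = global_cohort.items[12]
        yhat = pipe.predict(item)
        y = item.record.subset(P2_OUTPUTS)
        assert np.max(np.abs(yhat - y)) < 1e-6  # exact linear cohort


class TestSerialization:
    def test_round_trip(self, tmp_path, global_cohort):
        X = stack_leads(global_cohort, P2_INPUTS)[:3000]
        Y = stack_leads(global_cohort, P2_OUTPUTS)[:3000]
        m = fit_sgd(X, Y, SGDConfig(seed=2))
        save_model(m, tmp_path / "model.json")
        back = load_model(tmp_path / "model.json")
        np.testing.assert_array_equal(back.A, m.A)
        np.testing.assert_array_equal(back.C, m.C)
        assert back.input_names == m.input_names
        np.testing.assert_array_equal(back.scaling.x_mean, m.scaling.x_mean)
        np.testing.assert_array_equal(predict(back, X), predict(m, X))
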