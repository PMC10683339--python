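"""OLS machinery, stage-wise fits, rules, and the two pseudo-outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtrlearn.qlearn_core import (
    RankDeficientError,
    contrast,
    fit_dtr,
    fit_stage1,
    fit_stage2,
    ols_fit,
    pseudo_outcome,
    rule_stage1_linear,
    rule_stage2,
)
from dtrlearn.simulation import PSI21, SimConfig, generate_trial, sim_spec1, sim_spec2
from dtrlearn.trial_data import ModelSpec, build_design

from conftest import make_trial


class TestOlsFit:
    def test_exact_interpolation_n_equals_p(self):
        coef, sd = ols_fit(np.array([[1.0, 0.0], [1.0, 1.0]]), np.array([2.0, 5.0]))
        np.testing.assert_allclose(coef, [2.0, 3.0])
        assert sd == 0.0

    def test_matches_normal_equations_oracle(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        y = np.array([0.0, 1.0, 2.0, 10.0])
        coef, sd = ols_fit(X, y)
        # independent oracle: explicit normal equations (X'X)^{-1} X'y
        expected = np.linalg.inv(X.T @ X) @ (X.T @ y)
        np.testing.assert_allclose(coef, expected, rtol=1e-12)
        rss = np.sum((y - X @ expected) ** 2)
        np.testing.assert_allclose(sd, np.sqrt(rss / 2), rtol=1e-12)

    def test_six_row_oracle(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(6), rng.normal(size=6), rng.normal(size=6)])
        y = rng.normal(size=6)
        coef, _ = ols_fit(X, y)
        np.testing.assert_allclose(coef, np.linalg.solve(X.T @ X, X.T @ y), rtol=1e-10)

    def test_duplicate_column_is_hard_error(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0)])
        with pytest.raises(RankDeficientError, match="collinear"):
            ols_fit(X, np.zeros(5), names=("const", "Z", "Zdup"))

    def test_more_columns_than_rows_is_hard_error(self):
        with pytest.raises(RankDeficientError):
            ols_fit(np.ones((2, 3)), np.zeros(2))


class TestStage2:
    def test_noiseless_recovery(self, noiseless_trial):
        spec = ModelSpec(stage=2, main_terms=("Z1",), effect_terms=("Z1",))
        fit = fit_stage2(noiseless_trial, spec)
        np.testing.assert_allclose(fit.beta0, [1.0, 2.0], atol=1e-10)
        np.testing.assert_allclose(fit.beta1, [3.0, -1.0], atol=1e-10)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-9)
        assert fit.n_fit == noiseless_trial.n

    def test_restricted_to_rerandomized(self):
        rng = np.random.default_rng(0)
        n = 30
        z1 = rng.normal(size=n)
        rr = np.arange(n) < 20
        y = 1 + z1 + rng.normal(size=n)
        data = make_trial(z1, 2 * rng.integers(0, 2, n) - 1, rng.normal(size=n), rr,
                          np.where(rr, 2 * rng.integers(0, 2, n) - 1, np.nan), y)
        spec = ModelSpec(stage=2, main_terms=("Z1",), effect_terms=("Z1",))
        fit = fit_stage2(data, spec)
        assert fit.n_fit == 20

    def test_consistency_of_treatment_block(self):
        # correctly specified effect block: beta1 -> c2 * psi21 even with c1 != 0
        cfg = SimConfig(c1=2.0, c2=2.0, n=50_000, reps=1, seed=11)
        data = generate_trial(cfg, cfg.replicate_rng(0))
        fit = fit_stage2(data, sim_spec2())
        X = build_design(data, sim_spec2()).full
        se = fit.resid_sd * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))[4:]
        np.testing.assert_array_less(np.abs(fit.beta1 - 2.0 * PSI21), 3 * se)

    def test_too_few_rerandomized_is_hard_error(self):
        data = make_trial([1.0, 2.0], [1, -1], [0, 1], [True, True], [1, -1], [0, 1])
        with pytest.raises(ValueError, match="n > p"):
            fit_stage2(data, ModelSpec(stage=2, main_terms=("Z1",), effect_terms=("Z1",)))


class TestContrastAndRules:
    def test_contrast_matches_rowwise_loop(self, noiseless_trial):
        spec = ModelSpec(stage=2, main_terms=("Z1",), effect_terms=("Z1", "Z2"))
        fit = fit_stage2(noiseless_trial, spec)
        t = contrast(fit, noiseless_trial)
        for i, (_, row) in enumerate(noiseless_trial.frame.iterrows()):
            expected = fit.beta1 @ np.array([1.0, row["Z1"], row["Z2"]])
            assert t[i] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("t,expected", [(2.5, -1.0), (-0.1, 1.0), (0.0, -1.0)])
    def test_sgn_convention(self, t, expected):
        assert rule_stage2(np.array([t]))[0] == expected

    def test_rule_invariant_to_positive_scaling(self):
        t = np.array([-3.0, -0.5, 0.0, 0.2, 4.0])
        np.testing.assert_array_equal(rule_stage2(t), rule_stage2(7.3 * t))

    def test_rule_matches_two_arm_enumeration(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=50)
        d = rule_stage2(t)
        # oracle: pick the arm minimizing a * t, ties to -1
        for ti, di in zip(t, d):
            best = min([-1.0, 1.0], key=lambda a: (a * ti, a))
            assert di == best

    def test_general_coding_minimizes_a_times_t(self):
        t = np.array([1.0, -1.0, 0.0])
        d = rule_stage2(t, codes=(1.0, -2.0))
        np.testing.assert_array_equal(d, [-2.0, 1.0, -2.0])


class TestPseudoOutcome:
    def test_zero_contrast_cases(self, noiseless_trial):
        # saturate effect block so we control t exactly via a zero-coefficient fit
        spec = ModelSpec(stage=2, main_terms=("Z1",), effect_terms=("Z1",))
        fit = fit_stage2(noiseless_trial, spec)
        fit.beta1 = np.zeros_like(fit.beta1)
        yq = pseudo_outcome(fit, noiseless_trial, "Q")
        ymq = pseudo_outcome(fit, noiseless_trial, "mQ")
        np.testing.assert_allclose(yq, fit.main_value(noiseless_trial.frame))
        np.testing.assert_allclose(ymq, noiseless_trial.y)

    @pytest.mark.parametrize(
        "a2,t,expected",
        [
            (1.0, -2.0, 10.0),  # already on the optimal arm: zero regret
            (1.0, 2.0, 6.0),  # regret min_a a*t - a2*t = -2 - 2 = -4
            (-1.0, 2.0, 10.0),
        ],
    )
    def test_mq_regret_adjustment_enumeration(self, a2, t, expected):
        data = make_trial([0.0] * 9, [1] * 9, [0.0] * 9, [True] * 9, [a2] * 9, [10.0] * 9)
        fit = fit_stage2_stub(t)
        got = pseudo_outcome(fit, data, "mQ")
        # oracle: Y + (min_a a*t) - a2*t by explicit two-arm enumeration
        oracle = 10.0 + min(-t, t) - a2 * t
        assert oracle == expected
        np.testing.assert_allclose(got, expected)

    def test_regret_nonpositive_and_zero_iff_optimal(self):
        cfg = SimConfig(c1=1.0, c2=1.5, n=300, reps=1, seed=3)
        data = generate_trial(cfg, cfg.replicate_rng(0))
        fit = fit_stage2(data, sim_spec2())
        t = contrast(fit, data)
        diff = pseudo_outcome(fit, data, "mQ") - data.y
        assert np.all(diff <= 1e-12)
        on_optimal = data.a2 == rule_stage2(t)
        np.testing.assert_allclose(diff[on_optimal], 0.0, atol=1e-12)
        assert np.all(diff[~on_optimal] < 0)

    def test_nonrerandomized_keep_observed_outcome(self):
        rr = np.array([True] * 10 + [False] * 5)
        rng = np.random.default_rng(1)
        data = make_trial(rng.normal(size=15), 2 * rng.integers(0, 2, 15) - 1,
                          rng.normal(size=15), rr,
                          np.where(rr, 2 * rng.integers(0, 2, 15) - 1, np.nan),
                          rng.normal(size=15))
        spec = ModelSpec(stage=2, main_terms=("Z1",), effect_terms=("Z1",))
        fit = fit_stage2(data, spec)
        for method in ("Q", "mQ"):
            po = pseudo_outcome(fit, data, method)
            np.testing.assert_array_equal(po[~rr], data.y[~rr])

    def test_q_equals_mq_when_stage2_noiseless(self, noiseless_trial, spec1):
        spec = ModelSpec(stage=2, main_terms=("Z1",), effect_terms=("Z1",))
        fit = fit_stage2(noiseless_trial, spec)
        f_q = fit_stage1(pseudo_outcome(fit, noiseless_trial, "Q"), noiseless_trial, spec1)
        f_mq = fit_stage1(pseudo_outcome(fit, noiseless_trial, "mQ"), noiseless_trial, spec1)
        np.testing.assert_allclose(f_q.beta0, f_mq.beta0, atol=1e-9)
        np.testing.assert_allclose(f_q.beta1, f_mq.beta1, atol=1e-9)


def fit_stage2_stub(t_const: float):
    """StageFit whose contrast is identically t_const (main effect 0)."""
    from dtrlearn.qlearn_core import StageFit

    spec = ModelSpec(stage=2, main_terms=(), effect_terms=())
    return StageFit(beta0=np.array([0.0]), beta1=np.array([t_const]), n_fit=9,
                    resid_sd=0.0, spec=spec)


class TestStage1:
    def test_exact_linear_recovery(self, spec1):
        rng = np.random.default_rng(2)
        n = 25
        z1 = rng.normal(size=n)
        a1 = 2.0 * rng.integers(0, 2, n) - 1
        data = make_trial(z1, a1, np.zeros(n), np.ones(n, bool),
                          2 * rng.integers(0, 2, n) - 1, np.zeros(n))
        pseudo = 0.5 - 1.5 * z1 + a1 * (2.0 + 0.25 * z1)
        fit = fit_stage1(pseudo, data, spec1)
        np.testing.assert_allclose(fit.beta0, [0.5, -1.5], atol=1e-10)
        np.testing.assert_allclose(fit.beta1, [2.0, 0.25], atol=1e-10)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-8)

    def test_six_row_normal_equations_oracle(self, spec1):
        rng = np.random.default_rng(9)
        z1 = rng.normal(size=6)
        a1 = np.array([1.0, -1, 1, -1, 1, -1])
        data = make_trial(z1, a1, np.zeros(6), np.ones(6, bool), a1, np.zeros(6))
        pseudo = rng.normal(size=6)
        fit = fit_stage1(pseudo, data, spec1)
        X = np.column_stack([np.ones(6), z1, a1, a1 * z1])
        expected = np.linalg.solve(X.T @ X, X.T @ pseudo)
        np.testing.assert_allclose(np.r_[fit.beta0, fit.beta1], expected, rtol=1e-9)

    def test_rule_matches_two_point_argmin(self, spec1):
        rng = np.random.default_rng(4)
        n = 60
        z1 = rng.normal(size=n)
        a1 = 2.0 * rng.integers(0, 2, n) - 1
        data = make_trial(z1, a1, np.zeros(n), np.ones(n, bool), a1, np.zeros(n))
        pseudo = rng.normal(size=n)
        fit = fit_stage1(pseudo, data, spec1)
        d1 = rule_stage1_linear(fit, data.frame)
        q_neg = fit.q_value(data.frame, -1.0)
        q_pos = fit.q_value(data.frame, 1.0)
        oracle = np.where(q_neg <= q_pos, -1.0, 1.0)
        np.testing.assert_array_equal(d1, oracle)

    @given(b0=st.floats(-5, 5), b1=st.floats(-5, 5), z=st.floats(-10, 10))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rule_is_minus_sgn_of_contrast(self, b0, b1, z):
        from dtrlearn.qlearn_core import StageFit
        import pandas as pd

        spec = ModelSpec(stage=1, main_terms=("Z1",), effect_terms=("Z1",))
        fit = StageFit(beta0=np.zeros(2), beta1=np.array([b0, b1]), n_fit=10,
                       resid_sd=0.0, spec=spec)
        frame = pd.DataFrame({"Z1": [z]})
        t = b0 + b1 * z
        expected = -1.0 if t >= 0 else 1.0
        assert rule_stage1_linear(fit, frame)[0] == expected


class TestFittedDTR:
    def test_roundtrip_serialization(self, spec1, spec2):
        cfg = SimConfig(c1=1.0, c2=1.0, n=200, reps=1, seed=6)
        data = generate_trial(cfg, cfg.replicate_rng(0))
        for method in ("Q", "mQ", "IQ", "mIQ"):
            fitted = fit_dtr(data, spec1, spec2, method)
            from dtrlearn.qlearn_core import FittedDTR

            back = FittedDTR.from_dict(fitted.to_dict())
            frame = data.frame
            np.testing.assert_allclose(back.q1(frame, 1.0), fitted.q1(frame, 1.0))
            np.testing.assert_array_equal(back.rule1(frame), fitted.rule1(frame))
            np.testing.assert_array_equal(back.rule2(frame), fitted.rule2(frame))
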