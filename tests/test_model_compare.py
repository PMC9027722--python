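import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cuspcat.cusp_fit import CuspModelSpec, FitOptions
from cuspcat.model_compare import (
    ModelFitIndices,
    PowerSpec,
    fit_linear,
    fit_logistic,
    implied_n_from_aicc,
    information_criteria,
    lr_test,
    pseudo_r2,
    regression_power,
    required_sample_size,
    select_model,
    _logistic_mean,
)
from cuspcat.study_data import DegenerateVarianceError, StandardizedTable

SPEC = CuspModelSpec()


def _table_frame(n, rng, y=None):
    df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["blhr", "hrdt", "anger"])
    df["achievement"] = y if y is not None else rng.normal(size=n)
    df["participant_id"] = [str(i) for i in range(n)]
    df["condition"] = "normative"
    return df


class TestInformationCriteria:
    def test_zero_loglik_zero_k(self):
        idx = information_criteria(0.0, 0, 10)
        assert idx.aic == 0.0 and idx.bic == 0.0

    @given(
        st.floats(min_value=-500, max_value=0),
        st.integers(min_value=1, max_value=12),
        st.integers(min_value=15, max_value=500),
    )
    @settings(deadline=None, max_examples=60)
    def test_identities_against_independent_arithmetic(self, ll, k, n):
        idx = information_criteria(ll, k, n)
        assert idx.aic == pytest.approx(2 * k - 2 * ll)
        assert idx.bic == pytest.approx(k * math.log(n) - 2 * ll)
        assert idx.aicc - idx.aic == pytest.approx(2 * k * (k + 1) / (n - k - 1))
        assert idx.aicc >= idx.aic

    def test_aicc_unavailable_for_tiny_n(self):
        assert information_criteria(-10.0, 5, 6).aicc is None

    def test_implied_n_inverts_the_aicc_gap(self):
        idx = information_criteria(-50.0, 7, 38)
        assert implied_n_from_aicc(idx.aic, idx.aicc, 7) == pytest.approx(38.0)


class TestFitLinear:
    def test_study_spec_parameter_count_and_exact_loglik(self, rng):
        df = _table_frame(10, rng)
        fit = fit_linear(df, SPEC, FitOptions(standardize_state=False))
        assert fit.k == 5
        # closed-form Gaussian ML log-likelihood
        resid = fit.state - fit.fitted
        sigma2 = float(np.mean(resid ** 2))
        expected = -0.5 * 10 * (math.log(2 * math.pi * sigma2) + 1)
        assert fit.loglik == pytest.approx(expected, rel=1e-10)

    def test_near_deterministic_linear_signal_saturates_r2(self, rng):
        X = rng.normal(size=(80, 3))
        y = 1.0 + X @ [0.5, -0.3, 0.8] + rng.normal(0, 1e-4, 80)
        df = pd.DataFrame(X, columns=["blhr", "hrdt", "anger"])
        df["achievement"] = y
        df["participant_id"] = "x"
        df["condition"] = "normative"
        fit = fit_linear(df, SPEC, FitOptions(standardize_state=False,
                                              standardize_covariates=False))
        assert fit.indices.pseudo_r2 > 99.9


class TestFitLogistic:
    def test_study_spec_parameter_count(self, rng):
        fit = fit_logistic(_table_frame(40, rng), SPEC, FitOptions(seed=0))
        assert fit.k == 6

    def test_recovers_the_response_surface_from_logistic_truth(self, rng):
        n = 500
        xa = rng.normal(size=(n, 1))
        xb = rng.normal(size=(n, 2))
        truth = np.array([0.4, 1.2, 1.0, 0.5, -0.4])
        mean = _logistic_mean(truth, xa, xb)
        y = mean + rng.normal(0, 0.05, n)
        df = pd.DataFrame(np.column_stack([xa, xb]), columns=["blhr", "anger", "hrdt"])
        df["achievement"] = y
        df["participant_id"] = "x"
        df["condition"] = "normative"
        fit = fit_logistic(df, SPEC, FitOptions(seed=1, standardize_state=False,
                                                standardize_covariates=False))
        # coefficients are identified only up to the joint (alpha, beta^2)
        # scale, so the check is on the fitted mean surface
        assert np.sqrt(np.mean((fit.fitted - mean) ** 2)) < 0.02
        assert fit.indices.pseudo_r2 > 80

    def test_constant_state_rejected(self, rng):
        df = _table_frame(30, rng, y=np.ones(30))
        with pytest.raises(DegenerateVarianceError):
            fit_logistic(df, SPEC, FitOptions(standardize_state=False))


class TestPseudoR2:
    def test_perfect_and_grand_mean_fits(self):
        from cuspcat.model_compare import _variance_ratio_r2

        y = np.array([1.0, 2.0, 4.0, 3.0])
        assert _variance_ratio_r2(y, y) == pytest.approx(100.0)
        assert _variance_ratio_r2(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_conventions_on_a_real_fit(self, default_records):
        from cuspcat import fit_cusp, split_by_condition

        normative, _ = split_by_condition(default_records)
        fit = fit_cusp(normative, SPEC, FitOptions(seed=0))
        for convention in ("delay_mode", "density_mean"):
            r2 = pseudo_r2(fit, convention=convention)
            assert r2 <= 100.0


class TestLRTest:
    def test_equal_likelihood_models_give_zero_chi2(self):
        a = SimpleNamespace(loglik=-50.0, k=5, name="linear")
        b = SimpleNamespace(loglik=-50.0, k=7, name="cusp")
        res = lr_test(a, b)
        assert res.chi2 == 0.0 and res.df == 2 and res.p == pytest.approx(1.0)

    def test_equal_k_is_an_error(self):
        a = SimpleNamespace(loglik=-50.0, k=5, name="m1")
        b = SimpleNamespace(loglik=-45.0, k=5, name="m2")
        with pytest.raises(ValueError):
            lr_test(a, b)

    def test_swap_symmetry_and_direction(self):
        a = SimpleNamespace(loglik=-48.0, k=7, name="cusp")
        b = SimpleNamespace(loglik=-52.0, k=5, name="linear")
        r1, r2 = lr_test(a, b), lr_test(b, a)
        assert r1.chi2 == r2.chi2 and r1.df == r2.df
        assert r1.direction == r2.direction == "cusp"

    def test_one_tailed_halves_the_p(self):
        a = SimpleNamespace(loglik=-48.0, k=6, name="logistic")
        b = SimpleNamespace(loglik=-50.0, k=7, name="cusp")
        assert lr_test(a, b, one_tailed=True).p == pytest.approx(lr_test(a, b).p / 2)


class TestSelectModel:
    def _idx(self, ll, k, n=100, r2=None):
        base = information_criteria(ll, k, n)
        return ModelFitIndices(aic=base.aic, aicc=base.aicc, bic=base.bic,
                               pseudo_r2=r2, k=k, n=n, loglik=ll)

    def test_cusp_with_lowest_criteria_wins(self):
        report = select_model({
            "linear": self._idx(-55.0, 5),
            "logistic": self._idx(-54.0, 6),
            "cusp": self._idx(-48.0, 7),
        })
        assert report.preferred_by["aic"] == "cusp"
        assert report.cusp_preferred

    def test_identical_models_tie_without_preference(self):
        idx = self._idx(-50.0, 5)
        report = select_model({"linear": idx, "logistic": idx, "cusp": idx})
        assert report.preferred_by["aic"] is None
        assert not report.cusp_preferred

    def test_failed_evidence_checklist_blocks_the_cusp(self):
        evidence = SimpleNamespace(overall=False)
        report = select_model({
            "linear": self._idx(-55.0, 5),
            "cusp": self._idx(-48.0, 7),
        }, evidence=evidence)
        assert report.preferred_by["aic"] == "cusp"
        assert not report.cusp_preferred


class TestPower:
    def test_medium_effect_three_predictors(self):
        n = required_sample_size(PowerSpec(f2=0.15, alpha=0.05, power=0.80,
                                           n_predictors=3))
        assert n == 77

    def test_minimality_at_the_returned_n(self):
        spec = PowerSpec()
        n = required_sample_size(spec)
        assert regression_power(n, spec) >= spec.power
        assert regression_power(n - 1, spec) < spec.power

    def test_larger_effects_need_fewer_participants(self):
        n_medium = required_sample_size(PowerSpec(f2=0.15))
        n_large = required_sample_size(PowerSpec(f2=0.35))
        assert n_large < n_medium

    def test_power_increases_with_n(self):
        spec = PowerSpec()
        powers = [regression_power(n, spec) for n in range(10, 201, 10)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(f2=-0.1)
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.2)
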