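"""Competing models, information criteria, likelihood-ratio tests, power.

The cusp regression is judged against two conventional competitors fitted
to the same standardized state and covariates:

* a Gaussian linear model (intercept + one slope per covariate + error sd);
* a logistic-curve model ``y = 1 / (1 + exp(-alpha/beta^2)) + e`` that
  reuses the asymmetry/bifurcation covariate structure and, like the cusp,
  saturates — but without bimodality or hysteresis.  It is fitted by
  nonlinear least squares, which under Gaussian error is maximum
  likelihood.

Model comparison uses AIC / AICc / BIC, a pseudo-R² (1 - Var(resid)/Var(y),
which for a mis-specified cusp fit can go negative), and likelihood-ratio
chi-square difference tests.  The cusp-vs-logistic pair is not nested; the
arithmetic is still reported but flagged as descriptive.

The module also houses the noncentral-F power calculator for the overall
F test of a multiple regression, used to find the minimal sample size for
a target power at a given Cohen f².
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .cusp_core import batch_log_norm_and_moments, density_modes
from .cusp_fit import (
    CuspFitResult,
    CuspModelSpec,
    FitOptions,
    control_coordinates,
    _prepare_table,
    _design,
)
from .study_data import DegenerateVarianceError, StandardizedTable

__all__ = [
    "ModelFitIndices",
    "CompetitorFit",
    "LRTestResult",
    "PowerSpec",
    "SelectionReport",
    "fit_linear",
    "fit_logistic",
    "information_criteria",
    "pseudo_r2",
    "lr_test",
    "select_model",
    "regression_power",
    "required_sample_size",
    "implied_n_from_aicc",
]


@dataclass(frozen=True)
class ModelFitIndices:
    """One comparison-table row: information criteria and pseudo-R² (%)."""

    aic: float
    aicc: float | None
    bic: float
    pseudo_r2: float | None
    k: int
    n: int
    loglik: float

    def to_dict(self) -> dict:
        return {
            "k": self.k, "n": self.n, "loglik": self.loglik,
            "aic": self.aic, "aicc": self.aicc, "bic": self.bic,
            "pseudo_r2_pct": self.pseudo_r2,
        }


@dataclass(frozen=True)
class CompetitorFit:
    """A fitted competitor model reduced to what comparison needs."""

    name: str
    loglik: float
    k: int
    n: int
    params: dict[str, float]
    fitted: np.ndarray = field(repr=False)
    state: np.ndarray = field(repr=False)
    indices: ModelFitIndices | None = None
    converged: bool = True


@dataclass(frozen=True)
class LRTestResult:
    """Likelihood-ratio chi-square difference between two fitted models."""

    chi2: float
    df: int
    p: float
    direction: str          # name of the model with the higher likelihood
    one_tailed: bool = False
    nested: bool = True     # False => interpret descriptively


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the multiple-regression power calculation."""

    f2: float = 0.15        # Cohen effect size R^2/(1-R^2)
    alpha: float = 0.05
    power: float = 0.80
    n_predictors: int = 3

    def __post_init__(self) -> None:
        if self.f2 <= 0:
            raise ValueError("f2 must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.n_predictors < 1:
            raise ValueError("need at least one predictor")


def information_criteria(loglik: float, k: int, n: int) -> ModelFitIndices:
    """AIC = 2k - 2LL; AICc = AIC + 2k(k+1)/(n-k-1); BIC = k ln n - 2LL.

    AICc is flagged unavailable (None) when n <= k + 1.
    """
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(n) - 2.0 * loglik if n > 0 else float("nan")
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1) if n > k + 1 else None
    return ModelFitIndices(aic=aic, aicc=aicc, bic=bic, pseudo_r2=None,
                           k=k, n=n, loglik=loglik)


def _variance_ratio_r2(state: np.ndarray, fitted: np.ndarray) -> float:
    sst = float(np.var(state, ddof=1))
    if sst <= 0:
        raise DegenerateVarianceError("state variable has zero variance")
    ssr = float(np.var(state - fitted, ddof=1))
    return 100.0 * (1.0 - ssr / sst)


def fit_linear(data, spec: CuspModelSpec | None = None,
               options: FitOptions | None = None) -> CompetitorFit:
    """Gaussian linear model of the state on all covariates (exact ML).

    Parameter count is intercept + one slope per distinct covariate + the
    error sd; for the study spec (3 covariates) that is k = 5.
    """
    spec = spec or CuspModelSpec()
    options = options or FitOptions()
    table = _prepare_table(data, spec, options)
    covs = spec.all_covariates
    X = sm.add_constant(table.data[covs].to_numpy(dtype=float))
    z = table.data[spec.state_variable].to_numpy(dtype=float)
    n = z.size
    k = len(covs) + 2
    if n <= k:
        raise ValueError(f"n={n} too small for k={k}")
    res = sm.OLS(z, X).fit()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    fitted = np.asarray(res.fittedvalues)
    ll = float(res.llf)  # Gaussian ML log-likelihood (ML variance)
    idx = information_criteria(ll, k, n)
    idx = ModelFitIndices(aic=idx.aic, aicc=idx.aicc, bic=idx.bic,
                          pseudo_r2=_variance_ratio_r2(z, fitted),
                          k=k, n=n, loglik=ll)
    params = dict(zip(["intercept", *covs], np.asarray(res.params)))
    params["sigma"] = float(np.sqrt(res.ssr / n))
    return CompetitorFit(name="linear", loglik=ll, k=k, n=n, params=params,
                         fitted=fitted, state=z, indices=idx)


def _logistic_mean(theta: np.ndarray, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    p = xa.shape[1]
    alpha = theta[0] + xa @ theta[1:1 + p]
    beta = theta[1 + p] + xb @ theta[2 + p:]
    denom = np.maximum(beta * beta, 1e-6)
    return 1.0 / (1.0 + np.exp(-np.clip(alpha / denom, -500, 500)))


def fit_logistic(data, spec: CuspModelSpec | None = None,
                 options: FitOptions | None = None) -> CompetitorFit:
    """Logistic-curve competitor by multi-start nonlinear least squares.

    ``y = 1/(1 + exp(-alpha/beta^2)) + e`` with alpha and beta linear in the
    same covariates as the cusp; k counts the shape coefficients plus the
    error sd (6 for the study spec).
    """
    spec = spec or CuspModelSpec()
    options = options or FitOptions()
    table = _prepare_table(data, spec, options)
    xa, xb, z = _design(table, spec)
    n = z.size
    n_shape = 2 + xa.shape[1] + xb.shape[1]
    k = n_shape + 1
    if n <= k:
        raise ValueError(f"n={n} too small for k={k}")
    if float(np.std(z)) < 1e-12:
        raise DegenerateVarianceError("state variable has zero variance")

    rng = np.random.default_rng(options.seed)
    starts = [np.r_[np.zeros(n_shape - 1), 1.0],
              np.r_[0.5, np.zeros(n_shape - 2), 1.0]]
    for _ in range(options.extra_random_starts):
        starts.append(rng.normal(0, 0.5, size=n_shape))
    best = None
    for s in starts:
        res = optimize.least_squares(
            lambda t: z - _logistic_mean(t, xa, xb), s,
            method="lm", max_nfev=5000,
        )
        if best is None or res.cost < best.cost:
            best = res
    fitted = _logistic_mean(best.x, xa, xb)
    ssr = float(np.sum((z - fitted) ** 2))
    sigma2 = ssr / n
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    idx = information_criteria(ll, k, n)
    idx = ModelFitIndices(aic=idx.aic, aicc=idx.aicc, bic=idx.bic,
                          pseudo_r2=_variance_ratio_r2(z, fitted),
                          k=k, n=n, loglik=ll)
    names = (["la0", *[f"la:{c}" for c in spec.asymmetry_covariates],
              "lb0", *[f"lb:{c}" for c in spec.bifurcation_covariates]])
    params = dict(zip(names, best.x))
    params["sigma"] = math.sqrt(sigma2)
    return CompetitorFit(name="logistic", loglik=ll, k=k, n=n, params=params,
                         fitted=fitted, state=z, indices=idx,
                         converged=bool(best.success))


def pseudo_r2(fit: CuspFitResult, table: StandardizedTable | None = None,
              spec: CuspModelSpec | None = None,
              convention: str = "delay_mode") -> float:
    """Cobb pseudo-R² (%) for a cusp fit: 1 - Var(residual)/Var(state).

    ``delay_mode`` takes the fitted value as the density mode on the
    observation's current sheet (the mode nearest the observed state) — the
    delay convention, sensitive to bimodality and capable of producing
    negative values under mis-specification.  ``density_mean`` uses the
    conditional density mean instead.
    """
    table = table if table is not None else fit.table
    spec = spec or fit.spec
    alpha, beta, y = control_coordinates(fit.coefficients, table, spec)
    if convention == "density_mean":
        _, ey, _ = batch_log_norm_and_moments(alpha, beta)
        fitted = ey
    elif convention == "delay_mode":
        fitted = np.empty_like(y)
        for i in range(y.size):
            modes = np.array(density_modes(float(alpha[i]), float(beta[i])))
            fitted[i] = modes[np.argmin(np.abs(modes - y[i]))]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return _variance_ratio_r2(y, fitted)


def _ll_k(fit) -> tuple[float, int, str]:
    if isinstance(fit, CuspFitResult):
        return fit.loglik, fit.k, "cusp"
    return fit.loglik, fit.k, fit.name


def lr_test(fit_a, fit_b, one_tailed: bool = False, nested: bool = True) -> LRTestResult:
    """Chi-square difference test: chi2 = |2 (LL_A - LL_B)|, df = |k_A - k_B|."""
    ll_a, k_a, name_a = _ll_k(fit_a)
    ll_b, k_b, name_b = _ll_k(fit_b)
    df = abs(k_a - k_b)
    if df == 0:
        raise ValueError("models have equal parameter counts; no df for the test")
    chi2 = abs(2.0 * (ll_a - ll_b))
    p = float(stats.chi2.sf(chi2, df))
    if one_tailed:
        p /= 2.0
    direction = name_a if ll_a >= ll_b else name_b
    return LRTestResult(chi2=chi2, df=df, p=p, direction=direction,
                        one_tailed=one_tailed, nested=nested)


@dataclass(frozen=True)
class SelectionReport:
    """Model-selection verdicts per criterion plus the combined rule.

    The combined verdict declares the cusp preferred only when it has the
    strictly lowest AIC *and* BIC among the fitted models and (when a
    diagnostics checklist is supplied) the cusp-evidence checklist passes.
    """

    preferred_by: dict[str, str | None]
    lr_results: dict[str, LRTestResult]
    cusp_preferred: bool
    evidence_passed: bool | None
    indices: dict[str, ModelFitIndices]

    def to_json(self) -> str:
        out = {
            "preferred_by": self.preferred_by,
            "cusp_preferred": self.cusp_preferred,
            "evidence_passed": self.evidence_passed,
            "models": {m: ix.to_dict() for m, ix in self.indices.items()},
            "lr_tests": {
                key: {"chi2": r.chi2, "df": r.df, "p": r.p,
                      "direction": r.direction, "one_tailed": r.one_tailed,
                      "nested": r.nested}
                for key, r in self.lr_results.items()
            },
        }
        return json.dumps(out, indent=2)


def select_model(indices: dict[str, ModelFitIndices],
                 lr_results: dict[str, LRTestResult] | None = None,
                 evidence=None, tie_tol: float = 1e-9) -> SelectionReport:
    """Apply the selection logic across fitted models.

    ``indices`` maps model names (one of them "cusp") to their fit indices;
    per-criterion winners are the strict minimizers (ties -> None).
    """
    preferred: dict[str, str | None] = {}
    for crit in ("aic", "aicc", "bic"):
        vals = {m: getattr(ix, crit) for m, ix in indices.items()
                if getattr(ix, crit) is not None}
        if not vals:
            preferred[crit] = None
            continue
        ranked = sorted(vals.items(), key=lambda kv: kv[1])
        if len(ranked) > 1 and ranked[1][1] - ranked[0][1] < tie_tol:
            preferred[crit] = None  # tie
        else:
            preferred[crit] = ranked[0][0]
    evidence_passed = None if evidence is None else bool(evidence.overall)
    cusp_wins = preferred.get("aic") == "cusp" and preferred.get("bic") == "cusp"
    cusp_preferred = bool(cusp_wins and (evidence_passed is not False))
    return SelectionReport(
        preferred_by=preferred,
        lr_results=lr_results or {},
        cusp_preferred=cusp_preferred,
        evidence_passed=evidence_passed,
        indices=indices,
    )


def regression_power(n: int, spec: PowerSpec) -> float:
    """Power of the overall F test of a multiple regression at sample size n.

    Numerator df = number of predictors, denominator df = n - p - 1,
    noncentrality lambda = f² · n.
    """
    p = spec.n_predictors
    df2 = n - p - 1
    if df2 < 1:
        return 0.0
    crit = stats.f.isf(spec.alpha, p, df2)
    return float(stats.ncf.sf(crit, p, df2, spec.f2 * n))


def required_sample_size(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest integer n whose overall-F power reaches the target."""
    n = spec.n_predictors + 2
    while n <= n_max:
        if regression_power(n, spec) >= spec.power:
            return n
        n += 1
    raise ValueError(f"target power {spec.power} unreachable below n={n_max}")


def implied_n_from_aicc(aic: float, aicc: float, k: int) -> float:
    """Effective sample size implied by a printed (AIC, AICc, k) triple.

    Inverts AICc - AIC = 2k(k+1)/(n-k-1); a consistency diagnostic for
    published comparison tables.
    """
    gap = aicc - aic
    if gap <= 0:
        raise ValueError("AICc must exceed AIC")
    return 2.0 * k * (k + 1) / gap + k + 1
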