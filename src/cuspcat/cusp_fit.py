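"""Maximum-likelihood cusp regression.

The observed achievement score is mapped to the canonical behavioral state
by an affine transform, and the asymmetry/bifurcation controls are linear
in covariates:

    y_i     = w0 + w1 * z_i                     (z_i: standardized state)
    alpha_i = a0 + a . x_i                      (asymmetry covariates)
    beta_i  = b0 + b . v_i                      (bifurcation covariates)
    z_i | x_i, v_i  ~  w1 * exp(f(y_i; alpha_i, beta_i)) / Z(alpha_i, beta_i)

so the per-observation negative log-likelihood is
``log Z_i - f(y_i) - log w1``, the last term being the change-of-variables
Jacobian of the affine state map (without it w1 is unidentified).  The
likelihood is invariant under the joint reflection
(y, alpha, w0, w1) -> (-y, -alpha, -w0, -w1); identifiability is restored
by constraining w1 > 0.

Estimation is multi-start quasi-Newton (L-BFGS-B) with the analytic
gradient: the score of the quartic-exponential family only needs the first
two density moments, which come from the same vectorized quadrature as the
normalizer.  Standard errors are the inverse observed information
(numerically differentiated gradient), with Wald Z and two-tailed normal
p-values matching the usual reporting layout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cusp_core import batch_log_norm_and_moments, potential
from .study_data import (
    ParticipantRecord,
    StandardizedTable,
    records_to_frame,
    standardize_columns,
)

__all__ = [
    "CuspModelSpec",
    "CuspCoefficients",
    "CuspFitResult",
    "FitOptions",
    "NonConvergenceError",
    "InsufficientDataError",
    "control_coordinates",
    "negative_log_likelihood",
    "fit_cusp",
    "standard_errors",
]


class NonConvergenceError(RuntimeError):
    """Every optimizer start failed; carries the best attempt diagnostics."""


class InsufficientDataError(ValueError):
    """Fewer observations than free parameters."""


@dataclass(frozen=True)
class CuspModelSpec:
    """Which columns drive the controls and which is the behavioral state.

    Defaults follow the two-condition achievement study design: baseline
    heart rate as the asymmetry variable, anger and task heart rate as the
    bifurcation variables, achievement as the state.
    """

    asymmetry_covariates: tuple[str, ...] = ("blhr",)
    bifurcation_covariates: tuple[str, ...] = ("anger", "hrdt")
    state_variable: str = "achievement"

    def __post_init__(self) -> None:
        if not self.state_variable:
            raise ValueError("state_variable must be non-empty")

    @property
    def n_params(self) -> int:
        # a0 + asymmetry slopes + b0 + bifurcation slopes + w0 + w1
        return 4 + len(self.asymmetry_covariates) + len(self.bifurcation_covariates)

    @property
    def param_names(self) -> list[str]:
        return (
            ["a0", *[f"a:{c}" for c in self.asymmetry_covariates]]
            + ["b0", *[f"b:{c}" for c in self.bifurcation_covariates]]
            + ["w0", "w1"]
        )

    @property
    def all_covariates(self) -> list[str]:
        seen: list[str] = []
        for c in (*self.asymmetry_covariates, *self.bifurcation_covariates):
            if c not in seen:
                seen.append(c)
        return seen


@dataclass(frozen=True)
class CuspCoefficients:
    """The a/b/w parameter block of a cusp regression."""

    a0: float
    a: tuple[float, ...]
    b0: float
    b: tuple[float, ...]
    w0: float
    w1: float

    def __post_init__(self) -> None:
        vals = (self.a0, *self.a, self.b0, *self.b, self.w0, self.w1)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("coefficients must be finite")
        if self.w1 <= 0:
            raise ValueError("w1 must be positive (identifiability gauge)")

    def to_vector(self) -> np.ndarray:
        return np.array([self.a0, *self.a, self.b0, *self.b, self.w0, self.w1])

    @classmethod
    def from_vector(cls, theta: np.ndarray, spec: CuspModelSpec) -> "CuspCoefficients":
        p = len(spec.asymmetry_covariates)
        q = len(spec.bifurcation_covariates)
        theta = np.asarray(theta, dtype=float)
        if theta.size != spec.n_params:
            raise ValueError(
                f"expected {spec.n_params} parameters for spec, got {theta.size}"
            )
        return cls(
            a0=float(theta[0]),
            a=tuple(theta[1 : 1 + p]),
            b0=float(theta[1 + p]),
            b=tuple(theta[2 + p : 2 + p + q]),
            w0=float(theta[2 + p + q]),
            w1=float(theta[3 + p + q]),
        )


@dataclass
class CuspFitResult:
    """Converged cusp fit: coefficients, likelihood, and Wald inference."""

    coefficients: CuspCoefficients
    loglik: float
    k: int
    n: int
    converged: bool
    spec: CuspModelSpec
    se: dict[str, float] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    start_points_tried: int = 0
    start_logliks: tuple[float, ...] = ()
    se_available: bool = False
    table: StandardizedTable | None = field(default=None, repr=False)

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.spec.param_names, self.coefficients.to_vector()))

    def to_report(self) -> dict:
        """JSON-serializable report mirroring the coefficient-table layout."""
        rows = []
        for name, est in self.estimates.items():
            rows.append(
                {
                    "coefficient": name,
                    "estimate": est,
                    "se": self.se.get(name, float("nan")),
                    "z": self.z.get(name, float("nan")),
                    "p": self.p.get(name, float("nan")),
                }
            )
        return {
            "rows": rows,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "converged": self.converged,
            "start_points_tried": self.start_points_tried,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_report(), indent=2)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration for the multi-start ML search."""

    seed: int = 0
    extra_random_starts: int = 2
    maxiter: int = 2000
    gtol: float = 1e-8
    standardize_covariates: bool = True
    standardize_state: bool = True
    w1_floor: float = 1e-3


# ---------------------------------------------------------------------------


def _design(table: StandardizedTable, spec: CuspModelSpec):
    df = table.data
    for c in (*spec.all_covariates, spec.state_variable):
        if c not in df.columns:
            raise ValueError(f"column {c!r} not present in table")
    xa = df[list(spec.asymmetry_covariates)].to_numpy(dtype=float) \
        if spec.asymmetry_covariates else np.empty((len(df), 0))
    xb = df[list(spec.bifurcation_covariates)].to_numpy(dtype=float) \
        if spec.bifurcation_covariates else np.empty((len(df), 0))
    z = df[spec.state_variable].to_numpy(dtype=float)
    return xa, xb, z


def control_coordinates(
    coeffs: CuspCoefficients, table: StandardizedTable, spec: CuspModelSpec
):
    """Per-observation (alpha_i, beta_i, y_i) triples.

    Returns three aligned arrays: asymmetry, bifurcation, canonical state.
    """
    xa, xb, z = _design(table, spec)
    if xa.shape[1] != len(coeffs.a) or xb.shape[1] != len(coeffs.b):
        raise ValueError("coefficient dimensions do not match the model spec")
    alpha = coeffs.a0 + xa @ np.asarray(coeffs.a)
    beta = coeffs.b0 + xb @ np.asarray(coeffs.b)
    y = coeffs.w0 + coeffs.w1 * z
    return alpha, beta, y


def _nll_grad(theta: np.ndarray, xa: np.ndarray, xb: np.ndarray, z: np.ndarray):
    p = xa.shape[1]
    q = xb.shape[1]
    a0 = theta[0]
    a = theta[1 : 1 + p]
    b0 = theta[1 + p]
    b = theta[2 + p : 2 + p + q]
    w0 = theta[2 + p + q]
    w1 = theta[3 + p + q]
    if w1 <= 0:
        raise ValueError("w1 must be positive")
    n = z.size
    alpha = a0 + xa @ a
    beta = b0 + xb @ b
    y = w0 + w1 * z
    logz, ey, ey2 = batch_log_norm_and_moments(alpha, beta)
    f = potential(y, 0.0, 0.0) + alpha * y + 0.5 * beta * y * y  # alpha*y+beta*y^2/2-y^4/4
    nll = float(np.sum(logz - f) - n * math.log(w1))
    # score: d nll / d theta
    da = ey - y                      # per-obs d/d alpha
    db = 0.5 * (ey2 - y * y)         # per-obs d/d beta
    g = alpha + beta * y - y ** 3    # d f / d y
    grad = np.empty_like(theta)
    grad[0] = da.sum()
    grad[1 : 1 + p] = xa.T @ da
    grad[1 + p] = db.sum()
    grad[2 + p : 2 + p + q] = xb.T @ db
    grad[2 + p + q] = -g.sum()
    grad[3 + p + q] = -float(z @ g) - n / w1
    return nll, grad


def negative_log_likelihood(
    coeffs: CuspCoefficients, table: StandardizedTable, spec: CuspModelSpec
) -> float:
    """Summed negative log-likelihood of the cusp regression.

    Includes the per-observation ``-log(w1)`` Jacobian term of the affine
    state map.
    """
    xa, xb, z = _design(table, spec)
    nll, _ = _nll_grad(coeffs.to_vector(), xa, xb, z)
    return nll


def _prepare_table(data, spec: CuspModelSpec, options: FitOptions) -> StandardizedTable:
    if isinstance(data, StandardizedTable):
        return data
    df = data if isinstance(data, pd.DataFrame) else records_to_frame(data)
    cols = list(spec.all_covariates) if options.standardize_covariates else []
    if options.standardize_state:
        cols = cols + [spec.state_variable]
    table = standardize_columns(df, cols)
    return table


def _starting_points(xa, xb, z, spec: CuspModelSpec, options: FitOptions):
    n = z.size
    rng = np.random.default_rng(options.seed)
    starts: list[np.ndarray] = []
    # (i) linear-regression-informed start
    X = np.column_stack([np.ones(n), xa, xb])
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    p, q = xa.shape[1], xb.shape[1]
    s = np.zeros(spec.n_params)
    s[0] = coef[0]
    s[1 : 1 + p] = coef[1 : 1 + p]
    s[1 + p] = 0.1
    s[2 + p : 2 + p + q] = 0.1 * coef[1 + p : 1 + p + q]
    s[2 + p + q] = 0.0
    s[3 + p + q] = 1.0
    starts.append(s)
    # (ii) all-zero with w1 = 1
    s = np.zeros(spec.n_params)
    s[-1] = 1.0
    starts.append(s)
    # (iii) seeded random perturbations
    for _ in range(options.extra_random_starts):
        s = rng.normal(0.0, 0.5, size=spec.n_params)
        s[-1] = abs(s[-1]) + 0.5
        starts.append(s)
    return starts


def fit_cusp(data, spec: CuspModelSpec | None = None, options: FitOptions | None = None,
             start: CuspCoefficients | None = None) -> CuspFitResult:
    """Fit the cusp regression by multi-start maximum likelihood.

    ``data`` may be participant records, a DataFrame, or a pre-built
    StandardizedTable.  Covariates (and, by default, the state) are
    z-scored before fitting; the returned coefficients live on that
    standardized scale, in the w1 > 0 gauge.  An explicit ``start`` is
    prepended to the deterministic multi-start schedule.
    """
    spec = spec or CuspModelSpec()
    options = options or FitOptions()
    table = _prepare_table(data, spec, options)
    xa, xb, z = _design(table, spec)
    n = z.size
    k = spec.n_params
    if n <= k:
        raise InsufficientDataError(f"n={n} observations for k={k} parameters")
    if np.std(z) < 1e-12:
        raise ValueError("state variable has zero variance")

    bounds = [(-25.0, 25.0)] * (k - 1) + [(options.w1_floor, 25.0)]
    starts = _starting_points(xa, xb, z, spec, options)
    if start is not None:
        starts.insert(0, start.to_vector())
    best = None
    start_lls: list[float] = []
    failures: list[str] = []
    for s in starts:
        start_lls.append(-_nll_grad(s, xa, xb, z)[0])
        try:
            res = optimize.minimize(
                _nll_grad,
                s,
                args=(xa, xb, z),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": options.maxiter, "ftol": 1e-12, "gtol": options.gtol},
            )
        except (ValueError, FloatingPointError) as exc:
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective at optimum")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise NonConvergenceError(
            f"all {len(starts)} starts failed: {failures}"
        )
    coeffs = CuspCoefficients.from_vector(best.x, spec)
    fit = CuspFitResult(
        coefficients=coeffs,
        loglik=-float(best.fun),
        k=k,
        n=n,
        converged=bool(best.success),
        spec=spec,
        start_points_tried=len(starts),
        start_logliks=tuple(start_lls),
        table=table,
    )
    return standard_errors(fit, table, spec)


def standard_errors(
    fit: CuspFitResult, table: StandardizedTable | None = None, spec: CuspModelSpec | None = None
) -> CuspFitResult:
    """Wald inference from the inverse observed information.

    The Hessian of the negative log-likelihood is built by central
    differencing the analytic gradient at the optimum; a non-positive-
    definite information matrix leaves the standard errors marked
    unavailable (NaN) rather than fabricating values.
    """
    table = table or fit.table
    spec = spec or fit.spec
    xa, xb, z = _design(table, spec)
    theta = fit.coefficients.to_vector()
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        if tm[-1] <= 0:  # keep w1 positive when differencing
            tm[-1] = theta[-1] / 2
            h = (tp[-1] - tm[-1]) / 2
        _, gp = _nll_grad(tp, xa, xb, z)
        _, gm = _nll_grad(tm, xa, xb, z)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    names = spec.param_names
    try:
        L = np.linalg.cholesky(H)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        ok = bool(np.all(np.isfinite(se)) and np.all(se > 0))
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        nanv = {nm: float("nan") for nm in names}
        return replace(fit, se=dict(nanv), z=dict(nanv), p=dict(nanv), se_available=False, table=table)
    zval = theta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    return replace(
        fit,
        se=dict(zip(names, se.astype(float))),
        z=dict(zip(names, zval.astype(float))),
        p=dict(zip(names, pval.astype(float))),
        se_available=True,
        table=table,
    )
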