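"""Nonlinear least-squares estimation for the enzyme-driven model families.

Three families are fitted:

* ``exponential`` — ``P = alpha * exp(b * vp)``, minimized on the raw rate
  scale (the scale on which enzyme–photosynthesis series are plotted).
* ``linear`` — ordinary least squares of the rate on the predictor, the
  comparison alternative.
* ``resource_response_full`` / ``resource_response_reduced`` — the saturating
  nitrogen law, minimized on the ``ln y`` scale (the data are log-transformed
  before this fit), with or without the free baseline ``ln_P0``.

Initialization is deterministic: the exponential fit starts from the OLS
regression of ``ln y`` on ``x`` (exact when the data are noiseless), the
nitrogen fit from a coarse profile grid over ``(R0, Kp)`` with the two
conditionally linear parameters solved exactly at each node.  A seeded set of
perturbed restarts guards against local minima; identical inputs and seed
give bit-identical results.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .core_model import (
    DomainError,
    ExponentialParams,
    LinearParams,
    ResourceResponseParams,
    ResponseSeries,
    ValidationError,
    predict_exponential,
    predict_linear,
    predict_resource_response,
)

__all__ = [
    "InsufficientDataError",
    "FitResult",
    "fit_exponential",
    "fit_linear",
    "fit_resource_response",
    "fit_model",
    "estimate_standard_errors",
    "information_criteria",
    "MODEL_KINDS",
]

MODEL_KINDS = (
    "exponential",
    "linear",
    "resource_response_full",
    "resource_response_reduced",
)

#: Convergence policy shared by all iterative fits: stop when the relative
#: change in RSS drops below 1e-10 or the gradient norm below 1e-8.
FTOL = 1e-10
GTOL = 1e-8
XTOL = 1e-12

#: Number of seeded perturbed restarts tried after the deterministic start.
N_RESTARTS = 8


class InsufficientDataError(ValidationError):
    """Fewer points than the model family requires."""


@dataclass
class FitResult:
    """One model family fitted to one series.

    ``k`` is the parameter count used in AIC and includes the residual
    variance (``k = k_model + 1`` with ``k_model`` the free curve
    parameters), applied uniformly across families so AIC differences are
    comparable.  ``rss`` and ``r_squared`` are on the fitting scale (raw y
    for exponential/linear, ln y for the nitrogen law); ``r_squared`` may be
    negative for badly misspecified fits and is never clamped.
    """

    model_kind: str
    params: object
    se: np.ndarray
    param_names: tuple
    n: int
    k_model: int
    k: int
    rss: float
    r_squared: float
    aic: float
    aicc: float
    converged: bool
    n_starts: int
    best_start: dict = field(default_factory=dict)
    se_defined: bool = True
    aicc_defined: bool = True
    message: str = ""

    @property
    def estimates(self) -> np.ndarray:
        return np.array([getattr(self.params, name) for name in self.param_names])

    def to_dict(self) -> dict:
        d = {
            "model_kind": self.model_kind,
            "n": self.n,
            "k": self.k,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "aic": self.aic,
            "aicc": self.aicc if self.aicc_defined else None,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }
        for name, est, se in zip(self.param_names, self.estimates, self.se):
            d[name] = float(est)
            d[f"se_{name}"] = float(se) if np.isfinite(se) else None
        return d


def information_criteria(rss: float, n: int, k: int) -> tuple:
    """Gaussian-likelihood AIC and small-sample AICc from a residual sum of squares.

    ``AIC = n ln(rss/n) + 2k`` and ``AICc = AIC + 2k(k+1)/(n-k-1)``.  ``k``
    counts all estimated parameters including the residual variance.  For an
    exact fit (``rss == 0``) the criterion diverges to ``-inf``, which is the
    correct limit for comparison purposes.  AICc is undefined (NaN) when
    ``n <= k + 1``.
    """
    if rss < 0:
        raise ValidationError(f"rss must be nonnegative, got {rss}")
    if n <= 0 or k <= 0:
        raise ValidationError("n and k must be positive")
    if rss == 0.0:
        aic = -np.inf
    else:
        aic = n * np.log(rss / n) + 2 * k
    if n <= k + 1:
        return aic, np.nan
    return aic, aic + 2 * k * (k + 1) / (n - k - 1)


def _r_squared(resid: np.ndarray, target: np.ndarray) -> float:
    tss = float(np.sum((target - target.mean()) ** 2))
    rss = float(np.sum(resid**2))
    if tss == 0.0:
        # constant target: no variance to explain
        return 0.0
    return 1.0 - rss / tss


def _jacobian(result: "FitResult", series: ResponseSeries) -> np.ndarray:
    """Analytic Jacobian of the fitted-scale predictions w.r.t. the free parameters."""
    x = series.x
    p = result.params
    if result.model_kind == "exponential":
        e = np.exp(p.b * x)
        return np.column_stack([e, p.alpha * x * e])
    if result.model_kind == "linear":
        return np.column_stack([np.ones_like(x), x])
    # resource response, ln scale: f = A*u + c with u = s/(Kp+s), s = x-R0
    s = x - p.R0
    den = p.Kp + s
    u = s / den
    dA = u
    dKp = -p.ln_P_max * s / den**2
    dR0 = -p.ln_P_max * p.Kp / den**2
    cols = [dA, dKp, dR0]
    if not p.reduced:
        cols.append(np.ones_like(x))
    return np.column_stack(cols)


def estimate_standard_errors(result: FitResult, series: ResponseSeries) -> np.ndarray:
    """Linearization-based standard errors ``sqrt(diag(s^2 (J'J)^-1))``.

    ``s^2 = RSS / (n - k_model)`` with ``J`` the Jacobian of the fitted-scale
    predictions at the optimum.  A singular ``J'J`` or zero residual degrees
    of freedom yields NaN standard errors flagged ``se_defined = False``
    rather than silent zeros.
    """
    if not result.converged:
        raise ValidationError("standard errors require a converged fit")
    n, k_model = result.n, result.k_model
    n_se = len(result.param_names)
    if n <= k_model:
        result.se_defined = False
        result.message = (result.message + " zero residual degrees of freedom").strip()
        return np.full(n_se, np.nan)
    J = _jacobian(result, series)
    jtj = J.T @ J
    s2 = result.rss / (n - k_model)
    # reject near-singular designs instead of returning garbage
    if not np.all(np.isfinite(jtj)) or np.linalg.cond(jtj) > 1e12:
        result.se_defined = False
        result.message = (result.message + " singular J'J; SEs undefined").strip()
        return np.full(n_se, np.nan)
    cov = s2 * np.linalg.inv(jtj)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def _finalize(
    model_kind: str,
    params,
    param_names,
    resid: np.ndarray,
    target: np.ndarray,
    series: ResponseSeries,
    k_model: int,
    converged: bool,
    n_starts: int,
    best_start: dict,
    message: str = "",
) -> FitResult:
    rss = float(np.sum(resid**2))
    k = k_model + 1  # + residual variance
    # below double-precision resolution of the target the fit is exact;
    # report the limiting AIC so exact fits tie instead of comparing noise
    tss = float(np.sum((target - target.mean()) ** 2))
    rss_for_ic = 0.0 if rss <= max(tss, 1.0) * 1e-20 else rss
    aic, aicc = information_criteria(rss_for_ic, len(target), k)
    result = FitResult(
        model_kind=model_kind,
        params=params,
        se=np.full(len(param_names), np.nan),
        param_names=tuple(param_names),
        n=len(target),
        k_model=k_model,
        k=k,
        rss=rss,
        r_squared=_r_squared(resid, target),
        aic=aic,
        aicc=aicc,
        converged=converged,
        n_starts=n_starts,
        best_start=best_start,
        aicc_defined=bool(np.isfinite(aicc)),
        message=message,
    )
    if converged:
        result.se = estimate_standard_errors(result, series)
    return result


def _require_n(series: ResponseSeries, minimum: int, family: str) -> None:
    if len(series) < minimum:
        raise InsufficientDataError(
            f"{family} fit requires at least {minimum} points, series has {len(series)}"
        )


def fit_linear(series: ResponseSeries) -> FitResult:
    """Ordinary least squares of the rate on the predictor (closed form)."""
    _require_n(series, 3, "linear")
    x, y = series.x, series.y
    if np.ptp(x) == 0:
        raise ValidationError("all x identical: linear design is rank deficient")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    params = LinearParams(intercept=float(beta[0]), slope=float(beta[1]))
    resid = y - predict_linear(params, x)
    return _finalize(
        "linear",
        params,
        ("intercept", "slope"),
        resid,
        y,
        series,
        k_model=2,
        converged=True,
        n_starts=1,
        best_start={"intercept": params.intercept, "slope": params.slope},
    )


def _loglinear_start(series: ResponseSeries) -> tuple:
    """OLS of ln y on x: exact for noiseless exponential data."""
    x, z = series.x, np.log(series.y)
    if np.ptp(x) == 0:
        raise ValidationError("all x identical: exponential design is degenerate")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return float(np.exp(beta[0])), float(beta[1])


def fit_exponential(series: ResponseSeries, seed: int = 0) -> FitResult:
    """Fit ``P = alpha * exp(b * vp)`` by raw-scale nonlinear least squares.

    Starts from the log-linear OLS solution plus ``N_RESTARTS`` seeded
    multiplicative perturbations; the best converged solution by RSS wins.
    Non-convergence of every start is reported via ``converged = False``,
    never raised.
    """
    _require_n(series, 3, "exponential")
    if series.predictor_kind != "enzyme_activity":
        warnings.warn(
            f"exponential enzyme fit applied to predictor_kind="
            f"{series.predictor_kind!r}; results may not be meaningful",
            stacklevel=2,
        )
    x, y = series.x, series.y
    a0, b0 = _loglinear_start(series)

    def residuals(theta):
        return theta[0] * np.exp(theta[1] * x) - y

    rng = np.random.default_rng(seed)
    starts = [(a0, b0)]
    for _ in range(N_RESTARTS):
        starts.append(
            (
                a0 * float(np.exp(rng.normal(0.0, 0.3))),
                b0 * float(1.0 + rng.normal(0.0, 0.3)) + float(rng.normal(0.0, 1e-3)),
            )
        )
    best = None
    best_start: dict = {}
    any_ok = False
    for a_init, b_init in starts:
        sol = least_squares(
            residuals,
            x0=[max(a_init, 1e-12), b_init],
            bounds=([1e-12, -np.inf], [np.inf, np.inf]),
            ftol=FTOL,
            gtol=GTOL,
            xtol=XTOL,
        )
        # converged solutions take priority; ties broken by RSS
        key = (not sol.success, sol.cost)
        if best is None or key < (not best.success, best.cost):
            best = sol
            best_start = {"alpha0": a_init, "b0": b_init}
        any_ok = any_ok or sol.success
    params = ExponentialParams(alpha=float(best.x[0]), b=float(best.x[1]))
    resid = predict_exponential(params, x) - y
    return _finalize(
        "exponential",
        params,
        ("alpha", "b"),
        resid,
        y,
        series,
        k_model=2,
        converged=bool(any_ok),
        n_starts=len(starts),
        best_start=best_start,
        message="" if any_ok else "no start converged",
    )


def _profile_grid_start(x: np.ndarray, z: np.ndarray, reduced: bool, eps: float):
    """Coarse grid over (R0, Kp); (ln_P_max, ln_P0) solved linearly at each node."""
    xmin, xrange = float(x.min()), float(np.ptp(x))
    r0_grid = np.linspace(xmin - 2.0 * xrange, xmin - eps, 15)
    kp_grid = np.geomspace(0.02 * xrange, 20.0 * xrange, 15)
    best = None
    for r0 in r0_grid:
        s = x - r0
        for kp in kp_grid:
            u = s / (kp + s)
            if reduced:
                denom = float(u @ u)
                if denom == 0:
                    continue
                A = float(u @ z) / denom
                c = 0.0
            else:
                X = np.column_stack([u, np.ones_like(u)])
                beta, *_ = np.linalg.lstsq(X, z, rcond=None)
                A, c = float(beta[0]), float(beta[1])
            if A <= 0:
                continue
            rss = float(np.sum((A * u + c - z) ** 2))
            if best is None or rss < best[0]:
                best = (rss, A, kp, r0, c)
    if best is None:  # pathological data; fall back to a neutral node
        best = (np.inf, max(float(z.max() - z.min()), 0.1), xrange or 1.0, xmin - eps, float(z.min()))
    return best[1:]


def fit_resource_response(series: ResponseSeries, reduced: bool = False, seed: int = 0) -> FitResult:
    """Fit the saturating nitrogen law on the ``ln y`` scale.

    Minimizes ``sum(ln y - [ln_P_max (x-R0)/(Kp+(x-R0)) + ln_P0])^2`` subject
    to ``Kp > 0`` and ``R0 <= min(x) - eps`` with
    ``eps = 1e-9 * range(x)``, so the effective resource stays nonnegative at
    every observation.  The constraint is enforced through optimizer bounds,
    never by clipping data.  ``reduced = True`` fixes ``ln_P0 = 0``.

    With a free baseline (``reduced = False``) the four raw parameters are
    not jointly identifiable — only the three combinations returned by
    :func:`leafedm.core_model.hyperbola_form` are determined by the data, the
    RSS is minimized over that ridge, and the per-parameter standard errors
    are correctly reported as undefined (singular ``J'J``).
    """
    _require_n(series, 3 if reduced else 4, "resource response")
    if series.predictor_kind != "leaf_N":
        warnings.warn(
            f"nitrogen response fit applied to predictor_kind="
            f"{series.predictor_kind!r}; results may not be meaningful",
            stacklevel=2,
        )
    x, z = series.x, np.log(series.y)
    xrange = float(np.ptp(x))
    if xrange == 0:
        raise ValidationError("all x identical: resource-response design is degenerate")
    eps = 1e-9 * xrange
    r0_max = float(x.min()) - eps

    A0, kp0, r00, c0 = _profile_grid_start(x, z, reduced, eps)

    if reduced:
        names = ("ln_P_max", "Kp", "R0")
        lower = [1e-10, 1e-12, -np.inf]
        upper = [np.inf, np.inf, r0_max]

        def residuals(theta):
            A, kp, r0 = theta
            s = x - r0
            return A * s / (kp + s) - z

        x0 = [A0, kp0, min(r00, r0_max)]
    else:
        names = ("ln_P_max", "Kp", "R0", "ln_P0")
        lower = [1e-10, 1e-12, -np.inf, -np.inf]
        upper = [np.inf, np.inf, r0_max, np.inf]

        def residuals(theta):
            A, kp, r0, c = theta
            s = x - r0
            return A * s / (kp + s) + c - z

        x0 = [A0, kp0, min(r00, r0_max), c0]

    rng = np.random.default_rng(seed)
    starts = [list(x0)]
    for _ in range(N_RESTARTS):
        pert = list(x0)
        pert[0] = x0[0] * float(np.exp(rng.normal(0.0, 0.3)))
        pert[1] = x0[1] * float(np.exp(rng.normal(0.0, 0.5)))
        pert[2] = min(x0[2] - abs(rng.normal(0.0, 0.2 * xrange)), r0_max)
        if not reduced:
            pert[3] = x0[3] + float(rng.normal(0.0, 0.3))
        starts.append(pert)

    best = None
    best_start: dict = {}
    any_ok = False
    for start in starts:
        start[0] = max(start[0], 1e-9)
        start[1] = max(start[1], 1e-9)
        sol = least_squares(
            residuals, x0=start, bounds=(lower, upper), ftol=FTOL, gtol=GTOL, xtol=XTOL
        )
        key = (not sol.success, sol.cost)
        if best is None or key < (not best.success, best.cost):
            best = sol
            best_start = dict(zip(names, start))
        any_ok = any_ok or sol.success
    theta = best.x
    params = ResourceResponseParams(
        ln_P_max=float(theta[0]),
        Kp=float(theta[1]),
        R0=float(theta[2]),
        ln_P0=0.0 if reduced else float(theta[3]),
        reduced=reduced,
    )
    resid = predict_resource_response(params, x) - z
    return _finalize(
        "resource_response_reduced" if reduced else "resource_response_full",
        params,
        names,
        resid,
        z,
        series,
        k_model=params.k_free,
        converged=bool(any_ok),
        n_starts=len(starts),
        best_start=best_start,
        message="" if any_ok else "no start converged",
    )


def fit_model(series: ResponseSeries, model_kind: str, seed: int = 0) -> FitResult:
    """Dispatch to the family-specific fitter by ``model_kind`` label."""
    if model_kind == "exponential":
        return fit_exponential(series, seed=seed)
    if model_kind == "linear":
        return fit_linear(series)
    if model_kind == "resource_response_full":
        return fit_resource_response(series, reduced=False, seed=seed)
    if model_kind == "resource_response_reduced":
        return fit_resource_response(series, reduced=True, seed=seed)
    raise ValidationError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
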