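"""Domain types and closed-form predictions of the enzyme-driven model (EDM).

The EDM describes leaf-level photosynthesis in C3 and C4 crop plants with two
laws:

* an exponential enzyme law ``P = alpha * exp(b * vp)`` relating the net
  photosynthetic rate ``P`` (µmol CO2 m^-2 s^-1) to the activity ``vp`` of a
  limiting photosynthetic enzyme (Rubisco, cpFBPase, PEPC, ...), and
* a saturating (Michaelis-Menten-type) nitrogen law on the log scale,
  ``ln P = ln_P_max * (R - R0) / (Kp + (R - R0)) + ln_P0``, where ``R`` is
  leaf nitrogen content, ``R0`` a storage-nitrogen offset so that ``R - R0``
  is the effective limiting resource, ``Kp`` the half-saturation constant and
  ``ln_P0`` the storage-nitrogen baseline (log photosynthetic rate at zero
  effective resource).

This module holds the parameter containers, the series container used across
the package, and the pure prediction functions.  Fitting lives in
:mod:`leafedm.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "DomainError",
    "ResponseSeries",
    "ExponentialParams",
    "LinearParams",
    "ResourceResponseParams",
    "predict_exponential",
    "predict_linear",
    "predict_resource_response",
    "half_saturation",
    "pnue",
    "capacity_ratio",
    "hyperbola_form",
]

Pathway = Literal["C3", "C4"]
PredictorKind = Literal["enzyme_activity", "leaf_N"]


class ValidationError(ValueError):
    """Input violates a structural contract (shape, sign, finiteness)."""


class DomainError(ValueError):
    """Input lies outside the mathematical domain of a model function."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ResponseSeries:
    """One digitized predictor/response point series with its metadata.

    ``x`` is the predictor (enzyme activity in µmol m^-2 s^-1, or leaf N in
    mmol m^-2 / g N m^-2 depending on ``predictor_kind``); ``y`` is the
    photosynthetic / CO2 assimilation rate in µmol CO2 m^-2 s^-1.  Every ``y``
    must be strictly positive because the nitrogen law is fitted on ``ln y``.
    Units are carried as metadata and never converted implicitly.
    """

    species: str
    pathway: Pathway
    predictor_kind: PredictorKind
    predictor_name: str
    x: np.ndarray
    y: np.ndarray
    x_units: str = ""
    y_units: str = "µmol CO2 m-2 s-1"
    co2_partial_pressure_Pa: Optional[float] = None
    source_ref: str = ""

    def __post_init__(self) -> None:
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        if self.pathway not in ("C3", "C4"):
            raise ValidationError(f"pathway must be 'C3' or 'C4', got {self.pathway!r}")
        if self.predictor_kind not in ("enzyme_activity", "leaf_N"):
            raise ValidationError(
                f"predictor_kind must be 'enzyme_activity' or 'leaf_N', got {self.predictor_kind!r}"
            )
        if len(self.x) != len(self.y):
            raise ValidationError(
                f"x and y must have equal length, got {len(self.x)} and {len(self.y)}"
            )
        if len(self.x) == 0:
            raise ValidationError("series must contain at least one point")
        if not np.all(np.isfinite(self.x)):
            raise ValidationError("x contains non-finite values")
        if not np.all(np.isfinite(self.y)):
            raise ValidationError("y contains non-finite values")
        if np.any(self.y <= 0):
            bad = int(np.argmax(self.y <= 0))
            raise ValidationError(
                f"y must be strictly positive (log-transform must exist); "
                f"y[{bad}] = {self.y[bad]}"
            )
        if self.co2_partial_pressure_Pa is not None and self.co2_partial_pressure_Pa < 0:
            raise ValidationError("co2_partial_pressure_Pa must be nonnegative")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def series_id(self) -> str:
        parts = [self.species, self.predictor_name]
        if self.co2_partial_pressure_Pa is not None:
            parts.append(f"{self.co2_partial_pressure_Pa:g}Pa")
        return "/".join(p.replace(" ", "_") for p in parts if p)


@dataclass(frozen=True)
class ExponentialParams:
    """Parameters of the exponential enzyme law ``P = alpha * exp(b * vp)``.

    ``alpha`` (> 0) is the photosynthetic rate at zero enzyme activity, in y
    units; ``b`` is the enzyme-activity potential, in reciprocal predictor
    units.
    """

    alpha: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValidationError(f"alpha must be finite and > 0, got {self.alpha}")
        if not np.isfinite(self.b):
            raise ValidationError(f"b must be finite, got {self.b}")


@dataclass(frozen=True)
class LinearParams:
    """Straight-line comparison model ``y = intercept + slope * x``."""

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValidationError("intercept and slope must be finite")


@dataclass(frozen=True)
class ResourceResponseParams:
    """Parameters of the saturating nitrogen law on the log scale.

    ``ln_P_max`` (> 0) is the asymptotic log photosynthetic rate above the
    baseline; ``Kp`` (> 0) the half-saturation constant in predictor units;
    ``R0`` the storage-nitrogen offset (predictor units); ``ln_P0`` the
    baseline log rate at zero effective resource.  When ``reduced`` is true
    the baseline is fixed at ``ln_P0 = 0`` and is excluded from the free
    parameter count.
    """

    ln_P_max: float
    Kp: float
    R0: float = 0.0
    ln_P0: float = 0.0
    reduced: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ln_P_max) and self.ln_P_max > 0):
            raise ValidationError(f"ln_P_max must be finite and > 0, got {self.ln_P_max}")
        if not (np.isfinite(self.Kp) and self.Kp > 0):
            raise ValidationError(f"Kp must be finite and > 0, got {self.Kp}")
        if not np.isfinite(self.R0):
            raise ValidationError(f"R0 must be finite, got {self.R0}")
        if not np.isfinite(self.ln_P0):
            raise ValidationError(f"ln_P0 must be finite, got {self.ln_P0}")
        if self.reduced and self.ln_P0 != 0.0:
            raise ValidationError("reduced parameterization requires ln_P0 == 0")

    @property
    def k_free(self) -> int:
        """Number of free curve parameters (3 when reduced, else 4)."""
        return 3 if self.reduced else 4


def _check_finite(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return arr


def predict_exponential(params: ExponentialParams, vp):
    """Photosynthetic rate ``alpha * exp(b * vp)`` at enzyme activity ``vp``.

    Strictly increasing in ``vp`` iff ``b > 0``; equals ``alpha`` at
    ``vp = 0``.  Accepts scalars or arrays.
    """
    vp_arr = _check_finite(vp, "vp")
    out = params.alpha * np.exp(params.b * vp_arr)
    return out if out.ndim else float(out)


def predict_linear(params: LinearParams, x):
    """Straight-line prediction ``intercept + slope * x``."""
    x_arr = _check_finite(x, "x")
    out = params.intercept + params.slope * x_arr
    return out if out.ndim else float(out)


def predict_resource_response(params: ResourceResponseParams, R):
    """Log photosynthetic rate at leaf nitrogen content ``R``.

    Returns ``ln_P_max * (R - R0) / (Kp + (R - R0)) + ln_P0`` (with
    ``ln_P0 = 0`` under the reduced parameterization).  Monotone
    nondecreasing in ``R`` with supremum ``ln_P0 + ln_P_max`` as R grows.

    Raises
    ------
    DomainError
        If any ``R < R0`` — the effective resource ``R - R0`` must be
        nonnegative at every observation.
    """
    R_arr = _check_finite(R, "R")
    if np.any(R_arr < params.R0):
        raise DomainError(
            f"R must satisfy R >= R0 = {params.R0} (effective resource R - R0 "
            "must be nonnegative)"
        )
    s = R_arr - params.R0
    out = params.ln_P_max * s / (params.Kp + s) + params.ln_P0
    return out if out.ndim else float(out)


def half_saturation(params: ResourceResponseParams) -> float:
    """Leaf-N content at which the log rate reaches half its span.

    At ``R = R0 + Kp`` the prediction minus ``ln_P0`` equals
    ``ln_P_max / 2`` — the defining property of the half-saturation
    constant ``Kp``.
    """
    return params.R0 + params.Kp


def pnue(P: float, N: float) -> float:
    """Photosynthetic nitrogen use efficiency: assimilation rate per unit leaf N.

    ``P`` in µmol CO2 m^-2 s^-1, ``N`` > 0 in the caller's leaf-N unit.
    """
    _check_finite(P, "P")
    N_arr = _check_finite(N, "N")
    if np.any(N_arr <= 0):
        raise ValidationError(f"N must be > 0, got {N}")
    return P / N


def hyperbola_form(params: ResourceResponseParams) -> dict:
    """The three identifiable combinations of the nitrogen law.

    On the ln scale the law collapses to a shifted hyperbola::

        ln P = D - B / (R - m),

    with ``D = ln_P_max + ln_P0`` (asymptotic log rate), ``B = ln_P_max * Kp``
    (curvature scale) and ``m = R0 - Kp`` (pole position).  Only these three
    combinations enter the predictions, so with a free baseline ``ln_P0`` the
    four raw parameters are not jointly identifiable from a single series —
    any parameter vector on the ridge of constant ``(D, B, m)`` fits
    identically.  Fixing ``ln_P0 = 0`` (the reduced variant) restores
    identifiability.
    """
    return {
        "D": params.ln_P_max + params.ln_P0,
        "B": params.ln_P_max * params.Kp,
        "m": params.R0 - params.Kp,
    }


def capacity_ratio(resource_params: ResourceResponseParams, exp_params: ExponentialParams) -> float:
    """Convenience ratio ``ln_P_max / b`` with the dimensions of a maximal enzyme activity.

    The two estimates come from different predictor axes (leaf N vs. enzyme
    activity), so the ratio is exposed for exploration only and is not
    asserted to equal any independently measured enzyme capacity.
    """
    if exp_params.b == 0:
        raise DomainError("capacity ratio undefined for b = 0")
    return resource_params.ln_P_max / exp_params.b
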