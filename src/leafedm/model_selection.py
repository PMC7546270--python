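"""AIC-based model comparison and regression significance testing.

Two comparisons are meaningful within one series because each pair shares a
fitting scale: exponential vs. linear on the raw rate scale, and full vs.
reduced nitrogen response on the ln scale.  Comparing across scales would
compare likelihoods of different data transforms, so mixed-scale requests are
rejected.

The original analysis framework reported ANOVA/Tukey p-values alongside the
regression fits; here the significance of a fitted relationship is assessed
with the standard regression F-test of the model against the intercept-only
model on its own fitting scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy import stats

from .core_model import ResponseSeries, ValidationError
from .fitting import MODEL_KINDS, FitResult, fit_model

__all__ = ["ModelComparison", "compare_models", "regression_f_test"]

#: AIC differences smaller than this are treated as ties and resolved toward
#: the model with fewer parameters (parsimony).
AIC_TIE_TOL = 1e-9

_RAW_SCALE = {"exponential", "linear"}
_LN_SCALE = {"resource_response_full", "resource_response_reduced"}


@dataclass
class ModelComparison:
    """Paired fits of one series with AIC ranking and significance test."""

    series_id: str
    fits: Dict[str, FitResult]
    delta_aic: float
    akaike_weights: Dict[str, float]
    preferred: str
    f_statistic: float
    f_pvalue: float
    exact_fit: bool = False
    caveat: Optional[str] = None

    def to_row(self) -> dict:
        row = {
            "series_id": self.series_id,
            "preferred": self.preferred,
            "delta_aic": self.delta_aic,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
        }
        for kind, fit in self.fits.items():
            row[f"aic_{kind}"] = fit.aic
            row[f"r2_{kind}"] = fit.r_squared
            row[f"weight_{kind}"] = self.akaike_weights[kind]
        if self.caveat:
            row["caveat"] = self.caveat
        return row


def _akaike_weights(aics: Dict[str, float]) -> Dict[str, float]:
    values = np.array(list(aics.values()))
    finite = values[np.isfinite(values)]
    if len(finite) == 0:
        # all exact fits: split evenly
        return {k: 1.0 / len(aics) for k in aics}
    amin = values.min()
    if amin == -np.inf:
        # exact fits dominate completely
        exact = [k for k, v in aics.items() if v == -np.inf]
        return {k: (1.0 / len(exact) if v == -np.inf else 0.0) for k, v in aics.items()}
    rel = np.exp(-(values - amin) / 2.0)
    rel /= rel.sum()
    return dict(zip(aics.keys(), rel))


def regression_f_test(fit: FitResult, series: ResponseSeries) -> Tuple[float, float, bool]:
    """F-test of the fitted model against the intercept-only model.

    ``F = [(TSS - RSS)/(k_model - 1)] / [RSS/(n - k_model)]`` on the model's
    own fitting scale, referred to an F(k_model-1, n-k_model) distribution.
    Returns ``(f_statistic, p_value, exact_fit)``; an exact fit (zero
    residual variance) reports the limiting ``p = 0`` with the flag set.
    """
    if not fit.converged:
        raise ValidationError("F-test requires a converged fit")
    n, k_model = fit.n, fit.k_model
    if n <= k_model:
        raise ValidationError("F-test requires n > k_model")
    target = np.log(series.y) if fit.model_kind in _LN_SCALE else series.y
    tss = float(np.sum((target - target.mean()) ** 2))
    rss = fit.rss
    df1, df2 = k_model - 1, n - k_model
    if rss <= max(tss, 1.0) * 1e-14:
        return np.inf, 0.0, True
    f_stat = ((tss - rss) / df1) / (rss / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), p, False


def compare_models(
    series: ResponseSeries, kinds: Iterable[str], seed: int = 0
) -> ModelComparison:
    """Fit each requested family to the series and rank them by AIC.

    Akaike weights are ``w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)``.
    The preferred model has minimal AIC; ties within ``AIC_TIE_TOL`` go to the
    family with fewer parameters.  Any non-converged member fit is kept and
    flagged in ``caveat`` rather than dropped.
    """
    kinds = list(dict.fromkeys(kinds))
    if len(kinds) < 2:
        raise ValidationError("model comparison requires at least two model kinds")
    unknown = [k for k in kinds if k not in MODEL_KINDS]
    if unknown:
        raise ValidationError(f"unknown model kinds {unknown}; expected subset of {MODEL_KINDS}")
    kindset = set(kinds)
    if not (kindset <= _RAW_SCALE or kindset <= _LN_SCALE):
        raise ValidationError(
            "cannot compare models fitted on different scales: "
            f"{sorted(kindset & _RAW_SCALE)} use raw y, "
            f"{sorted(kindset & _LN_SCALE)} use ln y"
        )

    fits = {kind: fit_model(series, kind, seed=seed) for kind in kinds}
    aics = {kind: fit.aic for kind, fit in fits.items()}
    weights = _akaike_weights(aics)

    aic_min = min(aics.values())
    # the equality branch covers exact fits, where aic_min is -inf
    tied = [k for k, a in aics.items() if a == aic_min or a - aic_min <= AIC_TIE_TOL]
    preferred = min(tied, key=lambda k: (fits[k].k_model, k))

    if kindset == {"exponential", "linear"}:
        delta = aics["linear"] - aics["exponential"]
    elif kindset == {"resource_response_full", "resource_response_reduced"}:
        delta = aics["resource_response_full"] - aics["resource_response_reduced"]
    else:
        ranked = sorted(aics.values())
        delta = ranked[1] - ranked[0]

    caveat = None
    bad = [k for k, f in fits.items() if not f.converged]
    if bad:
        caveat = f"non-converged fits: {', '.join(sorted(bad))}"

    f_stat, f_p, exact = regression_f_test(fits[preferred], series) if fits[
        preferred
    ].converged else (np.nan, np.nan, False)

    return ModelComparison(
        series_id=series.series_id,
        fits=fits,
        delta_aic=float(delta),
        akaike_weights=weights,
        preferred=preferred,
        f_statistic=f_stat,
        f_pvalue=f_p,
        exact_fit=exact,
        caveat=caveat,
    )
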