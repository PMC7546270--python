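"""Published ground-truth parameter presets for the synthetic-data generator.

Two preset families mirror the reference fits reported for the enzyme-driven
model on digitized literature data:

* ``enzyme/...`` — exponential enzyme-law parameters ``(alpha, b)`` for 13
  enzyme–photosynthesis series across wheat, rice, maize and sorghum, with
  the reported standard errors and R² kept as provenance metadata.
* ``nitrogen/...`` — reduced nitrogen-law parameters ``(ln_P_max, Kp)`` for
  7 species × CO2 partial-pressure combinations at 36 and 100 Pa (baseline
  ``ln_P0`` fixed at 0, offset ``R0 = 0``).

Preset names are addressable as ``family/species/label`` and drive
:func:`leafedm.synthetic_data.gen_study_suite`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

from .core_model import ExponentialParams, ResourceResponseParams

__all__ = ["EnzymePreset", "NitrogenPreset", "ENZYME_PRESETS", "NITROGEN_PRESETS", "get_preset"]


@dataclass(frozen=True)
class EnzymePreset:
    name: str
    species: str
    pathway: str
    enzyme: str
    params: ExponentialParams
    se_alpha: float
    se_b: float
    r_squared: float


@dataclass(frozen=True)
class NitrogenPreset:
    name: str
    species: str
    pathway: str
    co2_partial_pressure_Pa: float
    params: ResourceResponseParams
    r_squared: float


def _enz(species: str, pathway: str, enzyme: str, alpha: float, se_a: float, b: float, se_b: float, r2: float) -> EnzymePreset:
    return EnzymePreset(
        name=f"enzyme/{species.replace(' ', '_')}/{enzyme}",
        species=species,
        pathway=pathway,
        enzyme=enzyme,
        params=ExponentialParams(alpha=alpha, b=b),
        se_alpha=se_a,
        se_b=se_b,
        r_squared=r2,
    )


def _nit(species: str, pathway: str, co2: float, ln_p_max: float, kp: float, r2: float) -> NitrogenPreset:
    return NitrogenPreset(
        name=f"nitrogen/{species.replace(' ', '_')}/{co2:g}Pa",
        species=species,
        pathway=pathway,
        co2_partial_pressure_Pa=co2,
        params=ResourceResponseParams(ln_P_max=ln_p_max, Kp=kp, R0=0.0, ln_P0=0.0, reduced=True),
        r_squared=r2,
    )


_ENZYME_LIST = [
    # Triticum aestivum (wheat), C3 Calvin-cycle enzymes
    _enz("Triticum aestivum", "C3", "NADP-G3PDH", 17.34, 2.04, 0.0026, 0.0003, 0.85),
    _enz("Triticum aestivum", "C3", "PGA-kinase", 16.36, 1.59, 0.0023, 0.0001, 0.98),
    _enz("Triticum aestivum", "C3", "cpFBPase", 17.37, 0.906, 0.0203, 0.0010, 0.98),
    _enz("Triticum aestivum", "C3", "Rubisco", 17.33, 2.17, 0.0137, 0.0019, 0.91),
    # Oryza sativa (rice), C3
    _enz("Oryza sativa", "C3", "NADP-G3PDH", 13.77, 2.02, 0.0029, 0.0004, 0.92),
    _enz("Oryza sativa", "C3", "PGA-kinase", 15.95, 0.65, 0.0020, 0.00009, 0.99),
    _enz("Oryza sativa", "C3", "cpFBPase", 11.66, 2.45, 0.0336, 0.00536, 0.92),
    _enz("Oryza sativa", "C3", "Rubisco", 16.78, 1.21, 0.0159, 0.00157, 0.92),
    # Zea mays (maize), C4 cycle enzymes
    _enz("Zea mays", "C4", "NADP-ME", 27.78, 1.73, 0.0033, 0.00057, 0.82),
    _enz("Zea mays", "C4", "PCK", 30.87, 0.79, 0.017, 0.00215, 0.83),
    _enz("Zea mays", "C4", "Rubisco", 24.80, 1.66, 0.013, 0.002, 0.85),
    # Sorghum bicolor, C4
    _enz("Sorghum bicolor", "C4", "Rubisco", 13.09, 1.04, 0.0406, 0.00508, 0.87),
    _enz("Sorghum bicolor", "C4", "PEPC", 15.94, 0.62, 0.0036, 0.000297, 0.95),
]

_NITROGEN_LIST = [
    # current CO2 partial pressure (36 Pa)
    _nit("Zea mays", "C4", 36.0, 4.72, 29.19, 0.96),
    _nit("Oryza sativa", "C3", 36.0, 4.58, 46.83, 0.97),
    _nit("Spinacia oleracea", "C3", 36.0, 4.15, 32.40, 0.99),
    _nit("Phaseolus vulgaris", "C3", 36.0, 3.98, 31.87, 0.96),
    # elevated CO2 partial pressure (100 Pa)
    _nit("Zea mays", "C4", 100.0, 5.31, 51.63, 0.96),
    _nit("anti-rbcS 77", "C3", 100.0, 4.73, 28.45, 0.97),
    _nit("Oryza sativa", "C3", 100.0, 4.45, 32.35, 0.99),
]

ENZYME_PRESETS: Dict[str, EnzymePreset] = {p.name: p for p in _ENZYME_LIST}
NITROGEN_PRESETS: Dict[str, NitrogenPreset] = {p.name: p for p in _NITROGEN_LIST}


def get_preset(name: str):
    """Look up a preset by its ``family/species/label`` name."""
    if name in ENZYME_PRESETS:
        return ENZYME_PRESETS[name]
    if name in NITROGEN_PRESETS:
        return NITROGEN_PRESETS[name]
    known = sorted(ENZYME_PRESETS) + sorted(NITROGEN_PRESETS)
    raise KeyError(f"unknown preset {name!r}; available: {known}")
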