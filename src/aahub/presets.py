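"""Published parameter presets for the three αα-hub domains.

Stability parameters (chemical, thermal, and two-dimensional global
analyses) and binding thermodynamics for the Arabidopsis TAF4 RST domain,
the Arabidopsis RCD1 RST domain, and the human TAF4 TAFH domain.  These
drive the synthetic-data defaults and the worked examples; temperatures are
stored in kelvin.
"""

from __future__ import annotations

from .constants import celsius_to_kelvin
from .itc import ITCModel
from .stability import ChemicalModelParams, StabilityParams2D, ThermalModelParams

__all__ = ["STABILITY_PRESETS", "ITC_PRESETS", "stability_preset", "itc_preset"]

STABILITY_PRESETS: dict[str, dict] = {
    "AtTAF4-RST": {
        "chemical": ChemicalModelParams(dG=7.0, m=3.7),
        "thermal": ThermalModelParams(dHvH=46.0, Tm=celsius_to_kelvin(68.0)),
        "twod": StabilityParams2D(
            Tm=celsius_to_kelvin(66.0), dHm=117.0, dCp=3.1, m0=3.4
        ),
        "dG_298": 5.9,
    },
    "AtRCD1-RST": {
        "chemical": ChemicalModelParams(dG=7.0, m=2.7),
        "thermal": ThermalModelParams(dHvH=54.8, Tm=celsius_to_kelvin(68.8)),
        "twod": StabilityParams2D(
            Tm=celsius_to_kelvin(59.0), dHm=118.0, dCp=1.8, m0=3.8
        ),
        "dG_298": 8.8,
    },
    "HsTAF4-TAFH": {
        "chemical": ChemicalModelParams(dG=13.2, m=5.5),
        "thermal": ThermalModelParams(dHvH=55.0, Tm=celsius_to_kelvin(74.1)),
        "twod": StabilityParams2D(
            Tm=celsius_to_kelvin(71.0), dHm=167.0, dCp=3.4, m0=4.1
        ),
        "dG_298": 12.9,
    },
}

#: Binding thermodynamics: (domain/ligand, temperature °C) → model + printed ΔG/−TΔS.
ITC_PRESETS: dict[str, dict] = {
    "AtTAF4-RST/DREB2A@25C": {
        "model": ITCModel(Kd=740e-9, N=1.24, dH=-5.19),
        "T": celsius_to_kelvin(25.0),
        "dG": -35.0,
        "minus_TdS": -29.8,
    },
    "AtTAF4-RST/DREB2A@30C": {
        "model": ITCModel(Kd=1050e-9, N=1.18, dH=-10.5),
        "T": celsius_to_kelvin(30.0),
        "dG": -34.7,
        "minus_TdS": -24.2,
    },
    "AtRCD1-RST/DREB2A@25C": {
        "model": ITCModel(Kd=16e-9, N=0.90, dH=-63.3),
        "T": celsius_to_kelvin(25.0),
        "dG": -44.6,
        "minus_TdS": 18.7,
    },
    "HsTAF4-TAFH/DREB2A@25C": {
        "model": ITCModel(Kd=110e-9, N=1.15, dH=-15.4),
        "T": celsius_to_kelvin(25.0),
        "dG": -39.5,
        "minus_TdS": -24.1,
    },
    "AtTAF4-RST/ANAC013@30C": {
        "model": ITCModel(Kd=1080e-9, N=0.68, dH=-1.8),
        "T": celsius_to_kelvin(30.0),
        "dG": -34.5,
        "minus_TdS": -32.7,
    },
}


def stability_preset(name: str) -> dict:
    """Stability parameter set for a named domain."""
    try:
        return STABILITY_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(STABILITY_PRESETS)}"
        ) from None


def itc_preset(name: str) -> dict:
    """Binding parameter set for a named domain/ligand/temperature."""
    try:
        return ITC_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(ITC_PRESETS)}") from None
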