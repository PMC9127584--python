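"""Closed-form two-state unfolding models.

A two-state (native ⇌ denatured) protein at equilibrium populates the
denatured state according to the Boltzmann factor of the unfolding free
energy ΔG_DN.  The models here describe ΔG_DN as a function of temperature
and denaturant concentration and map it onto spectroscopic observables via
state baselines:

* chemical denaturation at fixed T: linear extrapolation,
  ΔG(c) = ΔG − m·c, with baselines linear in denaturant;
* thermal denaturation: van't Hoff, ΔG(T) = ΔH_vH·(1 − T/Tm), with
  polynomial baselines in temperature;
* the full stability surface combining both axes (Gibbs–Helmholtz with a
  heat-capacity term and a temperature-dependent m-value polynomial),

      ΔG(T, x) = ΔHm·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm))
                 − x·(m0 + m1·T + m2·T²)

The fraction unfolded is fU = exp(−ΔG/RT) / (1 + exp(−ΔG/RT)), so ΔG > 0
means a predominantly folded protein, fU(Tm, 0) = 1/2, and Cm = ΔG/m is the
denaturant midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import R

__all__ = [
    "StabilityParams2D",
    "ChemicalModelParams",
    "ThermalModelParams",
    "delta_g_surface",
    "fraction_unfolded",
    "observable_2d",
    "observable_chemical",
    "observable_thermal",
    "cm_value",
    "vant_hoff_ratio",
    "equal_unfolding_window",
]


def _poly_t(coeffs, T):
    """Evaluate a low-order polynomial with coefficients (a, b, c, ...) at T."""
    out = np.zeros_like(np.asarray(T, dtype=float))
    for k, c in enumerate(coeffs):
        out = out + c * np.asarray(T, dtype=float) ** k
    return out


@dataclass(frozen=True)
class StabilityParams2D:
    """Parameters of the two-dimensional stability surface ΔG(T, x).

    Attributes
    ----------
    Tm : float
        Midpoint temperature at zero denaturant, kelvin.
    dHm : float
        Unfolding enthalpy at Tm, kJ mol⁻¹.
    dCp : float
        Unfolding heat capacity change, kJ mol⁻¹ K⁻¹.
    m0, m1, m2 : float
        Coefficients of the m-value polynomial m(T) = m0 + m1·T + m2·T²
        (kJ mol⁻¹ M⁻¹, per K, per K²); T in kelvin.  m1 and m2 default to
        zero — a temperature-dependent m-value is rarely identifiable on
        small grids.
    """

    Tm: float
    dHm: float
    dCp: float = 0.0
    m0: float = 0.0
    m1: float = 0.0
    m2: float = 0.0

    def __post_init__(self):
        if not self.Tm > 0:
            raise ValueError(f"Tm must be positive kelvin, got {self.Tm}")
        if not np.isfinite(self.dHm):
            raise ValueError("dHm must be finite")

    def m_eff(self, T):
        """Effective m-value m(T) = m0 + m1·T + m2·T² at T (kelvin)."""
        return self.m0 + self.m1 * T + self.m2 * T**2


@dataclass(frozen=True)
class ChemicalModelParams:
    """Linear-extrapolation chemical denaturation model at fixed temperature.

    baselineN / baselineD are (intercept, slope) pairs in denaturant
    concentration: y_state(c) = a + b·c.
    """

    dG: float
    m: float
    baselineN: tuple[float, float] = (0.0, 0.0)
    baselineD: tuple[float, float] = (1.0, 0.0)

    @property
    def cm(self) -> float:
        return cm_value(self.dG, self.m)


@dataclass(frozen=True)
class ThermalModelParams:
    """Van't Hoff thermal denaturation model.

    Baselines are polynomial coefficient tuples in kelvin, lowest order
    first, degree ≤ 2.
    """

    dHvH: float
    Tm: float
    baselineN: tuple[float, ...] = (0.0,)
    baselineD: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        if not self.Tm > 0:
            raise ValueError(f"Tm must be positive kelvin, got {self.Tm}")
        if len(self.baselineN) > 3 or len(self.baselineD) > 3:
            raise ValueError("baselines are at most quadratic in T")


def _check_T(T):
    if np.any(np.asarray(T) <= 0):
        raise ValueError("temperature must be positive kelvin")


def delta_g_surface(params: StabilityParams2D, T, x=0.0):
    """Unfolding free energy ΔG_DN(T, x) in kJ mol⁻¹.

    Gibbs–Helmholtz in temperature, linear extrapolation in denaturant with
    a polynomial m(T).  Exactly zero at (T=Tm, x=0).

    Parameters
    ----------
    T : kelvin (scalar or array)
    x : molar denaturant (scalar or array), ≥ 0
    """
    _check_T(T)
    if np.any(np.asarray(x) < 0):
        raise ValueError("denaturant concentration must be non-negative")
    T = np.asarray(T, dtype=float)
    x = np.asarray(x, dtype=float)
    dg = (
        params.dHm * (1.0 - T / params.Tm)
        + params.dCp * (T - params.Tm - T * np.log(T / params.Tm))
        - x * params.m_eff(T)
    )
    return dg if dg.ndim else float(dg)


def _boltzmann_fu(dg, T):
    """Two-state unfolded population from ΔG (kJ mol⁻¹) at T (K)."""
    # logistic form is overflow-safe for both signs of ΔG
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(np.asarray(dg, dtype=float) / (R * np.asarray(T, dtype=float))))


def fraction_unfolded(params: StabilityParams2D, T, x=0.0):
    """Fraction of molecules unfolded, fU ∈ (0, 1); fU(Tm, 0) = 1/2."""
    fu = _boltzmann_fu(delta_g_surface(params, T, x), T)
    return fu if np.ndim(fu) else float(fu)


def observable_2d(params: StabilityParams2D, baselines: ThermalModelParams | tuple, T, x=0.0):
    """Spectroscopic observable over the (T, x) surface.

    y = yN(T) + (yD(T) − yN(T))·fU(T, x), with baselines polynomial in T
    only (denaturant-independent).  ``baselines`` may be a
    :class:`ThermalModelParams` (its baselines are used) or a
    ``(coeffsN, coeffsD)`` pair.
    """
    if isinstance(baselines, ThermalModelParams):
        bn, bd = baselines.baselineN, baselines.baselineD
    else:
        bn, bd = baselines
    fu = fraction_unfolded(params, T, x)
    yn = _poly_t(bn, T)
    yd = _poly_t(bd, T)
    y = yn + (yd - yn) * fu
    return y if np.ndim(y) else float(y)


def observable_chemical(params: ChemicalModelParams, T, c):
    """Chemical denaturation observable at denaturant concentration c (M).

    Linear-extrapolation two-state sigmoid between linear baselines;
    midpoint at Cm = ΔG/m.  ``m <= 0`` describes no cooperative unfolding
    transition and raises.
    """
    _check_T(T)
    if np.any(np.asarray(c) < 0):
        raise ValueError("denaturant concentration must be non-negative")
    if params.m <= 0:
        raise ValueError("non-cooperative model: m must be > 0 for an unfolding transition")
    c = np.asarray(c, dtype=float)
    dg = params.dG - params.m * c
    fu = _boltzmann_fu(dg, T)
    yn = params.baselineN[0] + params.baselineN[1] * c
    yd = params.baselineD[0] + params.baselineD[1] * c
    y = yn + (yd - yn) * fu
    return y if np.ndim(y) else float(y)


def observable_thermal(params: ThermalModelParams, T):
    """Thermal denaturation observable; ΔG(T) = ΔH_vH·(1 − T/Tm)."""
    _check_T(T)
    T = np.asarray(T, dtype=float)
    dg = params.dHvH * (1.0 - T / params.Tm)
    fu = _boltzmann_fu(dg, T)
    yn = _poly_t(params.baselineN, T)
    yd = _poly_t(params.baselineD, T)
    y = yn + (yd - yn) * fu
    return y if y.ndim else float(y)


def cm_value(dG: float, m: float) -> float:
    """Denaturant midpoint Cm = ΔG/m (M)."""
    if m == 0:
        raise ValueError("Cm undefined for m = 0")
    return dG / m


def vant_hoff_ratio(dHvH: float, dHm: float, threshold: float = 0.8) -> tuple[float, bool]:
    """Ratio ΔH_vH/ΔHm and an incomplete-unfolding flag.

    A van't Hoff enthalpy (from the sharpness of a single thermal
    transition) well below the enthalpy of the global analysis indicates
    the thermal transition does not reach a fully unfolded state.  Returns
    ``(ratio, flagged)`` with ``flagged = ratio < threshold``.
    """
    if dHm == 0:
        raise ValueError("ratio undefined for dHm = 0")
    ratio = dHvH / dHm
    return ratio, bool(ratio < threshold)


def equal_unfolding_window(
    params: StabilityParams2D,
    f_low: float,
    f_high: float,
    x: float = 0.0,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Temperatures at which the unfolded fraction equals f_low and f_high.

    Solves fU(T, x) = f by bracketing/bisection on the heat-denaturation
    branch of [273.15, Tm + 50].  With ΔCp > 0 the stability curve has a
    maximum (cold denaturation below it), so the search starts at the
    temperature of maximum stability rather than at the interval edge.
    Useful for choosing temperature windows that probe the same degree of
    unfolding in different proteins.
    """
    if not (0 < f_low < f_high < 1):
        raise ValueError("require 0 < f_low < f_high < 1")
    t_max = params.Tm + 50.0
    grid = np.linspace(273.15, t_max, 4001)
    fu_grid = fraction_unfolded(params, grid, x)
    t_min = grid[int(np.argmin(fu_grid))]

    def solve(f_target):
        def g(T):
            return fraction_unfolded(params, T, x) - f_target

        if g(t_min) > 0 or g(t_max) < 0:
            raise ValueError(
                f"target fraction {f_target} not attainable on the heat branch "
                f"[{t_min:.2f}, {t_max:.2f}] K (minimum fU = {fu_grid.min():.4f})"
            )
        return brentq(g, t_min, t_max, xtol=tol)

    return solve(f_low), solve(f_high)
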