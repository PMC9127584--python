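"""One-set-of-sites ITC isotherm simulation, fitting and thermodynamics.

An isothermal titration calorimetry experiment injects a titrant (syringe
species X) into a cell containing the titrand (M).  For a single class of N
independent sites with dissociation constant Kd, the bound-complex
concentration after each injection follows from mass balance,

    MX = ((S + X + Kd) − sqrt((S + X + Kd)² − 4·S·X)) / 2,   S = N·M,

the physical root of the binding quadratic.  The perfusion cell has fixed
volume: each injection displaces an equal volume of the current mixture, so
both species are diluted cumulatively.  The heat of injection i is the
enthalpy of the net complex formed,

    q_i = ΔH·V0·(MX_i − MX_{i−1}·(1 − v_i/V0)),

i.e. the displaced complex leaves athermally and is not re-counted.  This
convention makes the stoichiometric-titration limit release exactly ΔH per
mole of injectant pre-saturation, and the dilution-corrected total heat
converge to N·ΔH·V0·M0 at saturating titrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R

__all__ = [
    "ITCExperiment",
    "ITCModel",
    "ThermoDecomposition",
    "simulate_isotherm",
    "fit_itc",
    "decompose_thermo",
]


@dataclass(frozen=True)
class ITCExperiment:
    """Titration geometry: cell/syringe concentrations and injection schedule.

    Volumes in litres, concentrations molar, temperature kelvin.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple
    temperature: float = 298.15

    def __post_init__(self):
        if min(self.cell_volume, self.cell_conc, self.syringe_conc) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        vols = tuple(float(v) for v in self.injection_volumes)
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be positive")
        object.__setattr__(self, "injection_volumes", vols)
        if sum(vols) > 0.3 * self.cell_volume:
            warnings.warn(
                "cumulative injected volume exceeds 30% of the cell volume; "
                "the displacement-dilution model becomes inaccurate",
                stacklevel=2,
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass(frozen=True)
class ITCModel:
    """One-set-of-sites binding parameters."""

    Kd: float
    N: float
    dH: float
    q_dil: float = 0.0

    def __post_init__(self):
        if self.Kd <= 0 or self.N <= 0:
            raise ValueError("Kd and N must be positive")

    def c_value(self, cell_conc: float) -> float:
        """Wiseman c = N·[cell]/Kd, governing isotherm shape."""
        return self.N * cell_conc / self.Kd


@dataclass(frozen=True)
class ThermoDecomposition:
    """Binding free energy split into enthalpic and entropic parts.

    dG = R·T·ln(Kd) = dH + minus_TdS exactly (all kJ mol⁻¹).
    """

    dG: float
    dH: float
    minus_TdS: float
    Kd: float
    T: float


def _bound_complex(s_tot: float, x_tot: float, kd: float) -> float:
    """Physical root of MX² − (S+X+Kd)·MX + S·X = 0."""
    b = s_tot + x_tot + kd
    disc = b * b - 4.0 * s_tot * x_tot
    # conjugate form avoids cancellation when 4SX << b²
    return 2.0 * s_tot * x_tot / (b + np.sqrt(max(disc, 0.0)))


def simulate_isotherm(model: ITCModel, exp: ITCExperiment) -> np.ndarray:
    """Per-injection molar heats (kJ per mol of injectant).

    Cumulative displacement dilution of both species, quadratic-root mass
    balance per injection, heats differenced with the displaced-complex
    correction; ``q_dil`` is added to every injection.
    """
    v0 = exp.cell_volume
    m_tot = exp.cell_conc
    x_tot = 0.0
    mx_prev = 0.0
    heats = np.empty(exp.n_injections)
    for i, v in enumerate(exp.injection_volumes):
        d = 1.0 - v / v0
        m_tot *= d
        x_tot = x_tot * d + exp.syringe_conc * v / v0
        mx = _bound_complex(model.N * m_tot, x_tot, model.Kd)
        dq = model.dH * v0 * (mx - mx_prev * d)
        heats[i] = dq / (exp.syringe_conc * v) + model.q_dil
        mx_prev = mx
    return heats


def fit_itc(
    heats,
    exp: ITCExperiment,
    init: ITCModel | None = None,
    fit_q_dil: bool = False,
    discard_first: bool = False,
    n_starts: int = 10,
    seed: int = 0,
) -> "FitResult":
    """Least-squares fit of the one-set-of-sites model to a thermogram.

    ``heats`` are molar heats (kJ per mol injectant), one per injection in
    injection order.  Kd is optimized on a log scale.  Returns a
    :class:`aahub.fitting.FitResult` whose ``parameters`` is an
    :class:`ITCModel`; a Wiseman c-value outside [1, 1000] is reported in
    ``messages``.
    """
    from .fitting import FitResult, _covariance  # deferred: avoids cycle at import

    import pandas as pd

    if isinstance(heats, pd.DataFrame):
        # injection order is physically meaningful: reject shuffled tables
        idx = heats["injection"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValueError("injection indices must be strictly increasing")
        heats = heats["heat_kJ_per_mol"]
    heats = np.asarray(heats, dtype=float)
    if heats.ndim != 1 or heats.size != exp.n_injections:
        raise ValueError("one heat per injection, in injection order")
    if heats.size < 10:
        warnings.warn("fewer than 10 injections: transition poorly sampled", stacklevel=2)

    mask = np.ones(heats.size, dtype=bool)
    if discard_first:
        mask[0] = False

    if init is None:
        dh0 = float(heats[mask][0] - heats[mask][-1])
        dh0 = dh0 if abs(dh0) > 1e-6 else float(heats[mask][0])
        init = ITCModel(Kd=exp.cell_conc / 10.0, N=1.0, dH=dh0, q_dil=0.0)

    x0 = [np.log10(init.Kd), init.N, init.dH] + ([init.q_dil] if fit_q_dil else [])
    lo = [-12.0, 0.05, -500.0] + ([-50.0] if fit_q_dil else [])
    hi = [0.0, 10.0, 500.0] + ([50.0] if fit_q_dil else [])

    def unpack(p):
        return ITCModel(Kd=10.0 ** p[0], N=p[1], dH=p[2], q_dil=p[3] if fit_q_dil else 0.0)

    def residuals(p):
        return (simulate_isotherm(unpack(p), exp) - heats)[mask]

    from .fitting import _multistart

    sol = _multistart(residuals, x0, (lo, hi), n_starts, seed)
    model = unpack(sol.x)

    names = ["Kd", "N", "dH"] + (["q_dil"] if fit_q_dil else [])
    cov = _covariance(sol, int(mask.sum()))
    se = np.sqrt(np.abs(np.diag(cov)))
    # delta-method error for Kd from the log10-scale fit
    se = se.tolist()
    se[0] = se[0] * model.Kd * np.log(10.0)
    values = [model.Kd, model.N, model.dH] + ([model.q_dil] if fit_q_dil else [])

    messages = []
    c = model.c_value(exp.cell_conc)
    if not (1.0 <= c <= 1000.0):
        messages.append(f"c-value {c:.3g} outside [1, 1000]: Kd poorly identifiable")

    return FitResult(
        model_class="itc_one_site",
        parameters=model,
        values=dict(zip(names, values)),
        standard_errors=dict(zip(names, se)),
        covariance=cov,
        residual_norm=float(2.0 * sol.cost),
        n_points=int(mask.sum()),
        messages=messages,
        derived={"c_value": c},
    )


def decompose_thermo(Kd: float, dH: float, T: float = 298.15) -> ThermoDecomposition:
    """Thermodynamic decomposition of binding at temperature T.

    ΔG = R·T·ln(Kd/M) and −TΔS = ΔG − ΔH, so ΔG = ΔH + (−TΔS) holds by
    construction (all kJ mol⁻¹).
    """
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    dg = R * T * np.log(Kd)
    return ThermoDecomposition(dG=float(dg), dH=float(dH), minus_TdS=float(dg - dH), Kd=Kd, T=T)
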