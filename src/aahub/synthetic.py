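"""Seeded generators for every input class the pipeline consumes.

Each generator is a deterministic function of (ground truth, seed) and
returns data in the same containers the analysis functions accept, so
analysis ∘ generation round-trips recover the generating parameters.  The
default study conditions mirror the experiments being emulated: CD melts
from 20–90 °C at 1 °C pitch, urea titrations 0–8 M, fluorescence surfaces
over a temperature × urea grid in triplicate, a 20-injection titration with
27 µM cell / 277 µM syringe concentrations, and ¹H,¹⁵N peak lists at
25–55 °C in 5 °C steps.

Noise is homoscedastic Gaussian by default (``proportional=True`` switches
to signal-proportional noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin
from .fitting import DenaturationDataset
from .itc import ITCExperiment, ITCModel, simulate_isotherm
from .nmr import PeakList
from .stability import (
    ChemicalModelParams,
    StabilityParams2D,
    ThermalModelParams,
    fraction_unfolded,
    observable_2d,
    observable_chemical,
    observable_thermal,
)

__all__ = [
    "GroundTruth",
    "default_itc_experiment",
    "gen_thermal_curve",
    "gen_chemical_curve",
    "gen_2d_surface",
    "gen_itc",
    "gen_temperature_peaklists",
]


@dataclass(frozen=True)
class GroundTruth:
    """The generating parameter set attached to every synthetic dataset."""

    params: object
    baselines: tuple | None
    sigma: float
    seed: int


def _noise(rng, sigma, signal, proportional):
    if sigma == 0:
        return np.zeros_like(signal)
    scale = sigma * np.abs(signal) if proportional else sigma
    return rng.normal(0.0, 1.0, size=signal.shape) * scale


_DEFAULT_T_GRID = celsius_to_kelvin(np.arange(20.0, 91.0, 1.0))
_DEFAULT_C_GRID = np.linspace(0.0, 8.0, 25)


def gen_thermal_curve(
    truth: ThermalModelParams,
    T_grid=None,
    sigma: float = 0.0,
    seed: int = 0,
    proportional: bool = False,
) -> DenaturationDataset:
    """Thermal melt: van't Hoff observable plus Gaussian noise."""
    T = np.asarray(_DEFAULT_T_GRID if T_grid is None else T_grid, dtype=float)
    rng = np.random.default_rng(seed)
    y = observable_thermal(truth, T)
    ds = DenaturationDataset.from_arrays(
        T=T, x=0.0, signal=y + _noise(rng, sigma, y, proportional), modality="cd222"
    )
    ds.ground_truth = GroundTruth(truth, None, sigma, seed)
    return ds


def gen_chemical_curve(
    truth: ChemicalModelParams,
    T: float = 298.15,
    c_grid=None,
    sigma: float = 0.0,
    seed: int = 0,
    proportional: bool = False,
) -> DenaturationDataset:
    """Chemical (urea) titration at fixed temperature plus Gaussian noise."""
    c = np.asarray(_DEFAULT_C_GRID if c_grid is None else c_grid, dtype=float)
    rng = np.random.default_rng(seed)
    y = observable_chemical(truth, T, c)
    ds = DenaturationDataset.from_arrays(
        T=T, x=c, signal=y + _noise(rng, sigma, y, proportional), modality="cd222"
    )
    ds.ground_truth = GroundTruth(truth, None, sigma, seed)
    return ds


def gen_2d_surface(
    truth: StabilityParams2D,
    baselines: tuple = ((1.0, 0.0, 0.0), (0.2, -1e-4, 0.0)),
    T_grid=None,
    c_grid=None,
    sigma: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    proportional: bool = False,
) -> DenaturationDataset:
    """Temperature × denaturant fluorescence surface with replicates.

    Defaults: 6 urea series (0–8 M) × 30 temperatures spanning the thermal
    transition, three replicates with independent noise.
    """
    T = np.asarray(
        celsius_to_kelvin(np.linspace(20.0, 90.0, 30)) if T_grid is None else T_grid,
        dtype=float,
    )
    c = np.asarray(np.linspace(0.0, 8.0, 6) if c_grid is None else c_grid, dtype=float)
    if T.size == 0 or c.size == 0:
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    TT, CC = np.meshgrid(T, c, indexing="ij")
    y_clean = observable_2d(truth, baselines, TT.ravel(), CC.ravel())
    frames = []
    for r in range(n_replicates):
        frames.append(
            pd.DataFrame(
                {
                    "T": TT.ravel(),
                    "x": CC.ravel(),
                    "signal": y_clean + _noise(rng, sigma, y_clean, proportional),
                    "replicate": f"r{r + 1}",
                }
            )
        )
    ds = DenaturationDataset(pd.concat(frames, ignore_index=True), modality="fluorescence_ratio")
    ds.ground_truth = GroundTruth(truth, baselines, sigma, seed)
    return ds


def default_itc_experiment(
    n_injections: int = 20,
    injection_volume: float = 2e-6,
    temperature: float = 298.15,
) -> ITCExperiment:
    """The emulated titration geometry: 200 µl cell at 27 µM, 277 µM syringe."""
    return ITCExperiment(
        cell_volume=200e-6,
        cell_conc=27e-6,
        syringe_conc=277e-6,
        injection_volumes=(injection_volume,) * n_injections,
        temperature=temperature,
    )


def gen_itc(
    truth: ITCModel,
    exp: ITCExperiment | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Thermogram: simulated molar heats plus Gaussian noise of SD ``sigma``
    (kJ per mol injectant)."""
    if exp is None:
        exp = default_itc_experiment()
    rng = np.random.default_rng(seed)
    q = simulate_isotherm(truth, exp)
    return q + _noise(rng, sigma, q, proportional=False)


def gen_temperature_peaklists(
    stability: StabilityParams2D,
    n_residues: int = 60,
    sensitivities=None,
    temperatures=None,
    sigma_shift: float = 0.0,
    intensity_decay: float = 0.05,
    detection_floor: float = 0.05,
    shift_scale: float = 1.0,
    seed: int = 0,
) -> list[PeakList]:
    """¹H,¹⁵N peak lists along a temperature series.

    Each residue's peak drifts from its (seeded) random position in
    proportion to the change in unfolded fraction ΔfU(T) times the
    residue's sensitivity coefficient; intensities decay exponentially with
    temperature and peaks drop out of the list below ``detection_floor``.

    ``sensitivities`` maps residue→coefficient (ppm per unit fU along ¹H);
    default is 1.0 everywhere.  The associated ¹⁵N drift is 5× larger,
    mimicking the nucleus's wider shift dispersion.
    """
    temps = np.asarray(
        celsius_to_kelvin(np.arange(25.0, 56.0, 5.0)) if temperatures is None else temperatures,
        dtype=float,
    )
    residues = np.arange(1, n_residues + 1)
    sens = np.ones(n_residues)
    if sensitivities is not None:
        for res, val in dict(sensitivities).items():
            sens[res - 1] = val
    rng = np.random.default_rng(seed)
    dh0 = rng.uniform(6.5, 9.5, n_residues)
    dn0 = rng.uniform(105.0, 130.0, n_residues)
    i0 = rng.uniform(0.8, 1.2, n_residues)
    fu_ref = fraction_unfolded(stability, temps[0], 0.0)
    lists = []
    for t in temps:
        dfu = fraction_unfolded(stability, t, 0.0) - fu_ref
        drift = shift_scale * sens * dfu
        dh = dh0 + drift + _noise(rng, sigma_shift, dh0, False)
        dn = dn0 + 5.0 * drift + _noise(rng, sigma_shift, dn0, False)
        inten = i0 * np.exp(-intensity_decay * (t - temps[0]))
        df = pd.DataFrame(
            {
                "residue": residues,
                "res_type": "X",
                "dH_ppm": dh,
                "dN_ppm": dn,
                "intensity": inten,
            }
        )
        df = df[df["intensity"] >= detection_floor]
        lists.append(PeakList(condition=float(t), data=df))
    return lists
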