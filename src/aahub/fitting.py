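"""Nonlinear least-squares fitting of denaturation data.

Fits the two-state models of :mod:`aahub.stability` to chemical melts,
thermal melts, and two-dimensional (temperature × denaturant) surfaces, with
replicate aggregation and CD preprocessing helpers (high-tension-voltage
filtering, mean-residue ellipticity, helicity, m-value/ΔASA correlation).

The optimizer is trust-region least squares (`scipy.optimize.least_squares`)
with data-driven initial guesses and seeded multistart jitter; parameter
standard errors come from the Jacobian-based covariance at the optimum, but
the headline uncertainty for replicated experiments is the across-replicate
standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import R, CAL_TO_J
from .stability import (
    ChemicalModelParams,
    StabilityParams2D,
    ThermalModelParams,
    cm_value,
    delta_g_surface,
    observable_2d,
    observable_chemical,
    observable_thermal,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DenaturationDataset",
    "FitResult",
    "ht_filter",
    "fit_chemical",
    "fit_thermal",
    "fit_global_2d",
    "aggregate_replicates",
    "mre_from_ellipticity",
    "helicity_from_mre222",
    "m_to_structural_extent",
    "structural_extent_from_m",
]

_COLUMNS = ["T", "x", "signal", "ht_voltage", "replicate"]


@dataclass
class DenaturationDataset:
    """Observed signal over a (temperature, denaturant) domain.

    ``data`` columns: T (kelvin), x (molar denaturant), signal, ht_voltage
    (volts, NaN when not recorded), replicate (label).
    """

    data: pd.DataFrame
    modality: str = "other"

    def __post_init__(self):
        df = self.data.copy()
        if "ht_voltage" not in df.columns:
            df["ht_voltage"] = np.nan
        if "replicate" not in df.columns:
            df["replicate"] = "r1"
        missing = {"T", "x", "signal"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if (df["T"] < 0).any() or (df["x"] < 0).any():
            raise ValueError("T and x must be non-negative")
        if df.duplicated(subset=["T", "x", "replicate"]).any():
            raise ValueError("duplicated (T, x, replicate) keys")
        self.data = df[_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_arrays(cls, T, x, signal, ht_voltage=None, replicate=None, modality="other"):
        n = len(np.atleast_1d(signal))
        df = pd.DataFrame(
            {
                "T": np.broadcast_to(np.asarray(T, dtype=float), (n,)).copy(),
                "x": np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy(),
                "signal": np.asarray(signal, dtype=float),
                "ht_voltage": (
                    np.full(n, np.nan) if ht_voltage is None else np.asarray(ht_voltage, dtype=float)
                ),
                "replicate": (
                    ["r1"] * n if replicate is None else list(np.broadcast_to(replicate, (n,)))
                ),
            }
        )
        return cls(df, modality=modality)

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())

    def subset(self, replicate) -> "DenaturationDataset":
        return DenaturationDataset(
            self.data[self.data["replicate"] == replicate].reset_index(drop=True),
            modality=self.modality,
        )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and replicate aggregation."""

    model_class: str
    parameters: object
    values: dict
    standard_errors: dict
    covariance: np.ndarray | None
    residual_norm: float
    n_points: int
    replicate_values: list = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    messages: list = field(default_factory=list)
    derived: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return not any("non-convergence" in m for m in self.messages)


def ht_filter(dataset: DenaturationDataset, threshold: float = 600.0) -> DenaturationDataset:
    """Drop points whose high-tension voltage exceeds ``threshold`` (volts).

    The photomultiplier HT voltage is a data-quality proxy: above the
    instrument ceiling (600 V by default) the ellipticity is unreliable.
    Points without a recorded voltage are retained.
    """
    df = dataset.data
    keep = ~(df["ht_voltage"] > threshold)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("ht_filter removed %d of %d points above %.0f V", n_removed, len(df), threshold)
    return DenaturationDataset(df[keep].reset_index(drop=True), modality=dataset.modality)


# ---------------------------------------------------------------------------
# optimizer machinery

def _multistart(residual_fn, x0, bounds, n_starts, seed, jitter=0.2, ftol=1e-10):
    """Trust-region least squares from jittered starts; best solution wins."""
    rng = np.random.default_rng(seed)
    lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
    best = None
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        trial = x0 * (1.0 + jitter * rng.uniform(-1, 1, size=x0.size))
        trial += jitter * rng.uniform(-1, 1, size=x0.size) * (x0 == 0)
        starts.append(np.clip(trial, lo, hi))
    for start in starts:
        try:
            sol = least_squares(residual_fn, start, bounds=(lo, hi), ftol=ftol, xtol=1e-12)
        except Exception:  # singular model at this start; try the next
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("non-convergence: no multistart reached an optimum")
    return best


def _covariance(sol, n_points):
    """Jacobian-based parameter covariance at the optimum."""
    _, s, vt = np.linalg.svd(sol.jac, full_matrices=False)
    threshold = np.finfo(float).eps * max(sol.jac.shape) * s[0]
    s = s[s > threshold]
    vt = vt[: s.size]
    dof = max(n_points - sol.x.size, 1)
    s_sq = 2.0 * sol.cost / dof
    cov = (vt.T / s**2) @ vt * s_sq
    if vt.shape[0] < sol.x.size:  # rank-deficient: undetermined directions
        cov = np.full((sol.x.size, sol.x.size), np.nan)
    return cov


def _finish(model_class, params_obj, names, sol, n_points, messages=(), derived=None):
    cov = _covariance(sol, n_points)
    se = np.sqrt(np.abs(np.diag(cov))) if np.all(np.isfinite(cov)) else np.full(len(names), np.nan)
    return FitResult(
        model_class=model_class,
        parameters=params_obj,
        values=dict(zip(names, sol.x.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        covariance=cov,
        residual_norm=float(2.0 * sol.cost),
        n_points=n_points,
        messages=list(messages),
        derived=derived or {},
    )


def _with_replicates(dataset, fit_one, result):
    """Fit each replicate separately and attach mean ± SD aggregation."""
    reps = dataset.replicates
    if len(reps) >= 2:
        rep_results = []
        for rep in reps:
            try:
                rep_results.append(fit_one(dataset.subset(rep)))
            except RuntimeError as err:
                result.messages.append(f"replicate {rep}: {err}")
        if len(rep_results) >= 2:
            agg = aggregate_replicates(rep_results)
            result.replicate_values = agg.replicate_values
            result.aggregate = agg.aggregate
    return result


# ---------------------------------------------------------------------------
# chemical denaturation (linear extrapolation)

def _init_chemical(c, y, T):
    """Data-driven start: baselines from terminal 10 % of the c-axis,
    midpoint from the half-signal crossing."""
    order = np.argsort(c)
    c, y = c[order], y[order]
    k = max(2, len(c) // 10)
    lo_c, lo_y = c[:k], y[:k]
    hi_c, hi_y = c[-k:], y[-k:]
    bn = np.polyfit(lo_c, lo_y, 1)[::-1] if len(set(lo_c)) > 1 else (lo_y.mean(), 0.0)
    bd = np.polyfit(hi_c, hi_y, 1)[::-1] if len(set(hi_c)) > 1 else (hi_y.mean(), 0.0)
    mid = 0.5 * (lo_y.mean() + hi_y.mean())
    crossings = np.nonzero(np.diff(np.sign(y - mid)))[0]
    cm_guess = c[crossings[0]] if crossings.size else float(np.median(c))
    m_guess = 3.0
    return [m_guess * max(cm_guess, 0.1), m_guess, bn[0], bn[1], bd[0], bd[1]]


def fit_chemical(
    dataset: DenaturationDataset,
    T: float,
    init=None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit a chemical denaturation curve (signal vs denaturant at fixed T).

    Estimates ΔG, m and linear native/denatured baselines; reports Cm = ΔG/m
    in ``derived``.
    """

    def fit_one(ds):
        df = ds.data
        c, y = df["x"].to_numpy(), df["signal"].to_numpy()
        if len(c) < 8:
            raise ValueError("need at least 8 points spanning the transition")
        x0 = list(init) if init is not None else _init_chemical(c, y, T)
        scale = max(np.ptp(y), 1.0)
        bounds = ([-100.0, 1e-3, -np.inf, -np.inf, -np.inf, -np.inf],
                  [200.0, 50.0, np.inf, np.inf, np.inf, np.inf])

        def residuals(p):
            params = ChemicalModelParams(p[0], p[1], (p[2], p[3]), (p[4], p[5]))
            return observable_chemical(params, T, c) - y

        sol = _multistart(residuals, x0, bounds, n_starts, seed)
        names = ["dG", "m", "aN", "bN", "aD", "bD"]
        p = sol.x
        params = ChemicalModelParams(p[0], p[1], (p[2], p[3]), (p[4], p[5]))
        messages = []
        cm = cm_value(p[0], p[1]) if p[1] > 0 else np.nan
        amplitude = abs((p[4] + p[5] * cm) - (p[2] + p[3] * cm)) if np.isfinite(cm) else 0.0
        if p[1] < 0.05 or not (c.min() <= cm <= c.max()) or amplitude < 0.1 * max(np.ptp(y), 1e-30):
            messages.append("no cooperative transition detected in the measured range")
        derived = {"Cm": cm, "T": T}
        return _finish("chemical", params, names, sol, len(c), messages, derived)

    result = fit_one(dataset)
    return _with_replicates(dataset, fit_one, result)


# ---------------------------------------------------------------------------
# thermal denaturation (van't Hoff)

def _init_thermal(T, y, baseline_degree):
    # collapse duplicate temperatures (replicates) so the gradient is defined
    grouped = pd.DataFrame({"T": T, "y": y}).groupby("T", sort=True)["y"].mean()
    T, y = grouped.index.to_numpy(), grouped.to_numpy()
    k = max(2, len(T) // 10)
    bn = np.polyfit(T[:k], y[:k], min(baseline_degree, k - 1))[::-1]
    bd = np.polyfit(T[-k:], y[-k:], min(baseline_degree, k - 1))[::-1]
    # Tm from the steepest smoothed gradient
    dy = np.gradient(pd.Series(y).rolling(3, center=True, min_periods=1).mean().to_numpy(), T)
    tm_guess = float(T[int(np.argmax(np.abs(dy)))])
    tm_guess = min(max(tm_guess, 280.0), 390.0)
    # transition width -> van't Hoff enthalpy: dfU/dT|Tm = dHvH / (4 R Tm^2)
    span = abs(np.polyval(bd[::-1], tm_guess) - np.polyval(bn[::-1], tm_guess))
    slope = np.max(np.abs(dy)) / max(span, 1e-12)
    dh_guess = float(np.clip(4.0 * R * tm_guess**2 * slope, 50.0, 800.0))
    return [dh_guess, tm_guess, *bn, *([0.0] * (baseline_degree + 1 - len(bn))),
            *bd, *([0.0] * (baseline_degree + 1 - len(bd)))]


def fit_thermal(
    dataset: DenaturationDataset,
    init=None,
    baseline_degree: int = 1,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit a thermal melt (signal vs temperature at zero denaturant).

    Estimates the van't Hoff enthalpy ΔH_vH, midpoint Tm, and polynomial
    baselines (linear by default, quadratic optional).
    """
    if baseline_degree not in (1, 2):
        raise ValueError("baseline_degree must be 1 or 2")
    nb = baseline_degree + 1

    def fit_one(ds):
        df = ds.data
        T, y = df["T"].to_numpy(), df["signal"].to_numpy()
        if len(T) < 8:
            raise ValueError("need at least 8 points spanning the transition")
        x0 = list(init) if init is not None else _init_thermal(T, y, baseline_degree)
        bounds = ([1.0, 274.0] + [-np.inf] * 2 * nb, [1000.0, 400.0] + [np.inf] * 2 * nb)

        def residuals(p):
            params = ThermalModelParams(p[0], p[1], tuple(p[2 : 2 + nb]), tuple(p[2 + nb :]))
            return observable_thermal(params, T) - y

        sol = _multistart(residuals, x0, bounds, n_starts, seed)
        p = sol.x
        names = (["dHvH", "Tm"] + [f"{c}N" for c in "abc"[:nb]] + [f"{c}D" for c in "abc"[:nb]])
        params = ThermalModelParams(p[0], p[1], tuple(p[2 : 2 + nb]), tuple(p[2 + nb :]))
        messages = []
        if p[1] > T.max():
            messages.append("Tm beyond measured range: identifiability limited")
        result = _finish("thermal", params, names, sol, len(T), messages)
        if np.isfinite(result.standard_errors.get("Tm", np.nan)) and result.standard_errors["Tm"] > 5.0:
            result.messages.append("wide standard errors: transition poorly determined")
        return result

    result = fit_one(dataset)
    return _with_replicates(dataset, fit_one, result)


# ---------------------------------------------------------------------------
# two-dimensional global fit

def _init_2d(T, x, y):
    """Start from the lowest-denaturant series for Tm/ΔHvH-style guesses."""
    x_levels = np.unique(x)
    mask = x == x_levels[0]
    base = _init_thermal(T[mask], y[mask], 2)
    dh, tm = base[0], base[1]
    bn, bd = base[2:5], base[5:8]
    return [tm, dh, 1.0, 3.0, *bn, *bd]


def fit_global_2d(
    dataset: DenaturationDataset,
    init=None,
    fit_m12: bool = False,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Global two-state fit over a temperature × denaturant surface.

    Simultaneously estimates Tm, ΔHm, ΔCp, the m-value polynomial (m0 only
    unless ``fit_m12``) and shared quadratic baselines in T.  ΔG at
    298.15 K / zero denaturant and Cm(298.15 K) are reported in ``derived``.
    """

    def fit_one(ds):
        df = ds.data
        T, x, y = df["T"].to_numpy(), df["x"].to_numpy(), df["signal"].to_numpy()
        if np.unique(x).size < 3:
            raise ValueError("need at least 3 denaturant series for a surface fit")
        x0 = list(init) if init is not None else _init_2d(T, x, y)
        if fit_m12 and len(x0) == 10:
            x0 = x0[:4] + [0.0, 0.0] + x0[4:]
        nm = 3 if fit_m12 else 1
        lo = [274.0, 1e-3, -10.0, 0.0] + [-1.0] * (nm - 1) + [-np.inf] * 6
        hi = [400.0, 1000.0, 20.0, 50.0] + [1.0] * (nm - 1) + [np.inf] * 6

        def residuals(p):
            params = StabilityParams2D(
                Tm=p[0], dHm=p[1], dCp=p[2],
                m0=p[3], m1=p[4] if fit_m12 else 0.0, m2=p[5] if fit_m12 else 0.0,
            )
            b = p[4 + (nm - 1) :]
            return observable_2d(params, (tuple(b[:3]), tuple(b[3:])), T, x) - y

        sol = _multistart(residuals, x0, (lo, hi), n_starts, seed)
        p = sol.x
        params = StabilityParams2D(
            Tm=p[0], dHm=p[1], dCp=p[2],
            m0=p[3], m1=p[4] if fit_m12 else 0.0, m2=p[5] if fit_m12 else 0.0,
        )
        names = ["Tm", "dHm", "dCp", "m0"] + (["m1", "m2"] if fit_m12 else [])
        names += ["aN", "bN", "cN", "aD", "bD", "cD"]
        messages = []
        for name, val, l, h in zip(names[:4], p[:4], lo[:4], hi[:4]):
            if np.isclose(val, l) or np.isclose(val, h):
                messages.append(f"{name} at bound {val:.3g}")
        dg298 = delta_g_surface(params, 298.15, 0.0)
        m298 = params.m_eff(298.15)
        derived = {
            "dG_298": dg298,
            "Cm_298": cm_value(dg298, m298) if m298 > 0 else np.nan,
        }
        return _finish("global_2d", params, names, sol, len(T), messages, derived)

    result = fit_one(dataset)
    return _with_replicates(dataset, fit_one, result)


# ---------------------------------------------------------------------------
# replicate aggregation and CD helpers

def aggregate_replicates(results: list[FitResult]) -> FitResult:
    """Unweighted per-parameter mean and sample SD across replicate fits."""
    if len(results) < 2:
        raise ValueError("need at least 2 replicate fits to aggregate")
    classes = {r.model_class for r in results}
    if len(classes) > 1:
        raise ValueError(f"mixed model classes: {sorted(classes)}")
    names = list(results[0].values)
    table = np.array([[r.values[n] for n in names] for r in results], dtype=float)
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    best = min(results, key=lambda r: r.residual_norm)
    return replace(
        best,
        replicate_values=[dict(r.values) for r in results],
        aggregate={n: (float(mu), float(s)) for n, mu, s in zip(names, mean, sd)},
    )


def mre_from_ellipticity(theta_mdeg, conc_mg_ml: float, path_cm: float, mean_residue_weight: float):
    """Mean residue ellipticity (deg cm² dmol⁻¹) from raw ellipticity.

    MRE = θ·MRW / (10·l·c) with θ in millidegrees, path l in cm and
    concentration c in mg ml⁻¹.
    """
    if conc_mg_ml <= 0 or path_cm <= 0:
        raise ValueError("concentration and path length must be positive")
    return np.asarray(theta_mdeg, dtype=float) * mean_residue_weight / (
        10.0 * path_cm * conc_mg_ml
    )


def helicity_from_mre222(
    mre222,
    n_res: int,
    T: float = 298.15,
    helix_max: float | None = None,
    coil: float = 640.0,
):
    """Fractional helicity from the mean residue ellipticity at 222 nm.

    Uses the chain-length-corrected helix limit −39 500·(1 − 2.57/n) and a
    coil reference of +640 deg cm² dmol⁻¹ by default; both are configurable
    because published reference values vary.  Result clipped to [0, 1].
    """
    if n_res < 2:
        raise ValueError("n_res must be ≥ 2")
    if helix_max is None:
        helix_max = -39500.0 * (1.0 - 2.57 / n_res)
    denom = helix_max - coil
    if abs(denom) < 1e-9:
        raise ValueError("degenerate helix/coil references")
    f = (np.asarray(mre222, dtype=float) - coil) / denom
    return float(np.clip(f, 0.0, 1.0)) if np.ndim(f) == 0 else np.clip(f, 0.0, 1.0)


def m_to_structural_extent(n_res: int) -> tuple[float, float]:
    """Predict (ΔASA Å², m kJ mol⁻¹ M⁻¹) for unfolding ``n_res`` residues.

    Empirical correlations: ΔASA = −907 + 93·n and m(urea)/cal mol⁻¹ M⁻¹ =
    374 + 0.11·ΔASA, converted to kJ.  ΔASA ≤ 0 (n ≲ 10) is outside the
    correlation's support and raises.
    """
    if n_res < 1:
        raise ValueError("n_res must be ≥ 1")
    dasa = -907.0 + 93.0 * n_res
    if dasa <= 0:
        raise ValueError(f"ΔASA = {dasa:.0f} Å² ≤ 0: below the correlation's support")
    m_cal = 374.0 + 0.11 * dasa
    return dasa, m_cal * CAL_TO_J / 1000.0


def structural_extent_from_m(m_kj: float) -> tuple[float, float]:
    """Invert the m-value correlations: (ΔASA Å², residues unfolded)."""
    m_cal = m_kj * 1000.0 / CAL_TO_J
    dasa = (m_cal - 374.0) / 0.11
    if dasa <= 0:
        raise ValueError(f"ΔASA = {dasa:.0f} Å² ≤ 0: m value below the correlation's support")
    n_res = (dasa + 907.0) / 93.0
    return dasa, n_res
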