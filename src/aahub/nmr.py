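"""Chemical-shift-perturbation and temperature-series analysis of peak lists.

Works on assigned ¹H,¹⁵N correlation (HSQC-type) peak lists recorded along a
titration or temperature series.  Provides the weighted-Euclidean CSP
(Δδ = sqrt(ΔδH² + (0.154·ΔδN)²)), per-condition CSP tables with quartile and
mean + 1 SD thresholds, relative peak intensities and highest-visible-
temperature maps, secondary chemical shifts with helical-segment calls, and
mono-exponential relaxation-decay fitting with R1·R2 products.

Missing peaks are missing data, never zeros: a residue absent from a
spectrum carries real information (exchange broadening, unfolding) and
propagates as NaN through every table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "NITROGEN_WEIGHT",
    "PeakList",
    "CSPTable",
    "RelaxationSeries",
    "csp",
    "csp_table",
    "quartile_thresholds",
    "initial_unfolding_csp",
    "relative_intensities",
    "highest_visible_temperature",
    "secondary_shifts",
    "helical_segments",
    "fit_relaxation",
    "r1r2_product",
]

#: Default ¹⁵N scaling in the weighted Euclidean CSP.
NITROGEN_WEIGHT = 0.154


@dataclass
class PeakList:
    """Assigned peaks of one spectrum at one condition.

    ``condition`` is a temperature in kelvin or a titration-point label.
    ``data`` is indexed by residue number with columns res_type, dH_ppm,
    dN_ppm and (optionally) intensity.
    """

    condition: float | str
    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        if df.index.name != "residue":
            if "residue" in df.columns:
                df = df.set_index("residue")
            else:
                df.index.name = "residue"
        if df.index.duplicated().any():
            raise ValueError("residue numbers must be unique within a peak list")
        for col in ("dH_ppm", "dN_ppm"):
            if col not in df.columns:
                raise ValueError(f"peak list missing column {col}")
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite values in {col}")
        if "intensity" not in df.columns:
            df["intensity"] = np.nan
        self.data = df.sort_index()

    @property
    def residues(self) -> np.ndarray:
        return self.data.index.to_numpy()


@dataclass
class CSPTable:
    """Per-residue, per-condition CSPs relative to a reference condition.

    Also retains the component ¹H and ¹⁵N shift differences so that CSPs
    *between* two non-reference conditions remain computable.
    """

    csp: pd.DataFrame           # residues × conditions, ppm
    ddH: pd.DataFrame
    ddN: pd.DataFrame
    reference: float | str
    weight: float = NITROGEN_WEIGHT

    def between(self, cond_a, cond_b) -> pd.Series:
        """CSP between two measured conditions (ppm, NaN where missing)."""
        dh = self.ddH[cond_a] - self.ddH[cond_b]
        dn = self.ddN[cond_a] - self.ddN[cond_b]
        return csp(dh, dn, self.weight)

    @property
    def conditions(self) -> list:
        return list(self.csp.columns)


@dataclass
class RelaxationSeries:
    """Peak intensity versus relaxation delay for one residue."""

    delays: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must align")
        if np.any(self.delays <= 0):
            raise ValueError("relaxation delays must be positive")


def csp(dH, dN, weight: float = NITROGEN_WEIGHT):
    """Weighted Euclidean chemical shift perturbation (ppm).

    sqrt(ΔδH² + (w·ΔδN)²); symmetric in the sign of both inputs and in the
    free/bound role assignment.
    """
    out = np.sqrt(np.square(dH) + np.square(weight * np.asarray(dN, dtype=float)))
    return float(out) if np.ndim(out) == 0 else out


def csp_table(
    reference: PeakList,
    series: list[PeakList],
    weight: float = NITROGEN_WEIGHT,
) -> CSPTable:
    """Per-residue CSPs of each condition in ``series`` versus ``reference``.

    Residues missing from either list are NaN for that condition.
    """
    residues = reference.residues
    if not any(len(np.intersect1d(residues, pl.residues)) for pl in series):
        raise ValueError("no residues shared between reference and series")
    conds = [pl.condition for pl in series]
    ddh = pd.DataFrame(index=pd.Index(residues, name="residue"), columns=conds, dtype=float)
    ddn = ddh.copy()
    for pl in series:
        shared = np.intersect1d(residues, pl.residues)
        if shared.size == 0:
            raise ValueError(f"condition {pl.condition}: no residues shared with reference")
        ddh.loc[shared, pl.condition] = (
            pl.data.loc[shared, "dH_ppm"] - reference.data.loc[shared, "dH_ppm"]
        )
        ddn.loc[shared, pl.condition] = (
            pl.data.loc[shared, "dN_ppm"] - reference.data.loc[shared, "dN_ppm"]
        )
    table = np.sqrt(ddh.astype(float) ** 2 + (weight * ddn.astype(float)) ** 2)
    return CSPTable(csp=table, ddH=ddh, ddN=ddn, reference=reference.condition, weight=weight)


def quartile_thresholds(table: CSPTable) -> pd.Series:
    """Upper-quartile (75th percentile) CSP per condition.

    Linear interpolation between closest ranks; missing residues excluded.
    Requires at least 4 measured residues per condition.
    """
    counts = table.csp.notna().sum(axis=0)
    if (counts < 4).any():
        bad = list(counts.index[counts < 4])
        raise ValueError(f"fewer than 4 measured residues for conditions {bad}")
    return table.csp.quantile(0.75, axis=0, interpolation="linear")


def initial_unfolding_csp(
    table: CSPTable,
    window: tuple[float, float],
) -> pd.DataFrame:
    """Temperature-normalized CSPs across an equal-unfolding window.

    Computes the per-residue CSP between the two conditions nearest the
    window endpoints (which must lie within the measured range), divides by
    the window width in kelvin, and flags residues whose normalized CSP
    strictly exceeds mean + 1 SD — candidates for locally less stable
    structure that unfolds first.

    Returns a DataFrame with columns ``csp_per_K`` and ``flagged``.
    """
    t_low, t_high = window
    conds = np.asarray(table.conditions, dtype=float)
    if t_low < conds.min() - 1e-9 or t_high > conds.max() + 1e-9:
        raise ValueError(
            f"window [{t_low}, {t_high}] outside measured conditions "
            f"[{conds.min()}, {conds.max()}]"
        )
    cond_lo = table.conditions[int(np.argmin(np.abs(conds - t_low)))]
    cond_hi = table.conditions[int(np.argmin(np.abs(conds - t_high)))]
    if cond_lo == cond_hi:
        raise ValueError("window endpoints map to the same measured condition")
    width = float(cond_hi) - float(cond_lo)
    normalized = table.between(cond_hi, cond_lo) / width
    mu = normalized.mean(skipna=True)
    sd = normalized.std(skipna=True, ddof=1)
    flagged = normalized > mu + sd  # strict: SD = 0 flags nothing
    return pd.DataFrame({"csp_per_K": normalized, "flagged": flagged.fillna(False)})


def relative_intensities(series: list[PeakList], reference_condition) -> pd.DataFrame:
    """Per-residue intensity ratios I(condition)/I(reference).

    A zero or missing reference intensity yields NaN for that residue.
    """
    ref = next((pl for pl in series if pl.condition == reference_condition), None)
    if ref is None:
        raise ValueError(f"reference condition {reference_condition} not in series")
    residues = ref.residues
    out = pd.DataFrame(
        index=pd.Index(residues, name="residue"),
        columns=[pl.condition for pl in series],
        dtype=float,
    )
    ref_int = ref.data["intensity"].replace(0.0, np.nan)
    for pl in series:
        shared = np.intersect1d(residues, pl.residues)
        out.loc[shared, pl.condition] = (
            pl.data.loc[shared, "intensity"] / ref_int.loc[shared]
        )
    return out


def highest_visible_temperature(
    series: list[PeakList],
    noise_level: float | None = None,
    detection_floor: float | None = None,
) -> pd.Series:
    """Highest condition at which each residue's peak is still detected.

    Detection means presence in the peak list with intensity above the
    floor.  The floor is ``detection_floor`` if given, else 3× the supplied
    ``noise_level``, else mere presence of the assignment.  Residues never
    detected are NaN.
    """
    floor = detection_floor if detection_floor is not None else (
        3.0 * noise_level if noise_level is not None else None
    )
    residues = sorted(set().union(*(set(pl.residues) for pl in series)))
    out = pd.Series(np.nan, index=pd.Index(residues, name="residue"))
    for pl in sorted(series, key=lambda p: float(p.condition)):
        present = pl.data.index
        if floor is not None:
            present = present[pl.data["intensity"].fillna(-np.inf) > floor]
        out.loc[present] = float(pl.condition)
    return out


def secondary_shifts(observed: pd.Series, random_coil: pd.Series) -> pd.Series:
    """Secondary chemical shifts Δδ = δ_observed − δ_random-coil (ppm).

    The two series must cover the same residues; positive ¹³Cα values
    indicate helical propensity.
    """
    obs = pd.Series(observed, dtype=float)
    rc = pd.Series(random_coil, dtype=float)
    if not obs.index.equals(rc.index):
        raise ValueError("observed and random-coil shifts must cover matching residues")
    return obs - rc


def helical_segments(
    delta: pd.Series,
    threshold: float = 0.5,
    min_run: int = 4,
) -> list[tuple[int, int]]:
    """Contiguous runs of ≥ ``min_run`` residues with Δδ above ``threshold``.

    Returns (first_residue, last_residue) pairs; residue numbering gaps
    break runs.
    """
    segments = []
    run_start = prev = None

    def close():
        if run_start is not None and prev - run_start + 1 >= min_run:
            segments.append((int(run_start), int(prev)))

    for res, val in delta.sort_index().items():
        if val > threshold:
            if run_start is not None and res == prev + 1:
                prev = res
            else:
                close()
                run_start = prev = res
        else:
            close()
            run_start = prev = None
    close()
    return segments


def fit_relaxation(series: RelaxationSeries) -> tuple[float, float]:
    """Mono-exponential decay fit I(t) = I0·exp(−R·t).

    Returns (R in s⁻¹, its standard error).  Duplicate delays are used as
    independent points.  Non-decaying data raise.
    """
    t, y = series.delays, series.intensities
    if t.size < 5:
        raise ValueError("need at least 5 relaxation delays")
    # log-linear start (guard against non-positive intensities)
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = [float(np.exp(intercept)), float(max(-slope, 1e-3))]
    else:
        p0 = [float(np.max(np.abs(y)) or 1.0), 1.0]

    def model(t, i0, rate):
        return i0 * np.exp(-rate * t)

    popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=10000)
    rate = float(popt[1])
    if rate <= 0:
        raise RuntimeError(f"non-decaying data: fitted rate {rate:.3g} s⁻¹ ≤ 0")
    return rate, float(np.sqrt(pcov[1, 1]))


def r1r2_product(R1, R2):
    """Elementwise R1·R2 product (s⁻²), decoupling global tumbling."""
    out = np.asarray(R1, dtype=float) * np.asarray(R2, dtype=float)
    return float(out) if np.ndim(out) == 0 else out
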