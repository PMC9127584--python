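"""File formats and run configuration.

All tabular formats are plain CSV/TSV with explicit headers.  Temperatures
in files are °C (matching how such experiments are reported) and are
converted to kelvin at the boundary; denaturant concentrations are molar.

Melt/titration/surface tables
    CSV with columns ``temperature_C`` and/or ``urea_M``, ``signal``,
    optional ``ht_voltage`` and ``replicate``.

ITC injection tables
    CSV with columns ``injection``, ``volume_uL`` and exactly one heat
    column declaring its unit: ``heat_uJ`` (raw) or ``heat_kJ_per_mol``.

Peak lists
    TSV with columns ``residue``, ``res_type``, ``dN_ppm``, ``dH_ppm``,
    ``intensity``; one file per condition, or a long-format file with a
    ``condition`` column.  Random-coil shifts: two-column TSV
    (``residue``, ``shift_ppm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .fitting import DenaturationDataset
from .itc import ITCExperiment
from .nmr import PeakList

__all__ = [
    "RunConfig",
    "read_melt",
    "read_titration",
    "read_surface",
    "write_denaturation",
    "read_itc",
    "write_itc",
    "read_peaklist",
    "read_peaklists_long",
    "write_peaklists_long",
    "read_random_coil",
]


def _read_csv(path, sep=","):
    path = Path(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def _to_dataset(df, path, need_T, need_x) -> DenaturationDataset:
    cols = set(df.columns)
    required = {"signal"} | ({"temperature_C"} if need_T else set()) | (
        {"urea_M"} if need_x else set()
    )
    missing = required - cols
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    numeric = pd.to_numeric(df["signal"], errors="coerce")
    bad = df.index[~np.isfinite(numeric)]
    if len(bad):
        raise ValueError(f"{path}: malformed signal at data rows {list(bad + 2)}")
    df = df.assign(signal=numeric)
    out = pd.DataFrame(
        {
            "T": celsius_to_kelvin(df["temperature_C"].astype(float))
            if "temperature_C" in cols
            else 298.15,
            "x": df["urea_M"].astype(float) if "urea_M" in cols else 0.0,
            "signal": df["signal"].astype(float),
        }
    )
    if "ht_voltage" in cols:
        out["ht_voltage"] = df["ht_voltage"].astype(float)
    if "replicate" in cols:
        out["replicate"] = df["replicate"]
    return DenaturationDataset(out)


def read_melt(path) -> DenaturationDataset:
    """Thermal melt CSV (temperature_C, signal, [ht_voltage, replicate])."""
    return _to_dataset(_read_csv(path), path, need_T=True, need_x=False)


def read_titration(path) -> DenaturationDataset:
    """Chemical titration CSV (urea_M, signal, [ht_voltage, replicate])."""
    return _to_dataset(_read_csv(path), path, need_T=False, need_x=True)


def read_surface(path) -> DenaturationDataset:
    """Two-dimensional surface CSV (temperature_C, urea_M, signal, ...)."""
    return _to_dataset(_read_csv(path), path, need_T=True, need_x=True)


def write_denaturation(dataset: DenaturationDataset, path) -> None:
    """Write a dataset back to the CSV dialect the readers accept."""
    df = dataset.data
    out = pd.DataFrame(
        {
            "temperature_C": kelvin_to_celsius(df["T"]),
            "urea_M": df["x"],
            "signal": df["signal"],
            "replicate": df["replicate"],
        }
    )
    if df["ht_voltage"].notna().any():
        out["ht_voltage"] = df["ht_voltage"]
    out.to_csv(path, index=False)


def read_itc(path, exp: ITCExperiment | None = None) -> pd.DataFrame:
    """ITC injection table → DataFrame with molar heats.

    Requires ``injection``, ``volume_uL`` and one declared heat column.
    ``heat_uJ`` needs the experiment geometry (syringe concentration) to
    convert to kJ per mol of injectant.
    """
    df = _read_csv(path)
    missing = {"injection", "volume_uL"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    heat_cols = [c for c in df.columns if c in ("heat_uJ", "heat_kJ_per_mol")]
    if len(heat_cols) != 1:
        raise ValueError(
            f"{path}: exactly one heat column with a declared unit "
            "(heat_uJ or heat_kJ_per_mol) is required"
        )
    idx = df["injection"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError(f"{path}: injection indices must be strictly increasing")
    out = df[["injection", "volume_uL"]].copy()
    if heat_cols[0] == "heat_uJ":
        if exp is None:
            raise ValueError(f"{path}: raw heats (heat_uJ) need experiment geometry")
        moles = exp.syringe_conc * df["volume_uL"].astype(float) * 1e-6
        out["heat_kJ_per_mol"] = df["heat_uJ"].astype(float) * 1e-9 / moles
    else:
        out["heat_kJ_per_mol"] = df["heat_kJ_per_mol"].astype(float)
    return out


def write_itc(heats_kj_per_mol, volumes_uL, path) -> None:
    """Write a thermogram in the molar-heat dialect."""
    heats = np.asarray(heats_kj_per_mol, dtype=float)
    pd.DataFrame(
        {
            "injection": np.arange(1, heats.size + 1),
            "volume_uL": np.broadcast_to(np.asarray(volumes_uL, dtype=float), heats.shape),
            "heat_kJ_per_mol": heats,
        }
    ).to_csv(path, index=False)


_PEAK_COLS = ["residue", "res_type", "dN_ppm", "dH_ppm", "intensity"]


def read_peaklist(path, condition) -> PeakList:
    """One-condition peak list TSV."""
    df = _read_csv(path, sep="\t")
    missing = {"residue", "dN_ppm", "dH_ppm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    return PeakList(condition=condition, data=df)


def read_peaklists_long(path) -> list[PeakList]:
    """Long-format peak list TSV with a ``condition_C`` column (°C)."""
    df = _read_csv(path, sep="\t")
    if "condition_C" not in df.columns:
        raise ValueError(f"{path}: long format needs a condition_C column")
    out = []
    for cond, group in df.groupby("condition_C"):
        out.append(
            PeakList(
                condition=float(celsius_to_kelvin(cond)),
                data=group.drop(columns="condition_C").reset_index(drop=True),
            )
        )
    return sorted(out, key=lambda pl: pl.condition)


def write_peaklists_long(series: list[PeakList], path) -> None:
    frames = []
    for pl in series:
        df = pl.data.reset_index()
        df.insert(0, "condition_C", kelvin_to_celsius(float(pl.condition)))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_random_coil(path) -> pd.Series:
    """Two-column TSV (residue, shift_ppm) → Series indexed by residue."""
    df = _read_csv(path, sep="\t")
    missing = {"residue", "shift_ppm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    return df.set_index("residue")["shift_ppm"].astype(float)


@dataclass
class RunConfig:
    """Declarative description of a full analysis run.

    Round-trips losslessly through YAML; referenced files are checked for
    existence at load time.
    """

    experiments: list = field(default_factory=list)
    model_options: dict = field(default_factory=dict)
    itc_geometry: dict = field(default_factory=dict)
    nmr_reference_C: float | None = None
    thresholds: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "experiments": self.experiments,
            "model_options": self.model_options,
            "itc_geometry": self.itc_geometry,
            "nmr_reference_C": self.nmr_reference_C,
            "thresholds": self.thresholds,
            "seed": self.seed,
        }

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        base = Path(path).parent
        for entry in cfg.experiments:
            f = entry.get("file")
            if f and not (base / f).exists() and not Path(f).exists():
                raise FileNotFoundError(f"config references missing file: {f}")
        return cfg
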