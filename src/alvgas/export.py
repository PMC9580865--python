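"""Deterministic CSV export of simulation outputs.

All writers produce headered CSV with units embedded in the column
names, dot-decimal formatting (repr-exact floats, locale independent)
and a fixed row order, so re-exporting the same object yields a
byte-identical file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding import DissociationCurve
from .exchange import CapillaryProfile
from .metrics import SweepResult
from .parameters import convert_pressure

__all__ = [
    "profile_frame",
    "export_profile_csv",
    "export_curves_csv",
    "export_sweep_csv",
    "export_comparison_csv",
]


def _write(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")
    return path


def _pressure_columns(df: pd.DataFrame, unit: str) -> pd.DataFrame:
    if unit == "mmHg":
        return df
    out = df.copy()
    for col in list(out.columns):
        if col.endswith("_mmHg"):
            out[col.replace("_mmHg", "_kPa")] = [convert_pressure(v, unit) for v in out[col]]
            del out[col]
    return out


def profile_frame(profile: CapillaryProfile, velocity_mm_s: float | None = None,
                  unit: str = "mmHg") -> pd.DataFrame:
    """Tabulate a capillary profile (one row per state, inlet first)."""
    arrays = profile.as_arrays()
    n = len(arrays["time_s"])
    df = pd.DataFrame({
        "section_index": np.arange(n),
        "position_um": arrays["time_s"] * (velocity_mm_s * 1000.0) if velocity_mm_s else np.nan,
        "time_s": arrays["time_s"],
        "pO2_mmHg": arrays["pO2_mmHg"],
        "pCO2_mmHg": arrays["pCO2_mmHg"],
        "saturation": arrays["saturation"],
        "o2_flux_ml_per_s": arrays["o2_flux_ml_per_s"],
    })
    return _pressure_columns(df, unit)


def export_profile_csv(profile: CapillaryProfile, path: str | Path,
                       velocity_mm_s: float | None = None, unit: str = "mmHg") -> Path:
    return _write(profile_frame(profile, velocity_mm_s, unit), path)


def export_curves_csv(curves: list[DissociationCurve], path: str | Path,
                      unit: str = "mmHg") -> Path:
    frames = [
        pd.DataFrame({"pO2_mmHg": c.pO2_grid, "saturation": c.saturation,
                      "condition": c.condition_label})
        for c in curves
    ]
    return _write(_pressure_columns(pd.concat(frames, ignore_index=True), unit), path)


def export_sweep_csv(result: SweepResult, path: str | Path) -> Path:
    if result.dlo2_matrix.ndim == 2:
        df = pd.DataFrame(
            result.dlo2_matrix,
            index=pd.Index(result.exposure_grid, name="surface_exposure"),
            columns=[f"recruitment_{r:g}" for r in result.recruitment_grid],
        ).reset_index()
    else:
        df = pd.DataFrame({
            "surface_exposure": result.exposure_grid,
            "recruitment": result.recruitment_grid,
            "dlo2_ml_per_mmHg_min": result.dlo2_matrix,
        })
    return _write(df, path)


def export_comparison_csv(rows: list[dict], path: str | Path) -> Path:
    flat = []
    for row in rows:
        r = {k: v for k, v in row.items() if k != "parameter_deltas"}
        r["parameter_deltas"] = ";".join(
            f"{k}={v:g}" for k, v in sorted(row.get("parameter_deltas", {}).items()))
        flat.append(r)
    return _write(pd.DataFrame(flat), path)
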