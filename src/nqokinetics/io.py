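"""CSV/JSON readers and table writers.

CSV dialects are comma-separated UTF-8 with a mandatory header row.

rate tables (tidy):     cosubstrate_uM, acceptor_uM, rate_uM_s, replicate
cytotox plates (tidy):  condition, drug_uM, modifier_uM, replicate, absorbance
progress curves (wide): first column time (unit declared in the plate map),
                        remaining columns one well each
progress curves (tidy): time, well, absorbance

The plate map is a JSON object carrying the optical and assay metadata that
instrument exports do not: extinction coefficient (M⁻¹cm⁻¹), pathlength (cm),
enzyme concentration (nM), the time unit, and per-well substrate
concentrations.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .doseresponse import DosePlate, DoseResponseResults, Ic50Comparison
from .kinetics import ND, KineticResults, RateGrid
from .progress import ProgressCurve

__all__ = [
    "read_rate_table",
    "read_rate_grid",
    "read_dose_plate",
    "read_plate_map",
    "read_progress_curves",
    "kinetics_table",
    "ic50_table",
    "comparison_table",
    "write_json",
]

RATE_COLUMNS = ("cosubstrate_uM", "acceptor_uM", "rate_uM_s", "replicate")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{what} is missing columns: {sorted(missing)}")


def read_rate_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"rate table {path} is empty")
    _require_columns(df, RATE_COLUMNS, f"rate table {path}")
    return df


def read_rate_grid(
    path: Union[str, Path],
    enzyme_nM: float,
    cosubstrate: str = "BNAH",
    acceptor: str = "menadione",
) -> RateGrid:
    return RateGrid.from_dataframe(read_rate_table(path), enzyme_nM, cosubstrate, acceptor)


def read_dose_plate(path: Union[str, Path]) -> DosePlate:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"plate table {path} is empty")
    return DosePlate(df)


def read_plate_map(path: Union[str, Path]) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        pm = json.load(fh)
    for key in ("epsilon", "pathlength", "time_unit", "wells"):
        if key not in pm:
            raise ValueError(f"plate map {path} lacks required key {key!r}")
    if pm["time_unit"] not in ("s", "min"):
        raise ValueError("plate-map time_unit must be 's' or 'min'")
    return pm


def read_progress_curves(
    path: Union[str, Path], plate_map: dict
) -> Tuple[List[ProgressCurve], dict]:
    """Read wide- or tidy-format absorbance traces using plate-map metadata.

    Returns the curves plus the per-well metadata dict from the map.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"progress-curve file {path} is empty")
    scale = 60.0 if plate_map["time_unit"] == "min" else 1.0
    eps = float(plate_map["epsilon"])
    pathlength = float(plate_map["pathlength"])
    wells = plate_map["wells"]
    curves: List[ProgressCurve] = []
    if {"time", "well", "absorbance"} <= set(df.columns):
        for well, sub in df.groupby("well", sort=False):
            if str(well) not in wells:
                raise ValueError(f"well {well!r} not described in the plate map")
            curves.append(
                ProgressCurve(
                    times=sub["time"].to_numpy(float) * scale,
                    absorbance=sub["absorbance"].to_numpy(float),
                    epsilon=eps, pathlength=pathlength, well_id=str(well),
                )
            )
    else:
        tcol = df.columns[0]
        times = df[tcol].to_numpy(float) * scale
        for col in df.columns[1:]:
            if col not in wells:
                raise ValueError(f"well {col!r} not described in the plate map")
            curves.append(
                ProgressCurve(
                    times=times, absorbance=df[col].to_numpy(float),
                    epsilon=eps, pathlength=pathlength, well_id=col,
                )
            )
    return curves, wells


# ---------------------------------------------------------------------------
# writers

def _fmt(x, digits: int = 5) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return ND
    if isinstance(x, str):
        return x
    return f"{x:.{digits}g}"


def kinetics_table(results: Sequence[KineticResults], labels: Sequence[str]) -> pd.DataFrame:
    """Published-table-shaped kinetics summary (one row per enzyme/cosubstrate).

    Columns follow the kcat / K_M / K_I / kcat-over-K_M layout with ND
    sentinels for cells that could not be determined.
    """
    rows = []
    for label, res in zip(labels, results):
        rec = res.to_dict()
        p, ci = rec["params"], rec["ci95"]

        def cell(name: str) -> str:
            v = p[name]
            if v == ND:
                return ND
            if name in ci:
                lo, hi = ci[name]
                return f"{_fmt(v)} ({_fmt(lo)}, {_fmt(hi)})"
            return f"{_fmt(v)} (fixed)"

        rows.append(
            {
                "label": label,
                "kcat_per_s": cell("kcat"),
                "K_M_cosubstrate_uM": cell("K_A"),
                "K_M_acceptor_uM": cell("K_B"),
                "K_I_acceptor_uM": cell("K_I") if rec["inhibition_detected"] == "yes" or p["K_I"] != ND else ND,
                "kcat_over_K_M_per_M_s": _fmt(rec["efficiency_M_per_s"], 3),
                "efficiency_ci95": f"({_fmt(rec['efficiency_ci95'][0], 3)}, {_fmt(rec['efficiency_ci95'][1], 3)})",
                "saturated": rec["saturated"],
                "n_obs": rec["n_obs"],
            }
        )
    return pd.DataFrame(rows)


def ic50_table(fits: Sequence[DoseResponseResults]) -> pd.DataFrame:
    rows = []
    for fit in fits:
        rec = fit.to_dict()
        lo, hi = rec["ic50_ci95_uM"]
        rows.append(
            {
                "condition": rec["condition"],
                "ic50_uM": _fmt(rec["ic50_uM"]),
                "ic50_ci95_uM": f"({_fmt(lo)}, {_fmt(hi)})",
                "hill": _fmt(rec["hill"], 3),
                "n_obs": rec["n_obs"],
                "flags": ";".join(rec["flags"]),
            }
        )
    return pd.DataFrame(rows)


def comparison_table(
    pairs: Sequence[Tuple[str, str]], comparisons: Sequence[Ic50Comparison]
) -> pd.DataFrame:
    rows = []
    for (a, b), cmp_ in zip(pairs, comparisons):
        rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "fold_change": _fmt(cmp_.fold_change, 4),
                "pvalue": _fmt(cmp_.pvalue, 3),
                "qualitative_only": cmp_.qualitative_only,
            }
        )
    return pd.DataFrame(rows)


def write_json(obj: dict, path: Union[str, Path]) -> None:
    """Deterministic JSON writer (sorted keys, no timestamps)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
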