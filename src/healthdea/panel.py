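"""Balanced province x year panel I/O, validation and positivization.

The health-system efficiency panel carries one initial input (I1, per-capita
health expenditure), three intermediate outputs (M1-M3, institutions /
technicians / beds per thousand population) and five final outputs (F1
diagnoses, F2 bed-utilization percentage, and three negative-direction
indicators: F3 infectious-disease incidence, F4 maternal mortality, F5
perinatal mortality).  Negative-direction indicators must be converted to
benefit form by taking reciprocals before any efficiency computation.

Panels are plain long-format CSV (one row per unit-year, comma separated,
UTF-8, single header row).  Missing cells are a hard error: the methodology
assumes a complete balanced panel and no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_COLUMNS",
    "COVARIATE_COLUMNS",
    "NEGATIVE_INDICATORS",
    "CHINA_PROVINCES",
    "REGION_GROUPING",
    "PanelError",
    "read_panel",
    "write_panel",
    "validate_panel",
    "positivize_indicators",
    "compute_descriptives",
]

INDICATOR_COLUMNS = ["I1", "M1", "M2", "M3", "F1", "F2", "F3", "F4", "F5"]
COVARIATE_COLUMNS = ["pgdp", "fiscal", "urban", "edu", "depend"]
#: indicators measured in "bad" direction (incidence / mortality rates)
NEGATIVE_INDICATORS = ["F3", "F4", "F5"]

#: the 31 provincial-level units of mainland China used throughout.
CHINA_PROVINCES = [
    "Beijing", "Tianjin", "Hebei", "Shanxi", "Inner Mongolia", "Liaoning",
    "Jilin", "Heilongjiang", "Shanghai", "Jiangsu", "Zhejiang", "Anhui",
    "Fujian", "Jiangxi", "Shandong", "Henan", "Hubei", "Hunan", "Guangdong",
    "Guangxi", "Hainan", "Chongqing", "Sichuan", "Guizhou", "Yunnan", "Tibet",
    "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
]

_EASTERN = [
    "Beijing", "Tianjin", "Hebei", "Liaoning", "Shanghai", "Jiangsu",
    "Zhejiang", "Fujian", "Shandong", "Guangdong", "Hainan",
]
_CENTRAL = [
    "Shanxi", "Jilin", "Heilongjiang", "Anhui", "Jiangxi", "Henan",
    "Hubei", "Hunan",
]
_WESTERN = [
    "Inner Mongolia", "Guangxi", "Chongqing", "Sichuan", "Guizhou", "Yunnan",
    "Tibet", "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
]

#: unit -> {eastern, central, western}; sizes 11 / 8 / 12.
REGION_GROUPING = {
    **{p: "eastern" for p in _EASTERN},
    **{p: "central" for p in _CENTRAL},
    **{p: "western" for p in _WESTERN},
}


class PanelError(ValueError):
    """Raised for any structural or value defect in a panel."""


def _require_columns(df: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in ["unit", "year", *columns] if c not in df.columns]
    if missing:
        raise PanelError(f"panel is missing columns: {missing}")


def validate_panel(
    df: pd.DataFrame,
    columns: list[str],
    positive: list[str] | None = None,
) -> pd.DataFrame:
    """Validate balance and positivity; return a (unit, year)-sorted copy.

    Parameters
    ----------
    df : long-format panel with ``unit`` and ``year`` columns.
    columns : value columns that must be present and numeric.
    positive : columns required to be strictly positive (defaults to all
        value columns).
    """
    _require_columns(df, columns)
    out = df.copy()
    out["year"] = out["year"].astype(int)

    dup = out.duplicated(subset=["unit", "year"], keep=False)
    if dup.any():
        cell = out.loc[dup, ["unit", "year"]].iloc[0]
        raise PanelError(
            f"duplicate (unit, year) cell: ({cell['unit']}, {cell['year']})"
        )

    units = sorted(out["unit"].unique())
    years = sorted(out["year"].unique())
    expected = len(units) * len(years)
    if len(out) != expected:
        have = set(zip(out["unit"], out["year"]))
        for u in units:
            for y in years:
                if (u, y) not in have:
                    raise PanelError(f"unbalanced panel: missing cell ({u}, {y})")

    for c in columns:
        vals = pd.to_numeric(out[c], errors="coerce")
        if vals.isna().any():
            bad = out.loc[vals.isna(), ["unit", "year"]].iloc[0]
            raise PanelError(
                f"non-numeric value in column {c} at ({bad['unit']}, {bad['year']})"
            )
        out[c] = vals.astype(float)

    for c in positive if positive is not None else columns:
        nonpos = out[c] <= 0
        if nonpos.any():
            bad = out.loc[nonpos, ["unit", "year"]].iloc[0]
            raise PanelError(
                f"non-positive value in column {c} at "
                f"({bad['unit']}, {bad['year']}): {out.loc[nonpos, c].iloc[0]}"
            )

    out = out.sort_values(["unit", "year"], kind="mergesort").reset_index(drop=True)
    out.attrs = dict(df.attrs)
    return out


def read_panel(
    path,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a balanced long-format panel CSV.

    ``columns`` defaults to the indicator schema; pass
    :data:`COVARIATE_COLUMNS` for the regression covariate panel.
    """
    if columns is None:
        columns = INDICATOR_COLUMNS
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_panel(df, columns)


def write_panel(df: pd.DataFrame, path) -> None:
    """Write a panel to CSV (shortest round-trip float repr, exact)."""
    df.to_csv(path, index=False)


def positivize_indicators(panel: pd.DataFrame) -> pd.DataFrame:
    """Replace the negative-direction indicators F3-F5 by their reciprocals.

    Incidence and mortality rates are "less is better"; taking the reciprocal
    turns them into benefit-direction outputs suitable for an output-oriented
    efficiency model.  No rescaling is applied afterwards: constant-returns
    DEA efficiency is invariant to the units of any single column.

    The returned frame is flagged via ``attrs['positivized']``; applying the
    transform twice is an error, as is a zero or negative rate (the
    reciprocal would be undefined).
    """
    if panel.attrs.get("positivized", False):
        raise PanelError("panel is already positivized; refusing to apply twice")
    for c in NEGATIVE_INDICATORS:
        if c not in panel.columns:
            raise PanelError(f"missing negative-direction indicator column {c}")
        bad = panel[c] <= 0
        if bad.any():
            row = panel.loc[bad].iloc[0]
            raise PanelError(
                f"reciprocal undefined: {c} <= 0 at ({row['unit']}, {row['year']})"
            )
    out = panel.copy()
    for c in NEGATIVE_INDICATORS:
        out[c] = 1.0 / out[c]
    out.attrs = dict(panel.attrs)
    out.attrs["positivized"] = True
    return out


@dataclass(frozen=True)
class Descriptives:
    count: int
    mean: float
    sd: float
    min: float
    max: float


def compute_descriptives(values) -> Descriptives:
    """Count / mean / sample sd (n-1) / min / max of a nonempty collection."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise PanelError("cannot summarize an empty collection")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return Descriptives(
        count=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(np.min(arr)),
        max=float(np.max(arr)),
    )
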