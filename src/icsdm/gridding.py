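"""From raw logbook records to the cell-month modelling table.

The models never see individual hauls: records are binned to the 0.25-degree
grid and summed per (species, cell, month, year), CPUE is recomputed as the
ratio of summed catch to summed effort (never a mean of per-record ratios),
covariates are joined by exact (cell, year, month) lookup, and the training
target — an empirical habitat suitability index in [0, 1] — is the min–max
normalized CPUE within each (species, month) stratum pooled across years.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .env import COVARIATES, EnvStack
from .grid import GridSpec

__all__ = [
    "aggregate_records",
    "match_environment",
    "empirical_hsi",
    "sample_counts",
    "REQUIRED_LOGBOOK_COLUMNS",
]

log = logging.getLogger(__name__)

REQUIRED_LOGBOOK_COLUMNS = ["date", "lat", "lon", "species", "catch_t", "effort_days"]

#: CellSample columns ahead of the covariate block
SAMPLE_COLUMNS = [
    "species",
    "i",
    "j",
    "lat",
    "lon",
    "year",
    "month",
    "catch_t",
    "effort_days",
    "hauls",
    "cpue",
    "hsi_emp",
    "complete",
]


def aggregate_records(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Sum logbook records into one row per (species, cell, month, year).

    Rows with negative catch or non-positive effort are rejected (dropped
    with their line numbers logged), positions are binned with the grid's
    half-open cell rule, and CPUE is catch/effort of the *sums*.
    """
    missing = [c for c in REQUIRED_LOGBOOK_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"logbook is missing required columns: {missing}")
    rec = records.copy()
    dates = pd.to_datetime(rec["date"], format="ISO8601")
    rec["year"] = dates.dt.year
    rec["month"] = dates.dt.month

    bad = (rec["catch_t"] < 0) | (rec["effort_days"] <= 0)
    if bad.any():
        lines = rec.index[bad].tolist()
        log.warning("rejecting %d logbook rows with negative catch or non-positive effort: lines %s",
                    len(lines), lines[:20])
        rec = rec[~bad]
    if len(rec) == 0:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)

    i, j = grid.assign_cell(rec["lat"].to_numpy(), rec["lon"].to_numpy())
    rec = rec.assign(i=i, j=j)
    if "hauls" not in rec.columns:
        rec["hauls"] = 0

    agg = (
        rec.groupby(["species", "i", "j", "year", "month"], as_index=False)
        .agg(catch_t=("catch_t", "sum"), effort_days=("effort_days", "sum"), hauls=("hauls", "sum"))
    )
    agg["cpue"] = agg["catch_t"] / agg["effort_days"]
    lat_c, lon_c = grid.center_of(agg["i"].to_numpy(), agg["j"].to_numpy())
    agg["lat"] = lat_c
    agg["lon"] = lon_c
    agg["hsi_emp"] = np.nan
    agg["complete"] = True
    out = agg[SAMPLE_COLUMNS].sort_values(["species", "year", "month", "i", "j"]).reset_index(drop=True)

    for (y, m), g in out.groupby(["year", "month"]):
        per_sp = g.groupby("species").size().to_dict()
        log.info("cell samples %04d-%02d: %s (overlap %d)", y, m, per_sp, _overlap(g))
    return out


def _overlap(samples: pd.DataFrame) -> int:
    """Number of (cell, year, month) keys where more than one species occurs."""
    k = samples.groupby(["i", "j", "year", "month"])["species"].nunique()
    return int((k > 1).sum())


def sample_counts(samples: pd.DataFrame) -> pd.DataFrame:
    """Operation-site counts per (year, month, species) plus the two-species
    overlap count — the bookkeeping table fisheries studies print."""
    rows = []
    for (y, m), g in samples.groupby(["year", "month"]):
        row = {"year": y, "month": m}
        for sp, gg in g.groupby("species"):
            row[str(sp)] = len(gg)
        row["overlap"] = _overlap(g)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


def match_environment(samples: pd.DataFrame, env: EnvStack) -> pd.DataFrame:
    """Fill the covariate block by exact (cell, year, month) lookup.

    Rows that land on masked environment cells keep NaN covariates and are
    flagged ``complete=False`` (they stay in the table for honest sample
    counts but are excluded from fitting).
    """
    if env.grid.shape != (env.grid.nlat, env.grid.nlon):  # pragma: no cover - tautology guard
        raise ValueError("malformed grid")
    out = samples.copy()
    if len(out) == 0:
        for c in COVARIATES:
            out[c] = np.nan
        return out
    # positions must have been binned on the same lattice
    lat_c, lon_c = env.grid.center_of(out["i"].to_numpy(), out["j"].to_numpy())
    if not (np.allclose(lat_c, out["lat"]) and np.allclose(lon_c, out["lon"])):
        raise ValueError("samples were binned on a different grid than the environment stack")
    for c in COVARIATES:
        out[c] = env.lookup(
            c,
            out["year"].to_numpy(),
            out["month"].to_numpy(),
            out["i"].to_numpy(),
            out["j"].to_numpy(),
        )
    incomplete = out[COVARIATES].isna().any(axis=1)
    out["complete"] = ~incomplete
    if incomplete.any():
        log.info("flagged %d sample rows on masked environment cells as incomplete", int(incomplete.sum()))
    return out


def empirical_hsi(samples: pd.DataFrame) -> pd.DataFrame:
    """Min–max normalize CPUE to [0, 1] within (species, month) strata.

    Pooling is across years within a month, so inter-annual contrast in
    CPUE survives into the target.  A degenerate stratum (all CPUE equal)
    gets HSI 0.5 everywhere, with a warning.
    """
    out = samples.copy()
    if out["cpue"].isna().any():
        raise ValueError("CPUE must be present before computing the empirical HSI")
    for (sp, m), g in out.groupby(["species", "month"]):
        lo, hi = g["cpue"].min(), g["cpue"].max()
        if hi - lo <= 0:
            warnings.warn(
                f"degenerate CPUE stratum (species={sp}, month={m}): all values equal; HSI set to 0.5",
                stacklevel=2,
            )
            out.loc[g.index, "hsi_emp"] = 0.5
        else:
            out.loc[g.index, "hsi_emp"] = (g["cpue"] - lo) / (hi - lo)
    return out
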