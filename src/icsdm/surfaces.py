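"""Per-cell habitat suitability surfaces.

A surface is one species' HSI field for one (year, month), tagged with the
role it plays in the workflow:

- ``truth`` — generative truth from the simulator;
- ``empirical`` — normalized CPUE at fished cells;
- ``regional_ss`` — single-species model predicted over the whole window;
- ``ic`` — prediction of the model carrying the competitor's suitability
  as a biotic covariate;
- ``cohabitation`` — two-species combined surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

__all__ = ["HSISurface", "ROLES", "surfaces_to_netcdf", "surfaces_to_long_frame"]

ROLES = ("truth", "empirical", "regional_ss", "ic", "cohabitation")


@dataclass
class HSISurface:
    """A suitability field in [0, 1] on a grid; NaN marks masked cells."""

    grid: GridSpec
    values: np.ndarray  # (nlat, nlon), float, NaN where masked
    species: str
    year: int
    month: int
    role: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"surface shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("HSI values must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def at(self, i, j) -> np.ndarray:
        return self.values[np.asarray(i), np.asarray(j)]

    def unmasked(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def surfaces_to_netcdf(surfaces: list[HSISurface], path) -> None:
    """Write surfaces as one NetCDF dataset, a ``(time, lat, lon)`` variable
    per (species, role) pair."""
    if not surfaces:
        raise ValueError("no surfaces to write")
    grid = surfaces[0].grid
    lats, lons = grid.cell_centers()
    groups: dict[tuple[str, str], list[HSISurface]] = {}
    for s in surfaces:
        groups.setdefault((s.species, s.role), []).append(s)
    data_vars = {}
    time_codes = sorted({s.year * 100 + s.month for s in surfaces})
    for (species, role), group in groups.items():
        arr = np.full((len(time_codes), grid.nlat, grid.nlon), np.nan)
        for s in group:
            arr[time_codes.index(s.year * 100 + s.month)] = s.values
        data_vars[f"hsi_{species}_{role}"] = (("time", "lat", "lon"), arr)
    ds = xr.Dataset(
        data_vars,
        coords={
            "time": time_codes,
            "year": ("time", [c // 100 for c in time_codes]),
            "month": ("time", [c % 100 for c in time_codes]),
            "lat": lats,
            "lon": lons,
        },
        attrs=grid.to_dict(),
    )
    ds.to_netcdf(path, engine="scipy")


def surfaces_from_netcdf(path) -> list[HSISurface]:
    """Inverse of :func:`surfaces_to_netcdf`; months that are entirely
    missing for a (species, role) variable are skipped."""
    ds = xr.load_dataset(path, engine="scipy")
    grid = GridSpec.from_dict(ds.attrs)
    years = ds["year"].values
    months = ds["month"].values
    out: list[HSISurface] = []
    for var in ds.data_vars:
        if not var.startswith("hsi_"):
            continue
        _, species, role = var.split("_", 2)
        arr = ds[var].values
        for t in range(arr.shape[0]):
            if np.isfinite(arr[t]).any():
                out.append(
                    HSISurface(grid, arr[t], species, int(years[t]), int(months[t]), role)
                )
    return out


def surfaces_to_long_frame(surfaces: list[HSISurface]) -> pd.DataFrame:
    """Tidy export: year,month,lat,lon,species,role,hsi (unmasked cells only)."""
    rows = []
    for s in surfaces:
        lats, lons = s.grid.cell_centers()
        ii, jj = np.nonzero(np.isfinite(s.values))
        rows.append(
            pd.DataFrame(
                {
                    "year": s.year,
                    "month": s.month,
                    "lat": lats[ii],
                    "lon": lons[jj],
                    "species": s.species,
                    "role": s.role,
                    "hsi": s.values[ii, jj],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
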