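"""Gridded monthly environment stacks.

An :class:`EnvStack` holds one value per (cell, month, year) for each of the
13 ocean covariates the habitat models consume: temperature at five depths
(0/50/100/150/200 m), sea-surface height, salinity, chlorophyll-a, the two
current components, eddy kinetic energy, and two basin-scale monthly climate
scalars (SST anomaly and the Oceanic Nino Index) broadcast over the grid.
Data live in an :class:`xarray.Dataset` with dims ``(time, lat, lon)`` where
``time`` enumerates (year, month) pairs; a boolean land/missing mask is
shared by all spatially resolved covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

__all__ = ["COVARIATES", "SCALAR_COVARIATES", "EnvStack"]

#: Canonical covariate names, in model-input order.
COVARIATES = [
    "T_0m",
    "T_50m",
    "T_100m",
    "T_150m",
    "T_200m",
    "SSH",
    "SSS",
    "CHL",
    "U",
    "V",
    "EKE",
    "SSTA",
    "ONI",
]

#: Basin-scale indices: one scalar per (year, month), broadcast over cells.
SCALAR_COVARIATES = ["SSTA", "ONI"]


@dataclass
class EnvStack:
    """Covariate fields on a grid for a set of (year, month) slices.

    Attributes
    ----------
    grid : GridSpec
    data : xarray.Dataset
        Variables = COVARIATES, dims ``(time, lat, lon)``; coordinate
        ``time`` is a pandas MultiIndex-free integer code ``year*100+month``
        with auxiliary ``year`` and ``month`` coords.
    mask : numpy.ndarray
        Boolean (nlat, nlon); True where the cell is masked (land/missing).
    """

    grid: GridSpec
    data: xr.Dataset
    mask: np.ndarray

    # -- construction -----------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        grid: GridSpec,
        fields: dict[str, np.ndarray],
        years: list[int],
        months: list[int],
        mask: np.ndarray | None = None,
    ) -> "EnvStack":
        """Build a stack from per-covariate arrays of shape (ntime, nlat, nlon).

        ``ntime`` enumerates the (year, month) product in year-major order.
        """
        missing = [c for c in COVARIATES if c not in fields]
        if missing:
            raise ValueError(f"missing covariates: {missing}")
        if mask is None:
            mask = np.zeros(grid.shape, dtype=bool)
        lats, lons = grid.cell_centers()
        ymeta = [(y, m) for y in years for m in months]
        time = [y * 100 + m for y, m in ymeta]
        ds = xr.Dataset(
            {
                name: (("time", "lat", "lon"), np.asarray(arr, dtype=float))
                for name, arr in fields.items()
                if name in COVARIATES
            },
            coords={
                "time": time,
                "year": ("time", [y for y, _ in ymeta]),
                "month": ("time", [m for _, m in ymeta]),
                "lat": lats,
                "lon": lons,
            },
        )
        return cls(grid=grid, data=ds, mask=mask.astype(bool))

    # -- access -----------------------------------------------------------

    def times(self) -> list[tuple[int, int]]:
        return list(zip(self.data["year"].values.tolist(), self.data["month"].values.tolist()))

    def _time_index(self, year: int, month: int) -> int:
        code = year * 100 + month
        idx = np.nonzero(self.data["time"].values == code)[0]
        if idx.size == 0:
            raise KeyError(f"(year={year}, month={month}) not in stack")
        return int(idx[0])

    def slice_fields(self, year: int, month: int) -> dict[str, np.ndarray]:
        """All covariate fields for one (year, month) as (nlat, nlon) arrays,
        NaN over masked cells."""
        t = self._time_index(year, month)
        out = {}
        for name in COVARIATES:
            arr = self.data[name].values[t].copy()
            arr[self.mask] = np.nan
            out[name] = arr
        return out

    def feature_matrix(self, year: int, month: int, covariates: list[str] | None = None):
        """Per-cell design matrix for one (year, month).

        Returns ``(X, valid)`` where X has shape (ncells, ncov) in row-major
        (i, j) cell order and ``valid`` flags rows whose cell is unmasked.
        """
        covariates = list(covariates or COVARIATES)
        fields = self.slice_fields(year, month)
        unknown = [c for c in covariates if c not in fields]
        if unknown:
            raise KeyError(f"covariates not in stack: {unknown}")
        X = np.column_stack([fields[c].ravel() for c in covariates])
        valid = ~self.mask.ravel()
        return X, valid

    def lookup(self, covariate: str, year, month, i, j) -> np.ndarray:
        """Vectorized point extraction for sample rows."""
        year = np.asarray(year)
        month = np.asarray(month)
        codes = self.data["time"].values
        t = np.searchsorted(codes, year * 100 + month)
        t = np.clip(t, 0, codes.size - 1)
        if not np.all(codes[t] == year * 100 + month):
            raise KeyError("some (year, month) pairs are missing from the stack")
        arr = self.data[covariate].values
        vals = arr[t, np.asarray(i), np.asarray(j)].astype(float)
        vals[self.mask[np.asarray(i), np.asarray(j)]] = np.nan
        return vals

    # -- I/O --------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        ds = self.data.copy()
        ds["land_mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        ds.attrs.update(self.grid.to_dict())
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        ds = xr.load_dataset(path, engine="scipy")
        grid = GridSpec.from_dict(ds.attrs)
        mask = ds["land_mask"].values.astype(bool)
        return cls(grid=grid, data=ds.drop_vars("land_mask"), mask=mask)

    def to_long_frame(self) -> pd.DataFrame:
        """Long CSV dialect: columns year,month,lat,lon,var,value."""
        df = (
            self.data.to_dataframe()
            .reset_index()
            .melt(id_vars=["time", "year", "month", "lat", "lon"], var_name="var", value_name="value")
            .drop(columns="time")
        )
        return df[["year", "month", "lat", "lon", "var", "value"]]
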