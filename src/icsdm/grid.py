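"""Regular lat/lon lattice used to bin fishing positions and environment fields.

Cells are half-open intervals ``[low, high)`` in both axes, indexed 0-based
from the south-west corner; points landing exactly on the northern or eastern
domain edge belong to the last row/column so the closed study window maps
onto the grid without loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "OutOfDomainError"]

_TOL = 1e-9


class OutOfDomainError(ValueError):
    """A position falls outside the grid bounds."""


@dataclass(frozen=True)
class GridSpec:
    """A 0.25-degree (by default) lat/lon lattice over a rectangular window.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max : float
        Domain bounds in decimal degrees.
    resolution : float
        Cell edge length in degrees; the spans must be integer multiples
        of it (to 1e-9).
    """

    lat_min: float = 34.0
    lat_max: float = 45.0
    lon_min: float = 144.0
    lon_max: float = 163.0
    resolution: float = 0.25

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("grid bounds must satisfy max > min on both axes")
        for span, name in (
            (self.lat_max - self.lat_min, "latitude"),
            (self.lon_max - self.lon_min, "longitude"),
        ):
            ratio = span / self.resolution
            if abs(ratio - round(ratio)) > _TOL * max(1.0, ratio):
                raise ValueError(
                    f"{name} span {span} is not a multiple of resolution {self.resolution}"
                )

    @property
    def nlat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def nlon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def ncells(self) -> int:
        return self.nlat * self.nlon

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center latitudes (nlat,) and longitudes (nlon,)."""
        half = self.resolution / 2.0
        lats = self.lat_min + half + self.resolution * np.arange(self.nlat)
        lons = self.lon_min + half + self.resolution * np.arange(self.nlon)
        return lats, lons

    def assign_cell(self, lat, lon):
        """Map positions to 0-based (i, j) cell indices.

        Accepts scalars or arrays.  Points exactly on the top/right domain
        edge fall into the last cell; anything outside the closed bounds
        raises :class:`OutOfDomainError` (no silent clamping).
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        bad = (
            (lat < self.lat_min - _TOL)
            | (lat > self.lat_max + _TOL)
            | (lon < self.lon_min - _TOL)
            | (lon > self.lon_max + _TOL)
        )
        if np.any(bad):
            k = np.argwhere(np.atleast_1d(bad))[0]
            raise OutOfDomainError(
                f"position (lat={np.atleast_1d(lat).ravel()[k[0] if k.size else 0]}, "
                f"lon={np.atleast_1d(lon).ravel()[k[0] if k.size else 0]}) outside "
                f"[{self.lat_min}, {self.lat_max}] x [{self.lon_min}, {self.lon_max}]"
            )
        i = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        j = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        # closed top/right edge -> last cell
        i = np.minimum(i, self.nlat - 1)
        j = np.minimum(j, self.nlon - 1)
        if i.ndim == 0:
            return int(i), int(j)
        return i, j

    def center_of(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates for (possibly vectorized) indices."""
        half = self.resolution / 2.0
        lat = self.lat_min + half + self.resolution * np.asarray(i)
        lon = self.lon_min + half + self.resolution * np.asarray(j)
        return lat, lon

    def to_dict(self) -> dict:
        return {
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: float(d[k]) for k in ("lat_min", "lat_max", "lon_min", "lon_max", "resolution")})
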