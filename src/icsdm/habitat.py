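"""Habitat-class maps, cohabitation surfaces, and monthly correlation
structure of suitability fields.

Suitability is cut into the five standard intervals
[0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1] — the last bin is
closed so HSI = 1 is class 5 — and cells at or above 0.6 (classes 4–5)
delimit *optimal* habitat.  Cohabitation surfaces combine the two species'
coupled predictions cellwise (geometric mean by default).  Correlation uses
Pearson r over jointly unmasked cells, pairwise-complete, no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec
from .surfaces import HSISurface

__all__ = [
    "CLASS_EDGES",
    "HabitatClassMap",
    "classify_hsi",
    "cohabitation_surface",
    "correlate_surfaces",
    "monthly_correlation_report",
    "optimal_area_series",
    "CorrelationReport",
]

CLASS_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
OPTIMAL_CLASS = 4  # classes 4 and 5 are optimal habitat (HSI >= 0.6)

COMBINERS = {
    "geometric_mean": lambda a, b: np.sqrt(a * b),
    "min": np.minimum,
    "product": lambda a, b: a * b,
}


@dataclass
class HabitatClassMap:
    """Five-class partition of one suitability surface."""

    grid: GridSpec
    classes: np.ndarray  # (nlat, nlon) int, 0 = masked, 1..5 otherwise
    species: str
    year: int
    month: int
    source_role: str

    @property
    def counts(self) -> dict[int, int]:
        return {k: int((self.classes == k).sum()) for k in range(1, 6)}

    @property
    def n_unmasked(self) -> int:
        return int((self.classes > 0).sum())

    @property
    def optimal_mask(self) -> np.ndarray:
        return self.classes >= OPTIMAL_CLASS

    def area_fractions(self) -> dict[int, float]:
        n = self.n_unmasked
        return {k: (v / n if n else float("nan")) for k, v in self.counts.items()}


def classify_hsi(surface: HSISurface) -> HabitatClassMap:
    """Bin a surface into the five habitat classes.

    Bins are half-open except the last: 0.8 <= HSI <= 1 is class 5, so the
    upper endpoint does not spill into a sixth class.  Values outside [0, 1]
    are a contract violation upstream and fatal here.
    """
    v = surface.values
    finite = np.isfinite(v)
    if finite.any() and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
        raise ValueError("surface values outside [0, 1]")
    cls = np.zeros(v.shape, dtype=int)
    # digitize against interior edges: right=False gives half-open bins,
    # then fold HSI == 1.0 back into class 5
    cls[finite] = np.digitize(v[finite], CLASS_EDGES[1:-1], right=False) + 1
    cls[finite & (v == 1.0)] = 5
    return HabitatClassMap(
        grid=surface.grid,
        classes=cls,
        species=surface.species,
        year=surface.year,
        month=surface.month,
        source_role=surface.role,
    )


def cohabitation_surface(
    surf_a: HSISurface,
    surf_b: HSISurface,
    rule: str = "geometric_mean",
) -> HSISurface:
    """Combine the two species' coupled surfaces into one cohabitation field.

    The construction of a joint two-species habitat surface admits several
    symmetric cellwise rules; the default geometric mean preserves [0, 1],
    is zero whenever either species finds a cell unsuitable, and sits
    between ``min`` and ``product`` cellwise.  The rule used is recorded in
    the surface metadata.
    """
    if rule not in COMBINERS:
        raise ValueError(f"unknown cohabitation rule {rule!r}; choose from {sorted(COMBINERS)}")
    for s in (surf_a, surf_b):
        if s.role != "ic":
            raise ValueError(f"cohabitation expects coupled (role 'ic') surfaces, got {s.role!r}")
    if (surf_a.year, surf_a.month) != (surf_b.year, surf_b.month):
        raise ValueError("surfaces are for different months")
    if surf_a.grid != surf_b.grid:
        raise ValueError("surfaces are on different grids")
    with np.errstate(invalid="ignore"):
        vals = COMBINERS[rule](surf_a.values, surf_b.values)
    vals = np.where(np.isfinite(surf_a.values) & np.isfinite(surf_b.values), vals, np.nan)
    return HSISurface(
        surf_a.grid,
        vals,
        species=f"{surf_a.species}+{surf_b.species}",
        year=surf_a.year,
        month=surf_a.month,
        role="cohabitation",
        meta={"rule": rule},
    )


def correlate_surfaces(surf_x: HSISurface, surf_y: HSISurface) -> tuple[float, float, int]:
    """Pearson r between two surfaces over jointly unmasked cells.

    Returns (r, two-sided p from the t transform, n cells used).
    """
    if surf_x.grid != surf_y.grid:
        raise ValueError("surfaces are on different grids")
    x = surf_x.values.ravel()
    y = surf_y.values.ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need at least 3 jointly unmasked cells, got {n}")
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        raise ValueError("zero variance in a surface; correlation undefined")
    res = stats.pearsonr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue), n


@dataclass
class CorrelationReport:
    """Monthly correlation structure between and within species."""

    months: list[int]
    cross_r: dict[int, float]
    cross_p: dict[int, float]
    cross_n: dict[int, int]
    within_a: pd.DataFrame  # month x month Pearson r
    within_b: pd.DataFrame
    species_a: str = "A"
    species_b: str = "B"

    @property
    def peak_month(self) -> int:
        return max(self.cross_r, key=self.cross_r.get)

    def to_dict(self) -> dict:
        return {
            "species": [self.species_a, self.species_b],
            "months": self.months,
            "cross_species_r": {str(m): self.cross_r[m] for m in self.months},
            "cross_species_p": {str(m): self.cross_p[m] for m in self.months},
            "cross_species_n": {str(m): self.cross_n[m] for m in self.months},
            "peak_month": self.peak_month,
            "within_species_r": {
                self.species_a: self.within_a.to_dict(),
                self.species_b: self.within_b.to_dict(),
            },
        }


def _within_species_matrix(surfaces: dict[int, HSISurface], months: list[int]) -> pd.DataFrame:
    mat = pd.DataFrame(np.nan, index=months, columns=months, dtype=float)
    for a in months:
        for b in months:
            if b < a:
                continue
            if a == b:
                mat.loc[a, b] = 1.0
            else:
                r, _, _ = correlate_surfaces(surfaces[a], surfaces[b])
                mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def monthly_correlation_report(
    surfaces_a: list[HSISurface],
    surfaces_b: list[HSISurface],
) -> CorrelationReport:
    """Cross-species r per month plus within-species month-to-month r.

    Expects one surface per month and per species over a common month set
    (a single prediction year); a month missing from either list is an
    error — correlations are never imputed.
    """
    map_a = {s.month: s for s in surfaces_a}
    map_b = {s.month: s for s in surfaces_b}
    if set(map_a) != set(map_b):
        raise ValueError(
            f"month sets differ: {sorted(map_a)} vs {sorted(map_b)}"
        )
    months = sorted(map_a)
    cross_r, cross_p, cross_n = {}, {}, {}
    for m in months:
        r, p, n = correlate_surfaces(map_a[m], map_b[m])
        cross_r[m], cross_p[m], cross_n[m] = r, p, n
    return CorrelationReport(
        months=months,
        cross_r=cross_r,
        cross_p=cross_p,
        cross_n=cross_n,
        within_a=_within_species_matrix(map_a, months),
        within_b=_within_species_matrix(map_b, months),
        species_a=surfaces_a[0].species,
        species_b=surfaces_b[0].species,
    )


def optimal_area_series(class_maps: list[HabitatClassMap]) -> pd.DataFrame:
    """Optimal-habitat extent per month: cell count, areal fraction, and the
    lat/lon bounding box of the optimal mask."""
    grids = {id(m.grid): m.grid for m in class_maps}
    if len({g.to_dict().values().__str__() for g in grids.values()}) > 1:  # pragma: no cover
        raise ValueError("class maps must share a grid")
    rows = []
    for cm in class_maps:
        mask = cm.optimal_mask
        count = int(mask.sum())
        lats, lons = cm.grid.cell_centers()
        if count:
            ii, jj = np.nonzero(mask)
            box = (
                float(lats[ii].min()),
                float(lats[ii].max()),
                float(lons[jj].min()),
                float(lons[jj].max()),
            )
        else:
            box = (np.nan, np.nan, np.nan, np.nan)
        rows.append(
            {
                "species": cm.species,
                "year": cm.year,
                "month": cm.month,
                "optimal_cells": count,
                "optimal_fraction": count / cm.n_unmasked if cm.n_unmasked else np.nan,
                "lat_min": box[0],
                "lat_max": box[1],
                "lon_min": box[2],
                "lon_max": box[3],
            }
        )
    return pd.DataFrame(rows)
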