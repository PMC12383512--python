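"""Synthetic study generator: ocean covariates, coupled two-species
suitability truths, and purse-seine-style logbooks.

The generator stands in for proprietary fishery logbooks and the gridded
ocean products they are matched against, so that the whole pipeline can be
exercised with a *known* species-environment response and a *known*,
tunable interspecific coupling.  Three stages mirror the real data flow:

1. :func:`generate_environment` draws smooth monthly covariate fields on
   the study grid (temperatures decreasing with depth, currents, EKE from
   current anomalies, basin-scale monthly scalars).
2. :func:`true_suitability` turns per-covariate unimodal (Gaussian)
   response curves into a base suitability per species (weighted geometric
   mean), then couples species B to species A through a multiplicative
   modifier ``base_B * (1 + gamma_B * suit_A)`` clipped to [0, 1] — the
   generative analogue of treating the competitor's habitat suitability as
   one extra biotic covariate.
3. :func:`sample_logbook` allocates a monthly effort budget over cells with
   probability proportional to ``truth**k`` (fleets concentrate on good
   habitat), splits cell effort across vessels, and draws catches as
   ``q * effort * truth`` with multiplicative lognormal noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .env import COVARIATES, EnvStack
from .grid import GridSpec
from .surfaces import HSISurface
from .util import substream

__all__ = [
    "ResponseCurve",
    "SpeciesResponse",
    "EffortModel",
    "generate_environment",
    "true_suitability",
    "sample_logbook",
    "simulate_logbook",
    "default_responses",
    "MONTH_NAMES",
]

MONTH_NAMES = {
    "june": 6,
    "july": 7,
    "august": 8,
    "september": 9,
    "october": 10,
    "november": 11,
}

#: mean temperature drop (degC) from the surface, per depth level
_DEPTH_LAPSE = {"T_0m": 0.0, "T_50m": 2.5, "T_100m": 5.0, "T_150m": 7.0, "T_200m": 8.5}


def _parse_month(m) -> int:
    if isinstance(m, str):
        key = m.strip().lower()
        if key not in MONTH_NAMES:
            raise ValueError(f"unknown month name {m!r}; expected June..November")
        return MONTH_NAMES[key]
    m = int(m)
    if m not in MONTH_NAMES.values():
        raise ValueError(f"month {m} outside the June–November fishing season")
    return m


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ResponseCurve:
    """Unimodal (Gaussian) response to one covariate: exp(-((x-opt)/tol)^2/2)."""

    optimum: float
    tolerance: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance width must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((np.asarray(x, dtype=float) - self.optimum) / self.tolerance) ** 2)


@dataclass(frozen=True)
class SpeciesResponse:
    """One species' environment responses plus its coupling to the other.

    ``gamma`` is the signed, dimensionless strength with which the *other*
    species' suitability modulates this species' final suitability.
    """

    name: str
    curves: dict[str, ResponseCurve] = field(default_factory=dict)
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("at least one covariate response is required")
        if not any(c.weight > 0 for c in self.curves.values()):
            raise ValueError("at least one response weight must be > 0")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")

    @property
    def covariates(self) -> list[str]:
        return list(self.curves)

    def base_suitability(self, fields: dict[str, np.ndarray]) -> np.ndarray:
        """Weighted geometric mean of the per-covariate responses, in [0, 1]."""
        missing = [c for c in self.curves if c not in fields]
        if missing:
            raise KeyError(f"covariates missing from environment: {missing}")
        wsum = sum(c.weight for c in self.curves.values())
        log_s = None
        for name, curve in self.curves.items():
            r = np.clip(curve(fields[name]), 1e-300, 1.0)
            term = (curve.weight / wsum) * np.log(r)
            log_s = term if log_s is None else log_s + term
        return np.exp(log_s)


@dataclass(frozen=True)
class EffortModel:
    """Observation process mapping true suitability to logbook records.

    Attributes
    ----------
    n_vessels : int
        Fleet size; each effort day is assigned to one vessel.
    monthly_budget : int
        Total fishing days spent by the fleet per month.
    concentration : float
        Exponent k in ``P(cell) ∝ truth**k``; larger k piles effort onto
        the best habitat.
    catchability : float
        q, tons caught per fishing day at suitability 1.
    sigma : float
        Lognormal dispersion of the multiplicative catch noise.
    detection_floor : float
        Cells with truth below this are never fished.
    hauls_per_day : float
        Net sets per fishing day (logbook bookkeeping only).
    trip_days : int
        Effort is committed in vessel-trips of this many days: a fleet
        that has found fish stays on it, which is what concentrates tens
        of fishing days into single cells.  ``trip_days=1`` recovers
        day-by-day multinomial allocation.
    """

    n_vessels: int = 40
    monthly_budget: int = 2500
    concentration: float = 3.0
    catchability: float = 15.0
    sigma: float = 0.10
    detection_floor: float = 0.2
    hauls_per_day: float = 2.0
    trip_days: int = 15

    def __post_init__(self) -> None:
        if self.trip_days < 1:
            raise ValueError("trip_days must be >= 1")
        if self.concentration < 0:
            raise ValueError("concentration exponent k must be >= 0")
        if self.catchability <= 0:
            raise ValueError("catchability q must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.monthly_budget <= 0:
            raise ValueError("monthly effort budget must be > 0")
        if self.n_vessels < 1:
            raise ValueError("need at least one vessel")


# ---------------------------------------------------------------------------
# environment generation


def _smooth_field(rng: np.random.Generator, shape, std: float, corr_cells: float = 2.0) -> np.ndarray:
    """Zero-mean Gaussian random field with spatial correlation and unit-std
    scaled to ``std``."""
    white = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(white, sigma=corr_cells, mode="nearest")
    s = sm.std()
    if s > 0:
        sm *= std / s
    return sm


def generate_environment(
    grid: GridSpec,
    years: list[int],
    months: list,
    seed: int,
    mask: np.ndarray | None = None,
) -> EnvStack:
    """Draw a full covariate stack for the requested (year, month) slices.

    Surface temperature carries a poleward cooling gradient plus a seasonal
    cycle and smooth spatial noise; deeper temperature levels subtract a
    fixed mean lapse and add their own (smaller) noise.  U/V are smooth
    current fields; EKE is computed from their anomalies about the monthly
    spatial mean, ``EKE = (u'^2 + v'^2) / 2``.  SSTA and ONI are monthly
    basin scalars broadcast to every cell.
    """
    if grid.ncells <= 0:
        raise ValueError("grid is empty")
    months = [_parse_month(m) for m in months]
    years = [int(y) for y in years]
    pairs = [(y, m) for y in years for m in months]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (year, month) requests")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError("mask shape must match the grid")

    rng = substream(seed, "environment")
    lats, _ = grid.cell_centers()
    lat2d = np.broadcast_to(lats[:, None], grid.shape)

    ntime = len(pairs)
    fields = {name: np.empty((ntime,) + grid.shape) for name in COVARIATES}

    # slow basin-scale index, AR(1) across the requested time sequence
    oni = np.empty(ntime)
    oni_state = rng.normal(0.0, 0.8)
    year_offset = {y: rng.normal(0.0, 0.5) for y in years}

    for t, (y, m) in enumerate(pairs):
        oni_state = 0.8 * oni_state + rng.normal(0.0, 0.35)
        oni[t] = oni_state
        seasonal = 1.5 * np.cos(2 * np.pi * (m - 8) / 12.0)
        sst_mean = 26.0 - 1.0 * (lat2d - grid.lat_min) + seasonal + year_offset[y]
        t0 = sst_mean + _smooth_field(rng, grid.shape, 0.8)
        fields["T_0m"][t] = t0
        for name, lapse in _DEPTH_LAPSE.items():
            if name == "T_0m":
                continue
            fields[name][t] = t0 - lapse + _smooth_field(rng, grid.shape, 0.4)
        fields["SSH"][t] = 0.6 - 0.02 * (lat2d - grid.lat_min) + _smooth_field(rng, grid.shape, 0.06)
        fields["SSS"][t] = 34.2 - 0.04 * (lat2d - grid.lat_min) + _smooth_field(rng, grid.shape, 0.15)
        fields["CHL"][t] = np.exp(-0.8 + 0.06 * (lat2d - grid.lat_min) + _smooth_field(rng, grid.shape, 0.35))
        u = 0.10 + _smooth_field(rng, grid.shape, 0.15)
        v = 0.00 + _smooth_field(rng, grid.shape, 0.15)
        fields["U"][t] = u
        fields["V"][t] = v
        up = u - u.mean()
        vp = v - v.mean()
        fields["EKE"][t] = 0.5 * (up**2 + vp**2)
        fields["SSTA"][t] = rng.normal(0.0, 0.6)  # broadcast scalar
        fields["ONI"][t] = oni[t]

    return EnvStack.from_arrays(grid, fields, years, months, mask=mask)


# ---------------------------------------------------------------------------
# truth surfaces


def true_suitability(
    env: EnvStack,
    resp_a: SpeciesResponse,
    resp_b: SpeciesResponse,
    coupling: str = "multiplicative",
) -> tuple[list[HSISurface], list[HSISurface]]:
    """Generative truth surfaces for both species over every stack slice.

    Coupling (``multiplicative``, the default): each species' final
    suitability is its base suitability times ``(1 + gamma * base_other)``,
    renormalized by the largest attainable factor ``1 + max(gamma, 0)`` so
    the modifier cannot saturate the [0, 1] range (saturation would clip
    away exactly the between-species signal the workflow is meant to
    recover), then clipped to [0, 1] as a formal guard.  The ``additive``
    alternative adds ``gamma * base_other`` instead.  With both gammas zero
    each surface is a function of that species' own responses only.
    """
    if coupling not in ("multiplicative", "additive"):
        raise ValueError(f"unknown coupling form {coupling!r}")
    out_a: list[HSISurface] = []
    out_b: list[HSISurface] = []
    norm_a = 1.0 + max(resp_a.gamma, 0.0)
    norm_b = 1.0 + max(resp_b.gamma, 0.0)
    for year, month in env.times():
        f = env.slice_fields(year, month)
        base_a = resp_a.base_suitability(f)
        base_b = resp_b.base_suitability(f)
        if coupling == "multiplicative":
            s_a = np.clip(base_a * (1.0 + resp_a.gamma * base_b) / norm_a, 0.0, 1.0)
            s_b = np.clip(base_b * (1.0 + resp_b.gamma * base_a) / norm_b, 0.0, 1.0)
        else:
            s_a = np.clip(base_a + resp_a.gamma * base_b, 0.0, 1.0)
            s_b = np.clip(base_b + resp_b.gamma * base_a, 0.0, 1.0)
        for name, s in ((resp_a.name, s_a), (resp_b.name, s_b)):
            ok = np.isfinite(s)
            if ok.any() and np.nanmax(s) == 0.0:
                raise ValueError(
                    f"coupling drove the {name} suitability surface to zero everywhere "
                    f"({year}-{month:02d}); adjust gamma or the responses"
                )
        out_a.append(HSISurface(env.grid, s_a, resp_a.name, year, month, "truth"))
        out_b.append(HSISurface(env.grid, s_b, resp_b.name, year, month, "truth"))
    return out_a, out_b


# ---------------------------------------------------------------------------
# logbook sampling


def _vessel_length(vessel_id: np.ndarray) -> np.ndarray:
    # fixed per-vessel attribute, never consumed by the pipeline
    return np.round(38.0 + 1.7 * (np.asarray(vessel_id) % 9), 1)


def sample_logbook(
    truth: HSISurface,
    effort_model: EffortModel,
    grid: GridSpec,
    seed: int,
) -> pd.DataFrame:
    """Simulate one month of logbook records against one truth surface.

    The monthly effort budget is allocated to fishable cells (truth at or
    above the detection floor) by a multinomial draw of vessel-trips with
    cell probabilities proportional to ``truth**k``; every trip spends
    ``trip_days`` days except the last, which is truncated so the budget is
    conserved exactly.  Each trip is assigned a vessel uniformly at random
    and (cell, vessel) groups become records; a record's catch is
    ``q * effort_days * truth * exp(sigma * z - sigma^2/2)``.
    """
    if truth.values.shape != grid.shape:
        raise ValueError("truth surface and grid are not conformable")
    em = effort_model
    rng = substream(seed, "logbook", truth.species, f"{truth.year}-{truth.month}")

    vals = truth.values
    feasible = np.isfinite(vals) & (vals >= em.detection_floor)
    if not feasible.any():
        raise ValueError(
            f"no fishable cells: all suitabilities below floor {em.detection_floor}"
        )
    ii, jj = np.nonzero(feasible)
    w = vals[ii, jj] ** em.concentration
    p = w / w.sum()
    n_trips = -(-em.monthly_budget // em.trip_days)  # ceil
    trips_per_cell = rng.multinomial(n_trips, p)
    # trip lengths: all trip_days except one truncated remainder trip, so
    # the summed effort equals the budget exactly
    lengths = np.full(n_trips, em.trip_days, dtype=int)
    rem = em.monthly_budget - (n_trips - 1) * em.trip_days
    lengths[-1] = rem
    cell_of_trip = np.repeat(np.arange(p.size), trips_per_cell)
    rng.shuffle(cell_of_trip)  # which trip is the truncated one is arbitrary

    ndays = calendar.monthrange(truth.year, truth.month)[1]
    rows = []
    vessel_of_trip = rng.integers(1, em.n_vessels + 1, size=n_trips)
    eff = pd.DataFrame(
        {"cell": cell_of_trip, "vessel": vessel_of_trip, "days": lengths}
    ).groupby(["cell", "vessel"], as_index=False)["days"].sum()
    for cell_k, grp in eff.groupby("cell"):
        vid = grp["vessel"].to_numpy()
        days = grp["days"].to_numpy()
        s = float(vals[ii[cell_k], jj[cell_k]])
        lat_lo = grid.lat_min + grid.resolution * ii[cell_k]
        lon_lo = grid.lon_min + grid.resolution * jj[cell_k]
        for v, d in zip(vid, days):
            noise = 1.0 if em.sigma == 0 else float(
                np.exp(rng.normal(-0.5 * em.sigma**2, em.sigma))
            )
            rows.append(
                {
                    "date": f"{truth.year:04d}-{truth.month:02d}-{int(rng.integers(1, ndays + 1)):02d}",
                    "lat": lat_lo + grid.resolution * float(rng.random()),
                    "lon": lon_lo + grid.resolution * float(rng.random()),
                    "species": truth.species,
                    "catch_t": em.catchability * int(d) * s * noise,
                    "hauls": int(round(int(d) * em.hauls_per_day)),
                    "effort_days": int(d),
                    "vessel_id": int(v),
                    "vessel_length_m": float(_vessel_length(v)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "date",
            "lat",
            "lon",
            "species",
            "catch_t",
            "hauls",
            "effort_days",
            "vessel_id",
            "vessel_length_m",
        ],
    )


def simulate_logbook(
    truths: list[HSISurface],
    effort_model: EffortModel,
    grid: GridSpec,
    seed: int,
) -> pd.DataFrame:
    """Concatenate monthly logbooks over a list of truth surfaces."""
    frames = [sample_logbook(t, effort_model, grid, seed) for t in truths]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# study defaults


def default_responses(gamma_a: float = 0.0, gamma_b: float = 0.8) -> tuple[SpeciesResponse, SpeciesResponse]:
    """The two-species configuration the bundled study design uses.

    Species A (sardine-like) occupies a productivity/front niche driven by
    the small-scale fields — chlorophyll, eddy kinetic energy and the two
    current components — so its distribution has fine spatial texture.
    Species B (mackerel-like) tolerates a broad subsurface-temperature and
    salinity range, so within the study window its own environmental
    preference is weak and, once coupled (gamma_b = 0.8 by default), the
    competitor's distribution carries much of its spatial structure — the
    situation the biotic-covariate workflow is designed to detect.
    """
    resp_a = SpeciesResponse(
        name="sardine",
        curves={
            "CHL": ResponseCurve(optimum=0.8, tolerance=0.22, weight=1.0),
            "EKE": ResponseCurve(optimum=0.02, tolerance=0.01, weight=0.8),
            "U": ResponseCurve(optimum=0.2, tolerance=0.12, weight=0.8),
            "V": ResponseCurve(optimum=0.05, tolerance=0.12, weight=0.8),
        },
        gamma=gamma_a,
    )
    resp_b = SpeciesResponse(
        name="mackerel",
        curves={
            "T_50m": ResponseCurve(optimum=13.0, tolerance=9.0, weight=1.0),
            "SSS": ResponseCurve(optimum=34.0, tolerance=2.0, weight=0.3),
        },
        gamma=gamma_b,
    )
    return resp_a, resp_b
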