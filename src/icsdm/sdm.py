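"""Habitat suitability models: single-species and competitor-coupled.

The estimator is a bagged regression-tree ensemble (random forest): each of
``n_trees`` trees is grown on a bootstrap resample considering ``mtry``
candidate covariates per split, and predictions are the tree mean.  Defaults
follow the standard fisheries-SDM setting of 1000 trees with mtry 4.  The
single-species model (ssSDM) maps the 13 environment covariates to the
empirical HSI at fished cells; the interspecific-competition model (icSDM)
adds one biotic covariate — the competitor's *regional* ssSDM prediction at
the same cell-month — and is otherwise identical (mtry deliberately stays
at its single-species value).

Stage order is part of the contract: an icSDM can only consume surfaces of
role ``regional_ss``, which prevents accidentally chaining ic predictions
into further ic fits.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .env import COVARIATES, EnvStack
from .grid import GridSpec
from .surfaces import HSISurface

__all__ = [
    "ModelSpec",
    "FittedSDM",
    "fit_sssdm",
    "fit_icsdm",
    "predict_regional",
    "predict_icsdm",
    "build_biotic_feature",
    "partial_response",
    "BIOTIC_FEATURE",
]

#: column name of the injected competitor-suitability covariate
BIOTIC_FEATURE = "hsi_other"

MIN_ROWS = 30


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters and bookkeeping for one ensemble fit."""

    covariates: tuple[str, ...] = tuple(COVARIATES)
    n_trees: int = 1000
    mtry: int = 4
    min_leaf: int = 5
    seed: int = 0
    response: str = "hsi_emp"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (1 <= self.mtry <= len(self.covariates)):
            raise ValueError(
                f"mtry must be in [1, {len(self.covariates)}], got {self.mtry}"
            )

    def with_biotic(self) -> "ModelSpec":
        """The icSDM variant: same settings, one extra covariate."""
        if BIOTIC_FEATURE in self.covariates:
            return self
        return replace(self, covariates=tuple(self.covariates) + (BIOTIC_FEATURE,))


class _ConstantModel:
    """Degenerate-response fallback: predicts the training constant."""

    def __init__(self, value: float, n_features: int):
        self.value = float(value)
        self.n_features = n_features
        self.feature_importances_ = np.zeros(n_features)

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.value)


@dataclass
class FittedSDM:
    """A trained ensemble plus the provenance needed to reuse it honestly."""

    model: object
    spec: ModelSpec
    species: str
    stage: str  # "ss" | "ic"
    years: tuple[int, ...]
    months: tuple[int, ...]
    response_range: tuple[float, float]
    feature_medians: pd.Series
    oob_r2: float | None = None

    @property
    def covariates(self) -> list[str]:
        return list(self.spec.covariates)

    @property
    def importances(self) -> pd.Series:
        imp = pd.Series(self.model.feature_importances_, index=self.covariates)
        return imp

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.covariates if c not in X.columns]
            if missing:
                raise KeyError(f"prediction input is missing covariates: {missing}")
            X = X[self.covariates].to_numpy(dtype=float)
        pred = self.model.predict(np.asarray(X, dtype=float))
        # tree means of a [0,1] response cannot leave the training range;
        # the clip is a formal guard asserted (as a no-op) in tests
        return np.clip(pred, 0.0, 1.0)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {
            "format_version": 1,
            "species": self.species,
            "stage": self.stage,
            "years": list(self.years),
            "months": list(self.months),
            "covariates": self.covariates,
            "n_trees": self.spec.n_trees,
            "mtry": self.spec.mtry,
            "min_leaf": self.spec.min_leaf,
            "seed": self.spec.seed,
            "response": self.spec.response,
            "response_range": list(self.response_range),
            "oob_r2": self.oob_r2,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "FittedSDM":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a fitted model")
        return obj


def _training_frame(samples: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    missing = [c for c in spec.covariates if c not in samples.columns]
    if missing:
        raise KeyError(f"samples are missing covariates: {missing}")
    usable = samples[samples["complete"]].dropna(subset=[spec.response, *spec.covariates])
    return usable


def _fit(samples: pd.DataFrame, spec: ModelSpec, stage: str, allow_constant: bool) -> FittedSDM:
    species = samples["species"].unique()
    if len(species) != 1:
        raise ValueError(f"expected samples of a single species, got {sorted(map(str, species))}")
    train = _training_frame(samples, spec)
    if len(train) < MIN_ROWS:
        raise ValueError(
            f"need at least {MIN_ROWS} complete rows to fit, got {len(train)}"
        )
    y = train[spec.response].to_numpy(dtype=float)
    if y.min() < -1e-9 or y.max() > 1 + 1e-9:
        raise ValueError("response must lie in [0, 1]")
    X = train[list(spec.covariates)].astype(float)

    if np.ptp(y) == 0:
        if not allow_constant:
            raise ValueError(
                "response is constant; refusing to fit (pass allow_constant=True "
                "to return a degenerate constant predictor)"
            )
        model: object = _ConstantModel(y[0], len(spec.covariates))
        oob = None
    else:
        rf = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=spec.mtry,
            min_samples_leaf=spec.min_leaf,
            bootstrap=True,
            oob_score=True,
            random_state=int(spec.seed),
            n_jobs=1,
        )
        rf.fit(X.to_numpy(), y)
        model = rf
        oob = float(rf.oob_score_)

    return FittedSDM(
        model=model,
        spec=spec,
        species=str(species[0]),
        stage=stage,
        years=tuple(sorted(train["year"].unique().tolist())) if "year" in train else (),
        months=tuple(sorted(train["month"].unique().tolist())) if "month" in train else (),
        response_range=(float(y.min()), float(y.max())),
        feature_medians=X.median(),
        oob_r2=oob,
    )


def fit_sssdm(samples: pd.DataFrame, spec: ModelSpec, allow_constant: bool = False) -> FittedSDM:
    """Fit the single-species model on one species' cell-month samples."""
    if BIOTIC_FEATURE in spec.covariates:
        raise ValueError(f"a single-species spec must not contain {BIOTIC_FEATURE!r}")
    return _fit(samples, spec, stage="ss", allow_constant=allow_constant)


def fit_icsdm(samples: pd.DataFrame, spec: ModelSpec, allow_constant: bool = False) -> FittedSDM:
    """Fit the competitor-coupled model; ``hsi_other`` must be in the table
    (see :func:`build_biotic_feature`) and in the covariate list."""
    if BIOTIC_FEATURE not in spec.covariates:
        spec = spec.with_biotic()
    if BIOTIC_FEATURE not in samples.columns:
        raise KeyError(
            f"samples lack the {BIOTIC_FEATURE!r} column; run build_biotic_feature first"
        )
    return _fit(samples, spec, stage="ic", allow_constant=allow_constant)


def predict_regional(
    model: FittedSDM,
    env: EnvStack,
    grid: GridSpec,
    year: int,
    month: int,
) -> HSISurface:
    """Evaluate a fitted ssSDM on every unmasked grid cell of one month."""
    if model.stage != "ss":
        raise ValueError("predict_regional expects a single-species (stage 'ss') model")
    X, valid = env.feature_matrix(year, month, covariates=model.covariates)
    out = np.full(grid.ncells, np.nan)
    out[valid] = model.predict(X[valid])
    return HSISurface(
        grid, out.reshape(grid.shape), model.species, int(year), int(month), "regional_ss"
    )


def _surface_map(surfaces) -> dict[tuple[int, int], HSISurface]:
    if isinstance(surfaces, HSISurface):
        surfaces = [surfaces]
    return {(s.year, s.month): s for s in surfaces}


def build_biotic_feature(samples: pd.DataFrame, surfaces_other) -> pd.DataFrame:
    """Attach the competitor's regional prediction at each sample's cell-month.

    ``surfaces_other`` is one surface or a list covering every (year, month)
    in the table; every surface must carry role ``regional_ss`` (injecting
    an ic surface would couple the models circularly, so it is rejected).
    Rows over masked surface cells are flagged incomplete.
    """
    smap = _surface_map(surfaces_other)
    for s in smap.values():
        if s.role != "regional_ss":
            raise ValueError(
                f"biotic feature must come from a regional_ss surface, got role {s.role!r}"
            )
    out = samples.copy()
    vals = np.full(len(out), np.nan)
    for (y, m), idx in out.groupby(["year", "month"]).groups.items():
        key = (int(y), int(m))
        if key not in smap:
            raise KeyError(f"no competitor surface for (year={y}, month={m})")
        s = smap[key]
        sub = out.loc[idx]
        vals[out.index.get_indexer(idx)] = s.at(sub["i"].to_numpy(), sub["j"].to_numpy())
    out[BIOTIC_FEATURE] = vals
    out.loc[~np.isfinite(vals), "complete"] = False
    return out


def predict_icsdm(
    model: FittedSDM,
    env: EnvStack,
    surface_other: HSISurface,
    grid: GridSpec,
    year: int,
    month: int,
) -> HSISurface:
    """Evaluate a fitted icSDM over the grid for one month.

    The competitor surface must be the regional_ss prediction for the same
    (year, month); output cells are missing wherever either the environment
    or the competitor surface is masked.
    """
    if model.stage != "ic":
        raise ValueError("predict_icsdm expects a stage 'ic' model")
    if surface_other.role != "regional_ss":
        raise ValueError("competitor surface must have role 'regional_ss'")
    if (surface_other.year, surface_other.month) != (int(year), int(month)):
        raise ValueError(
            f"competitor surface is for {surface_other.year}-{surface_other.month:02d}, "
            f"requested {year}-{month:02d}"
        )
    env_covs = [c for c in model.covariates if c != BIOTIC_FEATURE]
    X_env, valid = env.feature_matrix(year, month, covariates=env_covs)
    other = surface_other.values.ravel()
    valid = valid & np.isfinite(other)
    X = pd.DataFrame(X_env, columns=env_covs)
    X[BIOTIC_FEATURE] = other
    out = np.full(grid.ncells, np.nan)
    out[valid] = model.predict(X[valid])
    return HSISurface(grid, out.reshape(grid.shape), model.species, int(year), int(month), "ic")


def partial_response(
    model: FittedSDM,
    covariate: str,
    values: np.ndarray,
    background: pd.Series | None = None,
) -> np.ndarray:
    """One-dimensional partial response: vary one covariate over ``values``
    holding all others at the training medians (or a supplied background)."""
    if covariate not in model.covariates:
        raise KeyError(f"{covariate!r} is not a model covariate")
    base = model.feature_medians if background is None else background
    X = pd.DataFrame(
        np.tile(base[model.covariates].to_numpy(dtype=float), (len(values), 1)),
        columns=model.covariates,
    )
    X[covariate] = np.asarray(values, dtype=float)
    return model.predict(X)
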