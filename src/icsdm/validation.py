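"""Model validation: repeated 80/20 holdout R-squared, paired model
comparison, and effort-concentration checks.

R-squared here is explanatory power on held-out cell-months,
``1 - SSE/SST``.  The single-species and coupled models are compared on
*split-matched* iterations: both see exactly the same random 80/20 splits,
so their per-iteration difference isolates the biotic covariate.  The
paired Wilcoxon p-values mirror the usual presentation of such comparisons;
because repeated holdout replicates are not independent they are
descriptive, not confirmatory, and are labelled as such in reports.

Effort concentration asks whether the fleet's fishing days pile up where
the model says habitat is good — the fraction of total effort in cells at
or above an HSI threshold (0.6 delimits "optimal" habitat), plus the
fraction of high-effort cells (>= 40 days) sitting in the highest occupied
habitat class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sdm import ModelSpec, _fit
from .surfaces import HSISurface
from .util import substream_seed

__all__ = [
    "repeated_holdout",
    "compare_models",
    "effort_concentration",
    "high_effort_in_top_class",
    "ValidationReport",
    "significance_stars",
]

log = logging.getLogger(__name__)

HIGH_EFFORT_DAYS = 40.0
OPTIMAL_HSI = 0.6


def _split_indices(n: int, train_fraction: float, seed: int, iteration: int) -> tuple[np.ndarray, np.ndarray]:
    """The 80/20 split of iteration ``i`` — a pure function of
    (seed, iteration, n), so two models evaluated with the same seed see
    identical splits and their R-squared vectors are pair-matched."""
    rng = np.random.default_rng(substream_seed(seed, "holdout", str(iteration)))
    perm = rng.permutation(n)
    ntrain = int(round(train_fraction * n))
    ntrain = min(max(ntrain, 1), n - 1)
    return perm[:ntrain], perm[ntrain:]


def repeated_holdout(
    samples: pd.DataFrame,
    spec: ModelSpec,
    iterations: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    stage: str = "ss",
) -> np.ndarray:
    """Repeated random-holdout explanatory power.

    Each iteration draws a fresh random train/test split of the complete
    rows, refits the ensemble on the training part, and records test
    R-squared.  An iteration whose test stratum has zero response variance
    is recorded as NaN (logged).  Returns a vector of length ``iterations``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    usable = samples[samples["complete"]].dropna(subset=[spec.response, *spec.covariates])
    usable = usable.reset_index(drop=True)
    n = len(usable)
    if n < 10:
        raise ValueError(f"need at least 10 complete rows for holdout validation, got {n}")
    y = usable[spec.response].to_numpy(dtype=float)

    r2 = np.full(iterations, np.nan)
    n_degenerate = 0
    for it in range(iterations):
        tr, te = _split_indices(n, train_fraction, seed, it)
        if np.ptp(y[te]) == 0:
            n_degenerate += 1
            continue
        model = _fit(
            usable.iloc[tr],
            ModelSpec(
                covariates=spec.covariates,
                n_trees=spec.n_trees,
                mtry=spec.mtry,
                min_leaf=spec.min_leaf,
                seed=substream_seed(seed, "holdout-fit", str(it)),
                response=spec.response,
            ),
            stage=stage,
            allow_constant=True,
        )
        pred = model.predict(usable.iloc[te])
        sse = float(np.sum((y[te] - pred) ** 2))
        sst = float(np.sum((y[te] - y[te].mean()) ** 2))
        r2[it] = 1.0 - sse / sst
    if n_degenerate:
        log.info("holdout: %d of %d iterations had zero test variance (recorded NaN)",
                 n_degenerate, iterations)
    return r2


def significance_stars(p: float) -> str:
    """Star coding used in the comparison figures."""
    if p < 1e-4:
        return "****"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_models(r2_ss: np.ndarray, r2_ic: np.ndarray) -> tuple[float, float, str]:
    """Paired comparison of split-matched holdout R-squared vectors.

    Returns (mean delta R-squared, two-sided paired Wilcoxon p, stars).
    If every pairwise difference is zero the Wilcoxon statistic is
    undefined; p is reported as 1.0 (no evidence of a difference).
    """
    r2_ss = np.asarray(r2_ss, dtype=float)
    r2_ic = np.asarray(r2_ic, dtype=float)
    if r2_ss.shape != r2_ic.shape:
        raise ValueError("R-squared vectors must be split-matched and equal length")
    ok = np.isfinite(r2_ss) & np.isfinite(r2_ic)
    d = r2_ic[ok] - r2_ss[ok]
    if d.size == 0:
        raise ValueError("no finite paired iterations")
    mean_delta = float(d.mean())
    if np.all(d == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
    return mean_delta, p, significance_stars(p)


def effort_concentration(
    surface: HSISurface,
    effort_by_cell: pd.DataFrame,
    threshold: float = OPTIMAL_HSI,
) -> float:
    """Fraction of total fishing effort in cells with HSI >= threshold.

    ``effort_by_cell`` needs columns i, j, effort_days; effort over masked
    surface cells counts toward the denominator only (habitat unknown is
    not habitat good).
    """
    eff = effort_by_cell["effort_days"].to_numpy(dtype=float)
    if (eff < 0).any():
        raise ValueError("effort must be >= 0")
    total = eff.sum()
    if total <= 0:
        raise ValueError("total effort is zero; concentration undefined")
    hsi = surface.at(effort_by_cell["i"].to_numpy(), effort_by_cell["j"].to_numpy())
    inside = np.isfinite(hsi) & (hsi >= threshold)
    return float(eff[inside].sum() / total)


def high_effort_in_top_class(
    surface: HSISurface,
    effort_by_cell: pd.DataFrame,
    effort_threshold: float = HIGH_EFFORT_DAYS,
    class_width: float = 0.2,
) -> float:
    """Fraction of high-effort cells (effort >= 40 days) whose HSI falls in
    the highest habitat class occupied by any fished cell."""
    eff = effort_by_cell["effort_days"].to_numpy(dtype=float)
    hsi = surface.at(effort_by_cell["i"].to_numpy(), effort_by_cell["j"].to_numpy())
    ok = np.isfinite(hsi)
    if not ok.any():
        raise ValueError("no fished cells with known HSI")
    # class index 0..4 with the top bin closed at 1.0
    cls = np.minimum((hsi[ok] / class_width).astype(int), 4)
    top = cls.max()
    high = ok & (eff >= effort_threshold)
    if not high.any():
        return float("nan")
    cls_high = np.minimum((hsi[high] / class_width).astype(int), 4)
    return float(np.mean(cls_high == top))


@dataclass
class ValidationReport:
    """Per-month holdout comparison plus effort-concentration summaries."""

    species: str
    months: list[int]
    r2_ss: dict[int, list[float]]
    r2_ic: dict[int, list[float]]
    iterations: int
    train_fraction: float
    seed: int
    mean_delta: dict[int, float] = field(default_factory=dict)
    p_value: dict[int, float] = field(default_factory=dict)
    stars: dict[int, str] = field(default_factory=dict)
    effort_fraction_optimal: float | None = None
    high_effort_top_class: float | None = None

    def summarize(self) -> None:
        for m in self.months:
            d, p, s = compare_models(np.array(self.r2_ss[m]), np.array(self.r2_ic[m]))
            self.mean_delta[m] = d
            self.p_value[m] = p
            self.stars[m] = s

    @property
    def delta_range(self) -> tuple[float, float]:
        """Min and max of the per-month mean gains — the headline reporting
        format for the coupled-vs-single comparison."""
        vals = [self.mean_delta[m] for m in self.months]
        return (float(min(vals)), float(max(vals)))

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "iterations": self.iterations,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "p_value_note": "paired Wilcoxon over split-matched holdout iterations; descriptive",
            "months": self.months,
            "per_month": {
                str(m): {
                    "r2_ss": list(np.asarray(self.r2_ss[m], dtype=float)),
                    "r2_ic": list(np.asarray(self.r2_ic[m], dtype=float)),
                    "mean_delta_r2": self.mean_delta.get(m),
                    "wilcoxon_p": self.p_value.get(m),
                    "stars": self.stars.get(m),
                }
                for m in self.months
            },
            "delta_r2_range": list(self.delta_range) if self.mean_delta else None,
            "effort_fraction_optimal": self.effort_fraction_optimal,
            "high_effort_top_class": self.high_effort_top_class,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long form: one row per (month, iteration, model)."""
        rows = []
        for m in self.months:
            for label, vec in (("ss", self.r2_ss[m]), ("ic", self.r2_ic[m])):
                for it, v in enumerate(vec):
                    rows.append(
                        {"species": self.species, "month": m, "model": label, "iteration": it, "r2": v}
                    )
        return pd.DataFrame(rows)
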