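"""Shared fixtures: a small but complete synthetic study.

The small study runs on a 20x20-cell grid with two training years and two
months, scaled fleet budgets, and a light ensemble — big enough for every
pipeline stage to behave, small enough that the suite stays fast.  All
fixtures are session-scoped and deterministic.
"""

from __future__ import annotations

import pytest

from icsdm import EffortModel, GridSpec, StudyConfig, fit_stage, simulate_study
from icsdm.workflow import build_cell_samples

SMALL_GRID = GridSpec(lat_min=34.0, lat_max=39.0, lon_min=144.0, lon_max=149.0)


def small_config(**overrides) -> StudyConfig:
    base = dict(
        grid=SMALL_GRID,
        train_years=(2017, 2018),
        predict_year=2019,
        months=(6, 7),
        effort_a=EffortModel(monthly_budget=1500, detection_floor=0.05, trip_days=10),
        effort_b=EffortModel(monthly_budget=600, detection_floor=0.2, trip_days=10),
        n_trees=40,
        iterations=4,
        seed=7,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def study_config() -> StudyConfig:
    return small_config()


@pytest.fixture(scope="session")
def sim(study_config):
    return simulate_study(study_config)


@pytest.fixture(scope="session")
def samples(sim, study_config):
    return build_cell_samples(sim.logbook, sim.env, study_config.train_years)


@pytest.fixture(scope="session")
def fitted(study_config, sim):
    return fit_stage(study_config, sim)
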