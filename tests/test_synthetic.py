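"""Generator behaviour: environment fields, coupled truths, logbooks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icsdm import (
    COVARIATES,
    EffortModel,
    EnvStack,
    GridSpec,
    ResponseCurve,
    SpeciesResponse,
    default_responses,
    generate_environment,
    sample_logbook,
    true_suitability,
)
from icsdm.surfaces import HSISurface

GRID = GridSpec(lat_min=34.0, lat_max=39.0, lon_min=144.0, lon_max=149.0)


@pytest.fixture(scope="module")
def env():
    return generate_environment(GRID, [2020], [6, 7], seed=3)


def test_seeded_determinism_bit_identical():
    a = generate_environment(GRID, [2020], [6], seed=5)
    b = generate_environment(GRID, [2020], [6], seed=5)
    for c in COVARIATES:
        np.testing.assert_array_equal(a.data[c].values, b.data[c].values)
    c = generate_environment(GRID, [2020], [6], seed=6)
    assert not np.array_equal(a.data["T_0m"].values, c.data["T_0m"].values)


def test_environment_slices_complete(env):
    assert set(env.times()) == {(2020, 6), (2020, 7)}
    for c in COVARIATES:
        assert env.data[c].shape == (2, GRID.nlat, GRID.nlon)
        assert np.isfinite(env.data[c].values).all()


def test_temperature_decreases_with_depth(env):
    f = env.slice_fields(2020, 6)
    means = [np.nanmean(f[c]) for c in ("T_0m", "T_50m", "T_100m", "T_150m", "T_200m")]
    assert all(a > b for a, b in zip(means, means[1:]))
    # configured surface-to-200m lapse is 8.5 degC; noise is much smaller
    assert means[0] - means[-1] == pytest.approx(8.5, abs=1.0)


def test_surface_temperature_latitudinal_gradient(env):
    t0 = env.slice_fields(2020, 6)["T_0m"]
    south = t0[: GRID.nlat // 3].mean()
    north = t0[-GRID.nlat // 3 :].mean()
    assert south > north


def test_eke_consistent_with_current_anomalies(env):
    f = env.slice_fields(2020, 6)
    up = f["U"] - f["U"].mean()
    vp = f["V"] - f["V"].mean()
    np.testing.assert_allclose(f["EKE"], 0.5 * (up**2 + vp**2), atol=1e-12)


def test_zero_currents_give_zero_eke():
    # U == V == 0 everywhere: anomalies vanish identically, so EKE == 0
    u = np.zeros(GRID.shape)
    up = u - u.mean()
    eke = 0.5 * (up**2 + up**2)
    assert np.all(eke == 0.0)


def test_scalar_covariates_are_constant_per_month(env):
    for c in ("SSTA", "ONI"):
        field = env.slice_fields(2020, 6)[c]
        assert np.nanstd(field) == 0.0


def test_environment_input_validation():
    with pytest.raises(ValueError, match="month"):
        generate_environment(GRID, [2020], ["Springuary"], seed=0)
    with pytest.raises(ValueError, match="June"):
        generate_environment(GRID, [2020], [1], seed=0)
    with pytest.raises(ValueError, match="duplicate"):
        generate_environment(GRID, [2020, 2020], [6], seed=0)


def test_land_mask_propagates():
    mask = np.zeros(GRID.shape, dtype=bool)
    mask[:3, :3] = True
    env = generate_environment(GRID, [2020], [6], seed=1, mask=mask)
    f = env.slice_fields(2020, 6)
    assert np.isnan(f["T_0m"][:3, :3]).all()
    assert np.isfinite(f["T_0m"][3:, 3:]).all()


# -- species responses and truth surfaces -----------------------------------


def test_response_curve_validation():
    with pytest.raises(ValueError):
        ResponseCurve(optimum=1.0, tolerance=0.0)
    with pytest.raises(ValueError):
        ResponseCurve(optimum=1.0, tolerance=1.0, weight=-0.5)
    with pytest.raises(ValueError):
        SpeciesResponse("x", {"T_0m": ResponseCurve(1, 1, 0.0)})
    with pytest.raises(ValueError):
        SpeciesResponse("x", {"T_0m": ResponseCurve(1, 1)}, gamma=float("nan"))


def test_single_covariate_at_optimum_gives_unit_suitability():
    fields = {c: np.full(GRID.shape, 0.0) for c in COVARIATES}
    fields["T_0m"] = np.full(GRID.shape, 15.0)
    stack = EnvStack.from_arrays(GRID, {c: v[None] for c, v in fields.items()}, [2020], [6])
    resp = SpeciesResponse("solo", {"T_0m": ResponseCurve(15.0, 3.0, 1.0)})
    other = SpeciesResponse("other", {"SSS": ResponseCurve(0.0, 1.0, 1.0)})
    (surf,), _ = true_suitability(stack, resp, other)
    np.testing.assert_allclose(surf.values, 1.0)


def test_zero_coupling_isolates_species(env):
    resp_a, resp_b = default_responses(gamma_a=0.0, gamma_b=0.0)
    surfs_a1, _ = true_suitability(env, resp_a, resp_b)
    alt_b = SpeciesResponse("mackerel", {"SSH": ResponseCurve(0.5, 0.1, 1.0)}, gamma=0.0)
    surfs_a2, _ = true_suitability(env, resp_a, alt_b)
    np.testing.assert_array_equal(surfs_a1[0].values, surfs_a2[0].values)


def test_coupling_increases_cross_species_correlation(env):
    corrs = []
    for gamma in (0.0, 0.4, 0.8):
        resp_a, resp_b = default_responses(gamma_a=0.0, gamma_b=gamma)
        sa, sb = true_suitability(env, resp_a, resp_b)
        corrs.append(np.corrcoef(sa[0].values.ravel(), sb[0].values.ravel())[0, 1])
    assert corrs[0] < corrs[1] < corrs[2]


def test_missing_covariate_rejected(env):
    bad = SpeciesResponse("x", {"NO_SUCH": ResponseCurve(0, 1)})
    good = SpeciesResponse("y", {"SSS": ResponseCurve(34, 1)})
    with pytest.raises(KeyError, match="NO_SUCH"):
        true_suitability(env, bad, good)


def test_truth_in_unit_interval(env):
    resp_a, resp_b = default_responses()
    sa, sb = true_suitability(env, resp_a, resp_b)
    for s in sa + sb:
        assert np.nanmin(s.values) >= 0.0 and np.nanmax(s.values) <= 1.0


# -- logbook sampling --------------------------------------------------------


def _truth(value_array):
    return HSISurface(GRID, value_array, "sardine", 2020, 6, "truth")


def test_effort_budget_conserved(env):
    resp_a, resp_b = default_responses()
    sa, _ = true_suitability(env, resp_a, resp_b)
    em = EffortModel(monthly_budget=777, detection_floor=0.05, trip_days=10)
    lb = sample_logbook(sa[0], em, GRID, seed=9)
    assert lb["effort_days"].sum() == 777
    assert (lb["catch_t"] >= 0).all()
    assert lb["lat"].between(GRID.lat_min, GRID.lat_max).all()
    assert lb["lon"].between(GRID.lon_min, GRID.lon_max).all()
    assert set(lb.columns) == {
        "date", "lat", "lon", "species", "catch_t", "hauls",
        "effort_days", "vessel_id", "vessel_length_m",
    }


def test_extreme_concentration_hits_argmax_cell():
    vals = np.full(GRID.shape, 0.5)
    vals[7, 11] = 0.95
    em = EffortModel(monthly_budget=200, concentration=50.0, detection_floor=0.2, trip_days=5)
    lb = sample_logbook(_truth(vals), em, GRID, seed=1)
    ii, jj = GRID.assign_cell(lb["lat"].to_numpy(), lb["lon"].to_numpy())
    assert (ii == 7).all() and (jj == 11).all()


def test_noise_free_catch_is_effort_times_suitability():
    vals = np.full(GRID.shape, 0.5)
    em = EffortModel(monthly_budget=100, sigma=0.0, catchability=1.0,
                     detection_floor=0.2, trip_days=5)
    lb = sample_logbook(_truth(vals), em, GRID, seed=2)
    np.testing.assert_allclose(lb["catch_t"], 0.5 * lb["effort_days"])


def test_empty_feasible_region_raises():
    vals = np.full(GRID.shape, 0.1)
    with pytest.raises(ValueError, match="fishable"):
        sample_logbook(_truth(vals), EffortModel(detection_floor=0.5), GRID, seed=0)


def test_effort_tracks_suitability_rank():
    # k > 0: Spearman correlation between cell effort and truth is positive
    big = GridSpec()
    rng = np.random.default_rng(12)
    vals = np.clip(rng.uniform(0.05, 1.0, big.shape), 0, 1)
    truth = HSISurface(big, vals, "sardine", 2020, 6, "truth")
    em = EffortModel(monthly_budget=6000, concentration=1.0,
                     detection_floor=0.05, trip_days=1)
    lb = sample_logbook(truth, em, big, seed=3)
    ii, jj = big.assign_cell(lb["lat"].to_numpy(), lb["lon"].to_numpy())
    per_cell = pd.DataFrame({"i": ii, "j": jj, "e": lb["effort_days"]}).groupby(["i", "j"])["e"].sum()
    assert len(per_cell) >= 500
    suit = np.array([vals[i, j] for i, j in per_cell.index])
    rho = stats.spearmanr(per_cell.to_numpy(), suit).statistic
    assert rho > 0.2


def test_same_seed_identical_logbooks(env):
    resp_a, resp_b = default_responses()
    sa, _ = true_suitability(env, resp_a, resp_b)
    em = EffortModel(monthly_budget=300, trip_days=5, detection_floor=0.05)
    lb1 = sample_logbook(sa[0], em, GRID, seed=4)
    lb2 = sample_logbook(sa[0], em, GRID, seed=4)
    pd.testing.assert_frame_equal(lb1, lb2)
    lb3 = sample_logbook(sa[0], em, GRID, seed=5)
    assert not lb1.equals(lb3)
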