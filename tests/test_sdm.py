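"""Ensemble fitting, regional prediction, and the biotic covariate."""

import numpy as np
import pandas as pd
import pytest

from icsdm import (
    COVARIATES,
    EnvStack,
    GridSpec,
    HSISurface,
    ModelSpec,
    build_biotic_feature,
    fit_icsdm,
    fit_sssdm,
    partial_response,
    predict_icsdm,
    predict_regional,
)
from icsdm.sdm import BIOTIC_FEATURE, FittedSDM

GRID = GridSpec(lat_min=34.0, lat_max=35.0, lon_min=144.0, lon_max=145.0)  # 4x4


def make_samples(n=200, response=None, seed=0, species="sardine"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({c: rng.normal(size=n) for c in COVARIATES})
    if response is None:
        response = np.clip(0.5 + 0.3 * np.tanh(df["T_0m"]), 0, 1)
    df["hsi_emp"] = response
    df["species"] = species
    df["year"] = 2020
    df["month"] = 6
    df["i"] = rng.integers(0, GRID.nlat, n)
    df["j"] = rng.integers(0, GRID.nlon, n)
    df["complete"] = True
    return df


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(n_trees=0)
    with pytest.raises(ValueError):
        ModelSpec(mtry=0)
    with pytest.raises(ValueError):
        ModelSpec(covariates=("T_0m", "SSS"), mtry=4)


def test_refuses_constant_response_without_override():
    df = make_samples(response=np.full(200, 0.7))
    with pytest.raises(ValueError, match="constant"):
        fit_sssdm(df, ModelSpec(n_trees=10))
    model = fit_sssdm(df, ModelSpec(n_trees=10), allow_constant=True)
    np.testing.assert_allclose(model.predict(df), 0.7)


def test_too_few_rows_rejected():
    with pytest.raises(ValueError, match="at least 30"):
        fit_sssdm(make_samples(n=10), ModelSpec(n_trees=10))


def test_step_function_recovered():
    rng = np.random.default_rng(1)
    df = make_samples(n=2000, seed=1)
    df["hsi_emp"] = (df["SSH"] > 0).astype(float)
    train, test = df.iloc[:1600], df.iloc[1600:]
    model = fit_sssdm(train, ModelSpec(n_trees=100, seed=5))
    pred = model.predict(test)
    y = test["hsi_emp"].to_numpy()
    r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
    assert r2 >= 0.9


def test_seeded_determinism_and_importances():
    df = make_samples(n=300)
    m1 = fit_sssdm(df, ModelSpec(n_trees=50, seed=11))
    m2 = fit_sssdm(df, ModelSpec(n_trees=50, seed=11))
    pd.testing.assert_series_equal(m1.importances, m2.importances)
    assert (m1.importances >= 0).all()
    assert m1.importances.sum() == pytest.approx(1.0)
    m3 = fit_sssdm(df, ModelSpec(n_trees=50, seed=12))
    assert not m1.importances.equals(m3.importances)


def test_prediction_invariant_to_row_and_column_order():
    df = make_samples(n=300)
    model = fit_sssdm(df, ModelSpec(n_trees=30, seed=2))
    X = df.sample(frac=1, random_state=3)
    p1 = model.predict(X)
    p2 = model.predict(X[list(reversed(X.columns))])
    np.testing.assert_array_equal(p1, p2)


def test_predictions_bounded_by_training_response():
    df = make_samples(n=300)
    df["hsi_emp"] = np.clip(df["hsi_emp"], 0.2, 0.8)
    model = fit_sssdm(df, ModelSpec(n_trees=30, seed=2))
    lo, hi = model.response_range
    pred = model.predict(make_samples(n=500, seed=9))
    assert pred.min() >= lo - 1e-12 and pred.max() <= hi + 1e-12
    # the [0, 1] clip inside predict() is a no-op for tree means
    assert pred.min() >= 0.0 and pred.max() <= 1.0


def toy_stack(values: dict, mask=None):
    fields = {c: np.full((1,) + GRID.shape, values.get(c, 0.0)) for c in COVARIATES}
    return EnvStack.from_arrays(GRID, fields, [2020], [6], mask=mask)


def test_regional_prediction_constant_env_gives_constant_surface():
    df = make_samples(n=300)
    model = fit_sssdm(df, ModelSpec(n_trees=30, seed=2))
    surf = predict_regional(model, toy_stack({"T_0m": 0.3}), GRID, 2020, 6)
    assert surf.role == "regional_ss"
    vals = surf.unmasked()
    assert np.ptp(vals) == 0.0


def test_regional_prediction_matches_per_cell_loop():
    df = make_samples(n=300, seed=4)
    model = fit_sssdm(df, ModelSpec(n_trees=20, seed=3))
    rng = np.random.default_rng(5)
    fields = {c: rng.normal(size=(1,) + GRID.shape) for c in COVARIATES}
    env = EnvStack.from_arrays(GRID, fields, [2020], [6])
    surf = predict_regional(model, env, GRID, 2020, 6)
    for i in range(GRID.nlat):
        for j in range(GRID.nlon):
            row = pd.DataFrame({c: [fields[c][0, i, j]] for c in COVARIATES})
            assert surf.values[i, j] == pytest.approx(float(model.predict(row)[0]))


def test_masked_cells_propagate():
    mask = np.zeros(GRID.shape, dtype=bool)
    mask[0, :] = True
    df = make_samples(n=300)
    model = fit_sssdm(df, ModelSpec(n_trees=10, seed=2))
    surf = predict_regional(model, toy_stack({}, mask=mask), GRID, 2020, 6)
    assert np.isnan(surf.values[0]).all()
    assert np.isfinite(surf.values[1:]).all()


# -- biotic feature ----------------------------------------------------------


def surface(values, role="regional_ss", species="mackerel"):
    return HSISurface(GRID, values, species, 2020, 6, role)


def test_biotic_feature_constant_surface():
    df = make_samples(n=50)
    aug = build_biotic_feature(df, surface(np.full(GRID.shape, 0.4)))
    assert (aug[BIOTIC_FEATURE] == 0.4).all()
    assert aug["complete"].all()


def test_biotic_feature_symmetric_construction():
    rng = np.random.default_rng(6)
    vals_a = rng.uniform(size=GRID.shape)
    vals_b = rng.uniform(size=GRID.shape)
    df_a = make_samples(n=50, species="sardine")
    df_b = make_samples(n=50, species="mackerel", seed=7)
    aug_a = build_biotic_feature(df_a, surface(vals_b, species="mackerel"))
    aug_b = build_biotic_feature(df_b, surface(vals_a, species="sardine"))
    np.testing.assert_allclose(
        aug_a[BIOTIC_FEATURE], vals_b[df_a["i"], df_a["j"]]
    )
    np.testing.assert_allclose(
        aug_b[BIOTIC_FEATURE], vals_a[df_b["i"], df_b["j"]]
    )


def test_biotic_feature_rejects_non_regional_roles():
    df = make_samples(n=50)
    with pytest.raises(ValueError, match="regional_ss"):
        build_biotic_feature(df, surface(np.full(GRID.shape, 0.4), role="ic"))


def test_biotic_feature_hand_join():
    vals = np.zeros(GRID.shape)
    vals[1, 2] = 0.9
    vals[0, 0] = 0.1
    df = make_samples(n=50).iloc[:3].copy()
    df["i"] = [1, 0, 1]
    df["j"] = [2, 0, 2]
    aug = build_biotic_feature(df, surface(vals))
    np.testing.assert_allclose(aug[BIOTIC_FEATURE], [0.9, 0.1, 0.9])


def test_masked_surface_cell_flags_incomplete():
    vals = np.full(GRID.shape, 0.5)
    vals[0, 0] = np.nan
    df = make_samples(n=50).iloc[:2].copy()
    df["i"] = [0, 1]
    df["j"] = [0, 1]
    aug = build_biotic_feature(df, surface(vals))
    assert not aug["complete"].iloc[0]
    assert aug["complete"].iloc[1]


def test_icsdm_requires_biotic_column():
    df = make_samples(n=100)
    with pytest.raises(KeyError, match=BIOTIC_FEATURE):
        fit_icsdm(df, ModelSpec(n_trees=10))


def test_icsdm_reduces_to_sssdm_without_biotic_feature():
    # identical covariates and seed: the coupled fit without hsi_other is
    # the single-species fit
    df = make_samples(n=300)
    spec = ModelSpec(n_trees=20, seed=9)
    m_ss = fit_sssdm(df, spec)
    aug = build_biotic_feature(df, surface(np.full(GRID.shape, 0.4)))
    m_ic_reduced = fit_icsdm(aug.assign(**{BIOTIC_FEATURE: aug[BIOTIC_FEATURE]}), spec.with_biotic())
    # compare against a fit that ignores the extra column entirely
    m_plain = fit_sssdm(aug[list(df.columns)], spec)
    probe = make_samples(n=100, seed=10)
    np.testing.assert_array_equal(m_ss.predict(probe), m_plain.predict(probe))


def test_predict_icsdm_mask_and_month_guards():
    df = make_samples(n=300)
    aug = build_biotic_feature(df, surface(np.full(GRID.shape, 0.4)))
    model = fit_icsdm(aug, ModelSpec(n_trees=10, seed=1).with_biotic())
    env = toy_stack({"T_0m": 0.1})
    comp = np.full(GRID.shape, 0.4)
    comp[2, 2] = np.nan
    out = predict_icsdm(model, env, surface(comp), GRID, 2020, 6)
    assert out.role == "ic"
    assert np.isnan(out.values[2, 2]) and np.isfinite(out.values[0, 0])
    with pytest.raises(ValueError, match="2020-07"):
        wrong = HSISurface(GRID, comp, "mackerel", 2020, 7, "regional_ss")
        predict_icsdm(model, env, wrong, GRID, 2020, 6)
    with pytest.raises(ValueError, match="regional_ss"):
        predict_icsdm(model, env, surface(comp, role="ic"), GRID, 2020, 6)


def test_constant_competitor_equals_sssdm_style_prediction():
    df = make_samples(n=300)
    aug = build_biotic_feature(df, surface(np.full(GRID.shape, 0.4)))
    model = fit_icsdm(aug, ModelSpec(n_trees=15, seed=2).with_biotic())
    env = toy_stack({"T_0m": -0.3, "SSS": 1.0})
    out = predict_icsdm(model, env, surface(np.full(GRID.shape, 0.4)), GRID, 2020, 6)
    # constant covariates and constant competitor: spatially constant field
    assert np.ptp(out.unmasked()) == 0.0


def test_partial_response_peaks_at_optimum_for_band_response():
    rng = np.random.default_rng(13)
    df = make_samples(n=2000, seed=13)
    df["hsi_emp"] = np.exp(-0.5 * ((df["T_0m"] - 0.5) / 0.8) ** 2)
    model = fit_sssdm(df, ModelSpec(n_trees=60, seed=3))
    grid_vals = np.linspace(-3, 3, 121)
    curve = partial_response(model, "T_0m", grid_vals)
    assert abs(grid_vals[np.argmax(curve)] - 0.5) < 0.4


def test_save_load_roundtrip(tmp_path):
    df = make_samples(n=100)
    model = fit_sssdm(df, ModelSpec(n_trees=10, seed=4))
    p = tmp_path / "model.pkl"
    model.save(p)
    loaded = FittedSDM.load(p)
    probe = make_samples(n=30, seed=5)
    np.testing.assert_array_equal(model.predict(probe), loaded.predict(probe))
    assert p.with_suffix(".pkl.json").exists()


def test_importance_reflects_coupling(fitted, study_config):
    """With gamma_b = 0.8 the injected competitor suitability should rank
    among the informative covariates for the coupled species."""
    imp = fitted.models_ic["mackerel"].importances
    assert imp[BIOTIC_FEATURE] > imp.median()
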