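"""Penalized-spline mixed model: basis, limits, recovery, inference."""
import numpy as np
import pandas as pd
import pytest

from equipain.association import (ModelData, build_penalized_basis,
                                  fit_association_model, partial_effect_curve,
                                  predict_scores)
from equipain.exceptions import ConfigurationError, InsufficientDataError

from conftest import simulate_model_frame


# ------------------------------------------------------------------- basis

def de_boor(knots, degree, j, x):
    """Independent recursive B-spline evaluator (Cox-de Boor)."""
    if degree == 0:
        # half-open intervals, closed at the right boundary
        if knots[j] <= x < knots[j + 1]:
            return 1.0
        if x == knots[-1] and knots[j] < knots[j + 1] <= x:
            return 1.0
        return 0.0
    out = 0.0
    d1 = knots[j + degree] - knots[j]
    if d1 > 0:
        out += (x - knots[j]) / d1 * de_boor(knots, degree - 1, j, x)
    d2 = knots[j + degree + 1] - knots[j + 1]
    if d2 > 0:
        out += (knots[j + degree + 1] - x) / d2 * de_boor(knots, degree - 1, j + 1, x)
    return out


def test_basis_partition_of_unity_and_de_boor_oracle():
    rng = np.random.default_rng(1)
    x = rng.uniform(0.0, 80.0, 120)
    basis = build_penalized_basis(x, k=10)
    B = basis.design(x)
    np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
    for xv in [0.5, 11.0, 40.0, 79.0]:
        row = basis.design(np.array([xv]))[0]
        ref = [de_boor(basis.knots, 3, j, xv) for j in range(basis.k)]
        np.testing.assert_allclose(row, ref, atol=1e-10)


def test_penalty_null_space_is_linear():
    rng = np.random.default_rng(2)
    x = rng.uniform(0.0, 80.0, 100)
    basis = build_penalized_basis(x, k=10)
    greville = np.array([basis.knots[j + 1: j + 4].mean() for j in range(basis.k)])
    alpha = 1.5 - 0.3 * greville  # coefficients of an exactly linear spline
    assert alpha @ basis.penalty @ alpha == pytest.approx(0.0, abs=1e-8)
    # and the spline they define is that straight line
    grid = np.linspace(0, 80, 33)
    np.testing.assert_allclose(basis.design(grid) @ alpha, 1.5 - 0.3 * grid,
                               atol=1e-9)


def test_basis_dimension_guard():
    with pytest.raises(ConfigurationError):
        build_penalized_basis(np.array([1.0, 2.0, 3.0]), k=10)


# ----------------------------------------------------------------- fitting

def test_ols_limit_equivalence():
    rng = np.random.default_rng(3)
    df = simulate_model_frame(rng, n_horses=4, per_horse=30)
    fit = fit_association_model(df, fix_lambda=np.inf, fix_phi=0.0,
                                fix_sigma2_horse_ratio=0.0)
    d = df.sort_values(["horse", "prop_time_pct"], kind="mergesort")
    X = np.column_stack([
        np.ones(len(d)),
        (d["timing"] == "before_gait").astype(float),
        d["tas_mm"] - d["tas_mm"].mean(),
    ])
    beta = np.linalg.lstsq(X, d["total"].to_numpy(), rcond=None)[0]
    np.testing.assert_allclose(fit.coef[:3], beta, atol=1e-6)
    assert fit.edf == pytest.approx(1.0, abs=1e-8)


def test_linear_truth_recovery():
    """Median over replicates: slope, EDF~1 and phi recovered at n=400.

    A single REML fit's EDF has a right tail even under linear truth, so the
    linearity property is asserted on the replicate median.
    """
    rng = np.random.default_rng(4)
    slopes, edfs, phis = [], [], []
    fit = None
    for _ in range(21):
        df = simulate_model_frame(rng, n_horses=8, per_horse=50, phi=0.0,
                                  sigma2_horse=0.0, slope=0.1)
        fit = fit_association_model(df, compute_tests=False)
        curve = partial_effect_curve(fit, np.linspace(5, 75, 30))
        slopes.append(np.polyfit(curve["tas"], curve["estimate"], 1)[0])
        edfs.append(fit.edf)
    for _ in range(7):
        df = simulate_model_frame(rng, n_horses=20, per_horse=20, phi=0.3,
                                  sigma2_horse=0.5, slope=0.1)
        phis.append(fit_association_model(df, compute_tests=False).phi)
    assert np.median(slopes) == pytest.approx(0.1, abs=0.02)
    assert np.median(edfs) <= 1.5
    assert np.median(phis) == pytest.approx(0.3, abs=0.1)
    # last replicate: straight line fits inside the pointwise band
    curve = partial_effect_curve(fit, np.linspace(5, 75, 30))
    resid = curve["estimate"] - np.polyval(np.polyfit(curve["tas"],
                                                      curve["estimate"], 1),
                                           curve["tas"])
    assert np.all(np.abs(resid) <= (curve["hi"] - curve["lo"]) / 2 + 1e-9)


def test_cubic_truth_needs_curvature():
    rng = np.random.default_rng(5)
    df = simulate_model_frame(
        rng, n_horses=10, per_horse=40, noise_sd=0.5,
        curve=lambda t: 5.0 * np.sin(t / 80.0 * 2.5))
    fit = fit_association_model(df)
    assert fit.edf >= 2.5


def test_timing_effect_wald():
    rng = np.random.default_rng(6)
    df = simulate_model_frame(rng, n_horses=10, per_horse=40, timing_effect=1.0,
                              noise_sd=1.0)
    fit = fit_association_model(df)
    assert fit.timing_coef == pytest.approx(1.0, abs=0.3)
    assert fit.p_timing < 0.01


def test_predictions_and_extrapolation():
    rng = np.random.default_rng(7)
    df = simulate_model_frame(rng, n_horses=6, per_horse=25)
    fit = fit_association_model(df)
    d = df.sort_values(["horse", "prop_time_pct"], kind="mergesort")
    pred_cond = predict_scores(fit, d, conditional=True)
    np.testing.assert_allclose(pred_cond, fit.fitted_conditional, atol=1e-10)
    # monotone smooth -> predictions monotone in tas on a grid
    grid = pd.DataFrame({"tas_mm": np.linspace(0, 80, 40),
                         "timing": "after_gait"})
    pg = predict_scores(fit, grid)
    assert np.all(np.diff(pg) > -1e-6)
    with pytest.warns(UserWarning, match="outside the training range"):
        predict_scores(fit, pd.DataFrame({"tas_mm": [500.0],
                                          "timing": ["after_gait"]}))


def test_partial_effect_centred_and_shrinks_with_n():
    rng = np.random.default_rng(8)
    small = simulate_model_frame(rng, n_horses=5, per_horse=20)
    large = simulate_model_frame(rng, n_horses=10, per_horse=40)
    grid = np.linspace(5, 75, 25)
    w = []
    for df in (small, large):
        fit = fit_association_model(df, compute_tests=False)
        curve = partial_effect_curve(fit, grid)
        w.append(float(np.mean(curve["hi"] - curve["lo"])))
        # centred over the training values
        x_lin, Z = fit.basis.smooth_columns(
            df.sort_values(["horse", "prop_time_pct"])["tas_mm"].to_numpy())
        train_effect = np.column_stack([x_lin, Z]) @ fit.coef[2:]
        centred = partial_effect_curve(
            fit, df.sort_values(["horse", "prop_time_pct"])["tas_mm"].to_numpy())
        assert np.mean(centred["estimate"]) == pytest.approx(0.0, abs=1e-8)
    assert w[1] < w[0]


def test_negative_r2_possible_on_null_data():
    rng = np.random.default_rng(9)
    seen_negative = False
    for _ in range(40):
        df = simulate_model_frame(rng, n_horses=4, per_horse=6, slope=0.0,
                                  timing_effect=0.0)
        fit = fit_association_model(df, compute_tests=False)
        if fit.r2_adj < 0:
            seen_negative = True
            break
    assert seen_negative


def test_preconditions():
    rng = np.random.default_rng(10)
    tiny = simulate_model_frame(rng, n_horses=2, per_horse=5)
    with pytest.raises(InsufficientDataError):
        fit_association_model(tiny)
    one_horse = simulate_model_frame(rng, n_horses=1, per_horse=30)
    with pytest.raises(InsufficientDataError):
        fit_association_model(one_horse)
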