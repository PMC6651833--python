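"""Unit and property tests for the four line-fitting methods."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from bbpcarbon import (
    BivariateDataset,
    DegenerateDataError,
    InsufficientDataError,
    NotSignificantError,
    UndefinedSlopeError,
    correlation_significance,
    fit_all,
    fit_ma,
    fit_ols,
    fit_rma,
    fit_sma,
)
from conftest import random_dataset


# --- worked example -------------------------------------------------------

@pytest.mark.parametrize(
    "fitter, B, A",
    [
        (fit_ols, 0.9, 1.3),
        (fit_sma, 1.0, 1.0),
        (fit_ma, 1.0, 1.0),
        (fit_rma, 1.0, 1.0),
    ],
)
def test_worked_example_slopes_intercepts(worked_dataset, fitter, B, A):
    fit = fitter(worked_dataset)
    assert fit.B == pytest.approx(B, abs=1e-12)
    assert fit.A == pytest.approx(A, abs=1e-12)
    assert fit.r == pytest.approx(0.9, abs=1e-12)
    assert fit.r2 == pytest.approx(0.81, abs=1e-12)
    assert fit.n == 5


def test_worked_example_ols_standard_errors(worked_dataset):
    # hand computation: SSE = 10 - 81/10 = 1.9, s^2 = 1.9/3
    fit = fit_ols(worked_dataset)
    s2 = 1.9 / 3.0
    assert fit.se_B == pytest.approx(math.sqrt(s2 / 10.0), rel=1e-12)
    assert fit.se_A == pytest.approx(math.sqrt(s2 * (1 / 5 + 9 / 10)), rel=1e-12)


def test_sma_se_b_equals_ols_se_b(worked_dataset):
    assert fit_sma(worked_dataset).se_B == fit_ols(worked_dataset).se_B


# --- exact-line and degenerate cases --------------------------------------

def test_exact_line_all_methods_identical(exact_line):
    for fit in fit_all(exact_line):
        assert fit.B == pytest.approx(2.0, rel=1e-12)
        assert fit.A == pytest.approx(1.0, rel=1e-10)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.predict(exact_line.x), exact_line.y, atol=1e-10)


@pytest.mark.parametrize("fitter", [fit_ols, fit_sma, fit_rma])
def test_constant_x_raises(fitter):
    data = BivariateDataset([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
    with pytest.raises(DegenerateDataError):
        fitter(data)


def test_too_few_points_raises():
    with pytest.raises(InsufficientDataError):
        fit_ols(BivariateDataset([1.0, 2.0], [1.0, 2.0]))


def test_ma_zero_covariance_raises():
    # symmetric cross: Sxy = 0 exactly
    data = BivariateDataset([-1.0, 1.0, 0.0, 0.0], [0.0, 0.0, -1.0, 1.0])
    with pytest.raises(UndefinedSlopeError):
        fit_ma(data)


def test_sma_gate_refuses_uncorrelated_data():
    rng = np.random.default_rng(7)
    x = np.arange(10.0)
    y = rng.permutation(np.arange(10.0))  # shuffled: near-zero correlation
    data = BivariateDataset(x, y)
    assert not correlation_significance(data).significant
    with pytest.raises(NotSignificantError):
        fit_sma(data, require_significance=True)
    # gate off: the fit proceeds
    assert np.isfinite(fit_sma(data, require_significance=False).B)


# --- correlation significance ---------------------------------------------

def test_significance_worked_example(worked_dataset):
    sig = correlation_significance(worked_dataset, alpha=0.05)
    assert sig.t == pytest.approx(0.9 * math.sqrt(3) / math.sqrt(0.19), rel=1e-12)
    assert sig.t == pytest.approx(3.576, abs=5e-4)
    assert sig.p == pytest.approx(0.0374, abs=5e-4)
    assert sig.significant and not sig.degenerate


def test_significance_zero_r_fails():
    data = BivariateDataset([-1.0, 1.0, 0.0, 0.0], [0.0, 0.0, -1.0, 1.0])
    sig = correlation_significance(data)
    assert sig.r == 0.0 and not sig.significant


def test_significance_perfect_line_degenerate(exact_line):
    sig = correlation_significance(exact_line)
    assert sig.significant and sig.degenerate and math.isinf(sig.t) and sig.p == 0.0


# --- oracle equivalence ----------------------------------------------------

def _minimize(fun, x0):
    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14,
                                     "maxiter": 20_000})
    return res.x


@pytest.mark.parametrize("seed", range(20))
def test_ols_matches_vertical_sse_minimizer(seed):
    data = random_dataset(np.random.default_rng(100 + seed))
    fit = fit_ols(data)

    def sse(p):
        b, a = p
        return float(np.sum((data.y - b * data.x - a) ** 2))

    b, a = _minimize(sse, [0.0, float(data.y.mean())])
    assert fit.B == pytest.approx(b, rel=1e-6, abs=1e-9)
    assert fit.A == pytest.approx(a, rel=1e-6, abs=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_ma_matches_perpendicular_sse_minimizer(seed):
    data = random_dataset(np.random.default_rng(200 + seed))
    fit = fit_ma(data)

    def perp_sse(p):
        b, a = p
        return float(np.sum((data.y - b * data.x - a) ** 2) / (1.0 + b * b))

    b0, a0 = fit_ols(data).B, fit_ols(data).A
    b, a = _minimize(perp_sse, [b0, a0])
    assert fit.B == pytest.approx(b, rel=1e-6, abs=1e-9)
    assert fit.A == pytest.approx(a, rel=1e-6, abs=1e-9)


def test_rma_equals_two_step_procedure(worked_dataset):
    d = worked_dataset
    rx, ry = np.ptp(d.x), np.ptp(d.y)
    norm = BivariateDataset((d.x - d.x.min()) / rx, (d.y - d.y.min()) / ry)
    expected = fit_ma(norm).B * ry / rx
    assert fit_rma(d).B == pytest.approx(expected, rel=1e-12)


def test_rma_outlier_sensitivity(worked_dataset):
    before = fit_rma(worked_dataset).B
    x = np.append(worked_dataset.x, 50.0)
    y = np.append(worked_dataset.y, 5.0)  # extreme leverage point off the line
    after = fit_rma(BivariateDataset(x, y)).B
    assert abs(after - before) / abs(before) > 0.05


# --- cross-method identities ----------------------------------------------

@pytest.mark.parametrize("seed", range(15))
def test_method_identities(seed):
    data = random_dataset(np.random.default_rng(300 + seed))
    ols, sma, ma, rma = fit_all(data, require_significance=False)
    # B_SMA = B_OLS / |r| (sign carried by r itself: B_SMA = sign(r)·s_y/s_x)
    assert sma.B == pytest.approx(ols.B / abs(ols.r),
                                  abs=1e-12 * max(1, abs(sma.B)))
    # |B_OLS| <= |B_SMA|, equality only for perfect correlation
    assert abs(ols.B) <= abs(sma.B) + 1e-15
    # r and r2 do not depend on the method
    for f in (sma, ma, rma):
        assert f.r == ols.r and f.r2 == ols.r2
    # every line passes through the centroid
    xbar, ybar = data.x.mean(), data.y.mean()
    for f in (ols, sma, ma, rma):
        assert f.predict(xbar) == pytest.approx(ybar, abs=1e-10 * max(1, abs(ybar)))


@pytest.mark.parametrize("seed", range(10))
def test_sma_axis_swap_gives_reciprocal_slope(seed):
    data = random_dataset(np.random.default_rng(400 + seed))
    b_xy = fit_sma(data, require_significance=False).B
    b_yx = fit_sma(data.swapped(), require_significance=False).B
    assert b_xy * b_yx == pytest.approx(1.0, rel=1e-10)


def test_ols_axis_swap_not_reciprocal(worked_dataset):
    # counterexample: slopes 0.9 both ways, product 0.81 = r^2, not 1
    b_xy = fit_ols(worked_dataset).B
    b_yx = fit_ols(worked_dataset.swapped()).B
    assert b_xy * b_yx == pytest.approx(0.81, abs=1e-12)
    assert b_xy * b_yx != pytest.approx(1.0, abs=1e-3)


def test_ma_axis_swap_gives_reciprocal_slope(worked_dataset):
    b = fit_ma(worked_dataset).B
    b_swapped = fit_ma(worked_dataset.swapped()).B
    assert b_swapped == pytest.approx(1.0 / b, rel=1e-12)


def test_sma_minus_ols_vanishes_as_noise_shrinks():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 10, size=80)
    noise = rng.normal(size=80)
    gaps = []
    for scale in [2.0, 1.0, 0.5, 0.25, 0.1, 0.01]:
        data = BivariateDataset(x, 1.7 * x + 3.0 + scale * noise)
        gaps.append(abs(fit_sma(data).B - fit_ols(data).B))
    assert all(a > b for a, b in zip(gaps, gaps[1:]))
    assert gaps[-1] < 1e-3


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
        min_size=4, max_size=40, unique_by=lambda p: p[0],
    )
)
def test_sma_ols_identity_property(points):
    x, y = map(np.array, zip(*points))
    data = BivariateDataset(x, y)
    if np.ptp(data.x) == 0 or np.ptp(data.y) == 0:
        return
    ols = fit_ols(data)
    if ols.r == 0:
        return
    sma = fit_sma(data, require_significance=False)
    assert sma.B == pytest.approx(ols.B / abs(ols.r), rel=1e-9, abs=1e-9)
    assert abs(ols.B) <= abs(sma.B) * (1 + 1e-12)


# --- dataset hygiene -------------------------------------------------------

def test_missing_rows_dropped_and_counted():
    data = BivariateDataset([1, 2, np.nan, 4, 5], [2, np.inf, 3, 4, 5])
    assert data.n == 3
    assert data.n_dropped == 2


def test_read_delimited_roundtrip(tmp_path, worked_dataset):
    path = tmp_path / "pairs.csv"
    path.write_text("tchla,bbp\n" + "\n".join(
        f"{a},{b}" for a, b in zip(worked_dataset.x, worked_dataset.y)))
    data = BivariateDataset.read_delimited(path)
    assert data.labels == ("tchla", "bbp")
    np.testing.assert_allclose(data.x, worked_dataset.x)
    np.testing.assert_allclose(data.y, worked_dataset.y)
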