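"""Type-I and type-II (model-II) linear regression.

Fits a straight line ``y = B*x + A`` through paired observations using one of
four estimators that differ in the deviations they minimize and therefore in
the scientific question they answer:

``OLS``
    Ordinary least squares (type I). Minimizes vertical deviations; the
    estimator of choice when the goal is to *predict* y from an x that is
    controlled or nearly error-free.
``SMA``
    Standard major axis (type II; also called reduced major axis).
    Slope is ``sign(r) * s_y / s_x``; appropriate when both variables carry
    comparable uncertainty and the slope/intercept themselves are the target.
``MA``
    Major axis (type II). Minimizes perpendicular distances; appropriate for
    bivariate-normal data sharing units and error variance.
``RMA``
    Ranged major axis (type II). MA computed on range-normalized data and
    back-transformed, so heterogeneous units can be mixed; sensitive to
    outliers because they stretch the normalizing ranges.

When the predictor is measured with error, the OLS slope is attenuated
(regression dilution) by the factor ``Var(x_true) / (Var(x_true) + Var(err_x))``
while SMA is unbiased when the error-variance ratio matches the slope; the
difference between methods vanishes as ``|r| -> 1``.

SMA should only be computed when the correlation between x and y is
significant, so :func:`fit_sma` applies a two-tailed t-test gate on r by
default (``alpha = 0.05``); the SMA slope itself cannot be tested for
significance and no such test is offered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BivariateDataset",
    "LinearFit",
    "SignificanceResult",
    "RegressionError",
    "InsufficientDataError",
    "DegenerateDataError",
    "UndefinedSlopeError",
    "NotSignificantError",
    "fit_ols",
    "fit_sma",
    "fit_ma",
    "fit_rma",
    "fit_all",
    "correlation_significance",
    "fits_to_frame",
    "write_fit_report",
]

MIN_N = 3  # smallest sample size any fit accepts


class RegressionError(ValueError):
    """Base class for regression failures."""


class InsufficientDataError(RegressionError):
    """Fewer than three finite (x, y) pairs."""


class DegenerateDataError(RegressionError):
    """A variable has zero variance (or zero range, for RMA)."""


class UndefinedSlopeError(RegressionError):
    """The slope sign/orientation is undefined (r = 0 or Sxy = 0)."""


class NotSignificantError(RegressionError):
    """The correlation-significance gate refused an SMA fit."""


@dataclass(frozen=True)
class BivariateDataset:
    """Paired (x, y) observations: the substrate of every fit.

    Rows with non-finite values in either variable are dropped on
    construction and counted in ``n_dropped``.

    Parameters
    ----------
    x, y : array-like
        Observations; equal length.
    labels : (str, str)
        Names of the x and y variables.
    units : (str, str)
        Units carried as metadata (not used in computation).
    """

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("x", "y")
    units: tuple[str, str] = ("", "")
    n_dropped: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError(
                f"x and y must have equal length (got {x.size} and {y.size})"
            )
        keep = np.isfinite(x) & np.isfinite(y)
        dropped = int(x.size - keep.sum())
        object.__setattr__(self, "x", x[keep])
        object.__setattr__(self, "y", y[keep])
        object.__setattr__(self, "n_dropped", self.n_dropped + dropped)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "units", tuple(self.units))

    @property
    def n(self) -> int:
        return int(self.x.size)

    def swapped(self) -> "BivariateDataset":
        """Return the dataset with the roles of x and y interchanged."""
        return BivariateDataset(
            self.y, self.x, labels=(self.labels[1], self.labels[0]),
            units=(self.units[1], self.units[0]),
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x: str,
        y: str,
        units: tuple[str, str] = ("", ""),
    ) -> "BivariateDataset":
        return cls(df[x].to_numpy(), df[y].to_numpy(), labels=(x, y), units=units)

    @classmethod
    def read_delimited(
        cls,
        path: str | Path,
        x: str | None = None,
        y: str | None = None,
        sep: str | None = None,
    ) -> "BivariateDataset":
        """Read a two-column delimited text file (CSV/TSV with a header row).

        By default the first column is x and the second y; ``x``/``y`` select
        columns by header name.
        """
        df = pd.read_csv(path, sep=sep, engine="python")
        if x is None:
            x = df.columns[0]
        if y is None:
            y = df.columns[1]
        return cls.from_dataframe(df, x, y)


@dataclass(frozen=True)
class LinearFit:
    """Result of a straight-line fit ``y = B*x + A``.

    ``r`` and ``r2`` are properties of the data, identical across methods;
    every method's line passes through the centroid (x̄, ȳ). Standard errors
    are populated for OLS and SMA; MA and RMA report NaN.
    """

    method: str
    B: float
    A: float
    se_B: float
    se_A: float
    r: float
    r2: float
    n: int

    def predict(self, x: Iterable[float] | float) -> np.ndarray | float:
        return self.B * np.asarray(x, dtype=float) + self.A

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SignificanceResult:
    """Two-tailed test of H0: r = 0 via ``t = r*sqrt(n-2)/sqrt(1-r^2)``."""

    significant: bool
    t: float
    p: float
    r: float
    n: int
    alpha: float
    degenerate: bool = False  # |r| = 1: infinite t, significant by convention


def _validated_moments(data: BivariateDataset):
    """Centroid and corrected sums of squares/products; checks n >= 3."""
    if data.n < MIN_N:
        raise InsufficientDataError(
            f"need at least {MIN_N} finite pairs, got {data.n}"
        )
    x, y = data.x, data.y
    xbar, ybar = float(x.mean()), float(y.mean())
    dx, dy = x - xbar, y - ybar
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    return xbar, ybar, sxx, syy, sxy


def _pearson(sxx: float, syy: float, sxy: float) -> float:
    if sxx <= 0.0 or syy <= 0.0:
        return 0.0
    r = sxy / math.sqrt(sxx * syy)
    return float(min(1.0, max(-1.0, r)))


def correlation_significance(
    data: BivariateDataset, alpha: float = 0.05
) -> SignificanceResult:
    """Decide whether the correlation between x and y differs from zero.

    Uses the exact t-statistic with ``n - 2`` degrees of freedom. A perfect
    correlation (|r| = 1) is significant by convention and flagged degenerate.
    """
    _, _, sxx, syy, sxy = _validated_moments(data)
    r = _pearson(sxx, syy, sxy)
    n = data.n
    denom = 1.0 - r * r
    if denom <= 0.0:
        return SignificanceResult(True, math.inf, 0.0, r, n, alpha, degenerate=True)
    t = r * math.sqrt(n - 2) / math.sqrt(denom)
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return SignificanceResult(p < alpha, t, p, r, n, alpha)


def _ols_core(xbar, ybar, sxx, syy, sxy, n):
    b = sxy / sxx
    a = ybar - b * xbar
    sse = max(syy - sxy * sxy / sxx, 0.0)
    s2 = sse / (n - 2)
    se_b = math.sqrt(s2 / sxx)
    se_a = math.sqrt(s2 * (1.0 / n + xbar * xbar / sxx))
    return b, a, se_b, se_a


def fit_ols(data: BivariateDataset) -> LinearFit:
    """Ordinary least squares: minimizes the sum of squared vertical deviations.

    Raises
    ------
    DegenerateDataError
        If x has zero variance.
    InsufficientDataError
        If fewer than three pairs remain.
    """
    xbar, ybar, sxx, syy, sxy = _validated_moments(data)
    if sxx <= 0.0:
        raise DegenerateDataError("x has zero variance; OLS slope undefined")
    b, a, se_b, se_a = _ols_core(xbar, ybar, sxx, syy, sxy, data.n)
    r = _pearson(sxx, syy, sxy)
    return LinearFit("OLS", b, a, se_b, se_a, r, r * r, data.n)


def fit_sma(
    data: BivariateDataset,
    require_significance: bool = True,
    alpha: float = 0.05,
) -> LinearFit:
    """Standard major axis: slope = sign(r) * s_y / s_x (equivalently B_OLS / r).

    The correlation-significance gate is ON by default: with
    ``require_significance`` the fit is refused (:class:`NotSignificantError`)
    unless the correlation passes a two-tailed t-test at ``alpha``.

    Standard errors follow common model-II practice: ``se_B`` equals the OLS
    slope standard error and ``se_A**2 = se_B**2 * x̄**2 + s_res**2 / n`` with
    ``s_res`` the residual standard deviation about the SMA line.
    """
    xbar, ybar, sxx, syy, sxy = _validated_moments(data)
    if sxx <= 0.0 or syy <= 0.0:
        raise DegenerateDataError("x and y must both have positive variance for SMA")
    r = _pearson(sxx, syy, sxy)
    if r == 0.0:
        raise UndefinedSlopeError("r = 0: the SMA slope sign is undefined")
    if require_significance:
        sig = correlation_significance(data, alpha=alpha)
        if not sig.significant:
            raise NotSignificantError(
                "SMA refused: correlation not significant "
                f"(r = {r:.4f}, p = {sig.p:.4g} >= alpha = {alpha})"
            )
    b = math.copysign(math.sqrt(syy / sxx), r)
    a = ybar - b * xbar
    # se_B: OLS slope standard error (model-II convention)
    _, _, se_b, _ = _ols_core(xbar, ybar, sxx, syy, sxy, data.n)
    resid = data.y - (b * data.x + a)
    s_res2 = float(resid @ resid) / (data.n - 2)
    se_a = math.sqrt(se_b * se_b * xbar * xbar + s_res2 / data.n)
    return LinearFit("SMA", b, a, se_b, se_a, r, r * r, data.n)


def fit_ma(data: BivariateDataset) -> LinearFit:
    """Major axis: minimizes the sum of squared perpendicular distances.

    Slope is the orientation of the first principal axis of the centered
    scatter: ``B = [(Syy - Sxx) + sqrt((Syy - Sxx)^2 + 4*Sxy^2)] / (2*Sxy)``.
    """
    xbar, ybar, sxx, syy, sxy = _validated_moments(data)
    if sxx <= 0.0 and syy <= 0.0:
        raise DegenerateDataError("both variables constant; MA undefined")
    if sxy == 0.0:
        raise UndefinedSlopeError(
            "Sxy = 0: the major-axis orientation is undefined"
        )
    d = syy - sxx
    b = (d + math.sqrt(d * d + 4.0 * sxy * sxy)) / (2.0 * sxy)
    a = ybar - b * xbar
    r = _pearson(sxx, syy, sxy)
    return LinearFit("MA", b, a, math.nan, math.nan, r, r * r, data.n)


def fit_rma(data: BivariateDataset) -> LinearFit:
    """Ranged major axis: MA on range-normalized data, slope back-transformed.

    Each variable is mapped to [0, 1] by ``(v - min) / range`` before the MA;
    the normalized slope is multiplied by ``range_y / range_x``. Because the
    ranges set the normalization, a single extreme outlier can shift the fit
    materially — outliers should be screened beforehand.
    """
    xbar, ybar, sxx, syy, sxy = _validated_moments(data)
    rx = float(np.ptp(data.x))
    ry = float(np.ptp(data.y))
    if rx <= 0.0 or ry <= 0.0:
        raise DegenerateDataError("zero range in x or y; RMA undefined")
    u = (data.x - data.x.min()) / rx
    v = (data.y - data.y.min()) / ry
    du, dv = u - u.mean(), v - v.mean()
    suu = float(du @ du)
    svv = float(dv @ dv)
    suv = float(du @ dv)
    if suv == 0.0:
        raise UndefinedSlopeError("normalized Sxy = 0: RMA orientation undefined")
    d = svv - suu
    b_norm = (d + math.sqrt(d * d + 4.0 * suv * suv)) / (2.0 * suv)
    b = b_norm * ry / rx
    a = ybar - b * xbar
    r = _pearson(sxx, syy, sxy)
    return LinearFit("RMA", b, a, math.nan, math.nan, r, r * r, data.n)


_FITTERS = {"OLS": fit_ols, "SMA": fit_sma, "MA": fit_ma, "RMA": fit_rma}


def fit_all(
    data: BivariateDataset,
    methods: Sequence[str] = ("OLS", "SMA", "MA", "RMA"),
    **sma_kwargs,
) -> list[LinearFit]:
    """Fit the requested methods; unknown method names raise ``KeyError``."""
    fits = []
    for m in methods:
        m = m.upper()
        f = _FITTERS[m]
        fits.append(f(data, **sma_kwargs) if m == "SMA" else f(data))
    return fits


def fits_to_frame(fits: Iterable[LinearFit]) -> pd.DataFrame:
    """Side-by-side fit table (one row per method)."""
    return pd.DataFrame([f.to_dict() for f in fits])


def write_fit_report(fits: Iterable[LinearFit], path: str | Path) -> None:
    """Serialize fits to ``.json`` or delimited text, by file extension."""
    path = Path(path)
    fits = list(fits)
    if path.suffix == ".json":
        path.write_text(json.dumps([f.to_dict() for f in fits], indent=2) + "\n")
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        fits_to_frame(fits).to_csv(path, sep=sep, index=False)
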