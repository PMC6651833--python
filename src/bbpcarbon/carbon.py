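"""Phytoplankton carbon and POC models built on particulate backscattering.

Two empirical linear models link the particulate backscattering coefficient
b_bp(λ) (m⁻¹) to carbon pools:

Phytoplankton carbon
    ``C_phyto = (b_bp(λ) - b_bp_k(λ)) * SF``

    where ``b_bp_k`` is the background backscattering of non-algal particles
    that does not covary with chlorophyll — estimated as the *intercept* of
    the TChla → b_bp linear fit (the b_bp at zero TChla) — and ``SF`` (mg C
    m⁻²) is a scaling factor calibrated so the mean Chl:C ratio matches a
    laboratory-consistent target (0.010). Because b_bp_k is a model parameter
    derived from an asymmetric relationship (TChla drives b_bp), OLS is the
    suitable fitting method; the two variables are never interchanged.

Particulate organic carbon
    ``POC = B * b_bp(λ) + A``

    a symmetric errors-in-both-variables comparison, for which SMA is the
    suitable fitting method.
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .regression import (
    BivariateDataset,
    LinearFit,
    fit_ols,
    fit_sma,
)

__all__ = [
    "CarbonModelParams",
    "PocModelParams",
    "SfCalibration",
    "CarbonField",
    "OrientationError",
    "derive_bbpk",
    "calibrate_sf",
    "cphyto_from_bbp",
    "fit_poc_model",
    "poc_from_bbp",
    "phyto_carbon_fraction",
]

log = logging.getLogger(__name__)

DEFAULT_CHL_TO_C = 0.010  # target mean Chl:C ratio used to calibrate SF
SF_ORIGINAL_443 = 13_000.0  # mg C m^-2, original scaling factor at 443 nm

_BBP_PAT = re.compile(r"b_?bp|backscat", re.IGNORECASE)
_CHL_PAT = re.compile(r"chl", re.IGNORECASE)


class OrientationError(ValueError):
    """Raised when the TChla→b_bp orientation is violated.

    b_bp_k is defined as the b_bp at zero TChla, so TChla must be the
    independent (x) variable; the variables cannot be interchanged.
    """


@dataclass(frozen=True)
class CarbonModelParams:
    """Parameters of the C_phyto model at one wavelength.

    Attributes
    ----------
    wavelength_nm : float
        Wavelength of b_bp (443, 555 or 700 nm in common use).
    bbp_k : float
        Background particulate backscattering (m⁻¹); intercept of the
        TChla→b_bp fit. Physically non-negative; a negative fitted value is
        kept but flagged.
    sf : float
        Scaling factor (mg C m⁻²); NaN until calibrated.
    method : str
        Regression method that produced ``bbp_k``.
    """

    wavelength_nm: float
    bbp_k: float
    sf: float = math.nan
    method: str = "OLS"
    se_bbp_k: float = math.nan
    negative_intercept: bool = False

    def with_sf(self, sf: float) -> "CarbonModelParams":
        if not (sf > 0):
            raise ValueError(f"SF must be positive, got {sf}")
        return CarbonModelParams(
            self.wavelength_nm, self.bbp_k, float(sf), self.method,
            self.se_bbp_k, self.negative_intercept,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PocModelParams:
    """Slope/intercept of the POC = B*b_bp + A model with provenance."""

    wavelength_nm: float
    B: float  # mg C m^-3 per m^-1
    A: float  # mg C m^-3
    se_B: float = math.nan
    se_A: float = math.nan
    method: str = "SMA"
    r2: float = math.nan
    n: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SfCalibration:
    """Result of an SF calibration: value plus sample accounting."""

    sf: float
    n_used: int
    n_excluded: int
    target_chl_to_c: float
    statistic: str


@dataclass(frozen=True)
class CarbonField:
    """Elementwise carbon estimates with a mask of negative values."""

    values: np.ndarray
    negative_mask: np.ndarray
    clamped: bool = False


def _check_orientation(matchups: BivariateDataset) -> None:
    x_label, y_label = matchups.labels
    if _BBP_PAT.search(x_label) and not _BBP_PAT.search(y_label):
        raise OrientationError(
            f"b_bp-like variable {x_label!r} found on the x axis: b_bp_k is the "
            "intercept of the TChla (x) -> b_bp (y) fit and the variables "
            "cannot be interchanged"
        )
    if _CHL_PAT.search(y_label) and not _CHL_PAT.search(x_label):
        raise OrientationError(
            f"chlorophyll-like variable {y_label!r} found on the y axis; "
            "TChla must be the independent variable"
        )


def derive_bbpk(
    matchups: BivariateDataset,
    method: str = "OLS",
    wavelength_nm: float = 700.0,
    require_significance: bool = True,
    alpha: float = 0.05,
) -> tuple[CarbonModelParams, LinearFit]:
    """Estimate the background backscattering b_bp_k from TChla→b_bp match-ups.

    The orientation is fixed: TChla on x, b_bp on y (checked against the
    dataset labels). ``method`` may be ``"OLS"`` (suitable for this asymmetric
    parameter-estimation problem) or ``"SMA"`` (used for comparison); the SMA
    significance gate propagates.

    Returns the parameter set (``sf`` unset) together with the full fit.
    """
    _check_orientation(matchups)
    method = method.upper()
    if method == "OLS":
        fit = fit_ols(matchups)
    elif method == "SMA":
        fit = fit_sma(matchups, require_significance=require_significance, alpha=alpha)
    else:
        raise ValueError(f"method must be OLS or SMA, got {method!r}")
    negative = fit.A < 0
    if negative:
        warnings.warn(
            f"fitted b_bp_k = {fit.A:.3g} m^-1 is negative; background "
            "backscattering cannot physically be below zero",
            stacklevel=2,
        )
    params = CarbonModelParams(
        wavelength_nm=wavelength_nm,
        bbp_k=fit.A,
        method=method,
        se_bbp_k=fit.se_A,
        negative_intercept=bool(negative),
    )
    return params, fit


def calibrate_sf(
    tchla: np.ndarray,
    bbp: np.ndarray,
    bbp_k: float,
    target_chl_to_c: float = DEFAULT_CHL_TO_C,
    statistic: str = "mean_of_ratios",
) -> SfCalibration:
    """Calibrate the scaling factor SF from TChla / b_bp match-ups.

    SF is chosen so that the average Chl:C over the match-ups equals
    ``target_chl_to_c``. With ``statistic="mean_of_ratios"`` (default)

        ``SF = mean( TChla_i / (b_bp_i - bbp_k) ) / target``

    over samples with ``b_bp > bbp_k``; samples at or below the background are
    excluded and counted. ``"ratio_of_means"`` uses
    ``(mean TChla) / (mean excess) / target`` instead.
    """
    if not target_chl_to_c > 0:
        raise ValueError("target_chl_to_c must be positive")
    tchla = np.asarray(tchla, dtype=float)
    bbp = np.asarray(bbp, dtype=float)
    excess = bbp - bbp_k
    valid = np.isfinite(tchla) & np.isfinite(excess) & (excess > 0)
    n_excluded = int(valid.size - valid.sum())
    if not valid.any():
        raise ValueError("no samples with b_bp above bbp_k; cannot calibrate SF")
    if statistic == "mean_of_ratios":
        sf = float(np.mean(tchla[valid] / excess[valid])) / target_chl_to_c
    elif statistic == "ratio_of_means":
        sf = float(tchla[valid].mean() / excess[valid].mean()) / target_chl_to_c
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    log.info(
        "SF calibration: %d samples used, %d excluded (b_bp <= bbp_k), SF = %.5g",
        int(valid.sum()), n_excluded, sf,
    )
    return SfCalibration(sf, int(valid.sum()), n_excluded, target_chl_to_c, statistic)


def cphyto_from_bbp(
    bbp,
    params: CarbonModelParams,
    clamp_negative: bool = False,
    wavelength_nm: float | None = None,
) -> CarbonField:
    """Apply C_phyto = (b_bp - bbp_k) * SF elementwise.

    Negative estimates (b_bp below the background) are kept and flagged by
    default; with ``clamp_negative`` they are set to zero but stay flagged.
    A wavelength mismatch between data and parameters only warns.
    """
    if not np.isfinite(params.sf) or params.sf <= 0:
        raise ValueError("params.sf is not calibrated")
    if wavelength_nm is not None and wavelength_nm != params.wavelength_nm:
        warnings.warn(
            f"b_bp wavelength {wavelength_nm} nm does not match model "
            f"wavelength {params.wavelength_nm} nm",
            stacklevel=2,
        )
    values = (np.asarray(bbp, dtype=float) - params.bbp_k) * params.sf
    negative = values < 0
    n_neg = int(negative.sum())
    if n_neg:
        log.info("C_phyto: %d negative value(s)%s", n_neg,
                 " clamped to 0" if clamp_negative else " retained")
    if clamp_negative:
        values = np.where(negative, 0.0, values)
    return CarbonField(values, negative, clamped=clamp_negative)


def fit_poc_model(
    matchups: BivariateDataset,
    method: str = "SMA",
    wavelength_nm: float = 700.0,
    require_significance: bool = True,
    alpha: float = 0.05,
) -> tuple[PocModelParams, LinearFit]:
    """Fit POC = B*b_bp + A. By convention b_bp is x and POC is y.

    SMA is the recommended default: POC and b_bp are interchangeable proxies
    of the same particle pool and both carry measurement uncertainty. OLS is
    available for comparison and yields ``|B_OLS| = |r| * |B_SMA|`` (lower
    slope, higher intercept whenever r < 1 and the centroid is positive).
    """
    method = method.upper()
    if method == "OLS":
        fit = fit_ols(matchups)
    elif method == "SMA":
        fit = fit_sma(matchups, require_significance=require_significance, alpha=alpha)
    else:
        raise ValueError(f"method must be OLS or SMA, got {method!r}")
    if fit.B <= 0:
        warnings.warn(
            f"POC model slope B = {fit.B:.3g} is not positive; the fit is not "
            "physically meaningful",
            stacklevel=2,
        )
    params = PocModelParams(
        wavelength_nm=wavelength_nm, B=fit.B, A=fit.A,
        se_B=fit.se_B, se_A=fit.se_A, method=method, r2=fit.r2, n=fit.n,
    )
    return params, fit


def poc_from_bbp(bbp, params: PocModelParams) -> np.ndarray:
    """Apply POC = B*b_bp + A elementwise."""
    return params.B * np.asarray(bbp, dtype=float) + params.A


def phyto_carbon_fraction(cphyto, poc) -> float:
    """Mean C_phyto / POC over match-ups.

    Diagnostic for the consistency expectation that phytoplankton contribute
    roughly 30% (±) of total particulate organic carbon; reported, never
    enforced.
    """
    cphyto = np.asarray(cphyto, dtype=float)
    poc = np.asarray(poc, dtype=float)
    valid = np.isfinite(cphyto) & np.isfinite(poc) & (poc != 0)
    if not valid.any():
        raise ValueError("no valid C_phyto/POC pairs")
    return float(np.mean(cphyto[valid] / poc[valid]))


def params_to_json(path: str | Path, **named_params) -> None:
    """Write named parameter sets (CarbonModelParams/PocModelParams) to JSON."""
    payload = {k: v.to_dict() for k, v in named_params.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
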