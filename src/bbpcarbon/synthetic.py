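"""Synthetic bio-optical data with the statistical structure the analysis assumes.

Three generators stand in for the observational inputs:

* :func:`gen_matchups` — bottle-style match-up tables for a linear relation
  with independent Gaussian error on *both* axes (the errors-in-variables
  setting that separates type-I from type-II regression). The latent
  predictor can be lognormal (chlorophyll-like: strictly positive,
  right-skewed) or Gaussian (abstract scenarios).
* :func:`gen_profile_series` — profiling-float-like b_bp(700) cast series on
  the standard depth-varying vertical grid (10 m from 1000 to 250 m, 1 m from
  250 to 10 m, 0.2 m from 10 m to the surface), built from a smooth seasonal
  baseline with a subsurface maximum, white noise, and Poisson-placed
  positive spikes whose locations are recorded as truth for QC testing.
* :func:`gen_gridded_series` — satellite-style monthly TChla/b_bp pairs with
  seasonality, calibrated so the realized r² hits a requested target (the
  observed long-term ocean-colour correlation is moderate, r² ≈ 0.56).

All randomness flows through ``numpy.random.default_rng`` seeded per
scenario: a fixed seed regenerates bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .qc import Profile, ProfileSeries

__all__ = [
    "BivariateScenario",
    "ProfileScenario",
    "GriddedScenario",
    "gen_matchups",
    "gen_profile_series",
    "gen_gridded_series",
    "make_depth_grid",
    "cruise_matchup_scenario",
    "poc_matchup_scenario",
    "float_series_scenario",
    "gridded_scenario",
]

# BGC-Argo-style acquisition grid: (z_from, z_to, dz), surface to parking depth
DEFAULT_GRID = ((0.0, 10.0, 0.2), (10.0, 250.0, 1.0), (250.0, 1000.0, 10.0))


@dataclass(frozen=True)
class BivariateScenario:
    """Ground truth for a linear match-up table with errors on both axes.

    ``y = b_true * x_latent + a_true``; observed x and y each add independent
    zero-mean Gaussian noise (``sd_x``, ``sd_y``). ``x_dist`` is ``"lognormal"``
    (``x_params = (mu, sigma)`` of log x) or ``"normal"``
    (``x_params = (mean, sd)``). An optional ``outlier_fraction`` of rows gets
    error draws inflated by ``outlier_scale``. With ``positive_x`` /
    ``positive_y`` non-positive observations are rejected and redrawn
    (physical positivity of concentrations and backscattering).
    """

    b_true: float
    a_true: float
    n: int
    x_dist: str = "lognormal"
    x_params: tuple[float, float] = (math.log(0.3), 0.9)
    sd_x: float = 0.0
    sd_y: float = 0.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    positive_x: bool = False
    positive_y: bool = False
    labels: tuple[str, str] = ("x", "y")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be at least 3")
        if self.sd_x < 0 or self.sd_y < 0:
            raise ValueError("error sds must be non-negative")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.x_dist not in {"lognormal", "normal"}:
            raise ValueError("x_dist must be 'lognormal' or 'normal'")


def _draw_latent(scenario: BivariateScenario, rng: np.random.Generator) -> np.ndarray:
    a, b = scenario.x_params
    if scenario.x_dist == "lognormal":
        return rng.lognormal(mean=a, sigma=b, size=scenario.n)
    return rng.normal(loc=a, scale=b, size=scenario.n)


def gen_matchups(
    scenario: BivariateScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate a match-up table; truth is recorded alongside the observations.

    Returns a DataFrame with columns ``x_true``, ``<x label>``, ``<y label>``
    and an ``outlier`` indicator; ``df.attrs["n_redrawn"]`` counts positivity
    redraws and ``df.attrs["scenario"]`` echoes the generating parameters.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    x_true = _draw_latent(scenario, rng)
    scale_x = np.full(scenario.n, scenario.sd_x)
    scale_y = np.full(scenario.n, scenario.sd_y)
    outlier = np.zeros(scenario.n, dtype=bool)
    if scenario.outlier_fraction > 0:
        k = int(round(scenario.outlier_fraction * scenario.n))
        idx = rng.choice(scenario.n, size=k, replace=False)
        outlier[idx] = True
        scale_x[idx] *= scenario.outlier_scale
        scale_y[idx] *= scenario.outlier_scale

    def _noisy(mean, scale, positive):
        vals = mean + rng.normal(size=mean.size) * scale
        n_redrawn = 0
        if positive:
            for _ in range(1000):
                bad = vals <= 0
                if not bad.any():
                    break
                n_redrawn += int(bad.sum())
                vals[bad] = mean[bad] + rng.normal(size=int(bad.sum())) * scale[bad]
            else:
                raise RuntimeError("positivity redraw did not converge")
        return vals, n_redrawn

    x_obs, redrawn_x = _noisy(x_true, scale_x, scenario.positive_x)
    y_mean = scenario.b_true * x_true + scenario.a_true
    y_obs, redrawn_y = _noisy(y_mean, scale_y, scenario.positive_y)

    xl, yl = scenario.labels
    df = pd.DataFrame({"x_true": x_true, xl: x_obs, yl: y_obs, "outlier": outlier})
    df.attrs["n_redrawn"] = redrawn_x + redrawn_y
    df.attrs["scenario"] = asdict(scenario)
    return df


def make_depth_grid(
    grid: Sequence[tuple[float, float, float]] = DEFAULT_GRID,
) -> np.ndarray:
    """Strictly increasing depth vector from piecewise (z_from, z_to, dz) specs."""
    pieces = []
    for z0, z1, dz in grid:
        if not (z1 > z0 and dz > 0):
            raise ValueError(f"invalid grid segment {(z0, z1, dz)}")
        pieces.append(np.arange(z0 + dz, z1 + dz / 2, dz))
    depths = np.concatenate(pieces)
    if not np.all(np.diff(depths) > 0):
        raise ValueError("grid segments must be contiguous and ordered")
    return np.round(depths, 6)


@dataclass(frozen=True)
class ProfileScenario:
    """Float-like b_bp(z, t) cast series: baseline shape, noise and spikes.

    The baseline is a deep background plus a surface-intensified term decaying
    over ``surface_efolding_m`` and a Gaussian subsurface maximum, both
    modulated seasonally (cosine, peak at ``season_peak_day``). Spikes occur
    independently per point with probability ``spike_rate``; amplitudes are
    ``noise_sd * (spike_amp_min + Exponential(spike_amp_scale))`` —
    positive by construction, 5–50× the noise sd in the default regime.
    """

    n_casts: int = 87
    start: str = "2013-07-16"
    cadence_days: float = 5.4
    grid: tuple = DEFAULT_GRID
    bbp_deep: float = 4.5e-4         # m^-1 background at depth
    bbp_surface: float = 1.1e-3      # m^-1 surface value at seasonal peak ref
    surface_efolding_m: float = 150.0
    scm_depth_m: float = 45.0        # subsurface maximum
    scm_amp: float = 6.0e-4
    scm_width_m: float = 20.0
    seasonal_amp: float = 0.3        # relative modulation of the varying terms
    season_peak_day: float = 105.0   # day of year of the bloom peak
    noise_sd: float = 5.0e-5         # m^-1 white noise
    spike_rate: float = 0.01         # per-point spike probability
    spike_amp_min: float = 5.0       # in units of noise_sd
    spike_amp_scale: float = 15.0    # exponential mean, in units of noise_sd
    wavelength_nm: float = 700.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_casts < 1:
            raise ValueError("n_casts must be positive")
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ValueError("noise_sd and spike_rate must be non-negative")
        if self.spike_amp_min <= 0 or self.spike_amp_scale < 0:
            raise ValueError("spike amplitudes must be positive")


def _baseline_bbp(z: np.ndarray, day_of_year: float, sc: ProfileScenario) -> np.ndarray:
    season = 1.0 + sc.seasonal_amp * math.cos(
        2.0 * math.pi * (day_of_year - sc.season_peak_day) / 365.25
    )
    surface = (sc.bbp_surface - sc.bbp_deep) * np.exp(-z / sc.surface_efolding_m)
    scm = sc.scm_amp * np.exp(-((z - sc.scm_depth_m) ** 2) / (2.0 * sc.scm_width_m**2))
    return sc.bbp_deep + season * (surface + scm)


def gen_profile_series(
    scenario: ProfileScenario, rng: np.random.Generator | None = None
) -> tuple[ProfileSeries, dict]:
    """Generate a cast series plus a truth record of injected spikes.

    Truth maps cast index to the depths and amplitudes of injected spikes so
    QC tests can score detection exactly.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    depths = make_depth_grid(scenario.grid)
    t0 = pd.Timestamp(scenario.start)
    profiles = []
    truth: dict = {"spikes": {}, "scenario": asdict(scenario)}
    for i in range(scenario.n_casts):
        t = t0 + pd.Timedelta(days=i * scenario.cadence_days)
        base = _baseline_bbp(depths, float(t.dayofyear), scenario)
        values = base + rng.normal(size=depths.size) * scenario.noise_sd
        spike_mask = rng.random(depths.size) < scenario.spike_rate
        amps = scenario.noise_sd * (
            scenario.spike_amp_min
            + rng.exponential(scale=scenario.spike_amp_scale, size=int(spike_mask.sum()))
        )
        values = values.copy()
        values[spike_mask] += amps
        profiles.append(Profile(depths, values, time=t,
                                wavelength_nm=scenario.wavelength_nm))
        truth["spikes"][i] = {
            "depths": depths[spike_mask].tolist(),
            "amplitudes": amps.tolist(),
        }
    series = ProfileSeries(tuple(profiles), scenario.wavelength_nm,
                           metadata={"generator": "gen_profile_series"})
    return series, truth


@dataclass(frozen=True)
class GriddedScenario:
    """Satellite-like monthly TChla/b_bp series with a target realized r².

    The latent chlorophyll signal is a seasonal cosine plus lognormal
    interannual jitter; b_bp follows ``b_true * latent + a_true`` with
    Gaussian noise whose amplitude is calibrated (root finding on the noise
    scale) so the realized squared correlation between the *observed* pair
    equals ``target_r2``. Infeasible targets (noise-free correlation already
    below target) raise ``ValueError``.
    """

    n_months: int = 219             # 1997–2015 monthly
    start: str = "1997-09-01"
    b_true: float = 2.5e-3          # m^-1 per mg m^-3 at 443 nm
    a_true: float = 8.5e-4          # m^-1
    chl_mean: float = 0.25          # mg m^-3
    chl_seasonal_amp: float = 0.15  # mg m^-3
    chl_jitter_sd: float = 0.35     # lognormal sigma of multiplicative jitter
    season_peak_month: float = 3.0
    sd_x: float = 0.0               # observation noise on TChla
    noise_sd: float = 0.0           # explicit b_bp noise, used when target_r2 is None
    target_r2: float | None = 0.56
    wavelength_nm: float = 443.0
    labels: tuple[str, str] = ("tchla", "bbp")
    seed: int | None = None


def gen_gridded_series(
    scenario: GriddedScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Monthly paired TChla/b_bp table with columns (time, tchla, bbp).

    ``df.attrs["noise_scale"]`` records the calibrated b_bp noise sd and
    ``df.attrs["realized_r2"]`` the achieved squared correlation.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    months = pd.date_range(scenario.start, periods=scenario.n_months, freq="MS")
    seasonal = scenario.chl_mean + scenario.chl_seasonal_amp * np.cos(
        2.0 * math.pi * (months.month - scenario.season_peak_month) / 12.0
    )
    jitter = rng.lognormal(mean=-0.5 * scenario.chl_jitter_sd**2,
                           sigma=scenario.chl_jitter_sd, size=scenario.n_months)
    latent = seasonal.to_numpy() * jitter
    tchla = latent + rng.normal(size=latent.size) * scenario.sd_x
    bbp_clean = scenario.b_true * latent + scenario.a_true
    unit_noise = rng.normal(size=latent.size)

    def realized_r2(s: float) -> float:
        y = bbp_clean + s * unit_noise
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(tchla, y)[0, 1]
        return r * r if np.isfinite(r) else 0.0

    if scenario.target_r2 is None:
        s_star = float(scenario.noise_sd)
    else:
        t = scenario.target_r2
        if not 0.0 < t <= 1.0:
            raise ValueError("target_r2 must be in (0, 1]")
        r2_0 = realized_r2(0.0)
        if r2_0 < t:
            raise ValueError(
                f"target r2 = {t} infeasible: noise-free realized r2 is {r2_0:.3f}"
            )
        s_hi = 10.0 * abs(scenario.b_true) * (np.std(latent) + 1.0)
        while realized_r2(s_hi) > t:
            s_hi *= 4.0
        s_star = brentq(lambda s: realized_r2(s) - t, 0.0, s_hi, xtol=1e-12)
    bbp = bbp_clean + s_star * unit_noise

    xl, yl = scenario.labels
    df = pd.DataFrame({"time": months, "x_true": latent, xl: tchla, yl: bbp})
    df.attrs["noise_scale"] = float(s_star)
    df.attrs["realized_r2"] = float(realized_r2(s_star))
    df.attrs["scenario"] = asdict(scenario)
    return df


# ---------------------------------------------------------------------------
# Canonical study conditions: the scenarios the pipeline and its tests run.
# ---------------------------------------------------------------------------

def cruise_matchup_scenario(seed: int | None = None, n: int = 300) -> BivariateScenario:
    """Cruise-style TChla → b_bp(700) match-ups.

    Truth b_bp = 6.1e-3 · TChla + 5.0e-4 m⁻¹ over a lognormal TChla field
    spanning roughly 0.03–3 mg m⁻³ (slope consistent with a mean Chl:C of
    0.010 at a scaling factor near 1.6e4 mg C m⁻²), with scatter on both axes
    sized so the realized correlation is strong but not tight (r² ≈ 0.87) —
    the regime in which the OLS and SMA intercepts separate by order
    1e-4 m⁻¹ (OLS above SMA).
    """
    return BivariateScenario(
        b_true=6.1e-3, a_true=5.0e-4, n=n,
        x_dist="lognormal", x_params=(math.log(0.3), 0.9),
        sd_x=0.10, sd_y=1.0e-3,
        positive_x=True, positive_y=True,
        labels=("tchla", "bbp"), seed=seed,
    )


def poc_matchup_scenario(seed: int | None = None, n: int = 300) -> BivariateScenario:
    """Cruise-style b_bp(700) → POC match-ups.

    Truth POC = 4.0e4 · b_bp + 10 mg m⁻³ over lognormal b_bp around 1e-3 m⁻¹,
    with comparable relative uncertainty on both axes (r² ≈ 0.8, in the range
    of published field b_bp–POC regressions).
    """
    return BivariateScenario(
        b_true=4.0e4, a_true=10.0, n=n,
        x_dist="lognormal", x_params=(math.log(8.0e-4), 0.7),
        sd_x=1.5e-4, sd_y=15.0,
        positive_x=True, positive_y=True,
        labels=("bbp", "poc"), seed=seed,
    )


def float_series_scenario(seed: int | None = None, n_casts: int = 87) -> ProfileScenario:
    """Float-like b_bp(700) series: 87 casts at ~5.4-day cadence (~15 months)."""
    return ProfileScenario(n_casts=n_casts, seed=seed)


def gridded_scenario(seed: int | None = None, n_months: int = 219) -> GriddedScenario:
    """Satellite-like monthly TChla/b_bp(443) series, realized r² = 0.56."""
    return GriddedScenario(n_months=n_months, seed=seed)
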