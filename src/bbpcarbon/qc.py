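"""Quality control and regularization of b_bp depth profiles.

Covers the pre-processing applied to optical backscattering profiles before
any carbon computation:

* **despiking** — profiling-float b_bp records carry occasional positive
  spikes (large particles or aggregates crossing the sensor volume). A point
  is a spike when its residual against a running-median filter (window of 5
  samples) exceeds twice the 90th quantile of the profile's residual signal;
  flagged points are removed, negative excursions are never touched.
* **depth binning** — ship-cast data are averaged within ±0.5 m of nominal
  1-m depth centers (closed interval).
* **dark-offset subtraction** — an averaged dark reading is subtracted from
  every point; negative results are flagged.
* **bottle matching** — binned profile values are paired with discrete
  bottle sampling depths (nearest within tolerance; shallower wins ties).

Profiles are depth-ordered with strictly increasing depths; every operation
preserves that ordering and accounts for removed or modified points in its
flags/report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Profile",
    "ProfileSeries",
    "despike",
    "bin_profile",
    "dark_offset",
    "match_bottles",
    "series_to_frame",
    "series_from_frame",
    "BOTTLE_DEPTHS_M",
]

# standard discrete bottle sampling depths for 0-400 m casts
BOTTLE_DEPTHS_M = (400.0, 200.0, 150.0, 80.0, 70.0, 60.0, 50.0, 40.0,
                   30.0, 20.0, 10.0, 5.0)

FLAG_OK = "ok"
FLAG_SPIKE = "spike"
FLAG_DARK = "dark-corrected"
FLAG_BINNED = "binned"
FLAG_NEGATIVE = "negative"


@dataclass(frozen=True)
class Profile:
    """A single depth-ordered profile of b_bp(λ).

    ``depth`` must be strictly increasing (m, positive down); ``values`` are
    b_bp in m⁻¹. ``flags`` carries one QC code string per retained point.
    """

    depth: np.ndarray
    values: np.ndarray
    time: object = None  # timestamp (pd.Timestamp) or float time coordinate
    wavelength_nm: float = 700.0
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float).ravel()
        values = np.asarray(self.values, dtype=float).ravel()
        if depth.size != values.size:
            raise ValueError("depth and values must have equal length")
        if depth.size > 1 and not np.all(np.diff(depth) > 0):
            raise ValueError("depths must be strictly increasing")
        flags = self.flags
        if flags is None:
            flags = np.full(depth.size, FLAG_OK, dtype=object)
        else:
            flags = np.asarray(flags, dtype=object).ravel()
            if flags.size != depth.size:
                raise ValueError("flags length must match depth length")
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "flags", flags)

    @property
    def n(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class ProfileSeries:
    """Time-ordered collection of profiles sharing one wavelength."""

    profiles: tuple[Profile, ...]
    wavelength_nm: float = 700.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        profiles = tuple(self.profiles)
        for p in profiles:
            if p.wavelength_nm != self.wavelength_nm:
                raise ValueError(
                    f"profile wavelength {p.wavelength_nm} nm differs from "
                    f"series wavelength {self.wavelength_nm} nm"
                )
        times = [p.time for p in profiles]
        if any(t is None for t in times):
            raise ValueError("every profile in a series needs a time")
        if len(times) > 1:
            t = pd.Series(times)
            if not t.is_monotonic_increasing or t.duplicated().any():
                raise ValueError("profile times must be strictly increasing")
        object.__setattr__(self, "profiles", profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    @property
    def times(self) -> list:
        return [p.time for p in self.profiles]

    def map(self, fn) -> "ProfileSeries":
        """Apply ``fn(profile) -> profile`` to every cast."""
        return ProfileSeries(tuple(fn(p) for p in self.profiles),
                             self.wavelength_nm, dict(self.metadata))


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Median filter with shrinking (truncated) windows at the profile ends."""
    h = window // 2
    n = values.size
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(values[max(0, i - h): min(n, i + h + 1)])
    return out


def despike(
    profile: Profile,
    window: int = 5,
    quantile: float = 0.90,
    factor: float = 2.0,
    positive_only: bool = False,
) -> tuple[Profile, dict]:
    """Remove positive spikes from a profile.

    The residual signal is the profile minus a running median (``window``
    samples, shrinking at the edges). Points whose residual exceeds
    ``factor`` × the ``quantile``-th quantile of the residual signal are
    flagged ``spike`` and dropped. The quantile is computed over *all*
    (signed) residuals by default — with ``positive_only`` over the positive
    residuals only — using linear interpolation between order statistics.
    Negative excursions are never removed.

    Returns the cleaned profile and a report with the removed depths,
    residuals and the threshold used. Profiles shorter than ``window`` are
    returned unchanged with a warning.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if not factor > 0:
        raise ValueError("factor must be positive")
    if profile.n < window:
        warnings.warn(
            f"profile has {profile.n} points (< window {window}); despiking skipped",
            stacklevel=2,
        )
        return profile, {"n_removed": 0, "removed_depths": [], "threshold": None,
                         "skipped": True}
    residual = profile.values - _running_median(profile.values, window)
    pool = residual[residual > 0] if positive_only else residual
    if pool.size == 0:
        threshold = np.inf
    else:
        threshold = factor * float(np.quantile(pool, quantile))
    if threshold <= 0.0:
        # Degenerate residual scale: most residuals are exactly zero (a
        # noise-free record), so the quantile carries no noise information
        # and any positive threshold crossing would be spurious.
        threshold = np.inf
    spikes = (residual > threshold) & (residual > 0)
    keep = ~spikes
    cleaned = Profile(
        profile.depth[keep], profile.values[keep], profile.time,
        profile.wavelength_nm, profile.flags[keep],
    )
    report = {
        "n_removed": int(spikes.sum()),
        "removed_depths": profile.depth[spikes].tolist(),
        "removed_residuals": residual[spikes].tolist(),
        "threshold": float(threshold),
        "skipped": False,
    }
    return cleaned, report


def bin_profile(
    profile: Profile,
    centers: Sequence[float],
    halfwidth: float = 0.5,
) -> tuple[Profile, dict]:
    """Average profile values within ±``halfwidth`` m of each nominal depth.

    The interval is closed: a point exactly at ``center ± halfwidth`` is
    included. Empty bins are omitted from the output and counted in the
    report. Binning with the same centers is idempotent.
    """
    if not halfwidth > 0:
        raise ValueError("halfwidth must be positive")
    centers = np.sort(np.asarray(centers, dtype=float))
    out_depth, out_val = [], []
    n_empty = 0
    for c in centers:
        mask = np.abs(profile.depth - c) <= halfwidth
        if mask.any():
            out_depth.append(c)
            out_val.append(float(profile.values[mask].mean()))
        else:
            n_empty += 1
    binned = Profile(
        np.asarray(out_depth), np.asarray(out_val), profile.time,
        profile.wavelength_nm, np.full(len(out_depth), FLAG_BINNED, dtype=object),
    )
    return binned, {"n_bins": len(out_depth), "n_empty_bins": n_empty}


def dark_offset(profile: Profile, dark_value: float) -> Profile:
    """Subtract an averaged dark reading from every point.

    Negative results are retained but flagged ``negative``; all points are
    marked ``dark-corrected``.
    """
    if not np.isfinite(dark_value):
        raise ValueError("dark_value must be finite")
    values = profile.values - dark_value
    flags = np.array(
        [FLAG_DARK if v >= 0 else f"{FLAG_DARK},{FLAG_NEGATIVE}" for v in values],
        dtype=object,
    )
    return Profile(profile.depth, values, profile.time,
                   profile.wavelength_nm, flags)


def match_bottles(
    profile: Profile,
    bottle_depths: Sequence[float] = BOTTLE_DEPTHS_M,
    tolerance: float = 0.5,
) -> pd.DataFrame:
    """Pair each bottle depth with the nearest profile point within tolerance.

    Ties between two equidistant profile points go to the shallower one.
    Unmatched bottles get NaN. Returns a table with columns
    ``bottle_depth``, ``profile_depth``, ``value``.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    rows = []
    for bd in bottle_depths:
        dist = np.abs(profile.depth - bd)
        if profile.n and dist.min() <= tolerance:
            # argmin returns the first (shallowest) index on ties
            i = int(np.argmin(dist))
            rows.append((float(bd), float(profile.depth[i]), float(profile.values[i])))
        else:
            rows.append((float(bd), np.nan, np.nan))
    return pd.DataFrame(rows, columns=["bottle_depth", "profile_depth", "value"])


def series_to_frame(series: ProfileSeries) -> pd.DataFrame:
    """Long-format table (time, depth, value, flag) for delimited-text IO."""
    frames = []
    for p in series:
        frames.append(pd.DataFrame({
            "time": p.time, "depth": p.depth, "value": p.values, "flag": p.flags,
        }))
    return pd.concat(frames, ignore_index=True)


def series_from_frame(df: pd.DataFrame, wavelength_nm: float = 700.0) -> ProfileSeries:
    """Rebuild a ProfileSeries from a long-format (time, depth, value[, flag]) table."""
    profiles = []
    for t, g in df.groupby("time", sort=True):
        g = g.sort_values("depth")
        flags = g["flag"].to_numpy(dtype=object) if "flag" in g else None
        profiles.append(Profile(g["depth"].to_numpy(), g["value"].to_numpy(),
                                time=t, wavelength_nm=wavelength_nm, flags=flags))
    return ProfileSeries(tuple(profiles), wavelength_nm)


def write_series(series: ProfileSeries, path: str | Path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_series(path: str | Path, wavelength_nm: float = 700.0) -> ProfileSeries:
    df = pd.read_csv(path, parse_dates=["time"])
    return series_from_frame(df, wavelength_nm=wavelength_nm)
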