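"""End-to-end synthetic experiments: match-ups → models → budgets.

Runs the full analysis chain under canonical study conditions:

1. cruise-style TChla→b_bp(700) match-ups → background backscattering
   b_bp_k under OLS (suitable) and SMA (comparison), SF calibration to a
   mean Chl:C of 0.010 (one SF per wavelength, shared by both branches);
2. cruise-style b_bp(700)→POC match-ups → POC model under SMA (suitable)
   and OLS (comparison);
3. float-like b_bp(700) cast series (despiked) → C_phyto and POC budget
   comparisons (depth-and-time integrals, anomalies, RPD) and the total
   C_phyto:POC ratio comparison;
4. cruise-like 0–400 m monthly casts → C_phyto budget comparison;
5. satellite-like monthly TChla/b_bp(443) series → b_bp_k under both
   methods, C_phyto series with the original SF of 13,000 mg C m⁻², mean
   series difference.

Every random draw descends from one integer seed; rerunning with the same
seed reproduces the report bit for bit. Reports embed the seed and a hash of
the configuration, never wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from . import budget, carbon, qc, regression, synthetic
from .carbon import SF_ORIGINAL_443

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Sizes, method choices and QC/z-range settings for one pipeline run.

    Defaults encode the recommended method assignment: OLS for the
    asymmetric TChla→b_bp parameter estimation, SMA for the symmetric
    b_bp↔POC comparison.
    """

    seed: int = 0
    n_matchups: int = 300
    n_casts: int = 87
    n_cruise_casts: int = 27
    n_months: int = 219
    method_bbpk: str = "OLS"       # suitable method for b_bp_k derivation
    method_poc: str = "SMA"        # suitable method for the POC model
    target_chl_to_c: float = carbon.DEFAULT_CHL_TO_C
    sf_statistic: str = "mean_of_ratios"
    despike_window: int = 5
    despike_quantile: float = 0.90
    despike_factor: float = 2.0
    z_range_float: tuple[float, float] = (0.0, 250.0)
    z_range_cruise: tuple[float, float] = (0.0, 400.0)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _child_seeds(seed: int, k: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(k)
    return [int(s) & 0x7FFFFFFF for s in state]


def run_pipeline(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Run the full synthetic analysis; returns a plain-dict report.

    ``seed`` overrides ``config.seed`` when given.
    """
    if config is None:
        config = PipelineConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    s_cruise, s_poc, s_float, s_cruise_casts, s_grid = _child_seeds(config.seed, 5)

    # --- 1. cruise match-ups: b_bp_k and SF -------------------------------
    cruise_df = synthetic.gen_matchups(
        synthetic.cruise_matchup_scenario(seed=s_cruise, n=config.n_matchups)
    )
    cruise_ds = regression.BivariateDataset.from_dataframe(
        cruise_df, "tchla", "bbp", units=("mg m-3", "m-1")
    )
    suitable, other = config.method_bbpk.upper(), (
        "SMA" if config.method_bbpk.upper() == "OLS" else "OLS"
    )
    params_suit, fit_suit = carbon.derive_bbpk(cruise_ds, method=suitable)
    params_other, fit_other = carbon.derive_bbpk(cruise_ds, method=other)
    cal = carbon.calibrate_sf(
        cruise_ds.x, cruise_ds.y, params_suit.bbp_k,
        target_chl_to_c=config.target_chl_to_c, statistic=config.sf_statistic,
    )
    params_suit = params_suit.with_sf(cal.sf)
    params_other = params_other.with_sf(cal.sf)  # one SF per wavelength, shared

    # --- 2. POC match-ups -------------------------------------------------
    poc_df = synthetic.gen_matchups(
        synthetic.poc_matchup_scenario(seed=s_poc, n=config.n_matchups)
    )
    poc_ds = regression.BivariateDataset.from_dataframe(
        poc_df, "bbp", "poc", units=("m-1", "mg m-3")
    )
    poc_suitable = config.method_poc.upper()
    poc_other = "OLS" if poc_suitable == "SMA" else "SMA"
    poc_params_suit, _ = carbon.fit_poc_model(poc_ds, method=poc_suitable)
    poc_params_other, _ = carbon.fit_poc_model(poc_ds, method=poc_other)

    # consistency diagnostic: phytoplankton fraction of POC on the match-ups
    cphyto_on_poc = carbon.cphyto_from_bbp(poc_ds.x, params_suit).values
    poc_pred = carbon.poc_from_bbp(poc_ds.x, poc_params_suit)
    phyto_fraction = carbon.phyto_carbon_fraction(cphyto_on_poc, poc_pred)

    # --- 3. float series: despike, then budget comparisons ----------------
    float_series, float_truth = synthetic.gen_profile_series(
        synthetic.float_series_scenario(seed=s_float, n_casts=config.n_casts)
    )
    n_spikes_removed = 0

    def _clean(profile):
        nonlocal n_spikes_removed
        cleaned, rep = qc.despike(
            profile, window=config.despike_window,
            quantile=config.despike_quantile, factor=config.despike_factor,
        )
        n_spikes_removed += rep["n_removed"]
        return cleaned

    float_clean = float_series.map(_clean)
    cmp_cphyto = budget.compare_budgets(
        float_clean, params_suit, params_other, "cphyto",
        z_range=config.z_range_float,
    )
    cmp_poc = budget.compare_budgets(
        float_clean, poc_params_suit, poc_params_other, "poc",
        z_range=config.z_range_float,
    )
    # total C_phyto:POC ratio, both-unsuitable vs both-suitable
    ratio_unsuitable = cmp_cphyto.integral_unsuitable / cmp_poc.integral_unsuitable
    ratio_suitable = cmp_cphyto.integral_suitable / cmp_poc.integral_suitable
    ratio_rpd = budget.rpd(ratio_unsuitable, ratio_suitable)

    # --- 4. cruise-like 0-400 m casts -------------------------------------
    cruise_sc = synthetic.ProfileScenario(
        n_casts=config.n_cruise_casts, cadence_days=30.0,
        grid=((0.0, 400.0, 1.0),), seed=s_cruise_casts,
    )
    cruise_series, _ = synthetic.gen_profile_series(cruise_sc)
    cmp_cruise = budget.compare_budgets(
        cruise_series.map(_clean), params_suit, params_other, "cphyto",
        z_range=config.z_range_cruise,
    )

    # --- 5. satellite-like monthly series ---------------------------------
    grid_df = synthetic.gen_gridded_series(
        synthetic.gridded_scenario(seed=s_grid, n_months=config.n_months)
    )
    grid_ds = regression.BivariateDataset.from_dataframe(
        grid_df, "tchla", "bbp", units=("mg m-3", "m-1")
    )
    sat_suit, sat_fit_suit = carbon.derive_bbpk(
        grid_ds, method=suitable, wavelength_nm=443.0
    )
    sat_other, _ = carbon.derive_bbpk(grid_ds, method=other, wavelength_nm=443.0)
    sat_suit = sat_suit.with_sf(SF_ORIGINAL_443)
    sat_other = sat_other.with_sf(SF_ORIGINAL_443)
    cphyto_sat_suit = carbon.cphyto_from_bbp(grid_ds.y, sat_suit).values
    cphyto_sat_other = carbon.cphyto_from_bbp(grid_ds.y, sat_other).values
    sat_cmp = budget.compare_series_means(cphyto_sat_suit, cphyto_sat_other)

    report = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": asdict(config),
        "cruise_matchups": {
            "n": cruise_ds.n,
            "fit_suitable": fit_suit.to_dict(),
            "fit_other": fit_other.to_dict(),
            "bbpk_suitable_m1": params_suit.bbp_k,
            "bbpk_other_m1": params_other.bbp_k,
            "sf_mg_c_m2": cal.sf,
            "sf_vs_original_443_percent": 100.0 * (cal.sf / SF_ORIGINAL_443 - 1.0),
            "sf_samples_used": cal.n_used,
            "sf_samples_excluded": cal.n_excluded,
            "phyto_fraction_of_poc": phyto_fraction,
        },
        "poc_matchups": {
            "n": poc_ds.n,
            "params_suitable": poc_params_suit.to_dict(),
            "params_other": poc_params_other.to_dict(),
        },
        "float_budgets": {
            "n_casts": len(float_clean),
            "n_spikes_removed": n_spikes_removed,
            "n_spikes_injected": sum(
                len(v["depths"]) for v in float_truth["spikes"].values()
            ),
            "cphyto": cmp_cphyto.to_dict(),
            "poc": cmp_poc.to_dict(),
            "cphyto_poc_ratio_rpd_percent": ratio_rpd,
        },
        "cruise_budgets": {"cphyto": cmp_cruise.to_dict()},
        "satellite": {
            "n_months": grid_ds.n,
            "r2": sat_fit_suit.r2,
            "bbpk_suitable_m1": sat_suit.bbp_k,
            "bbpk_other_m1": sat_other.bbp_k,
            "sf_mg_c_m2": SF_ORIGINAL_443,
            "cphyto_mean_suitable_mg_c_m3": float(np.mean(cphyto_sat_suit)),
            "cphyto_mean_difference_mg_c_m3": sat_cmp["mean_difference"],
            "difference_percent_of_mean": sat_cmp["percent_of_suitable_mean"],
        },
    }
    # attach heavyweight objects for callers that plot or export; not serialized
    report["_objects"] = {
        "cruise_df": cruise_df,
        "poc_df": poc_df,
        "grid_df": grid_df,
        "cruise_fits": (fit_suit, fit_other),
        "cmp_cphyto": cmp_cphyto,
        "cmp_poc": cmp_poc,
        "params": (params_suit, params_other, poc_params_suit, poc_params_other),
        "cphyto_sat": (cphyto_sat_suit, cphyto_sat_other, grid_df["time"]),
    }
    return report


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write the serializable part of a pipeline report to ``report.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {k: v for k, v in report.items() if not k.startswith("_")}
    path = outdir / "report.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
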