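"""End-to-end orchestration: synthetic generation -> thresholds -> indices
per period/scenario -> bias correction + ensembling -> trends -> severity
+ mortality burden -> rasters -> manifest.

Future-period indices are computed against the *historical reference*
climatology (thresholds frozen), and each ensemble member is bias-
corrected before the equal-weight average is taken.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bc
from . import indices as ci
from . import severity as sv
from . import spatial as sp
from . import synthetic as syn
from . import trends as tr
from .config import PipelineConfig, config_hash
from .errors import HeatkitError
from .series import (
    DailySeries,
    write_catalogue_csv,
    write_series_csv,
    write_series_netcdf,
)

__all__ = ["run_pipeline", "PIPELINE_DECISIONS"]

logger = logging.getLogger(__name__)

#: design decisions a run actually exercises; echoed into the manifest
PIPELINE_DECISIONS = [
    "min_duration=3-day heatwave convention; strict (>) exceedance",
    "15-day centered window, type-7 percentile estimator",
    "thresholds frozen at the historical reference climatology",
    "bias-correct each member per calendar month, then equal-weight ensemble",
    "Sen's slope reported; MK normal approximation, tie-corrected, no pre-whitening",
    "country heatwave days = mean HWF over the country's stations",
    "IDW: k nearest stations, planar degree distances",
    "severity gap policy: (0,12] below-normal, (39,40) very-extreme",
]


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scenario_truth(
    spec, cfg: PipelineConfig, scenario_trend: float
) -> DailySeries:
    """Reference-process truth extended to the far-future horizon with the
    scenario's warming trend past the historical window.

    Chronological RNG consumption guarantees the historical slice equals
    the plain reference series exactly.
    """
    far_end = max(p[1] for p in cfg.periods.values())
    scfg = replace(
        cfg.synthetic,
        end_year=far_end,
        trend_switch_year=cfg.synthetic.end_year,
        future_trend=scenario_trend,
    )
    return syn.generate_reference_series(spec, scfg)


def _indices_for_period(
    series: DailySeries,
    clim_tx: ci.ThresholdClimatology,
    clim_tn: ci.ThresholdClimatology,
    period: tuple[int, int],
    min_duration: int,
) -> pd.DataFrame:
    years = [y for y in series.years if period[0] <= y <= period[1]]
    return ci.indices_table(series, clim_tx, clim_tn, years, min_duration)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns the manifest dict (also written as
    manifest.json). Any stage failure aborts with a stage-named error."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    hist = cfg.periods["historical"]

    def record(path: Path) -> None:
        outputs.append(path)

    try:
        stage = "generate"
        catalogue = syn.generate_station_catalogue(cfg.synthetic)
        record(_write_csv_catalogue(catalogue, out / "stations.csv"))
        far_end = max(p[1] for p in cfg.periods.values())
        demog = syn.generate_demography(
            syn.COUNTRY_CODES, range(hist[0], far_end + 1), cfg.synthetic.seed
        )
        record(_write_csv(demog, out / "demography.csv"))
        ref = {s.station_id: syn.generate_reference_series(s, cfg.synthetic) for s in catalogue}
        series_dir = out / "reference"
        series_dir.mkdir(exist_ok=True)
        for sid, s in ref.items():
            record(write_series_csv(s, series_dir / f"{sid}.csv"))
        if cfg.write_netcdf:
            record(write_series_netcdf(list(ref.values()), out / "reference.nc"))

        stage = "thresholds"
        clim_tx = {
            sid: ci.calendar_day_percentile(
                s, "tmax", hist, cfg.percentile, cfg.window_halfwidth
            )
            for sid, s in ref.items()
        }
        clim_tn = {
            sid: ci.calendar_day_percentile(
                s, "tmin", hist, cfg.percentile, cfg.window_halfwidth
            )
            for sid, s in ref.items()
        }

        stage = "indices"
        ref_indices = pd.concat(
            [
                _indices_for_period(
                    ref[sid], clim_tx[sid], clim_tn[sid], hist, cfg.min_duration
                )
                for sid in ref
            ],
            ignore_index=True,
        )
        ref_indices["severity"] = ref_indices["hwm"].map(
            lambda v: sv.classify_hwm(v, strict=False)
        )
        record(_write_csv(ref_indices, out / "indices_reference_historical.csv"))

        stage = "correct"
        eval_rows = []
        scenario_indices: dict[tuple[str, str], pd.DataFrame] = {}
        for scen_name, scen_trend in cfg.scenarios.items():
            truths = {
                s.station_id: _scenario_truth(s, cfg, scen_trend)
                for s in catalogue
            }
            corrected_members = []
            for m_i, model in enumerate(cfg.models):
                members = []
                for s in catalogue:
                    truth = truths[s.station_id]
                    mcfg = replace(
                        cfg.synthetic,
                        gcm_bias=model.bias,
                        gcm_var_inflation=model.var_inflation,
                        gcm_noise_sd=model.noise_sd,
                    )
                    raw = syn.generate_gcm_series(truth, mcfg, model_seed=m_i)
                    params = {
                        var: bc.fit_params(ref[s.station_id], raw, hist, var)
                        for var in ("tmax", "tmin")
                    }
                    corr = bc.correct_series(raw, params)
                    etab = bc.evaluation_table(ref[s.station_id], raw, corr, hist)
                    etab.insert(0, "scenario", scen_name)
                    etab.insert(1, "model", model.name)
                    eval_rows.append(etab)
                    members.append(corr)
                corrected_members.append(members)
            ensembles = {
                catalogue[j].station_id: bc.ensemble_mean(
                    [corrected_members[i][j] for i in range(len(cfg.models))]
                )
                for j in range(len(catalogue))
            }
            for period_name, period in cfg.periods.items():
                tab = pd.concat(
                    [
                        _indices_for_period(
                            ensembles[sid],
                            clim_tx[sid],
                            clim_tn[sid],
                            period,
                            cfg.min_duration,
                        )
                        for sid in ensembles
                    ],
                    ignore_index=True,
                )
                tab["severity"] = tab["hwm"].map(
                    lambda v: sv.classify_hwm(v, strict=False)
                )
                scenario_indices[(period_name, scen_name)] = tab
                record(
                    _write_csv(
                        tab, out / f"indices_{period_name}_{scen_name}.csv"
                    )
                )
        record(
            _write_csv(
                pd.concat(eval_rows, ignore_index=True), out / "evaluation.csv"
            )
        )

        stage = "trends"
        trend_files = []
        for (period_name, scen_name), tab in scenario_indices.items():
            for index_name in ci.INDEX_COLUMNS:
                rows = []
                for sid, grp in tab.groupby("station_id"):
                    y = grp.sort_values("year")[index_name].to_numpy(dtype=float)
                    x = grp.sort_values("year")["year"].to_numpy(dtype=float)
                    finite = np.isfinite(y)
                    if finite.sum() < 4:
                        rows.append(
                            {
                                "station": sid,
                                "index": index_name,
                                "period": period_name,
                                "scenario": scen_name,
                                "slope": np.nan,
                                "p_value": np.nan,
                                "significant": False,
                            }
                        )
                        continue
                    res = tr.mann_kendall(y, alpha=cfg.alpha, x=x)
                    rows.append(
                        {
                            "station": sid,
                            "index": index_name,
                            "period": period_name,
                            "scenario": scen_name,
                            "slope": res.slope,
                            "p_value": res.p_value,
                            "significant": res.significant,
                        }
                    )
                tf = _write_csv(
                    pd.DataFrame(rows),
                    out / f"trends_{index_name}_{period_name}_{scen_name}.csv",
                )
                record(tf)
                trend_files.append(tf)

        stage = "severity"
        sev_rows = []
        for (period_name, scen_name), tab in scenario_indices.items():
            for year, grp in tab.groupby("year"):
                label, met = sv.regional_category(
                    dict(zip(grp["station_id"], grp["hwm"]))
                )
                sev_rows.append(
                    {
                        "scenario": scen_name,
                        "period": period_name,
                        "year": int(year),
                        "regional_severity": label,
                        "labels_met": "|".join(met),
                    }
                )
        record(_write_csv(pd.DataFrame(sev_rows), out / "severity_regional.csv"))

        stage = "burden"
        station_country = {s.station_id: s.country for s in catalogue}
        risk = sv.RiskSpec(cfg.rr, cfg.rr_low, cfg.rr_high)
        burden_frames = []
        hist_burden = sv.country_burden(
            ref_indices, demog, station_country, risk, scenario="reference"
        )
        burden_frames.append(hist_burden)
        record(_write_csv(hist_burden, out / "burden_reference_historical.csv"))
        for scen_name in cfg.scenarios:
            tabs = [
                scenario_indices[(p, scen_name)] for p in cfg.periods
            ]
            all_tab = pd.concat(tabs, ignore_index=True)
            b = sv.country_burden(
                all_tab, demog, station_country, risk, scenario=scen_name
            )
            burden_frames.append(b)
            record(_write_csv(b, out / f"burden_{scen_name}.csv"))
        totals = (
            pd.concat(burden_frames, ignore_index=True)
            .groupby(["scenario", "year"], as_index=False)[
                ["attributable", "attributable_low", "attributable_high"]
            ]
            .sum()
        )
        record(_write_csv(totals, out / "burden_region_totals.csv"))

        stage = "rasterize"
        lons = [s.lon for s in catalogue]
        lats = [s.lat for s in catalogue]
        grid = sp.RasterSpec.covering(lons, lats, cfg.raster_cell_size)
        clip_pool: dict[str, list[sp.Raster]] = {}
        for tf in trend_files:
            tdf = pd.read_csv(tf)
            index_name = tdf["index"].iloc[0] if len(tdf) else None
            if index_name not in cfg.raster_indices:
                continue
            merged = tdf.set_index("station")["slope"]
            pts = [
                (s.lon, s.lat, float(merged[s.station_id]))
                for s in catalogue
                if np.isfinite(merged.get(s.station_id, np.nan))
            ]
            if len(pts) < cfg.idw_k:
                logger.warning("skipping raster for %s: too few stations", tf.name)
                continue
            raster = sp.idw_interpolate(pts, grid, cfg.idw_k, cfg.idw_power)
            clip_pool.setdefault(index_name, []).append(raster)
            rpath = out / "rasters" / (tf.stem.replace("trends_", "slope_") + ".csv")
            rpath.parent.mkdir(exist_ok=True)
            grid_df = pd.DataFrame(
                raster.values, index=np.round(grid.lats, 6), columns=np.round(grid.lons, 6)
            )
            grid_df.index.name = "lat"
            grid_df.to_csv(rpath, float_format="%.6f")
            record(rpath)
        clip_bounds = {
            name: sp.clip_for_display(rasters, signed=True)
            for name, rasters in clip_pool.items()
        }
        cb_path = out / "rasters" / "display_bounds.json"
        cb_path.parent.mkdir(exist_ok=True)
        cb_path.write_text(json.dumps(clip_bounds, sort_keys=True, indent=2))
        record(cb_path)
    except HeatkitError as exc:
        raise HeatkitError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config_hash": config_hash(cfg),
        "decisions": PIPELINE_DECISIONS,
        "outputs": sorted(
            {
                str(p.relative_to(out)): _sha256(p)
                for p in outputs
            }.items()
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_csv_catalogue(catalogue, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    return write_catalogue_csv(catalogue, path)
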