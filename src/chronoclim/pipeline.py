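"""End-to-end driver: debias -> harmonize -> derive -> fill -> summarize.

The pipeline wires the stage modules together for a paleo-mode run on an
archive of coarse decadal stacks plus a fine observed climatology (the
synthetic fixture has the same geometry as the production archives).  Future
mode differs only in skipping the seasonal-to-monthly stage and the coastal
fill, and in using the empirical rather than the linear quantile map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as cio
from .coastal import fill_submerged, shoreline_for_decade
from .downscale import (
    apply_gamma,
    bilinear_regrid,
    downscale_additive,
    downscale_factor,
    normalize_shortwave,
)
from .evapo import pet_penman_monteith, run_bucket, surface_pressure
from .fixtures import Fixture, FixtureScenario, generate, make_fixture
from .gdd import gdd_monthly_cycle
from .grids import DEFAULT_VARIABLES, MONTH_DAYS, seasonal_from_monthly
from .qmap import fit_paleo_linear_qmap, qmap_to_fine
from .s2m import s2m_additive, s2m_factor, s2m_gamma
from .summaries import build_windows, derive_etr_wdi, summarize_window

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "downscale_paleo", "derive_secondary", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    fixture: Fixture
    monthly: dict[str, np.ndarray]  # var -> (n_decades, 12, fine)
    secondary: dict[str, np.ndarray]
    summaries: dict[str, dict[str, np.ndarray]]  # window label -> rasters
    output_root: Path | None = None


def _seasonal_anomaly_to_monthly(anom_seasonal: np.ndarray) -> np.ndarray:
    """(..., 4) seasonal anomalies -> (..., 12) smooth monthly anomalies."""
    return s2m_additive(anom_seasonal)


def _seasonal_factors_to_monthly(
    F_seasonal: np.ndarray, P_clim: np.ndarray
) -> np.ndarray:
    """Cell-wise nonlinear solve: (4, nlat, nlon) factors -> (12, nlat, nlon)."""
    nlat, nlon = F_seasonal.shape[1:]
    out = np.empty((12, nlat, nlon))
    for i in range(nlat):
        for j in range(nlon):
            out[:, i, j] = s2m_factor(F_seasonal[:, i, j], P_clim[:, i, j])
    return out


def downscale_paleo(fx: Fixture, seasonal: bool | None = None) -> dict[str, np.ndarray]:
    """Debias and downscale every primary variable of a paleo archive.

    The model's own present state is the mean over the last 11 decades of the
    run (110 years).  Returns fine-grid monthly stacks per variable.
    """
    sc = fx.scenario
    if seasonal is None:
        seasonal = sc.seasonal_only
    coarse, fine = fx.coarse_grid, fx.fine_grid
    n_dec = len(fx.decades)
    out: dict[str, np.ndarray] = {}

    # coarse observed precipitation climatology for factor weighting
    p_clim_coarse = fx.baseline_obs_prcp.mean(axis=0)

    for var, stack_monthly in fx.model_paleo.items():
        kind = DEFAULT_VARIABLES[var].kind
        stack = (
            seasonal_from_monthly(stack_monthly, axis=1) if seasonal else stack_monthly
        )
        ref = stack[-11:].mean(axis=0)
        fine_stack = np.empty((n_dec, 12, *fine.shape))

        if var == "prcp":
            maps = _fit_qmaps(fx, seasonal)
            # mapped values live in observation space, so the normalizer is
            # the observed climatology aggregated to the coarse grid
            p_clim = (
                seasonal_from_monthly(p_clim_coarse, axis=0)
                if seasonal
                else p_clim_coarse
            )
            for d in range(n_dec):
                p_alt = _apply_qmaps(maps, stack[d])
                with np.errstate(divide="ignore", invalid="ignore"):
                    fac = np.where(p_clim == 0, 1.0, p_alt / np.maximum(p_clim, 1e-12))
                fac = np.maximum(fac, 0.0)
                if seasonal:
                    fac = _seasonal_factors_to_monthly(
                        np.maximum(fac, 1e-6), p_clim_coarse
                    )
                fine_stack[d] = np.maximum(
                    fx.obs_clim["prcp"] * bilinear_regrid(fac, coarse, fine), 0.0
                )
        elif kind == "additive":
            anom = stack - ref
            if seasonal:
                anom = np.moveaxis(
                    s2m_additive(np.moveaxis(anom, 1, -1)), -1, 1
                )
            for d in range(n_dec):
                fine_stack[d] = fx.obs_clim[var] + bilinear_regrid(
                    anom[d], coarse, fine
                )
        elif kind == "factor":
            for d in range(n_dec):
                if seasonal:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        F = np.where(ref == 0, 1.0, stack[d] / np.maximum(ref, 1e-12))
                    fac = _seasonal_factors_to_monthly(
                        np.clip(F, 1e-6, 10.0), p_clim_coarse
                    )
                    fine_stack[d] = np.maximum(
                        fx.obs_clim[var] * bilinear_regrid(fac, coarse, fine), 0.0
                    )
                else:
                    fine_stack[d] = downscale_factor(
                        stack[d], ref, fx.obs_clim[var], coarse, fine
                    )
        else:  # gamma (shortwave)
            toa_c = (
                seasonal_from_monthly(fx.toa_coarse, axis=0)
                if seasonal
                else fx.toa_coarse
            )
            shat_ref = normalize_shortwave(ref, toa_c)
            obs_shat = normalize_shortwave(fx.obs_clim[var], fx.toa)
            for d in range(n_dec):
                shat_alt = normalize_shortwave(stack[d], toa_c)
                with np.errstate(invalid="ignore"):
                    gam = np.log(shat_alt) / np.log(shat_ref)
                gam = np.where(np.isfinite(gam), np.clip(gam, 1e-3, 1e3), 1.0)
                if seasonal:
                    gam = np.moveaxis(
                        s2m_gamma(np.moveaxis(gam, 0, -1)), -1, 0
                    )
                gam_fine = np.maximum(bilinear_regrid(gam, coarse, fine), 1e-3)
                fine_stack[d] = apply_gamma(obs_shat, gam_fine, fx.toa)
        out[var] = fine_stack
        logger.info("downscaled %s (%s, seasonal=%s)", var, kind, seasonal)
    return out


def _fit_qmaps(fx: Fixture, seasonal: bool) -> np.ndarray:
    """Per-cell, per-calendar-slice linear quantile maps from the baselines."""
    p = fx.baseline_obs_prcp
    q = fx.baseline_model_prcp
    if seasonal:
        p = seasonal_from_monthly(p, axis=1)
        q = seasonal_from_monthly(q, axis=1)
    n_slice, nlat, nlon = p.shape[1:]
    maps = np.empty((n_slice, nlat, nlon), dtype=object)
    for m in range(n_slice):
        for i in range(nlat):
            for j in range(nlon):
                maps[m, i, j] = fit_paleo_linear_qmap(p[:, m, i, j], q[:, m, i, j])
    return maps


def _apply_qmaps(maps: np.ndarray, field: np.ndarray) -> np.ndarray:
    out = np.empty_like(field)
    for idx in np.ndindex(maps.shape):
        out[idx] = maps[idx](field[idx])
    return np.maximum(out, 0.0)


def derive_secondary(
    fx: Fixture, monthly: dict[str, np.ndarray], gdd_base: float = 5.0
) -> dict[str, np.ndarray]:
    """Secondary bioclimatic variables from the downscaled primaries.

    GDD from the normal daily-temperature model (daily SD from the modern
    monthly SD field, held constant across time); PET by Penman-Monteith with
    downscaled albedo; AET from the single bucket run over each decade's
    repeating annual cycle (24-month spin-up); then ETR and WDI.
    """
    n_dec = monthly["tmax"].shape[0]
    fine_shape = fx.fine_grid.shape
    pressure = surface_pressure(fx.elevation)

    gdd = np.empty((n_dec, 12, *fine_shape))
    pet = np.empty_like(gdd)
    aet = np.empty_like(gdd)
    for d in range(n_dec):
        tmean = 0.5 * (monthly["tmax"][d] + monthly["tmin"][d])
        gdd[d] = gdd_monthly_cycle(tmean, fx.sigma_monthly, gdd_base)
        for m in range(12):
            pet[d, m] = pet_penman_monteith(
                monthly["tmax"][d, m],
                monthly["tmin"][d, m],
                monthly["vap"][d, m],
                monthly["wnd"][d, m],
                monthly["swd"][d, m],
                monthly["swu"][d, m],
                monthly["lwn"][d, m],
                pressure,
                MONTH_DAYS[m],
            )
        # steady annual cycle: tile 3 years, discard the 24-month spin-up
        pr3 = np.tile(monthly["prcp"][d], (3, 1, 1))
        pet3 = np.tile(pet[d], (3, 1, 1))
        t3 = np.tile(tmean, (3, 1, 1))
        nd3 = np.tile(MONTH_DAYS, 3)
        aet_all, _, _ = run_bucket(pr3, pet3, t3, n_days=nd3, spinup_months=24)
        aet[d] = aet_all[24:]

    etr, wdi = derive_etr_wdi(aet, pet, monthly["prcp"])
    return {"GDD": gdd, "PET": pet, "AET": aet, "ETR": etr, "WDI": wdi}


def run_pipeline(config: dict) -> PipelineResult:
    """Execute the full workflow from a configuration mapping.

    Keys: ``mode`` ("paleo"), ``scenario`` (FixtureScenario field overrides,
    incl. ``seed``), ``output`` (directory; omit for in-memory only),
    ``gdd_base`` (0 or 5), ``fill_coast`` (bool), ``write_fixture`` (bool).
    """
    mode = config.get("mode", "paleo")
    if mode != "paleo":
        raise ValueError("only paleo mode is wired end-to-end; future mode "
                         "reuses the same stages without s2m/coastal fill")
    sc = FixtureScenario(**config.get("scenario", {}))
    fx = generate(sc)

    stage = "downscale"
    try:
        monthly = downscale_paleo(fx)
        stage = "derive"
        secondary = derive_secondary(fx, monthly, gdd_base=config.get("gdd_base", 5.0))
        stage = "fill-coast"
        if config.get("fill_coast", True):
            epochs = sorted({shoreline_for_decade(d) for d in fx.decades})
            masks = {e: fx.past_land for e in epochs}
            for var in list(monthly) + list(secondary):
                store = monthly if var in monthly else secondary
                for i, d in enumerate(fx.decades):
                    mask = masks[shoreline_for_decade(d)]
                    store[var][i] = fill_submerged(
                        np.where(fx.present_land, store[var][i], np.nan),
                        fx.fine_grid,
                        fx.present_land,
                        mask,
                    )
        stage = "summarize"
        windows = build_windows(
            "paleo", run_range=(int(fx.decades[0]), int(fx.decades[-1]))
        )
        window_data_all: dict[str, dict[str, np.ndarray]] = {}
        for win in windows:
            sel = np.isin(fx.decades, win.member_decades)
            data = {
                "TMIN": monthly["tmin"][sel],
                "TMAX": monthly["tmax"][sel],
                "PRCP": monthly["prcp"][sel],
                "GDD": secondary["GDD"][sel],
                "AET": secondary["AET"][sel],
                "PET": secondary["PET"][sel],
                "ETR": secondary["ETR"][sel],
                "WDI": secondary["WDI"][sel],
            }
            window_data_all[win.label] = summarize_window(data)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    output_root = None
    if "output" in config:
        output_root = Path(config["output"])
        if config.get("write_fixture", False):
            make_fixture(sc, output_root / "fixture")
        cio.write_packed_netcdf(
            output_root / "netcdf" / "primary.nc",
            {v: monthly[v] for v in monthly},
            fx.fine_grid,
            {"decade": fx.decades, "month": np.arange(1, 13)},
        )
        cio.write_packed_netcdf(
            output_root / "netcdf" / "secondary.nc",
            secondary,
            fx.fine_grid,
            {"decade": fx.decades, "month": np.arange(1, 13)},
        )
        model_name = config.get("model_name", "fixture-model")
        for label, rasters in window_data_all.items():
            for name, ras in rasters.items():
                cio.write_geotiff(
                    cio.summary_path(output_root / "tifs", model_name, label, name),
                    np.where(np.isfinite(ras), ras, 0.0),
                    fx.fine_grid,
                )
        logger.info("wrote artifact tree under %s", output_root)

    return PipelineResult(fx, monthly, secondary, window_data_all, output_root)
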