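"""Synthetic model/observation archives with planted, recoverable truths.

The generator emulates the data geometry of the production archives -- a
coarse climate-model grid (default 10 x 7 cells at 2.5 degrees) nested in a
fine 0.5-degree observational grid, decadal paleo stacks (optionally
seasonal-only), 11-decade overlapping baselines, land/sea masks per epoch,
and daily station series -- at desk scale, with every planted signal stored
alongside so each pipeline stage can be scored against ground truth:

* a constant temperature anomaly (default +3 degC) in the early decades, with
  the reference decades left unperturbed, so change-factor downscaling must
  return obs + anomaly exactly;
* a constant precipitation change factor (default 1.4) recoverable through
  the 11-decade linear quantile map;
* multiplicative vapour/wind factors and a shortwave exponent;
* station series whose daily noise SD is known, for the degree-day estimator.

Annual cycles are two-harmonic sinusoids plus smooth spatial structure; the
generator makes no attempt at ESM physics or realistic spatial covariance.
Regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import (
    DEFAULT_VARIABLES,
    Grid,
    MONTH_DAYS,
    make_grid,
    seasonal_from_monthly,
)
from .io import write_packed_netcdf
from .solar import PRESENT_ORBIT, toa_insolation_monthly

__all__ = ["FixtureScenario", "Fixture", "generate", "make_fixture",
           "correlated_monthly_pair", "station_series"]


@dataclass(frozen=True)
class FixtureScenario:
    """Knobs of the synthetic study: grids, run length, planted signals."""

    seed: int = 0
    lon_min: float = -170.0
    lat_min: float = 30.0
    n_coarse_lon: int = 10
    n_coarse_lat: int = 7
    coarse_res: float = 2.5
    fine_res: float = 0.5
    #: decade indices of the paleo archive (20 decades ending at 0.5 ka BP
    #: reference block, so the last 11 decades form the model reference)
    first_decade: int = -60
    n_decades: int = 20
    seasonal_only: bool = False
    temp_anomaly: float = 3.0  # degC, additive (tmax/tmin, lwn scaled)
    factor_anomaly: float = 0.8  # vap/wnd multiplicative change
    precip_factor: float = 1.4  # planted change factor, wet cells
    gamma_anomaly: float = 1.2  # shortwave exponent change
    sigma_daily: float = 4.0  # degC, station daily noise SD
    sigma_monthly: float = 1.5  # degC, interannual monthly SD field


@dataclass
class Fixture:
    """In-memory synthetic archive plus its planted truths."""

    scenario: FixtureScenario
    coarse_grid: Grid
    fine_grid: Grid
    present_land: np.ndarray  # fine-grid mask
    past_land: np.ndarray  # fine-grid mask (older epoch, wider coastline)
    elevation: np.ndarray  # fine grid, m
    obs_clim: dict[str, np.ndarray]  # var -> (12, fine)
    sigma_monthly: np.ndarray  # (12, fine)
    toa: np.ndarray  # (12, fine) top-of-atmosphere insolation
    toa_coarse: np.ndarray  # (12, coarse)
    model_ref: dict[str, np.ndarray]  # var -> (12, coarse)
    model_paleo: dict[str, np.ndarray]  # var -> (n_decades, 12, coarse)
    decades: np.ndarray
    anomaly_scale: np.ndarray  # per-decade planted-signal scale in [0, 1]
    baseline_obs_prcp: np.ndarray  # (11, 12, coarse)
    baseline_model_prcp: np.ndarray  # (11, 12, coarse)
    truths: dict = field(default_factory=dict)

    @property
    def reference_decades(self) -> np.ndarray:
        """Last 11 decades of the run: the model's own present state."""
        return self.decades[-11:]


def _smooth_field(rng: np.random.Generator, grid: Grid, base: float, amp: float) -> np.ndarray:
    """Deterministic smooth spatial structure + a little seeded texture."""
    lon, lat = np.meshgrid(grid.lons, grid.lats)
    lon_n = (lon - lon.min()) / max(np.ptp(lon), 1e-9)
    lat_n = (lat - lat.min()) / max(np.ptp(lat), 1e-9)
    f = base + amp * (
        0.6 * np.sin(np.pi * lon_n) * np.cos(np.pi * lat_n)
        + 0.4 * lat_n
        + 0.1 * rng.standard_normal(grid.shape).round(3)
    )
    return f


def _annual_cycle(
    rng: np.random.Generator, grid: Grid, base: float, amp1: float, amp2: float,
    positive: bool = False,
) -> np.ndarray:
    """Two-harmonic (12, lat, lon) cycle with smooth spatial modulation."""
    mean = _smooth_field(rng, grid, base, abs(base) * 0.3 + 1.0)
    a1 = _smooth_field(rng, grid, amp1, amp1 * 0.3)
    a2 = _smooth_field(rng, grid, amp2, amp2 * 0.3)
    ph1 = rng.uniform(0, 2 * np.pi)
    ph2 = rng.uniform(0, 2 * np.pi)
    j = np.arange(12)[:, None, None]
    cyc = (
        mean[None]
        + a1[None] * np.cos(2 * np.pi * j / 12 - ph1)
        + a2[None] * np.cos(4 * np.pi * j / 12 - ph2)
    )
    if positive:
        cyc = np.maximum(cyc, 0.05 * abs(base))
    return cyc


def _aggregate_to_coarse(fine_field: np.ndarray, fine: Grid, coarse: Grid) -> np.ndarray:
    """Block-average fine cells into their owning coarse cells."""
    ratio = round(coarse.resolution / fine.resolution)
    shp = fine_field.shape
    blocked = fine_field.reshape(
        *shp[:-2], coarse.n_lat, ratio, coarse.n_lon, ratio
    )
    return blocked.mean(axis=(-3, -1))


def generate(scenario: FixtureScenario | None = None) -> Fixture:
    """Build the synthetic archive for a scenario (deterministic per seed)."""
    sc = scenario or FixtureScenario()
    rng = np.random.default_rng(sc.seed)

    lon_max = sc.lon_min + sc.n_coarse_lon * sc.coarse_res
    lat_max = sc.lat_min + sc.n_coarse_lat * sc.coarse_res
    coarse = make_grid(sc.lon_min, lon_max, sc.lat_min, lat_max, sc.coarse_res)
    fine = make_grid(sc.lon_min, lon_max, sc.lat_min, lat_max, sc.fine_res)

    # masks: a sea strip on the western edge today; at the older epoch part of
    # the shelf (the two easternmost sea columns) was exposed land
    present = np.ones(fine.shape, dtype=bool)
    present[:, :6] = False
    past = present.copy()
    past[:, 4:6] = True

    elevation = np.maximum(_smooth_field(rng, fine, 400.0, 800.0), 0.0)

    obs_clim = {
        "tmax": _annual_cycle(rng, fine, 18.0, 12.0, 2.0),
        "tmin": _annual_cycle(rng, fine, 6.0, 10.0, 1.5),
        "prcp": _annual_cycle(rng, fine, 60.0, 30.0, 10.0, positive=True),
        "vap": _annual_cycle(rng, fine, 12.0, 5.0, 1.0, positive=True),
        "wnd": _annual_cycle(rng, fine, 4.0, 1.0, 0.3, positive=True),
        "lwn": _annual_cycle(rng, fine, -60.0, 15.0, 3.0),
    }
    toa = toa_insolation_monthly(fine.lats, PRESENT_ORBIT)[:, :, None] * np.ones(
        (1, 1, fine.n_lon)
    )
    toa_coarse = toa_insolation_monthly(coarse.lats, PRESENT_ORBIT)[:, :, None] * np.ones(
        (1, 1, coarse.n_lon)
    )
    # shortwave as a fraction of TOA: cloudier in the wet season
    shat = np.clip(
        0.55 + 0.1 * np.cos(2 * np.pi * np.arange(12) / 12)[:, None, None]
        - 0.002 * (obs_clim["prcp"] - 60.0),
        0.1,
        0.9,
    )
    obs_clim["swd"] = shat * toa
    obs_clim["swu"] = 0.15 * obs_clim["swd"]

    # model reference climatology: coarse aggregation of obs plus a bias the
    # change-factor method must cancel
    model_ref: dict[str, np.ndarray] = {}
    for var, clim in obs_clim.items():
        agg = _aggregate_to_coarse(clim, fine, coarse)
        if DEFAULT_VARIABLES[var].kind == "additive":
            model_ref[var] = agg + 2.0
        elif DEFAULT_VARIABLES[var].kind == "factor":
            model_ref[var] = agg * 1.3
        else:  # gamma: bias the normalized fraction multiplicatively, clipped
            model_ref[var] = np.clip(agg * 1.1, 0.0, 0.98 * toa_coarse)

    # planted-signal schedule: full anomaly in the early decades, ramping to
    # zero before the 11-decade reference block so the reference stays clean
    decades = sc.first_decade + np.arange(sc.n_decades)
    scale = np.zeros(sc.n_decades)
    n_full = max(sc.n_decades - 15, 1)
    scale[:n_full] = 1.0
    ramp = sc.n_decades - 11 - n_full
    if ramp > 0:
        scale[n_full : n_full + ramp] = np.linspace(1.0, 0.0, ramp + 2)[1:-1]

    model_paleo: dict[str, np.ndarray] = {}
    for var, ref in model_ref.items():
        kind = DEFAULT_VARIABLES[var].kind
        stack = np.empty((sc.n_decades, *ref.shape))
        for i, s in enumerate(scale):
            if kind == "additive":
                stack[i] = ref + s * sc.temp_anomaly
            elif var == "prcp":
                stack[i] = ref * sc.precip_factor**s
            elif kind == "factor":
                stack[i] = ref * sc.factor_anomaly**s
            else:
                shat_ref = np.clip(ref / toa_coarse, 1e-6, 1 - 1e-6)
                stack[i] = toa_coarse * shat_ref ** (sc.gamma_anomaly**s)
        model_paleo[var] = stack

    # 11-decade 1901-2011 overlapping baselines for the precipitation map:
    # decadal variability around the climatology, with the observed series a
    # near-proportional response to the model series
    nbase = 11
    base_var = rng.uniform(0.85, 1.15, size=(nbase, 1, *coarse.shape))
    q_base = model_ref["prcp"][None] * base_var
    p_base = _aggregate_to_coarse(obs_clim["prcp"], fine, coarse)[None] * base_var * (
        1.0 + 0.02 * rng.standard_normal((nbase, 1, *coarse.shape))
    )
    q_base = np.maximum(q_base, 0.0)
    p_base = np.maximum(p_base, 0.0)

    truths = {
        "temp_anomaly": sc.temp_anomaly,
        "factor_anomaly": sc.factor_anomaly,
        "precip_factor": sc.precip_factor,
        "gamma_anomaly": sc.gamma_anomaly,
        "sigma_daily": sc.sigma_daily,
        "anomaly_scale": scale.tolist(),
    }

    return Fixture(
        scenario=sc,
        coarse_grid=coarse,
        fine_grid=fine,
        present_land=present,
        past_land=past,
        elevation=elevation,
        obs_clim=obs_clim,
        sigma_monthly=np.full((12, *fine.shape), sc.sigma_monthly),
        toa=toa,
        toa_coarse=toa_coarse,
        model_ref=model_ref,
        model_paleo=model_paleo,
        decades=decades,
        anomaly_scale=scale,
        baseline_obs_prcp=np.broadcast_to(p_base, (nbase, 12, *coarse.shape)).copy(),
        baseline_model_prcp=np.broadcast_to(q_base, (nbase, 12, *coarse.shape)).copy(),
        truths=truths,
    )


def station_series(
    seed: int,
    n_years: int = 5,
    sigma_daily: float = 4.0,
    mean: float = 8.0,
    amplitude: float = 14.0,
    diurnal_halfrange: float = 5.0,
) -> pd.DataFrame:
    """Daily station record: sinusoidal annual cycle + normal daily noise.

    Columns date, tmax, tmin; the daily-mean noise SD equals ``sigma_daily``
    by construction, which is the ground truth for the degree-day estimator.
    """
    rng = np.random.default_rng(seed)
    days = pd.date_range("1951-01-01", periods=365 * n_years, freq="D")
    doy = days.dayofyear.values
    cycle = mean + amplitude * np.cos(2 * np.pi * (doy - 200) / 365.0)
    tmean = cycle + sigma_daily * rng.standard_normal(len(days))
    return pd.DataFrame(
        {
            "date": days,
            "tmax": tmean + diurnal_halfrange,
            "tmin": tmean - diurnal_halfrange,
        }
    )


def correlated_monthly_pair(
    seed: int, n_months: int = 660, rho: float = 0.6, shape: tuple[int, ...] = (3, 3)
) -> tuple[np.ndarray, np.ndarray]:
    """Two monthly series whose anomaly correlation is ``rho`` by construction.

    Both share an annual cycle; anomalies are bivariate normal with the given
    correlation at every cell.
    """
    if n_months % 12:
        raise ValueError("n_months must be a multiple of 12")
    rng = np.random.default_rng(seed)
    cyc = 10.0 * np.cos(2 * np.pi * np.arange(n_months) / 12.0)
    cyc = cyc.reshape(-1, *[1] * len(shape))
    za = rng.standard_normal((n_months, *shape))
    zb = rho * za + np.sqrt(1 - rho**2) * rng.standard_normal((n_months, *shape))
    return cyc + za, cyc + zb


def make_fixture(scenario: FixtureScenario, outdir: str | Path) -> Path:
    """Write the synthetic archive tree (NetCDF + CSV + truth YAML).

    Layout: obs/ (climatologies, sigma, elevation, masks), model/ (reference
    and decadal stacks, baselines), stations/, truths.yml.
    """
    outdir = Path(outdir)
    fx = generate(scenario)
    month = {"month": np.arange(1, 13)}

    write_packed_netcdf(
        outdir / "obs" / "climatology.nc", fx.obs_clim, fx.fine_grid, month
    )
    write_packed_netcdf(
        outdir / "obs" / "ancillary.nc",
        {
            "elevation": fx.elevation,
            "present_land": fx.present_land.astype(float),
            "past_land": fx.past_land.astype(float),
        },
        fx.fine_grid,
    )
    write_packed_netcdf(
        outdir / "obs" / "sigma_monthly.nc", {"sigma": fx.sigma_monthly},
        fx.fine_grid, month,
    )

    model_fields = {}
    for var, stack in fx.model_paleo.items():
        model_fields[var] = (
            seasonal_from_monthly(stack, axis=1) if scenario.seasonal_only else stack
        )
    tdim = {"decade": fx.decades}
    sdim = {"season": np.arange(4)} if scenario.seasonal_only else month
    write_packed_netcdf(
        outdir / "model" / "paleo.nc", model_fields, fx.coarse_grid,
        {**tdim, **sdim},
    )
    write_packed_netcdf(
        outdir / "model" / "reference.nc", fx.model_ref, fx.coarse_grid, month
    )
    write_packed_netcdf(
        outdir / "model" / "baselines.nc",
        {"obs_prcp": fx.baseline_obs_prcp, "model_prcp": fx.baseline_model_prcp},
        fx.coarse_grid,
        {"baseline_decade": np.arange(-5, 6), **month},
    )

    st = station_series(scenario.seed, sigma_daily=scenario.sigma_daily)
    (outdir / "stations").mkdir(parents=True, exist_ok=True)
    st.to_csv(outdir / "stations" / "station_000.csv", index=False)

    with open(outdir / "truths.yml", "w") as fh:
        yaml.safe_dump(fx.truths, fh)
    return outdir
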