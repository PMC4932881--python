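"""Centennial and decadal statistical summaries of monthly climate stacks.

Paleo products are summarized in 200-year windows centered on 500-year steps
(20 decadal members each, except the truncated 0 ka window); 21st-century
products use 20-year windows stepped every 10 years (2011-2030 ... 2081-2100)
plus a 1950-2005 historical climatology.  Statistics are computed per member
(decade or year) from its 12 monthly values, then averaged across members --
the order is part of the product definition, not an implementation choice.

Raster names follow the <period>-<stat>-<VAR> grammar: an-avg / an-sum for
annual level, an-sd / an-cv for variability (sd for temperature-scale
variables, cv for ratio-scale ones), and qt/mo-lwr/hgr for the lowest and
highest quarterly and monthly aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import SEASON_MONTHS, decade_to_years

__all__ = [
    "SummaryWindow",
    "TABLE_STATS",
    "build_windows",
    "summarize_window",
    "derive_etr_wdi",
    "crosscorr_monthly_anomalies",
]


@dataclass(frozen=True)
class SummaryWindow:
    """One summary window: calendar span plus member decades (paleo mode)."""

    label: str  # e.g. "0.5ka" or "2011-2030"
    start_year: int
    end_year: int
    member_decades: tuple[int, ...] = ()


# which variable takes which annual level statistic, variability statistic,
# and which extremes exist (per the raster naming table)
_SUM_VARS = {"PRCP", "GDD", "AET", "PET", "WDI"}
_AVG_VARS = {"TMIN", "TMAX", "ETR"}
_SD_VARS = {"TMIN", "TMAX", "GDD"}  # interval-scale: sd, not cv

TABLE_STATS: dict[str, tuple[str, ...]] = {
    "TMIN": ("an-avg", "an-sd", "qt-lwr", "mo-lwr"),
    "TMAX": ("an-avg", "an-sd", "qt-hgr", "mo-hgr"),
    "PRCP": ("an-sum", "an-cv", "qt-lwr", "qt-hgr", "mo-lwr", "mo-hgr"),
    "GDD": ("an-sum", "an-sd", "qt-lwr", "qt-hgr", "mo-lwr", "mo-hgr"),
    "AET": ("an-sum", "an-cv", "qt-lwr", "qt-hgr", "mo-lwr", "mo-hgr"),
    "PET": ("an-sum", "an-cv", "qt-lwr", "qt-hgr", "mo-lwr", "mo-hgr"),
    "ETR": ("an-avg", "an-cv", "qt-lwr", "qt-hgr", "mo-lwr", "mo-hgr"),
    "WDI": ("an-sum", "an-cv", "qt-lwr", "qt-hgr", "mo-lwr", "mo-hgr"),
}

#: Last decade index of each paleo run flavour.
RUN_END_DECADE = {"ccsm3": 3, "ecbilt": -1}


def build_windows(
    mode: str,
    run_range: tuple[int, int] | None = None,
    start_ka: float | None = None,
) -> list[SummaryWindow]:
    """Construct the summary windows for a run.

    ``paleo``: centers every 500 years from ``start_ka`` (default set by the
    run range) down to 0 ka; each window holds the decades lying wholly
    within +-100 years of the center, truncated to the run range (the 0 ka
    window therefore spans 1850-1990 when the run ends at decade +3, and
    1850-1950 when it ends at decade -1).  Empty windows are dropped.

    ``future``: the fixed 20-year/10-year ladder 2011-2030 ... 2081-2100 plus
    the 1950-2005 historical climatology; members are individual years.
    """
    if mode == "future":
        windows = [SummaryWindow("1950-2005", 1950, 2005)]
        for start in range(2011, 2082, 10):
            windows.append(SummaryWindow(f"{start}-{start + 19}", start, start + 19))
        return windows
    if mode != "paleo":
        raise ValueError("mode must be 'paleo' or 'future'")
    if run_range is None:
        raise ValueError("paleo mode needs a (first_decade, last_decade) run range")

    d0, d1 = run_range
    lo_year = decade_to_years(d0)[0]
    hi_year = decade_to_years(d1)[1]
    if start_ka is None:
        # oldest 500-yr center at or beyond the run start; empty windows drop
        start_ka = np.ceil(2.0 * (1950 - lo_year) / 1000.0) / 2.0

    windows: list[SummaryWindow] = []
    for center_ka in np.arange(start_ka, -0.25, -0.5):
        cy = 1950 - 1000.0 * center_ka
        members = [
            d
            for d in range(d0, d1 + 1)
            if decade_to_years(d)[0] >= cy - 100 and decade_to_years(d)[1] <= cy + 100
        ]
        if not members:
            continue
        label = f"{center_ka:g}ka"
        windows.append(
            SummaryWindow(
                label,
                max(int(cy - 100), lo_year),
                min(int(cy + 100), hi_year),
                tuple(members),
            )
        )
    return windows


def _member_stats(monthly: np.ndarray, var: str) -> dict[str, np.ndarray]:
    """Statistics of one member from its (12, ...) monthly stack."""
    out: dict[str, np.ndarray] = {}
    if var in _SUM_VARS:
        out["an-sum"] = monthly.sum(axis=0)
        seasonal = np.stack(
            [monthly[list(m)].sum(axis=0) for m in SEASON_MONTHS]
        )
    else:
        out["an-avg"] = monthly.mean(axis=0)
        seasonal = np.stack(
            [monthly[list(m)].mean(axis=0) for m in SEASON_MONTHS]
        )
    sd = monthly.std(axis=0, ddof=0)
    if var in _SD_VARS:
        out["an-sd"] = sd
    else:
        mean = monthly.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = sd / mean
        out["an-cv"] = np.where(mean == 0, np.nan, cv)
    out["mo-lwr"] = monthly.min(axis=0)
    out["mo-hgr"] = monthly.max(axis=0)
    out["qt-lwr"] = seasonal.min(axis=0)
    out["qt-hgr"] = seasonal.max(axis=0)
    return out


def summarize_window(window_data: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Summary rasters for one window.

    ``window_data`` maps variable names (TMIN, TMAX, PRCP, GDD, AET, PET,
    ETR, WDI) to stacks of shape (n_members, 12, ...).  Statistics are
    computed per member and then averaged across members; only the name
    combinations that exist in the raster naming table are emitted.
    """
    rasters: dict[str, np.ndarray] = {}
    for var, stack in window_data.items():
        if var not in TABLE_STATS:
            raise ValueError(f"unknown summary variable {var!r}")
        stack = np.asarray(stack, dtype=float)
        if stack.ndim < 2 or stack.shape[1] != 12 or stack.shape[0] < 1:
            raise ValueError(f"{var}: expected (n_members, 12, ...) stack")
        per_member = [_member_stats(stack[i], var) for i in range(stack.shape[0])]
        for stat in TABLE_STATS[var]:
            vals = np.stack([m[stat] for m in per_member])
            rasters[f"{stat}-{var}"] = vals.mean(axis=0)
    return rasters


def derive_etr_wdi(
    aet: np.ndarray, pet: np.ndarray, precip: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Monthly moisture indices: ETR = AET/PET (NaN where PET = 0) and
    WDI = PET - precipitation (negative where supply exceeds demand)."""
    aet = np.asarray(aet, dtype=float)
    pet = np.asarray(pet, dtype=float)
    precip = np.asarray(precip, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        etr = aet / pet
    etr = np.where(pet > 0, etr, np.nan)
    return etr, pet - precip


def crosscorr_monthly_anomalies(
    series_a: np.ndarray, series_b: np.ndarray
) -> np.ndarray:
    """Per-cell Pearson correlation of monthly anomalies.

    Each (time, ...) series is reduced to anomalies from its own mean annual
    cycle (time length must be a multiple of 12, at least 24 months); cells
    where either series has zero anomaly variance are NaN.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share shape")
    nt = a.shape[0]
    if nt < 24 or nt % 12 != 0:
        raise ValueError("need a common time axis of >=24 whole years of months")

    def anomalies(x: np.ndarray) -> np.ndarray:
        cyc = x.reshape(nt // 12, 12, *x.shape[1:]).mean(axis=0)
        return x - np.tile(cyc, (nt // 12, *[1] * (x.ndim - 1)))

    da, db = anomalies(a), anomalies(b)
    num = (da * db).sum(axis=0)
    den = np.sqrt((da**2).sum(axis=0) * (db**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return np.where(den == 0, np.nan, np.clip(r, -1.0, 1.0))
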