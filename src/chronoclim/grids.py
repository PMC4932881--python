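"""Raster geometry, variable semantics, and decadal time conventions.

Everything downstream (debiasing, seasonal harmonization, bioclimatic
derivation, summaries) operates on regular lon/lat grids with cell-center
registration and on decadal stacks of monthly fields.  The decade-index
convention is the one used by the downscaled archives: decade 0 spans
1 Jan 1951 - 31 Dec 1960, decade d spans 1951+10d .. 1960+10d, so the
22 ka transient run occupies indices -2200 .. +3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import xarray as xr

__all__ = [
    "Grid",
    "VariableSpec",
    "DecadalSeries",
    "MonthlyClimatology",
    "SeasonalMeans",
    "MONTH_DAYS",
    "SEASON_MONTHS",
    "SEASON_NAMES",
    "make_grid",
    "decade_to_years",
    "decade_age_ka",
    "seasonal_from_monthly",
]

# Day counts for a climatological (non-leap-structured) year.  Decadal mean
# climatologies have no leap-year identity, so February carries the long-run
# average 28.25 days; the year totals 365.25 days.
MONTH_DAYS = np.array(
    [31.0, 28.25, 31.0, 30.0, 31.0, 30.0, 31.0, 31.0, 30.0, 31.0, 30.0, 31.0]
)

# Season membership (0-based month indices).  Winter is {Jan, Feb, Dec} of the
# same climatological cycle: the annual cycle is periodic, so December wraps.
SEASON_MONTHS = ((0, 1, 11), (2, 3, 4), (5, 6, 7), (8, 9, 10))
SEASON_NAMES = ("DJF", "MAM", "JJA", "SON")

VariableKind = Literal["additive", "factor", "gamma"]


@dataclass(frozen=True)
class VariableSpec:
    """Downscaling semantics of one climate variable.

    ``kind`` selects the change-factor flavour: ``additive`` (difference
    anomalies; temperature, net longwave), ``factor`` (ratio anomalies for
    zero-bounded variables; precipitation, vapour pressure, wind speed) or
    ``gamma`` (exponent anomalies of top-of-atmosphere-normalized shortwave).
    """

    name: str
    units: str
    kind: VariableKind
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "factor", "gamma"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "factor" and self.lower_bound not in (None, 0, 0.0):
            raise ValueError("factor variables are bounded below by zero")
        if self.kind == "factor":
            object.__setattr__(self, "lower_bound", 0.0)


#: Default variable registry mirroring the archive's primary variables.
DEFAULT_VARIABLES = {
    "tmax": VariableSpec("tmax", "degC", "additive"),
    "tmin": VariableSpec("tmin", "degC", "additive"),
    "prcp": VariableSpec("prcp", "mm month-1", "factor"),
    "vap": VariableSpec("vap", "hPa", "factor"),
    "wnd": VariableSpec("wnd", "m s-1", "factor"),
    "lwn": VariableSpec("lwn", "W m-2", "additive"),
    "swd": VariableSpec("swd", "W m-2", "gamma"),
    "swu": VariableSpec("swu", "W m-2", "gamma"),
}


@dataclass(frozen=True)
class Grid:
    """Regular lon/lat raster with cell-center registration.

    Cells own the half-open box [edge, edge + resolution) on both axes.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float
    n_lon: int
    n_lat: int
    land_mask: Optional[np.ndarray] = field(default=None, compare=False)

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes, west to east."""
        return self.lon_min + self.resolution * (np.arange(self.n_lon) + 0.5)

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, south to north."""
        return self.lat_min + self.resolution * (np.arange(self.n_lat) + 0.5)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) array shape of fields on this grid."""
        return (self.n_lat, self.n_lon)

    def coords(self) -> dict:
        return {"lat": self.lats, "lon": self.lons}

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(coords=self.coords())
        ds.lat.attrs.update(units="degrees_north", standard_name="latitude")
        ds.lon.attrs.update(units="degrees_east", standard_name="longitude")
        if self.land_mask is not None:
            ds["land_mask"] = (("lat", "lon"), self.land_mask.astype(np.int8))
        ds.attrs["resolution"] = self.resolution
        return ds


def _axis_cells(lo: float, hi: float, res: float, axis: str) -> int:
    n = (hi - lo) / res
    n_int = round(n)
    if abs(n - n_int) > 1e-9 or n_int < 1:
        raise ValueError(
            f"{axis} extent [{lo}, {hi}] is not an integer multiple of "
            f"resolution {res}"
        )
    return int(n_int)


def make_grid(
    lon_min: float,
    lon_max: float,
    lat_min: float,
    lat_max: float,
    resolution: float,
    land_mask: Optional[np.ndarray] = None,
) -> Grid:
    """Build a regular cell-centered grid, rejecting non-divisible bounds.

    The production domain (-173 to -48 E, 10 to 80 N at 0.5 degrees) yields
    250 x 140 cells.
    """
    n_lon = _axis_cells(lon_min, lon_max, resolution, "longitude")
    n_lat = _axis_cells(lat_min, lat_max, resolution, "latitude")
    if land_mask is not None:
        land_mask = np.asarray(land_mask, dtype=bool)
        if land_mask.shape != (n_lat, n_lon):
            raise ValueError(
                f"land_mask shape {land_mask.shape} != grid shape {(n_lat, n_lon)}"
            )
    return Grid(lon_min, lon_max, lat_min, lat_max, resolution, n_lon, n_lat, land_mask)


def decade_to_years(decade_index: int) -> tuple[int, int]:
    """Calendar span of a decade index: decade 0 is 1951-1960."""
    start = 1951 + 10 * int(decade_index)
    return start, start + 9


def decade_age_ka(decade_index: int) -> float:
    """Age of a decade's midpoint in ka BP (present = 1950 AD)."""
    start, end = decade_to_years(decade_index)
    mid = (start + end) / 2.0
    return (1950.0 - mid) / 1000.0


@dataclass
class MonthlyClimatology:
    """12 monthly fields (month, lat, lon) of one variable on a grid."""

    grid: Grid
    variable: VariableSpec
    values: np.ndarray  # (12, n_lat, n_lon)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12, *self.grid.shape):
            raise ValueError(
                f"expected shape {(12, *self.grid.shape)}, got {self.values.shape}"
            )


@dataclass
class SeasonalMeans:
    """4 seasonal fields (DJF, MAM, JJA, SON) of one variable on a grid."""

    grid: Grid
    variable: VariableSpec
    values: np.ndarray  # (4, n_lat, n_lon)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4, *self.grid.shape):
            raise ValueError(
                f"expected shape {(4, *self.grid.shape)}, got {self.values.shape}"
            )


@dataclass
class DecadalSeries:
    """Decade-indexed stack of 12-month fields.

    ``values`` has shape (n_decades, 12, n_lat, n_lon); decade i of the stack
    is decade index ``decades[i]`` in the 1951-base convention.
    """

    grid: Grid
    variable: VariableSpec
    decades: np.ndarray  # integer decade indices
    values: np.ndarray

    def __post_init__(self) -> None:
        self.decades = np.asarray(self.decades, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.decades), 12, *self.grid.shape)
        if self.values.shape != expected:
            raise ValueError(f"expected shape {expected}, got {self.values.shape}")

    def year_spans(self) -> list[tuple[int, int]]:
        return [decade_to_years(d) for d in self.decades]


def seasonal_from_monthly(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Collapse 12 monthly slices to 4 unweighted seasonal means.

    Seasons are the climatological quarters DJF, MAM, JJA, SON with December
    wrapping within the same cycle, so DJF = mean(months 1, 2, 12).  Missing
    (NaN) months propagate into their season.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[axis] != 12:
        raise ValueError("monthly axis must have length 12")
    moved = np.moveaxis(values, axis, 0)
    out = np.empty((4, *moved.shape[1:]), dtype=float)
    for s, members in enumerate(SEASON_MONTHS):
        out[s] = (moved[members[0]] + moved[members[1]] + moved[members[2]]) / 3.0
    return np.moveaxis(out, 0, axis)
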