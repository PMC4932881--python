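"""Packed NetCDF and GeoTIFF serialization plus YAML configuration.

Archives store fields as 16-bit integers with CF-style ``add_offset`` /
``scale_factor`` attributes (unpacked = add_offset + packed * scale_factor)
and missing_value = -32768 outside the downscaling domain.  Summary rasters
go to GeoTIFF-style .tif files, one statistic per file, in the directory
grammar [model]/[time]/[name].tif (paleo) and [scenario]/[model]/[time]/
[name].tif (future).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr
import yaml

from .grids import Grid, make_grid

__all__ = [
    "PackingSpec",
    "FILL_VALUE",
    "choose_packing",
    "pack_field",
    "unpack_field",
    "write_packed_netcdf",
    "read_packed_netcdf",
    "write_geotiff",
    "read_geotiff",
    "summary_path",
    "load_config",
]

FILL_VALUE = np.int16(-32768)
_INT_RANGE = 65000  # usable span, leaving headroom around the sentinel


@dataclass(frozen=True)
class PackingSpec:
    """Affine int16 packing: unpacked = add_offset + packed * scale_factor."""

    add_offset: float
    scale_factor: float

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def choose_packing(values: np.ndarray) -> PackingSpec:
    """Midrange offset and range/65000 scale; deterministic per field."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return PackingSpec(0.0, 1e-6)
    lo, hi = float(finite.min()), float(finite.max())
    scale = max((hi - lo) / _INT_RANGE, 1e-6)
    return PackingSpec((hi + lo) / 2.0, scale)


def pack_field(values: np.ndarray, spec: PackingSpec, name: str = "field") -> np.ndarray:
    """Round to int16; NaN cells become the -32768 sentinel.

    Raises when a finite value would overflow the 16-bit range.
    """
    values = np.asarray(values, dtype=float)
    packed = np.round((values - spec.add_offset) / spec.scale_factor)
    finite = np.isfinite(values)
    if finite.any():
        lo, hi = packed[finite].min(), packed[finite].max()
        if lo < -32767 or hi > 32767:
            raise OverflowError(
                f"variable {name!r}: packed range [{lo}, {hi}] overflows int16"
            )
    out = np.where(finite, packed, float(FILL_VALUE)).astype(np.int16)
    return out


def unpack_field(packed: np.ndarray, spec: PackingSpec) -> np.ndarray:
    """Invert the packing; sentinel cells come back as NaN."""
    packed = np.asarray(packed)
    out = spec.add_offset + packed.astype(float) * spec.scale_factor
    return np.where(packed == FILL_VALUE, np.nan, out)


def write_packed_netcdf(
    path: str | Path,
    fields: dict[str, np.ndarray],
    grid: Grid,
    extra_dims: dict[str, np.ndarray] | None = None,
    attrs: dict | None = None,
) -> None:
    """Write int16-packed fields on a grid to a classic NetCDF file.

    ``fields`` maps names to arrays of shape (*extra_dims, n_lat, n_lon);
    every variable carries self-describing add_offset / scale_factor /
    missing_value attributes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    coords = dict(extra_dims or {})
    coords.update(grid.coords())
    ds = xr.Dataset(coords=coords)
    dim_names = (*tuple(extra_dims or {}), "lat", "lon")
    for name, values in fields.items():
        spec = choose_packing(values)
        packed = pack_field(values, spec, name=name)
        ds[name] = (dim_names[-np.ndim(values):], packed)
        ds[name].attrs.update(
            add_offset=spec.add_offset,
            scale_factor=spec.scale_factor,
            missing_value=FILL_VALUE,
        )
    ds.attrs.update(attrs or {})
    ds.attrs.setdefault("resolution", grid.resolution)
    ds.to_netcdf(path, engine="scipy")


def read_packed_netcdf(path: str | Path) -> tuple[dict[str, np.ndarray], Grid]:
    """Read a packed archive back to float fields and its grid."""
    with xr.open_dataset(path, engine="scipy", mask_and_scale=False) as ds:
        lats = ds["lat"].values
        lons = ds["lon"].values
        res = float(ds.attrs.get("resolution", np.diff(lats).mean()))
        grid = make_grid(
            float(lons[0] - res / 2),
            float(lons[-1] + res / 2),
            float(lats[0] - res / 2),
            float(lats[-1] + res / 2),
            res,
        )
        fields = {}
        for name, var in ds.data_vars.items():
            spec = PackingSpec(
                float(var.attrs["add_offset"]), float(var.attrs["scale_factor"])
            )
            fields[name] = unpack_field(var.values, spec)
    return fields, grid


def write_geotiff(path: str | Path, values: np.ndarray, grid: Grid) -> None:
    """Write a single 2-d float32 raster with GeoTIFF georeferencing tags.

    Rows run north to south per raster convention; ModelPixelScale and
    ModelTiepoint tags anchor the grid in lon/lat degrees.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(values, dtype=np.float32)
    if values.shape != grid.shape:
        raise ValueError("raster shape must match grid")
    data = values[::-1]  # row 0 = northernmost
    res = grid.resolution
    pixel_scale = (res, res, 0.0)
    tiepoint = (0.0, 0.0, 0.0, grid.lon_min, grid.lat_max, 0.0)
    tifffile.imwrite(
        path,
        data,
        extratags=[
            (33550, "d", 3, pixel_scale),  # ModelPixelScaleTag
            (33922, "d", 6, tiepoint),  # ModelTiepointTag
        ],
    )


def read_geotiff(path: str | Path) -> np.ndarray:
    """Read a raster written by write_geotiff, back in south-up orientation."""
    return np.asarray(tifffile.imread(path), dtype=float)[::-1]


def summary_path(
    root: str | Path,
    model: str,
    time_label: str,
    stat_name: str,
    scenario: str | None = None,
) -> Path:
    """Output path per the archive grammar: [scenario/]model/time/name.tif."""
    root = Path(root)
    parts = ([scenario] if scenario else []) + [model, time_label, f"{stat_name}.tif"]
    return root.joinpath(*parts)


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg
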