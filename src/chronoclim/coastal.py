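"""Extrapolation of climate onto formerly exposed (now submerged) coastal cells.

During the deglaciation, sea level rise submerged shelf areas that were land
at the last glacial maximum.  Those cells have no modern observational
climatology, so their downscaled paleoclimate is extrapolated from nearby
cells that are land today.  The search uses an elliptical distance stretched
east-west (climate varies less in longitude than latitude),

    a = sqrt((1 - w) d^2 + w (R |dphi|)^2),    w = 0.75,

with d the great-circle distance.  The search radius a_max starts at 1.5
grid spacings and grows by one spacing until donors are found; donors within
the winning radius are averaged with inverse-distance weights 1/a.
"""

from __future__ import annotations

import numpy as np

from .grids import Grid, decade_age_ka

__all__ = [
    "EARTH_RADIUS_KM",
    "elliptical_distance",
    "fill_submerged",
    "shoreline_for_decade",
]

EARTH_RADIUS_KM = 6371.0
DEFAULT_W = 0.75


def _great_circle_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Haversine great-circle distance on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (lon1, lat1, lon2, lat2))
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def elliptical_distance(
    p1: tuple[float, float] | np.ndarray,
    p2: tuple[float, float] | np.ndarray,
    w: float = DEFAULT_W,
) -> np.ndarray:
    """East-west-stretched distance a = sqrt((1-w) d^2 + w (R |dphi|)^2).

    Points are (lon, lat) in degrees.  Symmetric, zero iff the points
    coincide; reduces to d/2 along a parallel at w = 0.75 and to d along a
    meridian (where d = R |dphi|).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = _great_circle_km(p1[..., 0], p1[..., 1], p2[..., 0], p2[..., 1])
    dphi = np.deg2rad(np.abs(p2[..., 1] - p1[..., 1]))
    return np.sqrt((1.0 - w) * d**2 + w * (EARTH_RADIUS_KM * dphi) ** 2)


def fill_submerged(
    field: np.ndarray,
    grid: Grid,
    present_land_mask: np.ndarray,
    past_land_mask: np.ndarray,
    w: float = DEFAULT_W,
) -> np.ndarray:
    """Fill past-land / present-sea cells from present-land donors.

    ``field`` may carry leading dimensions (months); donor values must be
    valid (finite) on present land.  Each target receives the 1/a-weighted
    mean of donors within the smallest search radius (1.5 eps, then +eps
    steps, with eps the latitude grid spacing expressed as a distance) that
    contains at least one donor.  Present-land cells are never modified, so
    the operation is idempotent.
    """
    field = np.asarray(field, dtype=float)
    present = np.asarray(present_land_mask, dtype=bool)
    past = np.asarray(past_land_mask, dtype=bool)
    if present.shape != grid.shape or past.shape != grid.shape:
        raise ValueError("masks must match the grid shape")
    if not present.any():
        raise ValueError("no present-day land cells to extrapolate from")

    lon2d, lat2d = np.meshgrid(grid.lons, grid.lats)
    # donors: present land with valid values in every slice of the field
    valid = np.isfinite(field).all(axis=tuple(range(field.ndim - 2)))
    donor = present & valid
    if not donor.any():
        raise ValueError("no valid donor cells")
    targets = past & ~present

    eps = EARTH_RADIUS_KM * np.deg2rad(grid.resolution)
    dlon = donor.ravel()
    dpts_lon = lon2d.ravel()[dlon]
    dpts_lat = lat2d.ravel()[dlon]
    dvals = field.reshape(*field.shape[:-2], -1)[..., dlon]

    out = field.copy()
    ti, tj = np.nonzero(targets)
    for i, j in zip(ti, tj):
        a = elliptical_distance(
            np.stack(
                [np.full_like(dpts_lon, lon2d[i, j]), np.full_like(dpts_lat, lat2d[i, j])],
                axis=-1,
            ),
            np.stack([dpts_lon, dpts_lat], axis=-1),
            w=w,
        )
        a_max = 1.5 * eps
        inside = a <= a_max
        while not inside.any():
            a_max += eps
            inside = a <= a_max
        wts = 1.0 / a[inside]
        wts /= wts.sum()
        out[..., i, j] = (dvals[..., inside] * wts).sum(axis=-1)
    return out


def shoreline_for_decade(decade_index: int) -> int:
    """Paleoshoreline epoch (ka BP, integer) assigned to a decade.

    Shorelines exist at 1 ka intervals; each decade takes the epoch nearest
    its mid-decade age, with exact half-interval ages going to the older
    epoch.
    """
    age = decade_age_ka(decade_index)
    return int(np.floor(age + 0.5))
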