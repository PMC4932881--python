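"""Top-of-atmosphere insolation from orbital elements.

Monthly mean downward solar flux above the atmosphere, B(lat, month), as a
function of eccentricity, obliquity and the longitude of perihelion -- the
normalizer used for shortwave downscaling across orbital configurations.

The daily mean flux at true solar longitude lambda is the classical analytic
integral over the day,

    W = S0/pi * rho * (H0 sin(phi) sin(delta) + cos(phi) cos(delta) sin(H0)),

with declination sin(delta) = sin(obliquity) sin(lambda), inverse-square
distance factor rho = ((1 + e cos(nu)) / (1 - e^2))^2, nu = lambda - lambda_p,
and sunrise hour angle H0 = arccos(-tan(phi) tan(delta)) (0 in polar night,
pi in polar day).  Calendar days are mapped to solar longitude through the
mean anomaly and a second-order equation of center, anchored so the March
equinox (lambda = 0) falls at day 79.5 of a 365-day year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OrbitalParams", "PRESENT_ORBIT", "daily_insolation", "toa_insolation",
           "toa_insolation_monthly"]

#: Solar constant, W m-2.
SOLAR_CONSTANT = 1361.0

_MONTH_DAYS_365 = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_EQUINOX_DAY = 79.5  # March equinox, day-of-year in a 365-day calendar


@dataclass(frozen=True)
class OrbitalParams:
    """Orbital elements: eccentricity, obliquity (deg), and the sun's
    ecliptic longitude at perihelion measured from the moving vernal
    equinox (deg)."""

    eccentricity: float = 0.0167
    obliquity_deg: float = 23.44
    lon_perihelion_deg: float = 282.9


PRESENT_ORBIT = OrbitalParams()


def _true_longitude(day: np.ndarray, orbit: OrbitalParams) -> np.ndarray:
    """True solar longitude (rad) for day-of-year (0..365, float)."""
    e = orbit.eccentricity
    lp = np.deg2rad(orbit.lon_perihelion_deg)

    def center(lm: np.ndarray) -> np.ndarray:
        M = lm - lp
        return 2.0 * e * np.sin(M) + 1.25 * e**2 * np.sin(2.0 * M)

    # mean longitude at the equinox anchor: solve lambda(lm_ve) = 0
    lm_ve = 0.0
    for _ in range(4):
        lm_ve = -center(np.asarray(lm_ve))
    lm = lm_ve + 2.0 * np.pi * (np.asarray(day, dtype=float) - _EQUINOX_DAY) / 365.0
    return lm + center(lm)


def daily_insolation(
    lat_deg: np.ndarray, day: np.ndarray, orbit: OrbitalParams = PRESENT_ORBIT
) -> np.ndarray:
    """Daily mean TOA flux (W m-2) at latitude for a day-of-year (broadcast)."""
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    lam = _true_longitude(day, orbit)
    e = orbit.eccentricity
    obl = np.deg2rad(orbit.obliquity_deg)
    lp = np.deg2rad(orbit.lon_perihelion_deg)

    sindec = np.sin(obl) * np.sin(lam)
    dec = np.arcsin(np.clip(sindec, -1.0, 1.0))
    rho = ((1.0 + e * np.cos(lam - lp)) / (1.0 - e**2)) ** 2

    cosH0 = -np.tan(lat) * np.tan(dec)
    H0 = np.arccos(np.clip(cosH0, -1.0, 1.0))
    W = (
        SOLAR_CONSTANT
        / np.pi
        * rho
        * (H0 * np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.sin(H0))
    )
    return np.maximum(W, 0.0)


def toa_insolation(
    lat_deg: float | np.ndarray, month: int, orbit: OrbitalParams = PRESENT_ORBIT
) -> np.ndarray:
    """Monthly mean TOA insolation (W m-2) for one calendar month (1..12)."""
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    start = int(_MONTH_DAYS_365[: month - 1].sum())
    days = start + 0.5 + np.arange(_MONTH_DAYS_365[month - 1])
    lat = np.atleast_1d(np.asarray(lat_deg, dtype=float))
    vals = daily_insolation(lat[:, None], days[None, :], orbit).mean(axis=1)
    return vals if np.ndim(lat_deg) else float(vals[0])


def toa_insolation_monthly(
    lats_deg: np.ndarray, orbit: OrbitalParams = PRESENT_ORBIT
) -> np.ndarray:
    """All 12 monthly means: shape (12, n_lat)."""
    lats_deg = np.asarray(lats_deg, dtype=float)
    return np.stack([toa_insolation(lats_deg, m, orbit) for m in range(1, 13)])
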