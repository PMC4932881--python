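"""Potential and actual evapotranspiration.

PET follows the FAO-56 Penman-Monteith reference-surface formulation, with
net radiation taken from the downscaled surface radiation balance: albedo is
the downscaled upward/downward shortwave ratio rather than a prescribed
constant, so snow-covered and bare months are handled by the radiation fields
themselves.  AET uses a single-bucket soil water balance (150 mm capacity)
with a degree-day snow model: precipitation falls as snow below 0 degC
(linearly mixed up to +3 degC), melt is proportional to positive monthly
temperature, evaporative demand is met first from rain + melt and then from
an exponentially limited soil store.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BucketState",
    "surface_pressure",
    "saturation_vapour_pressure",
    "pet_penman_monteith",
    "snow_fraction",
    "aet_bucket",
    "run_bucket",
]

#: Soil water holding capacity, mm (constant through time).
BUCKET_CAPACITY = 150.0
#: Degree-day melt coefficient, mm water per degC per day.
MELT_COEFF = 2.0
#: Snow/rain transition: all snow at or below SNOW_T_ALL, all rain at or above SNOW_T_NONE (degC).
SNOW_T_ALL = 0.0
SNOW_T_NONE = 3.0

# W m-2 -> MJ m-2 day-1
_WM2_TO_MJ = 0.0864


def surface_pressure(elevation: np.ndarray) -> np.ndarray:
    """Standard-atmosphere surface pressure (kPa) from elevation (m).

    P = 101.3 ((293 - 0.0065 z) / 293)^5.26; monotone decreasing in z.
    """
    z = np.asarray(elevation, dtype=float)
    if (z < -500).any():
        raise ValueError("elevation below -500 m is outside the formula's range")
    return 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26


def saturation_vapour_pressure(T: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure (kPa) at temperature T (degC), Magnus form."""
    T = np.asarray(T, dtype=float)
    return 0.6108 * np.exp(17.27 * T / (T + 237.3))


def pet_penman_monteith(
    Tmax: np.ndarray,
    Tmin: np.ndarray,
    vap_hPa: np.ndarray,
    wind: np.ndarray,
    sw_down: np.ndarray,
    sw_up: np.ndarray,
    lw_net: np.ndarray,
    pressure_kPa: np.ndarray,
    n_days: float,
) -> np.ndarray:
    """Reference-surface Penman-Monteith PET, mm per month.

    Radiative input is the shortwave balance sw_down (1 - albedo) plus the
    net downward longwave; albedo = sw_up / sw_down is clipped into
    [0.05, 0.95] (a physically impossible sw_up > sw_down is thereby
    neutralized).  Negative computed PET is clipped to zero.
    """
    Tmax = np.asarray(Tmax, dtype=float)
    Tmin = np.asarray(Tmin, dtype=float)
    T = 0.5 * (Tmax + Tmin)

    with np.errstate(divide="ignore", invalid="ignore"):
        albedo = np.asarray(sw_up, dtype=float) / np.asarray(sw_down, dtype=float)
    albedo = np.clip(np.where(np.isfinite(albedo), albedo, 0.95), 0.05, 0.95)
    rn = (np.asarray(sw_down, dtype=float) * (1.0 - albedo) + np.asarray(lw_net, dtype=float)) * _WM2_TO_MJ

    es = 0.5 * (saturation_vapour_pressure(Tmax) + saturation_vapour_pressure(Tmin))
    ea = np.asarray(vap_hPa, dtype=float) / 10.0  # hPa -> kPa
    deficit = np.maximum(es - ea, 0.0)

    delta = 4098.0 * saturation_vapour_pressure(T) / (T + 237.3) ** 2
    gamma_ps = 0.000665 * np.asarray(pressure_kPa, dtype=float)
    u2 = np.asarray(wind, dtype=float)

    num = 0.408 * delta * rn + gamma_ps * (900.0 / (T + 273.0)) * u2 * deficit
    den = delta + gamma_ps * (1.0 + 0.34 * u2)
    et0_daily = num / den
    return np.maximum(et0_daily, 0.0) * n_days


@dataclass(frozen=True)
class BucketState:
    """Soil water and snowpack state of the single-bucket model (mm)."""

    soil: float | np.ndarray = BUCKET_CAPACITY / 2.0
    snow: float | np.ndarray = 0.0
    capacity: float = BUCKET_CAPACITY


def snow_fraction(T: np.ndarray) -> np.ndarray:
    """Fraction of monthly precipitation falling as snow (1 below 0 degC,
    0 above +3 degC, linear between)."""
    T = np.asarray(T, dtype=float)
    return np.clip((SNOW_T_NONE - T) / (SNOW_T_NONE - SNOW_T_ALL), 0.0, 1.0)


def aet_bucket(
    precip: np.ndarray,
    pet: np.ndarray,
    T: np.ndarray,
    state: BucketState,
    n_days: float = 30.4375,
    melt_coeff: float = MELT_COEFF,
) -> tuple[np.ndarray, BucketState, np.ndarray]:
    """One monthly step of the single-bucket water balance.

    Returns (aet, new_state, runoff).  Demand (PET) is met first from liquid
    supply (rain + snowmelt); any shortfall draws on the soil store with the
    exponential extraction soil (1 - exp(-shortfall / capacity)), which never
    exceeds either the store or the shortfall.  Liquid surplus refills the
    soil to capacity and the rest runs off.  The monthly balance
    precip = AET + runoff + d(soil) + d(snow) closes exactly; with no liquid
    water (frozen months, ice) AET is zero.
    """
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    T = np.asarray(T, dtype=float)
    if (precip < 0).any() or (pet < 0).any():
        raise ValueError("precip and pet must be non-negative")

    fsnow = snow_fraction(T)
    snowfall = precip * fsnow
    rain = precip - snowfall

    snow0 = np.asarray(state.snow, dtype=float)
    melt = np.minimum(snow0 + snowfall, melt_coeff * np.maximum(T, 0.0) * n_days)
    snow1 = snow0 + snowfall - melt

    supply = rain + melt
    soil0 = np.asarray(state.soil, dtype=float)

    shortfall = np.maximum(pet - supply, 0.0)
    extraction = soil0 * -np.expm1(-shortfall / state.capacity)
    aet = np.minimum(supply, pet) + extraction

    surplus = np.maximum(supply - pet, 0.0)
    soil1 = soil0 - extraction + surplus
    runoff = np.maximum(soil1 - state.capacity, 0.0)
    soil1 = np.minimum(soil1, state.capacity)

    return aet, replace(state, soil=soil1, snow=snow1), runoff


def run_bucket(
    precip: np.ndarray,
    pet: np.ndarray,
    T: np.ndarray,
    state: BucketState | None = None,
    n_days: np.ndarray | None = None,
    spinup_months: int = 24,
    melt_coeff: float = MELT_COEFF,
) -> tuple[np.ndarray, np.ndarray, BucketState]:
    """Run the bucket over a (time, ...) monthly forcing stack.

    The first ``spinup_months`` are run twice and the first pass discarded, so
    results do not depend on the arbitrary initial store (soil starts at half
    capacity).  Returns (aet, runoff, final_state) for the full stack.
    """
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    T = np.asarray(T, dtype=float)
    nt = precip.shape[0]
    if n_days is None:
        n_days = np.full(nt, 30.4375)
    state = state or BucketState()

    spin = min(spinup_months, nt)
    for t in range(spin):
        _, state, _ = aet_bucket(
            precip[t], pet[t], T[t], state, n_days[t], melt_coeff
        )

    aet = np.empty_like(precip)
    runoff = np.empty_like(precip)
    for t in range(nt):
        aet[t], state, runoff[t] = aet_bucket(
            precip[t], pet[t], T[t], state, n_days[t], melt_coeff
        )
    return aet, runoff, state
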