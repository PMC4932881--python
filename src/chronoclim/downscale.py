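"""Change-factor debiasing and bilinear downscaling.

The change-factor (delta) method cancels time-constant model bias: the model
supplies only its simulated *change* relative to its own reference state, and
that anomaly is interpolated onto the fine observational grid and combined
with the observed climatology.  Three flavours exist:

* additive -- obs + (model_t - model_ref), for unbounded variables;
* factor   -- obs * (model_t / model_ref), for zero-bounded variables;
* gamma    -- obs_normalized ** gamma, for shortwave radiation expressed as a
  fraction of top-of-atmosphere insolation so values stay in [0, 1] under any
  orbital configuration.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grids import Grid

__all__ = [
    "bilinear_regrid",
    "downscale_additive",
    "downscale_factor",
    "normalize_shortwave",
    "shortwave_gamma",
    "apply_gamma",
]

#: Below this top-of-atmosphere flux (W m-2) a cell-month is polar night.
POLAR_NIGHT_B = 1.0
#: Normalized shortwave is clamped into [SHAT_EPS, 1 - SHAT_EPS] before logs.
SHAT_EPS = 1e-6


def bilinear_regrid(
    coarse_field: np.ndarray,
    coarse_grid: Grid,
    fine_grid: Grid,
    extend: bool = True,
) -> np.ndarray:
    """Bilinear interpolation from coarse cell centers to fine cell centers.

    Fine centers outside the coarse center hull are clamped to the hull edge
    (nearest-inside extension) when ``extend`` is true, else set to NaN.
    Leading dimensions (months, decades) are broadcast.
    """
    coarse_field = np.asarray(coarse_field, dtype=float)
    if coarse_field.shape[-2:] != coarse_grid.shape:
        raise ValueError("coarse field shape does not match coarse grid")
    lats, lons = coarse_grid.lats, coarse_grid.lons
    flat = coarse_field.reshape(-1, *coarse_grid.shape)

    fy, fx = np.meshgrid(fine_grid.lats, fine_grid.lons, indexing="ij")
    pts = np.column_stack([fy.ravel(), fx.ravel()])
    if extend:
        pts[:, 0] = np.clip(pts[:, 0], lats[0], lats[-1])
        pts[:, 1] = np.clip(pts[:, 1], lons[0], lons[-1])

    out = np.empty((flat.shape[0], *fine_grid.shape), dtype=float)
    for k in range(flat.shape[0]):
        interp = RegularGridInterpolator(
            (lats, lons), flat[k], method="linear", bounds_error=False, fill_value=np.nan
        )
        out[k] = interp(pts).reshape(fine_grid.shape)
    return out.reshape(*coarse_field.shape[:-2], *fine_grid.shape)


def _check_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(
            f"model fields must share a grid: shapes {np.shape(a)} vs {np.shape(b)}"
        )


def downscale_additive(
    model_t: np.ndarray,
    model_ref: np.ndarray,
    obs_climatology: np.ndarray,
    coarse_grid: Grid,
    fine_grid: Grid,
) -> np.ndarray:
    """obs + bilinear(model_t - model_ref); exactly obs when no change."""
    _check_same_grid(model_t, model_ref)
    anomaly = np.asarray(model_t, float) - np.asarray(model_ref, float)
    return np.asarray(obs_climatology, float) + bilinear_regrid(
        anomaly, coarse_grid, fine_grid
    )


def downscale_factor(
    model_t: np.ndarray,
    model_ref: np.ndarray,
    obs_climatology: np.ndarray,
    coarse_grid: Grid,
    fine_grid: Grid,
    max_factor: float = 10.0,
) -> np.ndarray:
    """obs * bilinear(model_t / model_ref) for zero-bounded variables.

    Reference zeros: if the period value is also zero the ratio is 1 (no
    change); otherwise the ratio is capped at ``max_factor``.  The cap only
    protects vapour/wind edge cases -- precipitation goes through quantile
    mapping instead.
    """
    model_t = np.asarray(model_t, float)
    model_ref = np.asarray(model_ref, float)
    _check_same_grid(model_t, model_ref)
    if (model_t < 0).any() or (model_ref < 0).any():
        raise ValueError("factor-kind variables must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = model_t / model_ref
    ratio = np.where(model_ref == 0, np.where(model_t == 0, 1.0, max_factor), ratio)
    ratio = np.minimum(ratio, max_factor)
    out = np.asarray(obs_climatology, float) * bilinear_regrid(
        ratio, coarse_grid, fine_grid
    )
    return np.maximum(out, 0.0)


def normalize_shortwave(S: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Shat = S / B, clamped into (0, 1); NaN where B is polar night."""
    S = np.asarray(S, float)
    B = np.asarray(B, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        shat = S / B
    shat = np.where(B < POLAR_NIGHT_B, np.nan, shat)
    return np.clip(shat, SHAT_EPS, 1.0 - SHAT_EPS)


def shortwave_gamma(
    model_S_alt: np.ndarray,
    model_S0: np.ndarray,
    B_alt: np.ndarray,
    B0: np.ndarray,
) -> np.ndarray:
    """Exponent anomaly gamma = log(Shat_alt) / log(Shat_0).

    gamma = 1 means no change; gamma is NaN (flagged) in polar night where
    the normalization is undefined.
    """
    shat_alt = normalize_shortwave(model_S_alt, B_alt)
    shat_0 = normalize_shortwave(model_S0, B0)
    with np.errstate(invalid="ignore"):
        gamma = np.log(shat_alt) / np.log(shat_0)
    return gamma


def apply_gamma(
    obs_Shat0: np.ndarray, gamma_fine: np.ndarray, B_alt: np.ndarray
) -> np.ndarray:
    """S_alt = B_alt * Shat_0 ** gamma; zero in polar night.

    The power transform keeps the normalized value inside [0, 1], so the
    output never exceeds the top-of-atmosphere flux.
    """
    shat0 = np.clip(np.asarray(obs_Shat0, float), SHAT_EPS, 1.0 - SHAT_EPS)
    gamma = np.asarray(gamma_fine, float)
    if np.nanmin(gamma) <= 0:
        raise ValueError("gamma must be positive")
    B_alt = np.asarray(B_alt, float)
    out = B_alt * shat0**gamma
    return np.where(B_alt < POLAR_NIGHT_B, 0.0, out)
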