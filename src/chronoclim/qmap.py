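"""Quantile-mapping bias correction for precipitation.

Plain ratio (factor) debiasing fails for precipitation: very dry model cells
produce huge fractional changes which are unphysical when the observed cell is
wet.  Quantile mapping instead uses the historical relationship between model
and observed variability: both baseline series are sorted independently and
the monotone pairing p_j = f(q_j) maps the model distribution onto the
observed one.

Two variants are provided:

* empirical -- piecewise-linear map through the sorted pairs, with linear
  extension of the end segments beyond the observed model range (the standard
  monthly-data approach, used in future mode);
* linear    -- with only 11 decadal baseline values (1901-2011) the empirical
  map is noisy, so a least-squares line p = a q + b is used instead.  For
  b < 0 and q_alt < q_1 the line is replaced by the origin-passing chord
  p = q (a q_1 + b) / q_1, continuous at q_1 and positive for q > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .downscale import bilinear_regrid
from .grids import Grid

__all__ = [
    "QuantileMap",
    "fit_empirical_qmap",
    "apply_empirical_qmap",
    "fit_paleo_linear_qmap",
    "apply_paleo_linear_qmap",
    "qmap_to_fine",
]


@dataclass(frozen=True)
class QuantileMap:
    """Fitted monotone map from model precipitation to observed."""

    mode: Literal["empirical", "linear"]
    p: np.ndarray  # sorted observed values
    q: np.ndarray  # sorted model values
    a: Optional[float] = None  # linear-mode slope
    b: Optional[float] = None  # linear-mode intercept

    def __call__(self, q_alt: np.ndarray) -> np.ndarray:
        if self.mode == "empirical":
            return apply_empirical_qmap(self, q_alt)
        return apply_paleo_linear_qmap(self, q_alt)


def _sorted_pair(obs: np.ndarray, model: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    model = np.asarray(model, dtype=float)
    if obs.shape != model.shape or obs.ndim != 1:
        raise ValueError("obs and model series must be 1-d and equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 baseline values to fit a quantile map")
    if (obs < 0).any() or (model < 0).any():
        raise ValueError("precipitation series must be non-negative")
    # stable sort: ties keep input order, so the fit is deterministic
    return np.sort(obs, kind="stable"), np.sort(model, kind="stable")


def fit_empirical_qmap(obs_series: np.ndarray, model_series: np.ndarray) -> QuantileMap:
    """Sort both series and pair them rank-by-rank."""
    p, q = _sorted_pair(obs_series, model_series)
    return QuantileMap("empirical", p=p, q=q)


def apply_empirical_qmap(qmap: QuantileMap, q_alt: np.ndarray) -> np.ndarray:
    """Piecewise-linear evaluation with end-segment linear extension.

    Exactly p_j at q_j; beyond [q_1, q_n] the first/last segment's slope is
    continued.  Output is clipped at zero (precipitation bound).
    """
    q_alt = np.asarray(q_alt, dtype=float)
    p, q = qmap.p, qmap.q
    out = np.interp(q_alt, q, p)

    # linear extension using the end segments (fall back to slope 1 if the
    # end segment is degenerate, i.e. repeated q values)
    def _slope(i0: int, i1: int) -> float:
        dq = q[i1] - q[i0]
        return (p[i1] - p[i0]) / dq if dq > 0 else 1.0

    lo = q_alt < q[0]
    hi = q_alt > q[-1]
    if lo.any():
        out = np.where(lo, p[0] + _slope(0, 1) * (q_alt - q[0]), out)
    if hi.any():
        out = np.where(hi, p[-1] + _slope(-2, -1) * (q_alt - q[-1]), out)
    return np.maximum(out, 0.0)


def fit_paleo_linear_qmap(p_decades: np.ndarray, q_decades: np.ndarray) -> QuantileMap:
    """Least-squares line p = a q + b through the sorted decadal pairs."""
    p, q = _sorted_pair(p_decades, q_decades)
    if np.ptp(q) == 0:
        raise ValueError("degenerate fit: all model baseline values identical")
    a, b = np.polyfit(q, p, 1)
    return QuantileMap("linear", p=p, q=q, a=float(a), b=float(b))


def apply_paleo_linear_qmap(qmap: QuantileMap, q_alt: np.ndarray) -> np.ndarray:
    """Evaluate the linear map with the below-range positivity rule.

    p = a q + b when b >= 0 or q_alt >= q_1; otherwise the origin-passing
    chord p = q (a q_1 + b) / q_1.  The branches agree at q_1 and the chord
    guarantees p > 0 whenever q > 0 (given a q_1 + b > 0).
    """
    q_alt = np.asarray(q_alt, dtype=float)
    a, b, q1 = qmap.a, qmap.b, qmap.q[0]
    line = a * q_alt + b
    if b >= 0 or q1 <= 0:
        return line
    chord = q_alt * (a * q1 + b) / q1
    return np.where(q_alt < q1, chord, line)


def qmap_to_fine(
    p_alt_coarse: np.ndarray,
    coarse_climatology: np.ndarray,
    obs_fine_climatology: np.ndarray,
    coarse_grid: Grid,
    fine_grid: Grid,
) -> np.ndarray:
    """Turn mapped coarse precipitation into fine fields via change factors.

    The mapped value is normalized by the coarse climatology; the resulting
    factor field is bilinearly interpolated and multiplied onto the fine
    observed climatology.  Zero-climatology cells get factor 1 (no change).
    """
    p_alt = np.asarray(p_alt_coarse, dtype=float)
    clim = np.asarray(coarse_climatology, dtype=float)
    if p_alt.shape != clim.shape:
        raise ValueError("mapped field and coarse climatology shapes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = p_alt / clim
    factor = np.where(clim == 0, 1.0, factor)
    factor = np.maximum(factor, 0.0)
    fine = np.asarray(obs_fine_climatology, dtype=float) * bilinear_regrid(
        factor, coarse_grid, fine_grid
    )
    return np.maximum(fine, 0.0)
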