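# chronoclim

Debiased, downscaled, *seamless* climate layers for ecological modelling —
the methodology used to build continuous climate series from the last glacial
maximum (21 ka BP) through 2100 AD, packaged as a tested Python library and
exercised on synthetic archives with planted, recoverable signals.

## The problem

Species-distribution and biodiversity models need climate inputs that span
the paleo record and 21st-century projections without seams. Raw earth-system
model output cannot be used directly: simulations carry systematic biases
against observations, are archived on coarse grids (often as seasonal rather
than monthly means, and decadal rather than yearly values), and omit cells
that were land under lower glacial sea levels. Stitching heterogeneous
downscaling treatments together confounds any ecological inference.

`chronoclim` implements one consistent treatment:

* **Change-factor (delta) debiasing + bilinear downscaling.** The model
  contributes only its simulated *change* from its own reference state
  (the last 110 years of a paleo run, 1950–2005 for future runs). Additive
  anomalies for temperature and net longwave, `out = obs + Δ`; ratio factors
  for zero-bounded variables (vapour pressure, wind), `out = obs · (m_t/m_ref)`;
  and for shortwave radiation normalized by top-of-atmosphere insolation
  `Ŝ = S/B`, an exponent transform `Ŝ_alt = Ŝ_0^γ` with
  `γ = log Ŝ_alt / log Ŝ_0`, which keeps `Ŝ ∈ [0, 1]` under any orbital
  configuration. Time-constant model bias cancels identically.
* **Quantile mapping for precipitation.** Sorted baseline series give the
  monotone map `p_j = f(q_j)` from model to observed quantiles; with only 11
  decadal baseline values (1901–2011) a least-squares line `p = aq + b` is
  used, with the origin-passing chord `p = q(aq₁+b)/q₁` below the baseline
  range when `b < 0`, so mapped precipitation stays positive.
* **Seasonal→monthly harmonization.** Among all 12-month vectors reproducing
  the four seasonal means exactly (`T₁+T₂+T₁₂ = 3S₁`, …), pick the smoothest:
  minimize the cyclic second-difference energy `Σ (T_{j−1} − 2T_j + T_{j+1})²`
  via a 16×16 Lagrange system (additive), or its log/weighted analogue solved
  with a Powell-hybrid root finder (positive factor variables).
* **Bioclimatic variables.** Growing degree days from monthly statistics via
  the truncated-normal expectation
  `GDD = σ/√(2π) e^{−z²/2} + (T̄−T₀)/2 · erfc(−z/√2)` with daily variance
  `σ²_daily = a·n·σ²_monthly + σ²_annual` (`a = 0.178`); Penman–Monteith
  reference PET with downscaled albedo; single-bucket AET (150 mm capacity)
  with a degree-day snow model; ETR = AET/PET and WDI = PET − P.
* **Coastal extrapolation.** Cells that were land in the past but are sea
  today take inverse-distance means of modern-land donors found by an
  incrementally growing elliptical search,
  `a = √((1−w)d² + w(R|Δφ|)²)`, `w = 0.75`.
* **Summaries and formats.** Centennial (200-yr windows every 500 yr, 20
  decadal members) and 20-yr/10-yr future summaries, statistic-per-raster
  naming (`an-sum-PRCP`, `mo-lwr-TMIN`, …), int16-packed NetCDF
  (`add_offset`/`scale_factor`, missing = −32768) and georeferenced TIFF
  output.

A synthetic-archive generator (`chronoclim.fixtures`) emulates the real data
geometry — a coarse model grid nested in a fine 0.5° observational grid,
decadal (optionally seasonal-only) stacks, 11-decade baselines, paleo land
masks, daily stations — with every planted signal stored for verification.

## Worked example

Degree days from monthly statistics (`python examples/growing_degree_days.py`):

```
month   actual    naive   normal-model
    1      0.0      0.0        0.1
    2      0.6      0.0        0.6
    3     10.0      0.0        8.9
    4     90.2     63.2       90.1
   ...
   11     14.6      0.0       14.6
   12      0.6      0.0        0.9
year    2246.0   2178.1     2245.4   (degC day)
```

`actual` is the truth from synthetic daily data, `naive` applies
`max(T̄ − 5, 0)` to the monthly mean, and `normal-model` is the
truncated-normal estimator: in shoulder seasons the naive estimate collapses
to zero while warm days still accumulate degree days; the estimator recovers
the annual total within 0.03 %.

End-to-end (`python examples/end_to_end_pipeline.py`) downscales a 20-decade
synthetic archive, derives the bioclimatic variables, fills the exposed-shelf
cells, and writes 44 summary rasters for the 0.5 ka window plus packed
NetCDF — a planted +3 °C change is recovered to machine precision
(`examples/downscale_paleo_decade.py`). The other scripts in `examples/`
demonstrate the quantile map, the seasonal→monthly solver, the water bucket,
and the coastal fill, each printing the quantities it computes.

There is also a thin CLI: `chronoclim run --seed 1 --out artifact/`,
`chronoclim windows --mode paleo`, `chronoclim decade 3`,
`chronoclim make-fixtures --out fx/`.

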