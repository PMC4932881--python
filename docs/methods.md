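# Methods

This note documents the models and numerical choices behind `chronoclim`, the
defaults and their units, what the synthetic archive does and does not
emulate, and the known limitations.

## Grids, calendars, and time conventions

Fields live on regular lon/lat grids with cell-center registration and
half-open cell ownership `[edge, edge + res)`, matching 0.5° observational
climatology grids. Longitudes are signed degrees east; the production domain
(−173 to −48 °E, 10–80 °N at 0.5°) is 250×140 cells. Cell counts must divide
exactly; non-divisible bounds are rejected naming the offending axis.

Decadal stacks use the convention decade 0 = 1 Jan 1951 – 31 Dec 1960, decade
*d* = 1951+10*d* … 1960+10*d*; a 22 ka transient run occupies indices −2200 …
+3 (ending 31 Dec 1990) and a 21 ka run −2100 … −1 (ending 31 Dec 1950).
Ages in ka BP are relative to 1950 AD.

Because decadal climatologies carry no leap-year identity, months use their
climatological day counts with February fixed at 28.25 days (365.25-day
year). Seasons are the cyclic quarters DJF/MAM/JJA/SON of a single
climatological cycle — December wraps to the same year's January — and
seasonal means are unweighted three-month means, consistent with the factor
3 in the seasonal constraints (the source archives' weighting is unknowable
from the data; equal weighting is the only choice that round-trips).

## Change-factor debiasing and downscaling

The delta method guarantees that a model with no simulated change returns
the observed climatology unchanged; any time-constant model bias cancels.
Anomalies are computed on the coarse model grid, bilinearly interpolated to
the fine grid (nearest-inside extension for fine cells outside the coarse
center hull, which keeps interpolation monotone: output within the min/max of
the four neighbours), and combined with the observed climatology.

Reference states default to the last 110 years (11 decades) of a paleo run
and 1950–2005 in future mode; both are configurable.

Ratio (factor) variables are bounded below by zero. Where the reference is
zero: ratio 1 if the numerator is also zero, otherwise capped (default 10).
The cap exists only for vapour/wind edge cases — precipitation never takes
this path (it is quantile-mapped) — and dry-cell pathology is exactly why.

Shortwave is expressed as the top-of-atmosphere fraction `Ŝ = S/B` (clamped
to [10⁻⁶, 1−10⁻⁶] before logs) so that the exponent transform `Ŝ_alt = Ŝ_0^γ`
can never leave the physical range, whatever the orbital configuration.
Cells with `B < 1 W m⁻²` are treated as polar night: output 0, γ undefined
there. Upward shortwave is normalized by the same downward `B`, so the
implied albedo (up/down) is not separately constrained. Top-of-atmosphere
insolation is computed from orbital elements (eccentricity, obliquity,
longitude of perihelion; present-day defaults e = 0.0167, ε = 23.44°,
ϖ = 282.9°, solar constant 1361 W m⁻²) via the analytic daily integral of
the zenith geometry, with calendar days mapped to solar longitude through a
second-order equation of center anchored at the 79.5-day March equinox of a
365-day year. The geometry is verified against hour-angle quadrature to
better than 0.5 %.

## Precipitation quantile mapping

Per coarse cell and calendar month (removing seasonal non-stationarity), the
observed and model baseline series are sorted independently (stable sort, so
ties are deterministic) and paired by rank. Future mode uses the empirical
piecewise-linear map with linear extension of the end segments beyond the
baseline range. Paleo mode has only 11 decadal values (1901–2011), so a
least-squares line `p = aq + b` replaces the noisy empirical map; for
`b < 0` and `q < q₁` the origin-passing chord `p = q(aq₁ + b)/q₁` is used —
continuous at `q₁` and positive for positive input. Mapped values are
normalized by the coarse *observed* climatology to change factors, which are
interpolated and multiplied onto the fine observed climatology. Cells with
zero climatology get factor 1 (nothing to rescale). The maps are fitted
per cell rather than pooled; the fit is cheap and local non-stationarity in
the model–observation variance relationship is the entire point of the
method.

## Seasonal→monthly harmonization

Naive interpolation of seasonal means damps the annual cycle and breaks
consistency (the re-aggregated summer no longer equals the archived summer).
The solvers instead minimize the cyclic second-difference energy subject to
exact seasonal-mean constraints.

* Additive: an equality-constrained quadratic program whose KKT conditions
  form a single constant 16×16 linear system (12 months + 4 multipliers).
  The Hessian is singular (constants are costless) but the constraints pin
  the level, so the KKT matrix is invertible; it is factored once and applied
  in batch. Constraint residuals are at machine precision.
* Factor variables (precipitation fractions, vapour, wind): smoothness is
  measured on log f (positivity by construction) and constraints are
  weighted by the monthly climatology,
  `Σ_{j∈s} P_j f_j = F_s Σ_{j∈s} P_j`. The 16-equation stationarity system
  is partly nonlinear and is solved with a Powell-hybrid (MINPACK-style)
  root finder, initialized from the flat per-season assignment
  `f_j = F_{season(j)}` with up to 3 deterministic jittered restarts.
  Acceptance is judged on residuals (constraints ≤ 10⁻⁸ relative,
  stationarity ≤ 10⁻⁶), not the solver's status flag, which reports failure
  when started at an exact root. Months with zero climatology weight are
  unconstrained and take whatever value makes the log-cycle smoothest; each
  season must carry positive total weight.
* Shortwave exponents: the additive solver applied to log γ, then
  exponentiated, preserving positivity and the seasonal means of log γ.

## Secondary variables

**Growing degree days.** Daily mean temperature is (Tmax + Tmin)/2. With a
normal daily PDF, the expected daily exceedance over base T₀ has the closed
form `σ/√(2π)·e^{−z²/2} + (T̄−T₀)/2·erfc(−z/√2)`, `z = (T̄−T₀)/σ`, which
reduces to the hinge as σ→0 and always dominates it (Jensen). Monthly GDD is
n times the daily expectation. Daily variance splits into weather memory and
annual-cycle parts, `σ²_daily = a·n·σ²_monthly + σ²_annual` with the
empirical constant a = 0.178 (configurable, not re-estimated here). The
annual-cycle term assumes a piecewise-linear daily cycle through the monthly
means at month centers; its within-month SD has the closed form
`n·√((5a₊² + 6a₊a₋ + 5a₋²)/192)`, `a₊ = 2(T_{j+1}−T_j)/(n_{j+1}+n_j)`,
`a₋ = 2(T_j−T_{j−1})/(n_j+n_{j−1})`, verified against brute-force daily
construction (the printed form of this radical in the literature is garbled;
the construction is authoritative). The modern daily SD field is applied
unchanged to paleo temperatures — decadal archives carry no daily variance
information, so constancy across time is an explicit assumption. Annual GDD
totals are sums of monthly totals, i.e. inherently day-weighted.

**PET.** FAO-56 Penman–Monteith reference-surface formulation:
`ET₀ = [0.408 Δ Rn + γ_ps·(900/(T+273))·u₂·(e_s − e_a)] / [Δ + γ_ps(1 + 0.34 u₂)]`
mm day⁻¹, scaled by month length. Net radiation comes from the downscaled
radiation balance: albedo = sw_up/sw_down clipped to [0.05, 0.95] (clipping
neutralizes physically impossible up > down), `Rn = sw_down(1−α) + lw_net`
converted at 0.0864 MJ m⁻² day⁻¹ per W m⁻². Using the downscaled albedo
rather than prescribed snow/bare values is deliberate: the radiation fields
already carry the surface state. Soil heat flux is taken as zero at monthly
scale. Negative computed PET is clipped to zero (reference ET is
non-negative by definition). Cold/snow behaviour is handled through the
radiation inputs and the snow bucket rather than by modifying the PM
equation itself; the snow-model constants here are this package's own
documented defaults. Surface pressure comes from the standard-atmosphere
formula `P = 101.3((293 − 0.0065z)/293)^5.26` kPa.

**AET.** Single bucket, capacity 150 mm (constant through time — soil
properties are unknowable over millennia, and sensitivity to realistic
alternatives is small). Monthly precipitation splits into snow/rain linearly
between 0 °C (all snow) and +3 °C (all rain); melt is degree-day,
2.0 mm °C⁻¹ day⁻¹ (configurable). Demand is met first from rain + melt, then
from the soil store via the exponential extraction
`soil·(1 − e^{−shortfall/capacity})`, which never exceeds the store or the
shortfall; liquid surplus refills the soil and the excess runs off. The
monthly balance `P = AET + runoff + Δsoil + Δsnow` closes exactly, and AET
is zero without liquid water (hence ≈0 on ice). Buckets start at half
capacity and a 24-month spin-up is discarded, removing initial-condition
sensitivity.

## Coastal extrapolation

Targets are cells land at the decade's assigned shoreline epoch but sea
today. Shoreline epochs exist every 1 ka; a decade takes the epoch nearest
its mid-decade age, with exact half-interval ages assigned to the older
epoch (a fixed rule is needed; decade midpoints never land exactly on one).
Donors are modern-land cells with valid values — never previously filled
cells, so filling is idempotent and order-independent. The elliptical
distance `a = √((1−w)d² + w(R|Δφ|)²)` (great-circle d on a 6371 km sphere,
w = 0.75) down-weights longitude because climate varies less east–west; the
search radius starts at 1.5 grid spacings and grows by one spacing until
donors exist, and donors are averaged with weights 1/a (a convex
combination, so filled values stay within the donor range). Extrapolated
shelf climates are inherently more uncertain than interpolated ones.

## Summaries

Statistics are computed **per member first** (each decade or year from its
12 monthly values), then averaged across window members — this order is part
of the product definition. Annual level: mean for TMIN/TMAX/ETR, sum for
PRCP/GDD/AET/PET/WDI. Variability: SD for interval-scale variables
(TMIN/TMAX/GDD), CV for ratio-scale ones (CV is undefined at zero mean →
missing). Extremes: lowest/highest monthly value and lowest/highest
quarterly aggregate, where quarters are the fixed calendar seasons
(DJF/MAM/JJA/SON; a running 3-month window would be the alternative — fixed
quarters are used and documented) and the quarterly aggregate is the mean
for mean-type variables and the sum for sum-type ones. Only the populated
cells of the naming grammar are emitted (e.g. `qt-lwr-TMIN` exists,
`qt-hgr-TMIN` does not).

Paleo windows: 200 years centered every 500 years, 20 decadal members,
except the 0 ka window, truncated at the run end (1850–1990 for a run ending
at decade +3; 1850–1950 for one ending at −1). Future windows: 1950–2005
plus 20-year spans every 10 years, 2011–2030 … 2081–2100 (overlapping by
construction; users wanting independence should take every other window).

The cross-correlation utility computes per-cell Pearson correlation of
anomalies from each series' own mean annual cycle — the validation check
that downscaling preserves inter-variable correlation structure.

## Storage

NetCDF variables are packed to int16 with per-field affine coefficients
(offset = midrange, scale = range/65000, floored at 10⁻⁶), CF attribute
names `add_offset`/`scale_factor`/`missing_value`, sentinel −32768 only
outside the downscaling domain; round-trip error is bounded by half the
scale factor. Files are written in NetCDF classic format. Summary rasters
are float32 TIFFs with GeoTIFF ModelPixelScale/ModelTiepoint tags, one
statistic per file, in the `[model]/[time]/[name].tif` (paleo) and
`[scenario]/[model]/[time]/[name].tif` (future) layout.

## The synthetic archive

The generator reproduces the *geometry and semantics* of the production
inputs at desk scale: a 10×7 coarse grid (2.5°) nested in a 50×35 fine grid
(0.5°), 20 decades with the planted change confined to the early decades and
the last 11 decades left unperturbed (so the model reference is clean and
truth recovery is exact), two-harmonic annual cycles with smooth spatial
structure, positive-bounded variables, TOA-normalized shortwave, 11-decade
overlapping precipitation baselines with ±15 % decadal variability and 2 %
observation noise, per-epoch land masks, and daily stations with known noise
SD (4 °C). Planted defaults: +3 °C additive anomaly, ×0.8 vapour/wind
factor, ×1.4 precipitation factor, shortwave exponent 1.2.

What it deliberately does not emulate: ESM physics, realistic spatial
covariance, inter-variable coherence (e.g. temperature–precipitation
correlation), observational inhomogeneities, or real paleoshorelines.
Passing tests therefore demonstrate the correctness of the *transformations*
— bias cancellation, constraint satisfaction, conservation, convention
handling — not the realism of any climate field.

Problem sizes in the tests and examples (20 decades, 50×35 fine cells,
10⁶-draw Monte Carlo for the degree-day oracle, 100-instance solver checks)
were chosen so the full suite runs in well under a minute while leaving the
statistical checks well-powered.

## Known limitations

* No elevation lapse-rate correction or topographic radiation adjustment:
  fine-scale structure comes entirely from the observed climatology.
* Monthly precipitation from seasonal archives cannot recover abrupt
  intra-annual shifts (monsoon onsets); the smoothness prior is a prior.
* Future (monthly-per-year) mode shares all stage implementations, but the
  end-to-end driver is wired for the paleo workflow; future-mode runs
  compose the stages directly (empirical quantile map, no seasonal solver,
  no coastal fill).
* Downscaled variables are debiased marginally; cross-variable correlation
  is not constrained (the cross-correlation utility exists to audit it).
* The snow/melt constants and the PM cold-season treatment are this
  package's explicit defaults, configurable per run.
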