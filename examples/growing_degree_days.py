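"""Growing degree days from monthly statistics.

Compares three monthly GDD (base 5 degC) estimates at a synthetic daily
station: the truth from daily data, the naive hinge of the monthly mean, and
the normal daily-temperature model that uses the monthly mean plus the daily
standard deviation.
"""

import numpy as np

from chronoclim import gdd_day_expectation
from chronoclim.fixtures import station_series
from chronoclim.gdd import gdd_naive_day

st = station_series(seed=7, n_years=10, sigma_daily=4.0)
tmean = 0.5 * (st.tmax + st.tmin)
months = st.date.dt.month.values

print("month   actual    naive   normal-model")
tot = np.zeros(3)
for m in range(1, 13):
    sel = months == m
    actual = np.maximum(tmean[sel] - 5.0, 0).mean() * 30.4
    naive = gdd_naive_day(tmean[sel].mean(), 5.0) * 30.4
    model = gdd_day_expectation(tmean[sel].mean(), tmean[sel].std(), 5.0) * 30.4
    tot += (actual, naive, model)
    print(f"{m:5d} {actual:8.1f} {naive:8.1f} {model:10.1f}")
print(f"year  {tot[0]:8.1f} {tot[1]:8.1f} {tot[2]:10.1f}   (degC day)")
print()
print("In warm months all three agree; in the shoulder seasons the naive")
print("estimate drops to zero while days above the base still accumulate")
print("degree days -- the normal model captures that tail.")
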