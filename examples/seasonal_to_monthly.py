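"""Consistent monthly values from seasonal means.

Takes four seasonal temperatures, solves for the smoothest 12-month cycle
that reproduces them exactly, and contrasts with naive linear interpolation,
which damps the annual cycle and breaks seasonal consistency.
"""

import numpy as np

from chronoclim import s2m_additive, seasonal_from_monthly

S = np.array([-8.0, 6.0, 21.0, 9.0])  # DJF, MAM, JJA, SON

T = s2m_additive(S)

# naive alternative: place each seasonal mean at its central month and
# interpolate linearly around the cycle
centers = np.array([0, 3, 6, 9])  # Jan, Apr, Jul, Oct as season centers
naive = np.interp(np.arange(12), np.r_[centers, 12], np.r_[S, S[0]], period=12)

print("months:        ", " ".join(f"{t:6.2f}" for t in T))
print("naive linear:  ", " ".join(f"{t:6.2f}" for t in naive))
print()
print("seasonal means of solver output:", np.round(seasonal_from_monthly(T), 10))
print("seasonal means of naive output: ", np.round(seasonal_from_monthly(naive), 3))
print("targets:                        ", S)
print()
print(f"annual-cycle range: solver {T.max() - T.min():.2f}, "
      f"naive {naive.max() - naive.min():.2f}, seasonal input {S.max() - S.min():.2f}")
print("The solver reproduces every seasonal mean exactly and keeps a wider,")
print("smoother annual cycle; the naive cycle fails the consistency check.")
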