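"""Extrapolating climate onto formerly exposed shelf cells.

At the last glacial maximum, sea level was lower and parts of today's sea
floor were land.  Those cells get values from nearby present-land donors via
an incremental elliptical search (stretched east-west, w = 0.75) with
inverse-distance weights.
"""

import numpy as np

from chronoclim import fill_submerged, make_grid, shoreline_for_decade

grid = make_grid(-130, -120, 40, 50, 1.0)
present = np.zeros(grid.shape, dtype=bool)
present[:, 4:] = True          # coastline: land in the east
past = present.copy()
past[2:8, 2:4] = True          # exposed shelf at the older epoch

lon, lat = np.meshgrid(grid.lons, grid.lats)
field = np.where(present, 10.0 + 0.5 * (lat - 45.0), np.nan)  # N-S gradient

filled = fill_submerged(field, grid, present, past)

print("decade -2100 uses the", shoreline_for_decade(-2100), "ka shoreline")
print()
print("filled shelf column (west of the modern coast):")
for i in range(2, 8):
    print(f"  lat {grid.lats[i]:5.1f}N  filled {filled[i, 3]:6.2f}  "
          f"nearest modern land {field[i, 4]:6.2f}")
print()
print("Each filled value is a convex combination of modern-land donors, so")
print("the north-south gradient carries onto the exposed shelf.")
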