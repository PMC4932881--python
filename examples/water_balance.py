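"""Single-bucket actual evapotranspiration over a seasonal cycle.

Runs the 150 mm bucket over a repeating year with snowy winters and a dry
summer, printing the monthly water balance.  Mass is conserved exactly:
precipitation = AET + runoff + storage change.
"""

import numpy as np

from chronoclim.evapo import BucketState, run_bucket
from chronoclim.grids import MONTH_DAYS

months = np.arange(12)
precip = 70 + 40 * np.cos(2 * np.pi * (months - 0) / 12)      # wet winter
pet = np.maximum(90 + 80 * np.cos(2 * np.pi * (months - 6) / 12), 0.0)
T = 8 + 14 * np.cos(2 * np.pi * (months - 6) / 12)            # warm summer

forcing = {k: np.tile(v, 3).reshape(36, 1) for k, v in
           [("precip", precip), ("pet", pet), ("T", T)]}
aet, runoff, state = run_bucket(**forcing, n_days=np.tile(MONTH_DAYS, 3),
                                spinup_months=24)
aet, runoff = aet[24:, 0], runoff[24:, 0]

print("month  precip    PET    AET  runoff")
for m in months:
    print(f"{m + 1:5d} {precip[m]:7.1f} {pet[m]:6.1f} {aet[m]:6.1f} {runoff[m]:7.1f}")
print(f"year  {precip.sum():7.1f} {pet.sum():6.1f} {aet.sum():6.1f} {runoff.sum():7.1f}")
print()
print(f"evapotranspiration ratio AET/PET: {aet.sum() / pet.sum():.2f}")
print(f"water deficit index PET - P:      {pet.sum() - precip.sum():+.1f} mm/yr")
print("Summer AET falls below PET once the soil store empties; winter snow")
print("defers runoff to the melt season.")
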