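"""Change-factor downscaling of one paleo decade.

Builds the synthetic archive (coarse model decades nested in a fine observed
climatology with a planted +3 degC change), downscales the oldest decade, and
shows that the planted change is recovered exactly while the model's constant
+2 degC bias cancels.
"""

import numpy as np

from chronoclim import fixtures, pipeline

fx = fixtures.generate(fixtures.FixtureScenario(seed=0))
monthly = pipeline.downscale_paleo(fx)

diff_old = monthly["tmax"][0] - fx.obs_clim["tmax"]   # oldest decade
diff_ref = monthly["tmax"][-1] - fx.obs_clim["tmax"]  # reference decade

print(f"planted change:                +{fx.truths['temp_anomaly']:.1f} degC")
print(f"recovered change (old decade): {diff_old.mean():+.6f} degC "
      f"(spread {diff_old.std():.2e})")
print(f"recovered change (reference):  {diff_ref.mean():+.6f} degC")
print()
print("The old decade returns obs + 3 exactly and the reference decade returns")
print("obs unchanged: the model's own bias never reaches the downscaled field.")
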