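"""Amalgamate two species' abundance surfaces into one conservation map.

Raw summation would let the abundant species drown out the rare one;
unit-max scaling first makes each species peak at 1, so both contribute
equally at their own hotspots, and weights then encode conservation
priority (here the rare species counts double).
"""

import numpy as np
import pandas as pd

from deltaboost.brt import PredictionSurface
from deltaboost.cons import combine_subsets

rng = np.random.default_rng(3)
n = 400
lat = np.repeat(np.linspace(53, 55, 20), 20)
lon = np.tile(np.linspace(-6, -4, 20), 20)


def surface(values):
    return PredictionSurface(df=pd.DataFrame(
        {"latitude": lat, "longitude": lon, "p_occurrence": 1.0,
         "positive_abundance": values, "combined_index": values}))


abundant = surface(rng.lognormal(3.0, 1.0, n))   # peaks ~100s
rare = surface(rng.lognormal(-1.0, 1.0, n))      # peaks ~1

combined = combine_subsets([abundant, rare], weights=[1.0, 2.0],
                           names=["thornback", "cuckoo"])
df = combined.df
print(f"abundant species max before scaling: "
      f"{abundant.df.combined_index.max():.1f}; rare: "
      f"{rare.df.combined_index.max():.2f}")
print(f"after unit-max scaling both peak at "
      f"{df.thornback_scaled.max():.0f} and {df.cuckoo_scaled.max():.0f}")
print(f"weighted total peaks at {df.total.max():.3f} "
      f"(bounded by the weight sum {sum(combined.weights):.0f})")
print("top conservation cell:",
      df.loc[df.total.idxmax(), ["latitude", "longitude", "total"]].round(3).to_dict())
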