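"""Population metrics of NHPI variation with simulated uncertainty.

Builds a deliberately bimodal coefficient table (half the population
prefers natal-like habitat, half avoids it) and shows why the average
alone is misleading: specialization and heterogeneity reveal the
structure.  Uncertainty is propagated by redrawing every coefficient
from Normal(x_i, se_i) 1000 times.
"""

import numpy as np
import pandas as pd

from nhpikit import propagate_uncertainty

rng = np.random.default_rng(8)
n = 80
records = pd.DataFrame(
    {
        "individual": [f"id{i:03d}" for i in range(n)],
        "year": 1,
        "phase": "prospecting",
        "cluster": np.where(np.arange(n) % 2 == 0, "lowland", "upland"),
        "x": np.where(np.arange(n) % 2 == 0, 1.0, -1.0) + rng.normal(0, 0.05, n),
        "se": 0.1,
    }
)

dists = propagate_uncertainty(
    records, metrics=("average", "specialization", "heterogeneity"),
    n_sim=1000, seed=1,
)
print(f"{'metric':<16} {'point':>7} {'median':>7} {'2.5%':>7} {'97.5%':>7}")
for d in dists:
    s = d.summary()
    print(f"{d.metric:<16} {s['point']:>7.3f} {s['median']:>7.3f} "
          f"{s['q2.5']:>7.3f} {s['q97.5']:>7.3f}")

print("\nThe average is ~0 although every individual has a strong "
      "preference: specialization (~1) exposes the magnitude and "
      "heterogeneity (~1) the spread. The quantiles come from the 1000 "
      "coefficient-perturbation replicates.")
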