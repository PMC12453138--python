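"""Subsampling adjustment and distance decay of shared taxa.

Because the number of communities grows through the record, gamma and zeta
are recomputed on repeated random draws of a fixed number of communities per
bin (here 3, 100 iterations). Distance decay pools each site over a Holocene
subdivision and relates the shared-taxon count of every community subset to
its mean pairwise great-circle distance.
"""

import numpy as np

from metazeta import (
    SimulationConfig,
    SubsampleConfig,
    adjusted_metrics,
    bin_communities,
    distance_decay,
    holocene_subdivisions,
    simulate_metacommunity,
)

table, _ = simulate_metacommunity(SimulationConfig(seed=1))
slices = [s for s in bin_communities(table) if not s.excluded]

recs = adjusted_metrics(slices, SubsampleConfig(n_communities=3, n_iterations=100, seed=1))
gammas = [r for r in recs if r.metric == "gamma"]
oldest, youngest = gammas[0], gammas[-1]
print(f"adjusted gamma (3 communities): {oldest.mean:.1f} +/- {oldest.sd:.1f} "
      f"(oldest usable bin) -> {youngest.mean:.1f} +/- {youngest.sd:.1f} (youngest)")
# still increasing: the gamma rise is not only a site-number artefact.

subs = holocene_subdivisions()  # Early / Middle / Late, 4000-year intervals
decay = distance_decay(table, subs)
for label in ("Early Holocene", "Late Holocene"):
    pairs = [r for r in decay if r.subdivision == label and r.order == 2]
    if not pairs:
        continue
    d = np.array([r.subset_distance_km for r in pairs])
    z = np.array([r.zeta for r in pairs], float)
    slope = np.polyfit(d, z, 1)[0]
    print(f"{label}: {len(pairs)} site pairs, "
          f"mean shared taxa {z.mean():.1f}, slope {slope * 100:.2f} taxa / 100 km")
# with distance-independent pools the slope hovers near zero; real records
# (and spatially structured simulations) show shared taxa falling with distance.
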