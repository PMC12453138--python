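"""The three-level temporal turnover partition on simulated data.

The species exchange ratio beta_d = (S_imm + S_ext)/S_tot between consecutive
500-year bins is computed per community (then averaged), on the whole
metacommunity union, and within the subset of taxa shared by all communities
of a bin. Under additive homogenisation the first two decline (an increasing
share of taxa persists) while the shared subset keeps exchanging.
"""

import numpy as np

from metazeta import SimulationConfig, bin_communities, simulate_metacommunity
from metazeta.turnover import (
    mean_turnover_across_communities,
    shared_set_per_bin,
    turnover_community,
    turnover_metacommunity,
    turnover_shared_subset,
)

table, _ = simulate_metacommunity(SimulationConfig(seed=1))
slices = [s for s in bin_communities(table) if not s.excluded]

community_recs = []
for site in sorted(table.records["site"].unique()):
    try:
        community_recs += turnover_community(site, slices)
    except KeyError:
        pass
means = mean_turnover_across_communities(community_recs)
meta = turnover_metacommunity(slices)
shared = turnover_shared_subset([shared_set_per_bin(s) for s in slices])

def halves(recs):
    vals = [r for r in recs if r is not None]
    h = len(vals) // 2
    return np.mean(vals[:h]), np.mean(vals[h:])

old, new = halves([m.mean_beta_d for m in means])
print(f"community-mean beta_d: {old:.2f} (older half) -> {new:.2f} (recent half)")
old, new = halves([r.beta_d for r in meta])
print(f"metacommunity beta_d:  {old:.2f} -> {new:.2f}")
vals = [r.beta_d for r in shared if r.beta_d is not None]
print(f"shared-subset beta_d:  mean {np.mean(vals):.2f} over {len(vals)} bin-pairs "
      f"({sum(r.beta_d is None for r in shared)} undefined)")
# community and metacommunity turnover fall over time; the shared subset
# stays high — the taxa driving homogenisation are largely transient.
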