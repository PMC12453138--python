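"""Regime-contract evaluation: metric series and trend directions per replicate.

The named simulation regimes make directional promises (e.g. additive
homogenisation: rising mean alpha, gamma, additive beta and pairwise zeta,
falling community-level temporal turnover). These helpers compute, for one
simulated replicate, the per-bin metric series the promises are about, and
classify each series' direction with the trend module's linear classifier —
the machinery behind regime-recovery checks and ensemble summaries.
"""

from __future__ import annotations

import numpy as np

from .diversity import alpha_per_bin, gamma_beta_per_bin, zeta_per_bin
from .io import bin_communities
from .simulate import SimulationConfig, simulate_metacommunity
from .trends import classify_trend
from .turnover import mean_turnover_across_communities, turnover_community

__all__ = ["replicate_metric_series", "classify_directions", "regime_direction_rates"]

# what each regime promises for the classified directions
REGIME_EXPECTATIONS = {
    "additive_homogenisation": dict(
        mean_alpha="increasing", gamma="increasing", beta_add="increasing",
        zeta2="increasing", community_turnover="decreasing",
    ),
    "diversifying_only": dict(beta_add="increasing"),
    "static": dict(),
}


def replicate_metric_series(cfg: SimulationConfig, min_communities: int = 2) -> dict:
    """Per-bin metric series of one simulated replicate.

    Returns a dict of (ages, values) pairs for mean_alpha, gamma, beta_add,
    zeta2, zeta_full and community_turnover (the per-bin-pair mean of
    community-level exchange ratios, dated by the younger bin).
    """
    tab, _ = simulate_metacommunity(cfg)
    slices = [s for s in bin_communities(tab, min_communities=min_communities)
              if not s.excluded]
    ages, alphas, gammas, betas, z2, zfull = [], [], [], [], [], []
    for s in slices:
        a = alpha_per_bin(s)
        gb = gamma_beta_per_bin(s, a)
        ages.append(s.bin.label)
        alphas.append(a.mean_alpha)
        gammas.append(gb.gamma)
        betas.append(gb.beta_add)
        z2.append(zeta_per_bin(s, 2).zeta)
        zfull.append(zeta_per_bin(s, s.n_communities).zeta)
    comm_recs = []
    for site in sorted({c.site_id for s in slices for c in s.communities}):
        try:
            comm_recs += turnover_community(site, slices)
        except KeyError:
            continue
    means = mean_turnover_across_communities(comm_recs) if comm_recs else []
    t_ages = [m.to_bin.label for m in means if m.mean_beta_d is not None]
    t_vals = [m.mean_beta_d for m in means if m.mean_beta_d is not None]
    out = dict(
        mean_alpha=(ages, alphas), gamma=(ages, gammas), beta_add=(ages, betas),
        zeta2=(ages, z2), zeta_full=(ages, zfull),
        community_turnover=(t_ages, t_vals),
    )
    return out


def classify_directions(series: dict, alpha: float = 0.05) -> dict:
    """Linear-trend direction per metric series ('increasing'/'decreasing'/'flat')."""
    out = {}
    for name, (ages, vals) in series.items():
        if len(vals) < 3:
            out[name] = "flat"
            continue
        out[name] = classify_trend(np.asarray(ages, float), np.asarray(vals, float),
                                   family="gaussian", linear=True, alpha=alpha)
    return out


def regime_direction_rates(
    regime: str, n_replicates: int = 100, base_seed: int = 0, **cfg_kw
) -> dict:
    """Fraction of replicates whose classified direction matches the regime's
    promise, per promised metric."""
    expect = REGIME_EXPECTATIONS[regime]
    hits = {m: 0 for m in expect}
    for i in range(n_replicates):
        cfg = SimulationConfig(regime=regime, seed=base_seed + i, **cfg_kw)
        got = classify_directions(replicate_metric_series(cfg))
        for m, want in expect.items():
            if got[m] == want:
                hits[m] += 1
    return {m: h / n_replicates for m, h in hits.items()}
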