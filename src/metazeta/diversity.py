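"""Per-bin diversity metrics: alpha, gamma, additive beta, zeta and zeta ratio.

All metrics operate on a :class:`~metazeta.io.MetacommunitySlice`. Alpha is
richness per sediment sample, averaged per bin; gamma is the pooled richness
of the slice; additive (spatial) beta is the Lande partition gamma minus mean
alpha. Zeta diversity of order *n* is the mean number of taxa shared by
subsets of *n* communities, computed on the pooled per-site taxon sets; the
zeta ratio zeta_{n+1}/zeta_n is the retention rate of shared taxa as more
communities are compared. Zeta order 1 equals mean community richness and is
kept internal only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import MetacommunitySlice, TimeBin

__all__ = [
    "AlphaRecord",
    "GammaBetaRecord",
    "ZetaRecord",
    "ZetaRatioRecord",
    "alpha_per_bin",
    "gamma_beta_per_bin",
    "zeta_per_bin",
    "zeta_all_orders",
    "zeta_ratio_per_bin",
    "retention_curve",
]


@dataclass
class AlphaRecord:
    bin: TimeBin
    per_sample_alphas: list
    mean_alpha: float
    sd_alpha: float
    n_communities: int
    mode: str = "per_sample_mean"


@dataclass
class GammaBetaRecord:
    bin: TimeBin
    gamma: int
    mean_alpha: float
    beta_add: float


@dataclass
class ZetaRecord:
    bin: TimeBin
    order: int
    zeta: float
    n_combinations_evaluated: int
    method: str  # "exact" | "monte_carlo"
    sd_over_combinations: float


@dataclass
class ZetaRatioRecord:
    bin: TimeBin
    order: int  # ratio zeta_{order+1} / zeta_{order}
    ratio: float | None  # None when zeta_order == 0


def alpha_per_bin(slc: MetacommunitySlice, mode: str = "per_sample_mean") -> AlphaRecord:
    """Average alpha diversity of one bin.

    ``per_sample_mean`` pools every sample's richness across all sites and
    averages; ``per_site_then_mean`` averages within each site first and then
    across sites (relevant when sites contribute unequal sample counts).
    """
    if slc.n_communities < 1:
        raise ValueError("slice has no communities")
    if mode == "per_sample_mean":
        values = [r for c in slc.communities for r in c.sample_richness]
    elif mode == "per_site_then_mean":
        values = [float(np.mean(c.sample_richness)) for c in slc.communities]
    else:
        raise ValueError(f"unknown alpha mode {mode!r}")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return AlphaRecord(
        bin=slc.bin,
        per_sample_alphas=[int(v) if float(v).is_integer() else float(v) for v in values],
        mean_alpha=float(arr.mean()),
        sd_alpha=sd,
        n_communities=slc.n_communities,
        mode=mode,
    )


def gamma_beta_per_bin(slc: MetacommunitySlice, alpha: AlphaRecord) -> GammaBetaRecord:
    """Gamma (pooled richness) and additive beta = gamma - mean alpha."""
    if alpha.bin != slc.bin:
        raise ValueError("alpha record computed on a different bin")
    gamma = len(slc.union())
    return GammaBetaRecord(
        bin=slc.bin,
        gamma=gamma,
        mean_alpha=alpha.mean_alpha,
        beta_add=gamma - alpha.mean_alpha,
    )


def _intersection_size(sets) -> int:
    it = iter(sets)
    inter = next(it)
    for s in it:
        inter = inter & s
        if not inter:
            return 0
    return len(inter)


def zeta_per_bin(
    slc: MetacommunitySlice,
    order: int,
    method: str = "auto",
    max_exact_combinations: int = 100_000,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> ZetaRecord:
    """Zeta diversity of one order for one bin.

    Exact mode averages the intersection size over all C(k, order) community
    subsets; Monte Carlo averages over ``n_mc`` uniformly drawn subsets
    (each subset drawn without replacement) and requires a seed. ``auto``
    selects exact whenever the number of subsets is at most
    ``max_exact_combinations`` — always the case at study scale (<= 10
    communities).
    """
    k = slc.n_communities
    if order < 2:
        raise ValueError("zeta order must be >= 2 (order 1 is mean alpha)")
    if order > k:
        raise ValueError(f"zeta order {order} exceeds number of communities {k}")
    sets = slc.taxon_sets()
    n_comb = math.comb(k, order)
    if method == "auto":
        method = "exact" if n_comb <= max_exact_combinations else "monte_carlo"
    if method == "exact":
        sizes = [_intersection_size(c) for c in combinations(sets, order)]
        n_eval = n_comb
    elif method == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo zeta requires a seed")
        rng = np.random.default_rng(seed)
        sizes = [
            _intersection_size([sets[i] for i in rng.choice(k, order, replace=False)])
            for _ in range(n_mc)
        ]
        n_eval = n_mc
    else:
        raise ValueError(f"unknown zeta method {method!r}")
    arr = np.asarray(sizes, dtype=float)
    return ZetaRecord(
        bin=slc.bin,
        order=order,
        zeta=float(arr.mean()),
        n_combinations_evaluated=n_eval,
        method=method,
        sd_over_combinations=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


def zeta_all_orders(slc: MetacommunitySlice, max_order: int | None = None, **kw) -> list:
    """Zeta records for orders 2..max_order (default: all communities)."""
    k = slc.n_communities
    top = k if max_order is None else min(max_order, k)
    return [zeta_per_bin(slc, n, **kw) for n in range(2, top + 1)]


def _zeta1(slc: MetacommunitySlice) -> float:
    """Order-1 zeta: mean richness of the pooled community sets (internal)."""
    return float(np.mean([len(s) for s in slc.taxon_sets()]))


def zeta_ratio_per_bin(zetas: list) -> list:
    """Zeta ratios zeta_{n+1}/zeta_n for a consecutive-order zeta series.

    The ratio is undefined (None) where the denominator zeta_n is zero.
    """
    if not zetas:
        return []
    zetas = sorted(zetas, key=lambda z: z.order)
    orders = [z.order for z in zetas]
    if orders != list(range(orders[0], orders[0] + len(orders))):
        raise ValueError(f"zeta orders not consecutive: {orders}")
    out = []
    for lo, hi in zip(zetas, zetas[1:]):
        if lo.bin != hi.bin:
            raise ValueError("zeta records from different bins")
        ratio = (hi.zeta / lo.zeta) if lo.zeta > 0 else None
        out.append(ZetaRatioRecord(bin=lo.bin, order=lo.order, ratio=ratio))
    return out


def retention_curve(bin: TimeBin, ratios: list) -> list:
    """Ordered (order, ratio) pairs — the retention-rate curve of one bin."""
    if len(ratios) < 2:
        raise ValueError("need at least two ratio records for a curve")
    pts = [(r.order, r.ratio) for r in sorted(ratios, key=lambda r: r.order)]
    if any(r.bin != bin for r in ratios):
        raise ValueError("ratio records from a different bin")
    return pts
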