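"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from metazeta.io import BinnedCommunity, MetacommunitySlice, TimeBin


def make_slice(taxon_sets, bin=None, site_ids=None, samples=None):
    """Build a MetacommunitySlice from raw taxon sets (one sample each).

    ``samples`` optionally gives per-site lists of per-sample taxon sets,
    whose union must equal the site's community set.
    """
    tb = bin or TimeBin(0.0, 500.0)
    sites = site_ids or [f"L{i}" for i in range(len(taxon_sets))]
    comms = []
    for i, (sid, taxa) in enumerate(zip(sites, taxon_sets)):
        if samples is not None:
            st = {f"{sid}_s{j}": frozenset(s) for j, s in enumerate(samples[i])}
        else:
            st = {f"{sid}_s0": frozenset(taxa)}
        comms.append(
            BinnedCommunity(
                site_id=sid, bin=tb, taxa=frozenset(taxa),
                n_samples=len(st), sample_taxa=st,
            )
        )
    return MetacommunitySlice(bin=tb, communities=comms)


@pytest.fixture
def toy_slice():
    """The three-community worked example {a,b,c}, {b,c,d}, {c,d,e}."""
    return make_slice([{"a", "b", "c"}, {"b", "c", "d"}, {"c", "d", "e"}])


def random_taxon_sets(rng, max_communities=12, max_taxa=40):
    """A random small metacommunity instance for oracle comparisons."""
    k = int(rng.integers(2, max_communities + 1))
    n_taxa = int(rng.integers(1, max_taxa + 1))
    pool = [f"t{j}" for j in range(n_taxa)]
    p = rng.uniform(0.05, 0.9)
    sets = []
    for _ in range(k):
        mask = rng.random(n_taxa) < p
        sets.append(frozenset(t for t, m in zip(pool, mask) if m))
    return sets


# ---------------------------------------------------------------------------
# Independent oracles (deliberately different algorithms from the package)
# ---------------------------------------------------------------------------

def oracle_zeta(sets, order):
    """Zeta via the incidence-count identity.

    zeta_n = sum over taxa of C(m_t, n) / C(k, n), where m_t is the number of
    communities containing taxon t — an algebraic route that never touches
    set intersections.
    """
    k = len(sets)
    counts = {}
    for s in sets:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    total = sum(math.comb(m, order) for m in counts.values())
    return total / math.comb(k, order)


def oracle_zeta_enumeration(sets, order):
    """Zeta by direct subset enumeration (second independent route)."""
    sizes = [
        len(set.intersection(*map(set, combo)))
        for combo in combinations(sets, order)
    ]
    return sum(sizes) / len(sizes)


def oracle_gamma(sets):
    seen = set()
    for s in sets:
        seen |= set(s)
    return len(seen)


def oracle_turnover(t1, t2):
    """(S_imm, S_ext, S_tot, beta_d) by element-wise counting."""
    t1, t2 = set(t1), set(t2)
    s_imm = sum(1 for t in t2 if t not in t1)
    s_ext = sum(1 for t in t1 if t not in t2)
    s_tot = len(t1 | t2)
    beta = (s_imm + s_ext) / s_tot if s_tot else None
    return s_imm, s_ext, s_tot, beta
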