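"""Temporal beta diversity (species exchange ratio) between consecutive bins.

For two taxon sets T1 (older) and T2 (younger),

    S_imm = |T2 \\ T1|   taxa appearing (immigration)
    S_ext = |T1 \\ T2|   taxa disappearing (extirpation)
    S_tot = |T1 ∪ T2|
    beta_d = (S_imm + S_ext) / S_tot        (Jaccard dissimilarity)

computed at three levels: per community (one series per site, averaged per
bin-pair), on the metacommunity union, and within the subset of taxa shared
among communities. A 0/0 pair (both sets empty) yields a missing beta_d,
never 0 — zero would fabricate stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import MetacommunitySlice, TimeBin

__all__ = [
    "TurnoverRecord",
    "SharedSet",
    "MeanTurnoverRecord",
    "turnover_between_sets",
    "turnover_community",
    "turnover_metacommunity",
    "mean_turnover_across_communities",
    "shared_set_per_bin",
    "turnover_shared_subset",
]


@dataclass
class TurnoverRecord:
    from_bin: TimeBin  # older
    to_bin: TimeBin  # younger
    level: str  # "community" | "metacommunity" | "shared_subset"
    site_id: str  # "-" above community level
    S_imm: int
    S_ext: int
    S_tot: int
    beta_d: float | None  # None when S_tot == 0
    note: str = ""


@dataclass
class SharedSet:
    bin: TimeBin
    order_used: int
    taxa: frozenset


@dataclass
class MeanTurnoverRecord:
    from_bin: TimeBin
    to_bin: TimeBin
    mean_beta_d: float | None
    n_used: int
    n_missing: int


def turnover_between_sets(
    t1: frozenset, t2: frozenset, from_bin: TimeBin, to_bin: TimeBin,
    level: str, site_id: str = "-", note: str = "",
) -> TurnoverRecord:
    s_imm = len(t2 - t1)
    s_ext = len(t1 - t2)
    s_tot = len(t1 | t2)
    beta = (s_imm + s_ext) / s_tot if s_tot > 0 else None
    if s_tot == 0:
        reason = "both sets empty; beta_d undefined"
        note = f"{note}; {reason}" if note else reason
    return TurnoverRecord(from_bin, to_bin, level, site_id, s_imm, s_ext, s_tot, beta, note)


def _eligible(slices: Iterable[MetacommunitySlice]) -> list:
    out = [s for s in slices if not s.excluded]
    return sorted(out, key=lambda s: -s.bin.lower)  # oldest first


def _pairs(bins_old_first: list, bridge_gaps: bool) -> list:
    """Consecutive (older, younger) index pairs; gaps only when bridged."""
    pairs = []
    for a, b in zip(bins_old_first, bins_old_first[1:]):
        if b.is_adjacent_older(a) or bridge_gaps:
            pairs.append((a, b))
    return pairs


def turnover_community(
    site_id: str, slices: Iterable[MetacommunitySlice], bridge_gaps: bool = False
) -> list:
    """Exchange ratio between consecutive bins for one site.

    Emits one record per consecutive bin-pair in which the site is present in
    both bins; temporal gaps (the site missing from an intervening bin, or
    non-adjacent bins) produce no record unless ``bridge_gaps`` is set.
    """
    slices = _eligible(slices)
    present = [s for s in slices if s.community(site_id) is not None]
    if not present:
        raise KeyError(f"site {site_id!r} not present in any eligible slice")
    out = []
    for old, young in zip(present, present[1:]):
        if not young.bin.is_adjacent_older(old.bin) and not bridge_gaps:
            continue
        rec = turnover_between_sets(
            old.community(site_id).taxa,
            young.community(site_id).taxa,
            from_bin=old.bin,
            to_bin=young.bin,
            level="community",
            site_id=site_id,
        )
        out.append(rec)
    return out


def turnover_metacommunity(
    slices: Iterable[MetacommunitySlice], bridge_gaps: bool = False
) -> list:
    """Exchange ratio between consecutive bins on metacommunity unions."""
    slices = _eligible(slices)
    out = []
    for old, young in zip(slices, slices[1:]):
        if not young.bin.is_adjacent_older(old.bin) and not bridge_gaps:
            continue
        out.append(
            turnover_between_sets(
                old.union(), young.union(),
                from_bin=old.bin, to_bin=young.bin, level="metacommunity",
            )
        )
    return out


def mean_turnover_across_communities(records: Iterable[TurnoverRecord]) -> list:
    """Average community-level beta_d per consecutive bin-pair.

    Missing values are excluded from the mean; the number used and the number
    missing are both reported.
    """
    groups: dict = {}
    for r in records:
        if r.level != "community":
            raise ValueError("expected community-level records")
        groups.setdefault((r.from_bin, r.to_bin), []).append(r)
    out = []
    for (fb, tb), recs in sorted(groups.items(), key=lambda kv: -kv[0][0].lower):
        vals = [r.beta_d for r in recs if r.beta_d is not None]
        out.append(
            MeanTurnoverRecord(
                from_bin=fb,
                to_bin=tb,
                mean_beta_d=float(np.mean(vals)) if vals else None,
                n_used=len(vals),
                n_missing=len(recs) - len(vals),
            )
        )
    return out


def shared_set_per_bin(slc: MetacommunitySlice, order: int | None = None) -> SharedSet:
    """Taxa shared at a given zeta order within one bin.

    Default (``order=None``): the taxa common to *all* communities present —
    the single full-order zeta combination, whose order can differ between
    bins as the number of communities does. An explicit lower ``order``
    returns the taxa occurring in at least that many communities.
    """
    k = slc.n_communities
    if k < 2:
        raise ValueError("shared set needs at least two communities")
    if order is None:
        order = k
    if not 2 <= order <= k:
        raise ValueError(f"order must be in [2, {k}]")
    if order == k:
        taxa = frozenset.intersection(*slc.taxon_sets())
    else:
        counts: dict = {}
        for s in slc.taxon_sets():
            for t in s:
                counts[t] = counts.get(t, 0) + 1
        taxa = frozenset(t for t, c in counts.items() if c >= order)
    return SharedSet(bin=slc.bin, order_used=order, taxa=taxa)


def turnover_shared_subset(
    shared_sets: Iterable[SharedSet], bridge_gaps: bool = False
) -> list:
    """Exchange ratio between consecutive bins' shared-taxa subsets."""
    sets = sorted(shared_sets, key=lambda s: -s.bin.lower)
    out = []
    for old, young in zip(sets, sets[1:]):
        if not young.bin.is_adjacent_older(old.bin) and not bridge_gaps:
            continue
        out.append(
            turnover_between_sets(
                old.taxa, young.taxa,
                from_bin=old.bin, to_bin=young.bin, level="shared_subset",
                note=f"orders {old.order_used}->{young.order_used}",
            )
        )
    return out
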