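"""Temporal turnover (species exchange ratio) at all three levels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metazeta.io import OccurrenceTable, TimeBin, bin_communities
from metazeta.simulate import SimulationConfig, simulate_metacommunity
from metazeta.turnover import (
    mean_turnover_across_communities,
    shared_set_per_bin,
    turnover_between_sets,
    turnover_community,
    turnover_metacommunity,
    turnover_shared_subset,
)

from conftest import make_slice, oracle_turnover, random_taxon_sets

B1 = TimeBin(1000, 1500)
B2 = TimeBin(500, 1000)
B3 = TimeBin(0, 500)


def two_bin_slices(t1, t2, site="L1"):
    return [
        make_slice([t1, {"z1", "z2"}], bin=B2, site_ids=[site, "Lz"]),
        make_slice([t2, {"z1", "z2"}], bin=B3, site_ids=[site, "Lz"]),
    ]


class TestCommunityTurnover:
    def test_symmetric_exchange(self):
        recs = turnover_community("L1", two_bin_slices({"a", "b"}, {"b", "c"}))
        (r,) = recs
        assert (r.S_imm, r.S_ext, r.S_tot) == (1, 1, 3)
        assert r.beta_d == pytest.approx(2 / 3)

    def test_no_exchange(self):
        (r,) = turnover_community("L1", two_bin_slices({"a", "b"}, {"a", "b"}))
        assert r.beta_d == 0.0

    def test_complete_turnover(self):
        (r,) = turnover_community("L1", two_bin_slices({"a"}, {"b"}))
        assert r.beta_d == 1.0

    def test_unknown_site_rejected(self):
        with pytest.raises(KeyError):
            turnover_community("nope", two_bin_slices({"a"}, {"b"}))

    def test_gap_produces_no_record(self):
        slices = [
            make_slice([{"a"}, {"z"}], bin=B1, site_ids=["L1", "Lz"]),
            make_slice([{"x"}, {"z"}], bin=B2, site_ids=["Lx", "Lz"]),  # L1 absent
            make_slice([{"b"}, {"z"}], bin=B3, site_ids=["L1", "Lz"]),
        ]
        assert turnover_community("L1", slices) == []
        bridged = turnover_community("L1", slices, bridge_gaps=True)
        assert len(bridged) == 1 and bridged[0].beta_d == 1.0

    def test_records_oriented_old_to_young(self):
        (r,) = turnover_community("L1", two_bin_slices({"a"}, {"a", "b"}))
        assert r.from_bin.lower > r.to_bin.lower
        assert r.S_imm == 1 and r.S_ext == 0  # appearance = immigration


class TestMetacommunityTurnover:
    def test_growth_only(self):
        slices = [
            make_slice([{"a", "b"}, {"c"}], bin=B2),
            make_slice([{"a", "b"}, {"c", "d"}], bin=B3),
        ]
        (r,) = turnover_metacommunity(slices)
        assert (r.S_imm, r.S_ext, r.S_tot) == (1, 0, 4)
        assert r.beta_d == pytest.approx(1 / 4)

    def test_identical_unions_zero(self):
        slices = [
            make_slice([{"a"}, {"b"}], bin=B2),
            make_slice([{"b"}, {"a"}], bin=B3),
        ]
        (r,) = turnover_metacommunity(slices)
        assert r.beta_d == 0.0

    def test_nested_sets_immigration_only(self):
        t1, t2 = {"a"}, {"a", "b", "c"}
        slices = [make_slice([t1, t1], bin=B2), make_slice([t2, t2], bin=B3)]
        (r,) = turnover_metacommunity(slices)
        assert r.S_ext == 0 and r.beta_d == pytest.approx(r.S_imm / r.S_tot)

    def test_aggregation_consistency_with_raw_table(self):
        """Metacommunity S_imm equals an independent pandas pass on raw data."""
        tab, _ = simulate_metacommunity(
            SimulationConfig(n_sites=5, t_start=5000, pool_core=30, pool_unique=8, seed=3)
        )
        slices = [s for s in bin_communities(tab, min_communities=1)]
        recs = turnover_metacommunity(slices)
        df = tab.records.assign(k=np.floor(tab.records["age"] / 500).astype(int))
        union_by_k = df.groupby("k")["taxon"].agg(set).to_dict()
        for r in recs:
            k_old = int(r.from_bin.lower // 500)
            k_new = int(r.to_bin.lower // 500)
            expect = len(union_by_k[k_new] - union_by_k[k_old])
            assert r.S_imm == expect


class TestMeanTurnover:
    def test_arithmetic_mean(self):
        r1 = turnover_between_sets(frozenset("ab"), frozenset("bc"), B2, B3, "community", "L1")
        r2 = turnover_between_sets(frozenset("ab"), frozenset("ab"), B2, B3, "community", "L2")
        (m,) = mean_turnover_across_communities([r1, r2])
        assert m.mean_beta_d == pytest.approx((2 / 3 + 0) / 2)
        assert m.n_used == 2 and m.n_missing == 0

    def test_single_community(self):
        r = turnover_between_sets(frozenset("a"), frozenset("b"), B2, B3, "community", "L1")
        (m,) = mean_turnover_across_communities([r])
        assert m.mean_beta_d == 1.0

    def test_missing_excluded_and_counted(self):
        good = turnover_between_sets(frozenset("ab"), frozenset("ac"), B2, B3, "community", "L1")
        empty = turnover_between_sets(frozenset(), frozenset(), B2, B3, "community", "L2")
        (m,) = mean_turnover_across_communities([good, empty])
        assert m.mean_beta_d == pytest.approx(2 / 3)
        assert m.n_used == 1 and m.n_missing == 1

    def test_wrong_level_rejected(self):
        r = turnover_between_sets(frozenset("a"), frozenset("b"), B2, B3, "metacommunity")
        with pytest.raises(ValueError):
            mean_turnover_across_communities([r])


class TestSharedSet:
    def test_triple_intersection(self, toy_slice):
        ss = shared_set_per_bin(toy_slice)
        assert ss.taxa == {"c"} and ss.order_used == 3

    def test_disjoint_empty(self):
        assert shared_set_per_bin(make_slice([{"a"}, {"b"}])).taxa == frozenset()

    def test_identical_full_set(self):
        s = make_slice([{"a", "b"}] * 3)
        assert shared_set_per_bin(s).taxa == {"a", "b"}

    def test_lower_order_at_least_n_communities(self, toy_slice):
        ss = shared_set_per_bin(toy_slice, order=2)
        assert ss.taxa == {"b", "c", "d"}  # taxa in >= 2 of the 3 communities


class TestSharedSubsetTurnover:
    def _sets(self, z1, z2):
        from metazeta.turnover import SharedSet
        return [SharedSet(B2, 2, frozenset(z1)), SharedSet(B3, 2, frozenset(z2))]

    def test_half_exchange(self):
        (r,) = turnover_shared_subset(self._sets({"c"}, {"c", "f"}))
        assert r.beta_d == pytest.approx(1 / 2)

    def test_no_change(self):
        (r,) = turnover_shared_subset(self._sets({"c"}, {"c"}))
        assert r.beta_d == 0.0

    def test_total_loss(self):
        (r,) = turnover_shared_subset(self._sets({"c"}, set()))
        assert (r.S_ext, r.S_tot, r.beta_d) == (1, 1, 1.0)

    def test_both_empty_missing_with_reason(self):
        (r,) = turnover_shared_subset(self._sets(set(), set()))
        assert r.beta_d is None and "empty" in r.note


class TestInvariants:
    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decomposition_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        sets = random_taxon_sets(rng, 6, 20)
        t1, t2 = sets[0], sets[1]
        r = turnover_between_sets(t1, t2, B2, B3, "community", "L1")
        s_imm, s_ext, s_tot, beta = oracle_turnover(t1, t2)
        assert (r.S_imm, r.S_ext, r.S_tot) == (s_imm, s_ext, s_tot)
        if r.beta_d is None:
            assert s_tot == 0
        else:
            assert r.beta_d * r.S_tot == pytest.approx(r.S_imm + r.S_ext)
            assert 0.0 <= r.beta_d <= 1.0
            assert (r.beta_d == 0.0) == (t1 == t2)
            assert (r.beta_d == 1.0) == (not (t1 & t2))
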