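"""Subsampling adjustment, Holocene subdivisions and distance decay."""

import math

import numpy as np
import pandas as pd
import pytest

from metazeta.io import OccurrenceTable, TimeBin
from metazeta.resample import (
    SubsampleConfig,
    adjusted_metrics,
    assign_subdivision,
    distance_decay,
    haversine_km,
    holocene_subdivisions,
)

from conftest import make_slice

TOY_SETS = [{"a", "b", "c"}, {"b", "c", "d"}, {"c", "d", "e"}]


class TestAdjustedMetrics:
    def test_sampling_all_communities_is_exact(self):
        s = make_slice(TOY_SETS)
        recs = adjusted_metrics([s], SubsampleConfig(n_communities=3, n_iterations=5, seed=0))
        by = {r.metric: r for r in recs}
        assert by["gamma"].mean == 5.0 and by["gamma"].sd == 0.0
        assert by["beta_add"].mean == pytest.approx(2.0)
        assert by["zeta"].mean == pytest.approx(5 / 3)
        assert by["zeta_full"].mean == 1.0

    def test_single_community_gamma_is_mean_richness(self):
        # all three communities have richness 3, so every draw gives 3
        s = make_slice(TOY_SETS)
        recs = adjusted_metrics(
            [s], SubsampleConfig(n_communities=1, n_iterations=200, seed=1),
            metrics=("gamma",),
        )
        (g,) = [r for r in recs if r.metric == "gamma"]
        assert g.mean == 3.0 and g.sd == 0.0

    def test_pairwise_enumeration_expectation(self):
        """Adjusted gamma with n=2 converges to the enumerated (4+5+4)/3."""
        s = make_slice(TOY_SETS)
        recs = adjusted_metrics(
            [s], SubsampleConfig(n_communities=2, n_iterations=10_000, seed=2),
            metrics=("gamma",),
        )
        (g,) = [r for r in recs if r.metric == "gamma"]
        se = g.sd / math.sqrt(g.n_iterations_used)
        assert abs(g.mean - 13 / 3) <= 3 * se

    def test_same_seed_identical_records(self):
        s = make_slice(TOY_SETS)
        cfg = SubsampleConfig(n_communities=2, n_iterations=50, seed=7)
        a = adjusted_metrics([s], cfg)
        b = adjusted_metrics([s], cfg)
        assert [(r.metric, r.mean, r.sd) for r in a] == [(r.metric, r.mean, r.sd) for r in b]

    def test_start_rule_excludes_early_bins(self):
        early = make_slice([{"a"}, {"b"}], bin=TimeBin(1000, 1500))
        late = make_slice(TOY_SETS, bin=TimeBin(500, 1000))
        recs = adjusted_metrics(
            [early, late], SubsampleConfig(n_communities=3, n_iterations=5, seed=0)
        )
        excluded = [r for r in recs if r.metric == "excluded"]
        assert len(excluded) == 1 and excluded[0].bin == early.bin

    def test_too_few_communities_after_start_is_error(self):
        big = make_slice(TOY_SETS, bin=TimeBin(1000, 1500))
        small = make_slice([{"a"}, {"b"}], bin=TimeBin(500, 1000))
        with pytest.raises(ValueError, match="too few"):
            adjusted_metrics([big, small], SubsampleConfig(n_communities=3, n_iterations=2, seed=0))

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            adjusted_metrics([make_slice(TOY_SETS)],
                             SubsampleConfig(n_communities=2, n_iterations=2, seed=0),
                             metrics=("shannon",))

    def test_turnover_metric_on_consecutive_bins(self):
        s1 = make_slice([{"a", "b"}, {"a", "b"}], bin=TimeBin(500, 1000))
        s2 = make_slice([{"a", "c"}, {"a", "c"}], bin=TimeBin(0, 500))
        recs = adjusted_metrics(
            [s1, s2], SubsampleConfig(n_communities=2, n_iterations=5, seed=0),
            metrics=("turnover",),
        )
        (t,) = [r for r in recs if r.metric == "turnover"]
        assert t.mean == pytest.approx(2 / 3)  # {a,b}->{a,c}


class TestSubdivisions:
    def test_default_spans(self):
        subs = holocene_subdivisions()
        assert [s.span for s in subs] == [4000.0, 4000.0, 3700.0]
        assert [s.label for s in subs] == [
            "Early Holocene", "Middle Holocene", "Late Holocene"]

    def test_late_glacial_excluded(self):
        assert assign_subdivision(12_000.0, holocene_subdivisions()) is None

    def test_edge_assignment(self):
        subs = holocene_subdivisions()
        assert assign_subdivision(11_700.0, subs).label == "Early Holocene"
        assert assign_subdivision(7_700.0, subs).label == "Middle Holocene"
        assert assign_subdivision(3_700.0, subs).label == "Late Holocene"
        assert assign_subdivision(0.0, subs).label == "Late Holocene"

    def test_custom_boundaries_echoed(self):
        subs = holocene_subdivisions((9000, 4500, 0), labels=("old", "new"))
        assert [(s.older, s.younger) for s in subs] == [(9000, 4500), (4500, 0)]

    def test_non_descending_rejected(self):
        with pytest.raises(ValueError):
            holocene_subdivisions((5000, 5000, 0))


class TestDistanceDecay:
    def _table(self, site_taxa, coords, age=1000.0):
        rows = [
            (site, f"{site}_s", age, t)
            for site, taxa in site_taxa.items() for t in taxa
        ]
        df = pd.DataFrame(rows, columns=["site", "sample", "age", "taxon"])
        return OccurrenceTable(df, sites=coords)

    def test_haversine_known_values(self):
        assert haversine_km(0, 0, 0, 0) == 0.0
        # one degree of latitude ~ 111.2 km
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.1)
        assert haversine_km(10, 50, 12, 50) == pytest.approx(
            haversine_km(12, 50, 10, 50))

    def test_identical_pair_records_distance_and_shared(self):
        tab = self._table(
            {"A": {"x", "y", "z"}, "B": {"x", "y", "z"}},
            {"A": (20.0, 68.0), "B": (21.0, 68.0)},
        )
        subs = holocene_subdivisions((1500.0, 0.0), labels=("only",))
        (rec,) = distance_decay(tab, subs)
        assert rec.order == 2 and rec.zeta == 3
        assert rec.subset_distance_km == pytest.approx(
            haversine_km(20.0, 68.0, 21.0, 68.0))

    def test_triple_mean_pairwise_distance_and_enumeration(self):
        coords = {"A": (20.0, 68.0), "B": (21.0, 68.0), "C": (22.0, 68.0)}
        tab = self._table(
            {"A": {"x", "y"}, "B": {"y", "z"}, "C": {"y"}}, coords)
        subs = holocene_subdivisions((1500.0, 0.0), labels=("only",))
        recs = distance_decay(tab, subs)
        (r3,) = [r for r in recs if r.order == 3]
        d = [haversine_km(*coords[a], *coords[b])
             for a, b in [("A", "B"), ("A", "C"), ("B", "C")]]
        assert r3.subset_distance_km == pytest.approx(np.mean(d))
        assert r3.zeta == 1  # only 'y' everywhere
        pair_zetas = sorted(r.zeta for r in recs if r.order == 2)
        assert pair_zetas == [1, 1, 1]

    def test_subset_distance_invariant_under_reordering(self):
        coords = {"A": (20.0, 68.0), "B": (24.0, 69.0), "C": (28.0, 70.0)}
        tab1 = self._table({"A": {"x"}, "B": {"x"}, "C": {"x"}}, coords)
        subs = holocene_subdivisions((1500.0, 0.0), labels=("only",))
        (r,) = [q for q in distance_decay(tab1, subs) if q.order == 3]
        perm = {"A": coords["C"], "B": coords["A"], "C": coords["B"]}
        tab2 = self._table({"A": {"x"}, "B": {"x"}, "C": {"x"}}, perm)
        (r2,) = [q for q in distance_decay(tab2, subs) if q.order == 3]
        assert r.subset_distance_km == pytest.approx(r2.subset_distance_km)

    def test_missing_coordinates_rejected(self):
        df = pd.DataFrame([("A", "s", 100.0, "x")],
                          columns=["site", "sample", "age", "taxon"])
        tab = OccurrenceTable(df)  # no coordinates at all
        with pytest.raises(ValueError, match="coordinates"):
            distance_decay(tab)

    def test_distance_independent_pools_give_flat_slope(self):
        """Communities drawn iid from one pool: zeta unrelated to distance."""
        from metazeta.simulate import SimulationConfig, simulate_metacommunity
        slopes = []
        for seed in range(40):
            cfg = SimulationConfig(n_sites=6, t_start=2000, pool_core=40,
                                   pool_unique=0, regime="static", seed=seed,
                                   onset_schedule=[0] * 6)
            tab, _ = simulate_metacommunity(cfg)
            subs = holocene_subdivisions((2000.0, 0.0), labels=("all",))
            recs = [r for r in distance_decay(tab, subs, orders=(2,))]
            x = np.array([r.subset_distance_km for r in recs])
            y = np.array([r.zeta for r in recs], dtype=float)
            if x.std() > 0 and y.std() > 0:
                slopes.append(np.polyfit(x, y, 1)[0])
        mean_slope = np.mean(slopes)
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(mean_slope) <= 3 * se + 1e-6
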