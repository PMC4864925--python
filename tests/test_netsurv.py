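"""Log-rank statistic, greedy module growth, and the permutation filter."""

import numpy as np
import pandas as pd
import pytest

from ptmdriver.errors import ConfigurationError
from ptmdriver.netsurv import (SurvivalCohort, build_graph, carriers_by_gene,
                               grow_module, hypermodules_search, logrank_test,
                               modules_frame, permutation_filter)

from oracles import logrank_oracle


def _random_cohort(rs, n):
    times = rs.exponential(50, n) + 0.5
    # force some ties to exercise the shared-risk-set convention
    times = np.round(times, 0) + 1.0
    events = (rs.random(n) < 0.7).astype(int)
    carriers = rs.random(n) < 0.4
    return carriers, times, events


class TestLogrank:
    def test_matches_from_definition_oracle_on_random_cohorts(self):
        """Agreement to 1e-8 with the per-event-time hypergeometric
        summation on small cohorts with tied event times."""
        rs = np.random.default_rng(21)
        checked = 0
        for _ in range(60):
            carriers, times, events = _random_cohort(rs, int(rs.integers(8, 50)))
            if carriers.all() or not carriers.any():
                continue
            stat, p = logrank_test(carriers, times, events)
            stat_o, p_o = logrank_oracle(carriers, times, events)
            if np.isnan(stat_o):
                assert np.isnan(stat)
                continue
            assert stat == pytest.approx(stat_o, abs=1e-8)
            assert p == pytest.approx(p_o, abs=1e-8)
            checked += 1
        assert checked >= 40

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rs = np.random.default_rng(22)
        for _ in range(20):
            carriers, times, events = _random_cohort(rs, 40)
            if carriers.all() or not carriers.any():
                continue
            stat, p = logrank_test(carriers, times, events)
            res = ll_logrank(times[carriers], times[~carriers],
                             event_observed_A=events[carriers],
                             event_observed_B=events[~carriers])
            assert stat == pytest.approx(res.test_statistic, rel=1e-9)
            assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_maximal_separation_is_significant(self):
        times = np.array([1.0] * 10 + [10.0] * 30)
        events = np.array([1] * 10 + [0] * 30)
        carriers = np.array([True] * 10 + [False] * 30)
        stat, p = logrank_test(carriers, times, events)
        assert p < 0.05

    def test_empty_group_returns_not_applicable(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 0])
        stat, p = logrank_test(np.zeros(3, dtype=bool), times, events)
        assert np.isnan(stat) and np.isnan(p)

    def test_no_events_returns_not_applicable(self):
        times = np.array([5.0, 6.0])
        events = np.array([0, 0])
        stat, p = logrank_test(np.array([True, False]), times, events)
        assert np.isnan(stat)

    def test_direction_sign_tracks_excess_carrier_events(self):
        times = np.array([1.0] * 8 + [20.0] * 20)
        events = np.ones(28, dtype=int)
        carriers = np.array([True] * 8 + [False] * 20)
        cohort = SurvivalCohort(times, events)
        _, _, direction = cohort.logrank(carriers)
        assert direction == 1  # early carrier deaths = reduced survival


def _line_graph_setup():
    """Nodes A-B-C-D in a path; A and B carry interleaved early deaths so
    their union separates survival better than either gene alone."""
    edges = pd.DataFrame({"protein_a": ["A", "B", "C"],
                          "protein_b": ["B", "C", "D"]})
    n = 40
    times = np.arange(1.0, n + 1.0)
    events = np.ones(n, dtype=int)
    carriers = {
        "A": np.zeros(n, dtype=bool), "B": np.zeros(n, dtype=bool),
        "C": np.zeros(n, dtype=bool), "D": np.zeros(n, dtype=bool)}
    carriers["A"][[0, 2, 4, 6, 8]] = True
    carriers["B"][[1, 3, 5, 7, 9]] = True
    carriers["C"][[20, 21]] = True
    cohort = SurvivalCohort(times, events)
    return edges, carriers, cohort


class TestGrowModule:
    def test_seed_without_neighbors_stays_alone(self):
        edges = pd.DataFrame({"protein_a": ["X"], "protein_b": ["Y"]})
        graph = build_graph(edges)
        graph.add_node("Z")
        times = np.arange(1.0, 21.0)
        events = np.ones(20, dtype=int)
        cohort = SurvivalCohort(times, events)
        carriers = {"Z": np.array([True] * 5 + [False] * 15)}
        mod = grow_module("Z", graph, carriers, cohort)
        assert mod.nodes == frozenset({"Z"})

    def test_unknown_seed_raises(self):
        edges, carriers, cohort = _line_graph_setup()
        with pytest.raises(KeyError):
            grow_module("MISSING", build_graph(edges), carriers, cohort)

    def test_neighbor_without_new_carriers_never_added(self):
        edges, carriers, cohort = _line_graph_setup()
        carriers["B"] = carriers["A"].copy()  # duplicates A's carriers
        graph = build_graph(edges)
        mod = grow_module("A", graph, carriers, cohort)
        assert "B" not in mod.nodes or mod.nodes == {"A"}

    def test_growth_collects_consistent_survival_signal(self):
        edges, carriers, cohort = _line_graph_setup()
        graph = build_graph(edges)
        mod = grow_module("A", graph, carriers, cohort)
        # B's carriers share the early-death pattern; C's do not help
        assert "B" in mod.nodes
        p_a_alone = cohort.logrank(carriers["A"])[1]
        assert mod.p_logrank < p_a_alone

    def test_growth_is_deterministic(self, small_bundle):
        from ptmdriver.mapping import classify_mutations
        ann = classify_mutations(small_bundle.mutations,
                                 small_bundle.proteome.sites,
                                 regions=small_bundle.proteome.merged_regions())
        surv = small_bundle.survival
        pidx = {p: i for i, p in enumerate(surv["patient_id"])}
        cohort = SurvivalCohort(surv["time"].to_numpy(float),
                                surv["event"].to_numpy(float))
        carriers = carriers_by_gene(ann, pidx, len(surv))
        graph = build_graph(small_bundle.network)
        seeds = [g for g in carriers if g in graph][:5]
        for seed in seeds:
            m1 = grow_module(seed, graph, carriers, cohort)
            m2 = grow_module(seed, graph, carriers, cohort)
            assert m1.nodes == m2.nodes
            assert m1.p_logrank == m2.p_logrank


class TestSearchAndFilter:
    def test_no_ptm_mutations_gives_empty_result(self, small_bundle):
        ann = small_bundle.mutations.copy()
        ann["category"] = "none"
        ann["region_id"] = ""
        mods = hypermodules_search(small_bundle.network, ann,
                                   small_bundle.survival)
        assert mods == []

    def test_duplicate_node_sets_deduplicated(self):
        edges, carriers, cohort = _line_graph_setup()
        surv = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(40)],
            "time": cohort.t[np.argsort(cohort._order)],
            "event": 1, "cancer_type": "T"})
        # classify-style annotation frame driving carriers: build directly
        ann_rows = []
        for gene, vec in carriers.items():
            for i in np.flatnonzero(vec):
                ann_rows.append({"sample_id": f"P{i}", "protein_id": gene,
                                 "position": 1, "ref_aa": "A", "alt_aa": "V",
                                 "cancer_type": "T", "category": "direct",
                                 "offset": 0, "nearest_site": 1,
                                 "site_types": "acetylation",
                                 "region_id": f"{gene}:1-8"})
        ann = pd.DataFrame(ann_rows)
        mods = hypermodules_search(edges, ann, surv, min_patients=5)
        node_sets = [m.nodes for m in mods]
        assert len(node_sets) == len(set(node_sets))

    def test_small_cancer_type_skipped(self, small_bundle):
        from ptmdriver.mapping import classify_mutations
        ann = classify_mutations(small_bundle.mutations,
                                 small_bundle.proteome.sites,
                                 regions=small_bundle.proteome.merged_regions())
        surv = small_bundle.survival.copy()
        mods = hypermodules_search(small_bundle.network, ann, surv,
                                   min_patients=10_000)
        assert mods == []

    def test_permutation_count_must_be_positive(self, small_bundle):
        with pytest.raises(ConfigurationError):
            permutation_filter([], small_bundle.network,
                               small_bundle.mutations, small_bundle.survival,
                               n_permutations=0)

    def test_add_one_rule_bounds_empirical_p(self, small_bundle, rng):
        from ptmdriver.mapping import classify_mutations
        ann = classify_mutations(small_bundle.mutations,
                                 small_bundle.proteome.sites,
                                 regions=small_bundle.proteome.merged_regions())
        mods = hypermodules_search(small_bundle.network, ann,
                                   small_bundle.survival,
                                   min_seed_carriers=3)
        filtered = permutation_filter(mods[:3], small_bundle.network, ann,
                                      small_bundle.survival,
                                      n_permutations=19,
                                      min_seed_carriers=3, rng=rng)
        for m in filtered:
            assert 1 / 20 <= m.p_empirical <= 1.0

    def test_modules_frame_columns(self, small_bundle, rng):
        from ptmdriver.mapping import classify_mutations
        ann = classify_mutations(small_bundle.mutations,
                                 small_bundle.proteome.sites,
                                 regions=small_bundle.proteome.merged_regions())
        mods = hypermodules_search(small_bundle.network, ann,
                                   small_bundle.survival,
                                   min_seed_carriers=3)
        df = modules_frame(mods)
        assert {"cancer_type", "nodes", "p_logrank", "direction",
                "p_empirical", "significant"} <= set(df.columns)
        assert (df["p_logrank"].to_numpy()[:-1]
                <= df["p_logrank"].to_numpy()[1:]).all()
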