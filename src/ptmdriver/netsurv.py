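"""Survival-correlated network module discovery.

A greedy search grows connected modules on the protein interaction
network: starting from a mutated seed gene, it repeatedly adds the
neighbouring gene whose carrier patients most improve the two-group
log-rank p value between module-mutation carriers and the rest of the
cohort, with strict improvement required and deterministic tie-breaking
(smallest p, then lexicographic gene id). Each cancer type is analysed
separately. Family-wise control over the search's selection effect uses
network-label-shuffling permutations: every permutation relabels the
gene<->node assignment (preserving topology and per-gene mutation
burden), reruns the full search, and records its best module p; a
module's empirical p is the add-one fraction of permutations whose best
p is at least as small.

Carriers are patients with at least one PTM-associated mutation
(direct/proximal/distal) in a module gene.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Module
from .errors import ConfigurationError, DegenerateInputError

_NA = (float("nan"), float("nan"))


class SurvivalCohort:
    """Pre-sorted survival data with a fast two-group log-rank test.

    The test uses the simultaneous-event (shared risk set) convention for
    ties: all events at one time contribute with the common risk set, and
    the variance term carries the multiple-event correction
    (n-d)/(n-1).
    """

    def __init__(self, times: np.ndarray, events: np.ndarray,
                 patient_ids: Optional[np.ndarray] = None):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=float)
        if (times <= 0).any():
            raise DegenerateInputError("survival times must be positive")
        self.n = times.size
        order = np.argsort(times, kind="stable")
        self._order = order
        self.t = times[order]
        self.e = events[order]
        self.patient_ids = (np.asarray(patient_ids)[order]
                            if patient_ids is not None else None)
        self.starts = np.flatnonzero(np.r_[True, self.t[1:] != self.t[:-1]])
        self.d = np.add.reduceat(self.e, self.starts)
        self.n_at_risk = (self.n - self.starts).astype(float)
        keep = (self.d > 0) & (self.n_at_risk > 1)
        self._ev = keep
        self._d_ev = self.d[keep]
        self._nr_ev = self.n_at_risk[keep]
        # (n-d)/(n-1) tie factor, fixed per event time
        self._tie = (self._nr_ev - self._d_ev) / (self._nr_ev - 1.0)

    def logrank(self, carrier: np.ndarray) -> tuple[float, float, int]:
        """Two-group log-rank chi-square (1 df) for carrier vs rest.

        Returns (statistic, p, direction); direction is +1 when carriers
        experience more events than expected (worse survival). NaNs when a
        group is empty or the variance degenerates.
        """
        g = carrier[self._order].astype(float)
        m = g.sum()
        if m == 0 or m == self.n:
            return _NA[0], _NA[1], 0
        cum = np.concatenate(([0.0], np.cumsum(g)))
        n1 = m - cum[self.starts]
        d1 = np.add.reduceat(self.e * g, self.starts)
        n1_ev = n1[self._ev]
        frac = n1_ev / self._nr_ev
        o_minus_e = float((d1[self._ev] - self._d_ev * frac).sum())
        var = float((self._d_ev * frac * (1.0 - frac) * self._tie).sum())
        if var <= 0:
            return _NA[0], _NA[1], 0
        statistic = o_minus_e * o_minus_e / var
        p = float(stats.chi2.sf(statistic, 1))
        return statistic, p, int(np.sign(o_minus_e))


def logrank_test(carrier_flags, times, events) -> tuple[float, float]:
    """Standalone two-group log-rank test; see SurvivalCohort.logrank."""
    cohort = SurvivalCohort(np.asarray(times), np.asarray(events))
    stat, p, _ = cohort.logrank(np.asarray(carrier_flags, dtype=bool))
    return stat, p


def carriers_by_gene(annotations: pd.DataFrame,
                     patient_index: Mapping[str, int],
                     n_patients: int) -> dict[str, np.ndarray]:
    """Boolean carrier vectors per gene from PTM-associated mutations."""
    out: dict[str, np.ndarray] = {}
    assoc = annotations[annotations["category"] != "none"]
    for gene, sub in assoc.groupby("protein_id"):
        vec = np.zeros(n_patients, dtype=bool)
        hit = False
        for s in sub["sample_id"]:
            j = patient_index.get(s)
            if j is not None:
                vec[j] = True
                hit = True
        if hit:
            out[gene] = vec
    return out


def grow_module(seed: str, graph: nx.Graph,
                gene_carriers: Mapping[str, np.ndarray],
                cohort: SurvivalCohort,
                cancer_type: str = "",
                max_size: int = 20) -> Module:
    """Greedy expansion from one seed gene.

    At each step the neighbour whose inclusion minimises the log-rank p is
    added, provided it strictly improves p (a neighbour contributing no new
    carriers cannot change p and is never added). Ties break to the
    lexicographically smallest gene id. Stops at ``max_size`` genes.
    """
    if seed not in graph:
        raise KeyError(f"seed gene {seed!r} is not in the network")
    current = {seed}
    carriers = gene_carriers.get(seed, np.zeros(cohort.n, dtype=bool)).copy()
    stat, p, direction = cohort.logrank(carriers)
    if np.isnan(p):
        p = 1.0
        stat = 0.0
    while len(current) < max_size:
        best_p, best_gene, best_stat, best_dir, best_car = np.inf, None, 0.0, 0, None
        frontier = sorted(set().union(*(graph.neighbors(u) for u in current))
                          - current)
        for cand in frontier:
            cvec = gene_carriers.get(cand)
            if cvec is None:
                continue
            new = carriers | cvec
            if new.sum() == carriers.sum():
                continue  # no new carriers: p cannot change
            s2, p2, d2 = cohort.logrank(new)
            if np.isnan(p2):
                continue
            if p2 < best_p:
                best_p, best_gene, best_stat, best_dir, best_car = \
                    p2, cand, s2, d2, new
        if best_gene is None or best_p >= p:
            break
        current.add(best_gene)
        carriers, p, stat, direction = best_car, best_p, best_stat, best_dir
    return Module(cancer_type=cancer_type, seed=seed, nodes=frozenset(current),
                  n_carriers=int(carriers.sum()), logrank_statistic=stat,
                  p_logrank=p, direction=direction)


def _search_one_cohort(graph: nx.Graph,
                       gene_carriers: Mapping[str, np.ndarray],
                       cohort: SurvivalCohort,
                       cancer_type: str,
                       max_size: int,
                       min_seed_carriers: int) -> list[Module]:
    seeds = sorted(g for g, v in gene_carriers.items()
                   if g in graph and int(v.sum()) >= min_seed_carriers)
    modules: dict[frozenset, Module] = {}
    for seed in seeds:
        mod = grow_module(seed, graph, gene_carriers, cohort,
                          cancer_type=cancer_type, max_size=max_size)
        prev = modules.get(mod.nodes)
        if prev is None or mod.p_logrank < prev.p_logrank:
            modules[mod.nodes] = mod
    return sorted(modules.values(), key=lambda m: (m.p_logrank, sorted(m.nodes)))


def build_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for a, b in zip(edges["protein_a"], edges["protein_b"]):
        if a != b:
            g.add_edge(a, b)
    return g


def hypermodules_search(edges: pd.DataFrame,
                        annotations: pd.DataFrame,
                        survival: pd.DataFrame,
                        max_size: int = 20,
                        min_seed_carriers: int = 1,
                        min_patients: int = 10) -> list[Module]:
    """One greedy run per eligible seed per cancer type; duplicate node
    sets deduplicated (keeping the best p); results sorted by p. Cancer
    types with fewer than ``min_patients`` patients are skipped."""
    graph = build_graph(edges)
    modules: list[Module] = []
    for cancer_type, sub in survival.groupby("cancer_type"):
        if len(sub) < min_patients:
            continue
        patient_index = {pid: j for j, pid in enumerate(sub["patient_id"])}
        cohort = SurvivalCohort(sub["time"].to_numpy(float),
                                sub["event"].to_numpy(float))
        gene_carriers = carriers_by_gene(annotations, patient_index, len(sub))
        modules.extend(_search_one_cohort(graph, gene_carriers, cohort,
                                          cancer_type, max_size,
                                          min_seed_carriers))
    return sorted(modules, key=lambda m: (m.p_logrank, m.cancer_type,
                                          sorted(m.nodes)))


def permutation_filter(modules: list[Module],
                       edges: pd.DataFrame,
                       annotations: pd.DataFrame,
                       survival: pd.DataFrame,
                       n_permutations: int = 100,
                       alpha: float = 0.05,
                       max_size: int = 20,
                       min_seed_carriers: int = 1,
                       min_patients: int = 10,
                       rng: Optional[np.random.Generator] = None
                       ) -> list[Module]:
    """Attach permutation empirical p values to observed modules.

    Each permutation relabels the gene<->node assignment on the network
    with a uniform random permutation of the node labels (topology and
    per-gene carrier sets are preserved; only their pairing changes),
    reruns the full greedy search, and records the best module p. A
    module's p_empirical is the add-one fraction of permutations whose
    best p <= the module's observed p; modules with p_empirical < alpha
    are marked significant.
    """
    if n_permutations < 1:
        raise ConfigurationError("n_network_permutations: must be >= 1")
    rng = rng or np.random.default_rng()
    graph = build_graph(edges)
    nodes = sorted(graph.nodes)

    best_by_type: dict[str, list[float]] = {}
    for cancer_type, sub in survival.groupby("cancer_type"):
        if len(sub) < min_patients:
            continue
        patient_index = {pid: j for j, pid in enumerate(sub["patient_id"])}
        cohort = SurvivalCohort(sub["time"].to_numpy(float),
                                sub["event"].to_numpy(float))
        gene_carriers = carriers_by_gene(annotations, patient_index, len(sub))
        bests = []
        for _ in range(n_permutations):
            perm = rng.permutation(len(nodes))
            relabel = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
            permuted = {relabel[g]: v for g, v in gene_carriers.items()
                        if g in relabel}
            found = _search_one_cohort(graph, permuted, cohort, cancer_type,
                                       max_size, min_seed_carriers)
            bests.append(min((m.p_logrank for m in found), default=1.0))
        best_by_type[cancer_type] = bests

    out = []
    for mod in modules:
        bests = best_by_type.get(mod.cancer_type)
        if bests is None:
            continue
        n_le = sum(1 for b in bests if b <= mod.p_logrank)
        p_emp = (1.0 + n_le) / (1.0 + len(bests))
        out.append(Module(cancer_type=mod.cancer_type, seed=mod.seed,
                          nodes=mod.nodes, n_carriers=mod.n_carriers,
                          logrank_statistic=mod.logrank_statistic,
                          p_logrank=mod.p_logrank, direction=mod.direction,
                          p_empirical=p_emp, significant=p_emp < alpha))
    return out


def modules_frame(modules: Iterable[Module]) -> pd.DataFrame:
    rows = [{"cancer_type": m.cancer_type, "seed": m.seed,
             "nodes": ",".join(sorted(m.nodes)), "n_nodes": len(m.nodes),
             "n_carriers": m.n_carriers,
             "logrank_statistic": m.logrank_statistic,
             "p_logrank": m.p_logrank, "direction": m.direction,
             "p_empirical": m.p_empirical, "significant": m.significant}
            for m in modules]
    return pd.DataFrame(rows, columns=["cancer_type", "seed", "nodes",
                                       "n_nodes", "n_carriers",
                                       "logrank_statistic", "p_logrank",
                                       "direction", "p_empirical",
                                       "significant"])
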