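"""Seeded synthetic proteomes, tumor cohorts, networks, and survival data.

The generator plants known ground truth so that every downstream stage of
the pipeline can be validated end to end:

* a proteome of lysine-bearing proteins with clustered acetylation /
  ubiquitination sites (a configurable fraction shared between the two
  PTM types), two-state disorder segments, Beta-distributed conservation
  with a mean uplift inside PTM regions, and random domain intervals;
* a tumor cohort with negative-binomially over-dispersed per-sample
  mutation burden plus a hypermutator tail, missense substitutions whose
  positions are uniform over residues except inside the PTM regions of
  planted driver genes, which are hit at a configured fold enrichment;
* boolean deleteriousness calls from a configurable number of independent
  predictors, with a higher per-call probability inside PTM regions;
* a sparse interaction network over modified proteins and a set of
  "enzyme" proteins, with one planted connected module;
* exponential survival times where carriers of PTM-region mutations in
  planted-module genes have their event hazard multiplied by the
  configured hazard ratio, with uniform-fraction censoring.

Randomness: each stage derives an independent stream from
``(config.seed, stage_index)``, so identical configurations reproduce
byte-identical bundles and stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AA20, ACETYL, UBIQ, SimulationConfig
from .datatypes import ProteinRecord, PTMSite, SyntheticTruth
from .errors import ConfigurationError, ConsistencyError
from .mapping import merge_regions, region_masks

_STAGE_PROTEOME = 0
_STAGE_TRUTH = 1
_STAGE_COHORT = 2
_STAGE_NETWORK = 3
_STAGE_GENESETS = 4

_NON_K = AA20.replace("K", "")
# row r: the 19 amino acids that are not AA20[r]
_ALT_TABLE = np.array([[aa for aa in AA20 if aa != ref] for ref in AA20])
_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


@dataclass
class Proteome:
    """Simulated (or loaded) protein records plus their PTM sites."""

    records: dict                      # protein_id -> ProteinRecord
    sites: list                        # list[PTMSite]

    @property
    def lengths(self) -> dict:
        return {pid: rec.length for pid, rec in self.records.items()}

    @property
    def protein_ids(self) -> list:
        return list(self.records)

    def ptm_bearing(self) -> list:
        return sorted({s.protein_id for s in self.sites})

    def merged_regions(self, window: int = 7):
        return merge_regions(self.sites, self.lengths, window=window)

    def region_mask_lookup(self, window: int = 7) -> dict:
        return region_masks(self.merged_regions(window), self.lengths)

    def sites_frame(self) -> pd.DataFrame:
        rows = [{"protein_id": s.protein_id, "position": s.position,
                 "ptm_types": ",".join(sorted(s.types)),
                 "source_15mer": s.source_15mer or ""}
                for s in self.sites]
        return pd.DataFrame(rows, columns=["protein_id", "position",
                                           "ptm_types", "source_15mer"])


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _disorder_track(length: int, rate: float, seg_mean: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Two-state segment process with stationary disordered fraction
    ``rate`` and mean disordered segment length ``seg_mean``."""
    if rate <= 0:
        return np.zeros(length, dtype=bool)
    if rate >= 1:
        return np.ones(length, dtype=bool)
    mask = np.zeros(length, dtype=bool)
    p_exit = 1.0 / seg_mean
    p_enter = p_exit * rate / (1.0 - rate)
    state = rng.random() < rate
    i = 0
    while i < length:
        p = p_exit if state else p_enter
        run = int(rng.geometric(min(1.0, p)))  # run length >= 1
        end = min(length, i + run)
        if state:
            mask[i:end] = True
        i = end
        state = not state
    return mask


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    mean = min(0.98, max(0.02, mean))
    return mean * concentration, (1.0 - mean) * concentration


def _choose_site_positions(k_positions: np.ndarray, rate: float,
                           cluster_strength: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Pick modified lysines with mild sequence clustering: a few anchor
    lysines attract sites in their neighbourhood."""
    n_k = k_positions.size
    if n_k == 0 or rate <= 0:
        return np.array([], dtype=int)
    n_sites = int(rng.binomial(n_k, min(1.0, rate)))
    if n_sites == 0:
        return np.array([], dtype=int)
    if n_sites >= n_k:
        return k_positions.copy()
    if cluster_strength > 0 and n_k > 3:
        n_anchors = max(1, n_k // 15)
        anchors = rng.choice(k_positions, size=n_anchors, replace=False)
        dist = np.abs(k_positions[:, None] - anchors[None, :]).min(axis=1)
        weights = 1.0 + cluster_strength * np.exp(-dist / 8.0)
    else:
        weights = np.ones(n_k)
    weights = weights / weights.sum()
    chosen = rng.choice(n_k, size=n_sites, replace=False, p=weights)
    return np.sort(k_positions[chosen])


def simulate_proteome(config: SimulationConfig) -> Proteome:
    """Generate protein sequences, PTM sites, and annotation tracks.

    Every emitted PTM site sits on a lysine; disorder and conservation
    tracks cover every residue; conservation lies in [0,1].
    """
    rng = _rng(config, _STAGE_PROTEOME)
    records: dict[str, ProteinRecord] = {}
    sites: list[PTMSite] = []
    width = max(4, len(str(config.n_proteins - 1)))

    for i in range(config.n_proteins):
        pid = f"P{i:0{width}d}"
        length = max(config.protein_length_min,
                     int(rng.poisson(config.protein_length_mean)))
        is_k = rng.random(length) < config.lysine_freq
        other = rng.choice(list(_NON_K), size=length)
        seq_arr = np.where(is_k, "K", other)
        sequence = "".join(seq_arr)

        k_positions = np.flatnonzero(is_k) + 1  # 1-based
        site_positions = _choose_site_positions(
            k_positions, config.ptm_site_rate, config.site_cluster_strength, rng)
        for pos in site_positions:
            if rng.random() < config.shared_site_rate:
                types = frozenset((ACETYL, UBIQ))
            elif rng.random() < config.acetyl_fraction:
                types = frozenset((ACETYL,))
            else:
                types = frozenset((UBIQ,))
            sites.append(PTMSite(protein_id=pid, position=int(pos), types=types))

        disorder = _disorder_track(length, config.disorder_segment_rate,
                                   config.disorder_segment_mean, rng)
        a0, b0 = _beta_params(0.5, config.conservation_concentration)
        conservation = rng.beta(a0, b0, size=length)
        # uplift conservation inside the merged PTM regions of this protein
        if site_positions.size:
            mask = np.zeros(length, dtype=bool)
            for pos in site_positions:
                mask[max(0, pos - 8):min(length, pos + 7)] = True
            a1, b1 = _beta_params(0.5 + config.conservation_ptm_shift,
                                  config.conservation_concentration)
            conservation[mask] = rng.beta(a1, b1, size=int(mask.sum()))

        domains = []
        n_dom = int(rng.poisson(config.domain_rate_per_kres * length / 1000.0))
        occupied = np.zeros(length, dtype=bool)
        for _ in range(n_dom):
            dlen = int(rng.integers(40, 121))
            if dlen >= length:
                continue
            start = int(rng.integers(1, length - dlen + 1))
            if occupied[start - 1:start + dlen - 1].any():
                continue
            occupied[start - 1:start + dlen - 1] = True
            domains.append((start, start + dlen - 1))
        domains.sort()

        records[pid] = ProteinRecord(protein_id=pid, sequence=sequence,
                                     disorder=disorder,
                                     conservation=conservation,
                                     domains=domains)
    return Proteome(records=records, sites=sites)


def make_truth(config: SimulationConfig, proteome: Proteome) -> SyntheticTruth:
    """Choose planted driver genes and a planted network module.

    Drivers are drawn uniformly from the PTM-bearing proteins. The module
    is planted on the most heavily modified proteins (largest total PTM-
    region length, excluding drivers), mirroring the heavily modified hub
    proteins (histones, ligases) that anchor survival modules in real
    interaction networks; this concentrates mutation carriers in the
    module genes relative to the background.
    """
    rng = _rng(config, _STAGE_TRUTH)
    bearing = proteome.ptm_bearing()
    n_drivers = min(config.n_driver_genes, len(bearing))
    drivers = sorted(str(g) for g in
                     rng.choice(bearing, size=n_drivers, replace=False)) \
        if n_drivers else []
    pool = [p for p in bearing if p not in set(drivers)]
    if len(pool) < config.planted_module_size:
        pool = bearing
    if len(pool) < config.planted_module_size:
        raise ConfigurationError(
            "planted_module_size: not enough PTM-bearing proteins to plant a module")
    region_length: dict[str, int] = {}
    for r in merge_regions(proteome.sites, proteome.lengths):
        region_length[r.protein_id] = region_length.get(r.protein_id, 0) \
            + r.length
    ranked = sorted(pool, key=lambda p: (-region_length.get(p, 0), p))
    module = frozenset(ranked[:config.planted_module_size])
    return SyntheticTruth(driver_genes=tuple(drivers),
                          planted_module=module,
                          planted_enrichment=config.driver_ptm_enrichment,
                          planted_hazard_ratio=config.module_hazard_ratio)


def _validate_truth(proteome: Proteome, truth: SyntheticTruth) -> None:
    known = set(proteome.records)
    unknown = (set(truth.driver_genes) | set(truth.planted_module)) - known
    if unknown:
        raise ConsistencyError(
            f"truth references unknown protein(s): {', '.join(sorted(unknown))}")


def simulate_cohort(config: SimulationConfig, proteome: Proteome,
                    truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a tumor cohort of missense mutations plus predictor calls.

    Per-sample burden ~ NegBin(mean=burden_mean, size=burden_dispersion);
    hypermutator samples have their burden multiplied. Mutation positions
    are uniform over residues, except that PTM-region residues of planted
    driver genes carry ``driver_ptm_enrichment``-fold weight. The
    reference amino acid always matches the sequence and the alternate is
    uniform over the 19 others, so every record is a missense substitution.

    Returns (mutations, predictor_calls). Mutations columns: sample_id,
    protein_id, position, ref_aa, alt_aa, cancer_type. Predictor calls
    carry the mutation key plus one boolean column per predictor.
    """
    if not proteome.records:
        raise ConsistencyError("proteome is empty")
    _validate_truth(proteome, truth)
    rng = _rng(config, _STAGE_COHORT)

    mut_cols = ["sample_id", "protein_id", "position", "ref_aa", "alt_aa",
                "cancer_type"]
    call_cols = [f"call_{k + 1}" for k in range(config.n_predictors)]
    if config.n_samples == 0:
        empty = pd.DataFrame(columns=mut_cols)
        return empty, pd.DataFrame(columns=mut_cols[:3] + ["alt_aa"] + call_cols)

    # per-sample burden
    m, k = config.burden_mean, config.burden_dispersion
    if m > 0:
        burdens = rng.negative_binomial(k, k / (k + m), size=config.n_samples)
    else:
        burdens = np.zeros(config.n_samples, dtype=int)
    if config.hypermutator_fraction > 0 and config.hypermutator_multiplier > 1:
        hyper = rng.random(config.n_samples) < config.hypermutator_fraction
        burdens = np.where(hyper,
                           (burdens * config.hypermutator_multiplier).astype(int),
                           burdens)
    sample_ids = np.array([f"S{j:04d}" for j in range(config.n_samples)])
    probs = config.cancer_type_probs
    cancer_types = rng.choice(np.array(config.cancer_types), size=config.n_samples,
                              p=np.array(probs) if probs is not None else None)

    # global residue table with driver PTM-region weights
    pids = proteome.protein_ids
    lengths = proteome.lengths
    masks = proteome.region_mask_lookup()
    driver_set = set(truth.driver_genes)
    res_pid = np.concatenate([np.repeat(i, lengths[pid])
                              for i, pid in enumerate(pids)])
    res_pos = np.concatenate([np.arange(1, lengths[pid] + 1) for pid in pids])
    weights = np.ones(res_pid.size)
    if config.driver_ptm_enrichment != 1.0 and driver_set:
        offset = 0
        for pid in pids:
            L = lengths[pid]
            if pid in driver_set:
                weights[offset:offset + L][masks[pid]] = config.driver_ptm_enrichment
            offset += L
    weights = weights / weights.sum()

    total = int(burdens.sum())
    if total == 0:
        empty = pd.DataFrame(columns=mut_cols)
        return empty, pd.DataFrame(columns=mut_cols[:3] + ["alt_aa"] + call_cols)
    residue_idx = rng.choice(res_pid.size, size=total, replace=True, p=weights)
    mut_sample = np.repeat(np.arange(config.n_samples), burdens)

    pid_arr = np.array(pids, dtype=object)[res_pid[residue_idx]]
    pos_arr = res_pos[residue_idx]
    seq_concat = "".join(proteome.records[pid].sequence for pid in pids)
    seq_arr = np.frombuffer(seq_concat.encode("ascii"), dtype="S1")
    ref_arr = seq_arr[residue_idx].astype("U1")
    ref_idx = np.array([_AA_INDEX[a] for a in ref_arr])
    alt_arr = _ALT_TABLE[ref_idx, rng.integers(0, 19, size=total)]

    mutations = pd.DataFrame({
        "sample_id": sample_ids[mut_sample],
        "protein_id": pid_arr,
        "position": pos_arr.astype(int),
        "ref_aa": ref_arr,
        "alt_aa": alt_arr,
        "cancer_type": cancer_types[mut_sample],
    })
    # a sample never carries the same substitution site twice
    mutations = mutations.drop_duplicates(
        subset=["sample_id", "protein_id", "position"]).reset_index(drop=True)

    in_region = np.fromiter(
        (masks[pid][pos - 1] for pid, pos in
         zip(mutations["protein_id"], mutations["position"])),
        dtype=bool, count=len(mutations))
    p_call = np.where(in_region, config.deleterious_prob_ptm,
                      config.deleterious_prob_background)
    calls = rng.random((len(mutations), config.n_predictors)) < p_call[:, None]
    predictors = mutations[["sample_id", "protein_id", "position", "alt_aa"]].copy()
    for j, col in enumerate(call_cols):
        predictors[col] = calls[:, j].astype(int)
    return mutations, predictors


def simulate_network_and_survival(
        config: SimulationConfig, proteome: Proteome, truth: SyntheticTruth,
        mutations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the interaction network and the patient survival table.

    Nodes are PTM-bearing proteins plus a random set of enzyme proteins;
    random edges are Bernoulli(network_edge_prob), and the planted module
    additionally receives a random spanning path so it is always
    connected. Patients carrying a PTM-region mutation in a planted-module
    gene have their exponential event hazard multiplied by
    ``module_hazard_ratio``; a ``censoring_rate`` fraction of patients is
    right-censored uniformly before their event.
    """
    _validate_truth(proteome, truth)
    if config.planted_module_size < 2:
        raise ConfigurationError("planted_module_size: must be >= 2")
    rng = _rng(config, _STAGE_NETWORK)

    bearing = proteome.ptm_bearing()
    non_bearing = sorted(set(proteome.records) - set(bearing))
    n_enz = int(round(config.enzyme_fraction * len(non_bearing)))
    enzymes = sorted(rng.choice(non_bearing, size=n_enz, replace=False)) \
        if n_enz else []
    nodes = sorted(set(bearing) | set(enzymes) | set(truth.planted_module))

    edges: set[tuple[str, str]] = set()
    n = len(nodes)
    if config.network_edge_prob > 0 and n > 1:
        iu, ju = np.triu_indices(n, k=1)
        draw = rng.random(iu.size) < config.network_edge_prob
        for a, b in zip(iu[draw], ju[draw]):
            edges.add((nodes[a], nodes[b]))
    # the planted module is wired like a protein complex: a spanning path
    # through a shuffled order guarantees connectivity, and additional
    # intra-module edges appear with module_internal_edge_prob
    module = sorted(truth.planted_module)
    order = rng.permutation(len(module))
    for a, b in zip(order[:-1], order[1:]):
        u, v = module[a], module[b]
        edges.add((min(u, v), max(u, v)))
    if config.module_internal_edge_prob > 0:
        for x in range(len(module)):
            for y in range(x + 1, len(module)):
                if rng.random() < config.module_internal_edge_prob:
                    edges.add((module[x], module[y]))
    edge_df = pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"])

    # survival
    samples = sorted({f"S{j:04d}" for j in range(config.n_samples)})
    sample_type = {f"S{j:04d}": None for j in range(config.n_samples)}
    if len(mutations):
        for s, ct in zip(mutations["sample_id"], mutations["cancer_type"]):
            sample_type[s] = ct
    # samples without mutations still need a cancer type label
    fallback = rng.choice(np.array(config.cancer_types), size=len(samples),
                          p=np.array(config.cancer_type_probs)
                          if config.cancer_type_probs is not None else None)
    masks = proteome.region_mask_lookup()
    carriers: set[str] = set()
    if len(mutations):
        in_module = mutations["protein_id"].isin(truth.planted_module)
        sub = mutations.loc[in_module]
        for s, pid, pos in zip(sub["sample_id"], sub["protein_id"],
                               sub["position"]):
            if masks[pid][pos - 1]:
                carriers.add(s)

    lam0 = np.log(2.0) / config.baseline_median_days
    rows = []
    for j, s in enumerate(samples):
        lam = lam0 * (config.module_hazard_ratio if s in carriers else 1.0)
        t_event = rng.exponential(1.0 / lam)
        censored = rng.random() < config.censoring_rate
        if censored:
            time = t_event * rng.random()
            event = 0
        else:
            time, event = t_event, 1
        rows.append({"patient_id": s,
                     "time": max(0.1, round(float(time), 2)),
                     "event": event,
                     "cancer_type": sample_type[s] or fallback[j]})
    survival = pd.DataFrame(rows, columns=["patient_id", "time", "event",
                                           "cancer_type"])
    return edge_df, survival


def simulate_gene_sets(config: SimulationConfig, proteome: Proteome,
                       truth: SyntheticTruth) -> dict[str, list]:
    """Random gene sets over PTM-bearing proteins, plus one planted set
    equal to the driver genes (the planted pathway signal) when enough
    drivers exist."""
    rng = _rng(config, _STAGE_GENESETS)
    bearing = proteome.ptm_bearing()
    lo, hi = config.geneset_size_range
    sets: dict[str, list] = {}
    width = max(3, len(str(max(1, config.n_gene_sets - 1))))
    for j in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(bearing))
        if size == 0:
            continue
        members = sorted(rng.choice(bearing, size=size, replace=False))
        sets[f"GS{j:0{width}d}"] = members
    if len(truth.driver_genes) >= 3:
        sets["GS_PLANTED"] = sorted(truth.driver_genes)
    return sets


@dataclass
class Bundle:
    """A full simulated dataset with its planted truth."""

    config: SimulationConfig
    proteome: Proteome
    truth: SyntheticTruth
    mutations: pd.DataFrame
    predictors: pd.DataFrame
    network: pd.DataFrame
    survival: pd.DataFrame
    gene_sets: dict


def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Run all generator stages with the config's seed."""
    proteome = simulate_proteome(config)
    truth = make_truth(config, proteome)
    mutations, predictors = simulate_cohort(config, proteome, truth)
    network, survival = simulate_network_and_survival(config, proteome, truth,
                                                      mutations)
    gene_sets = simulate_gene_sets(config, proteome, truth)
    return Bundle(config=config, proteome=proteome, truth=truth,
                  mutations=mutations, predictors=predictors,
                  network=network, survival=survival, gene_sets=gene_sets)
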