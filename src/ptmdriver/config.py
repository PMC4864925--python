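"""Configuration objects for the simulator and the analysis pipeline.

Positions are 1-based and all intervals are closed throughout the package:
a PTM region around a lysine at position p spans residues max(1, p-7) ..
min(L, p+7) inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Optional

from .errors import ConfigurationError

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

ACETYL = "acetylation"
UBIQ = "ubiquitination"
PTM_TYPES = (ACETYL, UBIQ)


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate, at reduced scale, a pan-cancer missense-mutation
    cohort over lysine-modified proteins: ~6 % lysine content, clustered
    acetylation/ubiquitination sites with an ~11 % shared-site fraction,
    negative-binomially over-dispersed per-sample mutation burden with a
    small hypermutator tail, a handful of driver genes whose PTM regions
    are mutated at a planted fold enrichment, a sparse interaction
    network with one planted survival-associated module, and exponential
    survival with a hazard multiplier for module-mutation carriers.
    """

    seed: int = 0
    # proteome
    n_proteins: int = 200
    protein_length_mean: float = 450.0
    protein_length_min: int = 60
    lysine_freq: float = 0.058
    ptm_site_rate: float = 0.15
    acetyl_fraction: float = 0.25       # acetylation share among single-type sites
    shared_site_rate: float = 0.11      # P(site carries both PTM types)
    site_cluster_strength: float = 3.0  # >0 concentrates sites near anchor lysines
    disorder_segment_rate: float = 0.25  # stationary fraction of disordered residues
    disorder_segment_mean: float = 30.0  # mean disordered segment length (residues)
    conservation_ptm_shift: float = 0.10  # mean conservation uplift inside PTM regions
    conservation_concentration: float = 8.0  # Beta concentration (a+b)
    domain_rate_per_kres: float = 3.0   # expected domains per 1000 residues
    # cohort
    n_samples: int = 300
    burden_mean: float = 40.0           # mutations per sample on this proteome
    burden_dispersion: float = 2.0      # NB size parameter k; var = m + m^2/k
    hypermutator_fraction: float = 0.03
    hypermutator_multiplier: float = 20.0
    n_driver_genes: int = 5
    driver_ptm_enrichment: float = 3.0  # fold uplift of PTM-region rate in drivers
    deleterious_prob_ptm: float = 0.35
    deleterious_prob_background: float = 0.20
    n_predictors: int = 5
    cancer_types: tuple = ("LUAD",)
    cancer_type_probs: Optional[tuple] = None
    # network + survival
    network_edge_prob: float = 0.02
    enzyme_fraction: float = 0.10       # non-modified proteins flagged as PTM enzymes
    module_internal_edge_prob: float = 0.4  # density of the planted module
    planted_module_size: int = 8
    module_hazard_ratio: float = 3.0
    baseline_median_days: float = 1000.0
    censoring_rate: float = 0.30
    # gene sets
    n_gene_sets: int = 50
    geneset_size_range: tuple = (5, 30)

    def __post_init__(self):
        probs = {
            "lysine_freq": self.lysine_freq,
            "ptm_site_rate": self.ptm_site_rate,
            "acetyl_fraction": self.acetyl_fraction,
            "shared_site_rate": self.shared_site_rate,
            "disorder_segment_rate": self.disorder_segment_rate,
            "hypermutator_fraction": self.hypermutator_fraction,
            "deleterious_prob_ptm": self.deleterious_prob_ptm,
            "deleterious_prob_background": self.deleterious_prob_background,
            "network_edge_prob": self.network_edge_prob,
            "module_internal_edge_prob": self.module_internal_edge_prob,
            "enzyme_fraction": self.enzyme_fraction,
            "censoring_rate": self.censoring_rate,
        }
        for name, v in probs.items():
            _check(0.0 <= v <= 1.0, name, f"must be a probability in [0,1], got {v}")
        counts = {
            "n_proteins": self.n_proteins,
            "planted_module_size": self.planted_module_size,
            "n_predictors": self.n_predictors,
        }
        for name, v in counts.items():
            _check(v >= 1, name, f"must be >= 1, got {v}")
        _check(self.n_samples >= 0, "n_samples", "must be >= 0")
        _check(self.n_driver_genes >= 0, "n_driver_genes", "must be >= 0")
        _check(self.n_gene_sets >= 0, "n_gene_sets", "must be >= 0")
        _check(self.module_hazard_ratio > 0, "module_hazard_ratio", "must be > 0")
        _check(self.driver_ptm_enrichment > 0, "driver_ptm_enrichment", "must be > 0")
        _check(self.burden_mean >= 0, "burden_mean", "must be >= 0")
        _check(self.burden_dispersion > 0, "burden_dispersion", "must be > 0")
        _check(self.hypermutator_multiplier >= 1, "hypermutator_multiplier", "must be >= 1")
        _check(self.protein_length_min >= 15, "protein_length_min", "must be >= 15")
        _check(self.planted_module_size >= 2, "planted_module_size",
               "a module needs at least 2 proteins")
        _check(self.planted_module_size <= self.n_proteins, "planted_module_size",
               "cannot exceed n_proteins")
        _check(0 < self.conservation_ptm_shift + 0.5 < 1.0 or self.conservation_ptm_shift >= 0,
               "conservation_ptm_shift", "must keep the shifted mean inside (0,1)")
        if self.cancer_type_probs is not None:
            _check(len(self.cancer_type_probs) == len(self.cancer_types),
                   "cancer_type_probs", "length must match cancer_types")
            _check(abs(sum(self.cancer_type_probs) - 1.0) < 1e-9,
                   "cancer_type_probs", "must sum to 1")
        lo, hi = self.geneset_size_range
        _check(1 <= lo <= hi, "geneset_size_range", "must satisfy 1 <= lo <= hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cancer_types"] = list(self.cancer_types)
        d["geneset_size_range"] = list(self.geneset_size_range)
        if self.cancer_type_probs is not None:
            d["cancer_type_probs"] = list(self.cancer_type_probs)
        return d


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the analysis pipeline.

    The defaults encode the study design: a ±7-residue flanking window
    around modified lysines, direct/proximal/distal mutation categories at
    offsets {0}/{1,2}/{3..7}, one-sided resampling tests with 100,000
    shuffles, 100 mutation-frequency bins for the known-cancer-gene
    permutation test, 100 network-shuffling permutations for module
    significance, Benjamini-Hochberg FDR at 0.05, gene-set size bounds
    (3..1000 modified proteins), at least two separately mutated proteins
    per reported gene set, and hotspots defined as regions with more than
    five mutations.
    """

    window: int = 7
    proximal_range: tuple = (1, 2)
    distal_range: tuple = (3, 7)
    n_shuffles: int = 100_000
    n_bins: int = 100
    n_gene_permutations: int = 100_000   # 1e7 at full study scale; scalable
    n_network_permutations: int = 100
    fdr_alpha: float = 0.05
    geneset_min: int = 3
    geneset_max: int = 1000
    min_mutated_proteins: int = 2
    hotspot_min_snvs: int = 6            # "more than five" mutations
    hypermutation_rule: str = "mad"      # "mad" | "none"
    hypermutation_param: float = 3.0
    max_module_size: int = 20
    min_seed_carriers: int = 1
    min_patients_per_type: int = 10
    overlap_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        _check(self.window >= 1, "window", "must be >= 1")
        _check(self.window >= max(self.distal_range), "window",
               "must be >= the largest distal offset")
        prox = set(range(self.proximal_range[0], self.proximal_range[1] + 1))
        dist = set(range(self.distal_range[0], self.distal_range[1] + 1))
        _check(not (prox & dist), "proximal_range",
               "proximal and distal offset ranges must be disjoint")
        _check(0 not in prox | dist, "proximal_range",
               "offset 0 is reserved for direct mutations")
        _check(self.geneset_min <= self.geneset_max, "geneset_min",
               "must be <= geneset_max")
        for name in ("n_shuffles", "n_bins", "n_gene_permutations",
                     "n_network_permutations", "hotspot_min_snvs",
                     "max_module_size"):
            _check(getattr(self, name) >= 1, name, "must be >= 1")
        _check(0 < self.fdr_alpha < 1, "fdr_alpha", "must be in (0,1)")
        _check(self.hypermutation_rule in ("mad", "none"), "hypermutation_rule",
               "must be one of 'mad', 'none'")
        _check(0 < self.overlap_threshold <= 1, "overlap_threshold",
               "must be in (0,1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["proximal_range"] = list(self.proximal_range)
        d["distal_range"] = list(self.distal_range)
        return d


def config_from_mapping(cls, mapping: dict):
    """Build a SimulationConfig or AnalysisConfig from a plain dict
    (e.g. parsed YAML), rejecting unknown keys."""
    valid = {f.name for f in fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown configuration field(s): {', '.join(sorted(unknown))}")
    kwargs = dict(mapping)
    for key in ("cancer_types", "cancer_type_probs", "geneset_size_range",
                "proximal_range", "distal_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)
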