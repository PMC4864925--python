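"""Core in-memory records shared by all analysis stages.

Tabular data (mutations, annotations, results) travel as pandas
DataFrames with documented column sets; the small structured records
below carry per-protein state and statistical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class ProteinRecord:
    """One protein isoform with optional per-residue annotation tracks.

    ``disorder`` and ``conservation`` are arrays of length ``len(sequence)``
    indexed 0-based internally; all public positions are 1-based.
    ``domains`` is a list of closed 1-based intervals.
    """

    protein_id: str
    sequence: str
    disorder: Optional[np.ndarray] = None       # bool, len == len(sequence)
    conservation: Optional[np.ndarray] = None   # float in [0,1]
    domains: list = field(default_factory=list)  # [(start, end), ...] closed, 1-based

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        return self.sequence[position - 1]

    def domain_mask(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        for start, end in self.domains:
            mask[start - 1:end] = True
        return mask


@dataclass(frozen=True)
class PTMSite:
    """A modified lysine. ``types`` is a frozenset over
    {'acetylation', 'ubiquitination'}; a site carrying both is a shared
    (combinatorial) site."""

    protein_id: str
    position: int                      # 1-based; sequence[position] == 'K'
    types: frozenset
    source_15mer: Optional[str] = None

    @property
    def shared(self) -> bool:
        return len(self.types) == 2


@dataclass(frozen=True)
class PTMRegion:
    """A maximal merged interval of overlapping ±window site flanks,
    clipped to the protein. Closed 1-based interval."""

    protein_id: str
    start: int
    end: int
    member_positions: tuple            # central lysine positions inside
    types: frozenset                   # union of member site types

    @property
    def region_id(self) -> str:
        return f"{self.protein_id}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class EnrichmentResult:
    """Observed vs resampled mutation counts with an empirical p value.

    ``fold_change`` is the per-residue mutation rate inside the tested
    sequence class divided by the rate outside it (NaN when not
    applicable). ``p_empirical`` uses the add-one rule and is therefore
    never 0 and never below 1/(n_shuffles+1).
    """

    label: str
    observed: int
    expected: float
    fold_change: float
    p_empirical: float
    n_shuffles: int
    stratum: Optional[str] = None
    applicable: bool = True
    note: str = ""


@dataclass
class ContingencyResult:
    """A 2x2 table with a one-sided Fisher exact p value. The odds ratio
    uses a 0.5 continuity substitution only when a zero cell occurs, and
    that substitution is reported via ``continuity_corrected``."""

    table: np.ndarray
    odds_ratio: float
    p: float
    sidedness: str = "greater"
    continuity_corrected: bool = False


@dataclass
class GeneModel:
    """Per-gene active-site mutation model under the disorder-only null.

    ``expected`` is the sum of fitted per-residue Poisson means over
    PTM-region residues; ``observed`` the PTM-region mutation count,
    broken down by direct/proximal/distal offset category.
    """

    gene: str
    length: int
    n_mutations: int
    region_length: int
    expected: float
    observed: int
    obs_direct: int
    obs_proximal: int
    obs_distal: int
    p: float
    fdr: float = float("nan")
    uniform_fallback: bool = False
    note: str = ""


@dataclass
class CancerGeneEnrichment:
    """Mutation-frequency-matched permutation test of the overlap between
    detected genes and a known cancer-gene list."""

    observed_overlap: int
    null_mean: float
    empirical_p: float
    n_bins: int
    n_permutations: int
    merged_bins: bool = False


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of a simulated bundle."""

    driver_genes: tuple
    planted_module: frozenset
    planted_enrichment: float
    planted_hazard_ratio: float

    def to_dict(self) -> dict:
        return {
            "driver_genes": list(self.driver_genes),
            "planted_module": sorted(self.planted_module),
            "planted_enrichment": self.planted_enrichment,
            "planted_hazard_ratio": self.planted_hazard_ratio,
        }


@dataclass
class Module:
    """A connected network module with a two-group log-rank survival
    contrast between carrier and non-carrier patients.

    ``direction`` is +1 when carriers have more events than expected
    (reduced survival), -1 otherwise, 0 for a degenerate contrast.
    """

    cancer_type: str
    seed: str
    nodes: frozenset
    n_carriers: int
    logrank_statistic: float
    p_logrank: float
    direction: int
    p_empirical: float = float("nan")
    significant: bool = False
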