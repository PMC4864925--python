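"""PTM-site mapping, region merging, and mutation classification.

Sites arrive either position-resolved or as 15-mer sequence windows
(central lysine ± 7 flanking residues, '_' padding at protein termini).
15-mers are matched exactly; every exact occurrence in a protein yields a
site and partially matching 15-mers are discarded.

Mutations are classified by their offset to the nearest modified lysine
of the same protein: 0 = direct, 1-2 = proximal, 3-7 = distal, otherwise
none. All positions are 1-based, all intervals closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import ProteinRecord, PTMSite, PTMRegion
from .errors import DegenerateInputError

PAD = "_"
CATEGORY_NONE = "none"
CATEGORIES = ("direct", "proximal", "distal", CATEGORY_NONE)


@dataclass
class MappingReport:
    """Counts of records rejected while mapping site tables."""

    n_input: int = 0
    n_mapped: int = 0
    rejected_non_central_k: int = 0
    rejected_no_match: int = 0
    rejected_bad_position: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _padded(sequence: str, window: int = 7) -> str:
    return PAD * window + sequence + PAD * window


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx
        start = idx + 1


def map_sites(site_records: pd.DataFrame,
              proteome: Mapping[str, ProteinRecord],
              window: int = 7) -> tuple[list[PTMSite], MappingReport]:
    """Resolve a site table to validated PTMSite objects.

    ``site_records`` columns: protein_id, ptm_type, and either
    ``source_15mer`` (a 15-character window, '_'-padded at termini, central
    residue K) or ``position`` (1-based lysine position). Rows with a
    15-mer are mapped by exact substring search against the '_'-padded
    protein sequence; every exact occurrence yields a site. Rows with a
    position are validated against the sequence (must be K, in bounds).

    Output is deduplicated by (protein, position); PTM types of duplicate
    records are unioned.
    """
    report = MappingReport(n_input=len(site_records))
    found: dict[tuple[str, int], set] = {}
    fifteen: dict[tuple[str, int], str] = {}
    size = 2 * window + 1

    for row in site_records.itertuples(index=False):
        pid = row.protein_id
        record = proteome.get(pid)
        if record is None:
            report.rejected_no_match += 1
            continue
        ptype = row.ptm_type
        mer = getattr(row, "source_15mer", None)
        if isinstance(mer, str) and mer:
            if len(mer) != size or mer[window] != "K":
                report.rejected_non_central_k += 1
                continue
            hits = list(_find_all(_padded(record.sequence, window), mer))
            if not hits:
                report.rejected_no_match += 1
                continue
            for idx in hits:
                pos = idx + 1  # padded index i -> central residue 1-based i+1
                key = (pid, pos)
                found.setdefault(key, set()).add(ptype)
                fifteen[key] = mer
        else:
            pos = int(row.position)
            if pos < 1 or pos > record.length:
                report.rejected_bad_position += 1
                continue
            if record.residue(pos) != "K":
                report.rejected_non_central_k += 1
                continue
            found.setdefault((pid, pos), set()).add(ptype)

    sites = [PTMSite(protein_id=pid, position=pos, types=frozenset(types),
                     source_15mer=fifteen.get((pid, pos)))
             for (pid, pos), types in sorted(found.items())]
    report.n_mapped = len(sites)
    return sites, report


def merge_regions(sites: Iterable[PTMSite],
                  protein_lengths: Mapping[str, int],
                  window: int = 7) -> list[PTMRegion]:
    """Merge per-site closed windows [p-window, p+window], clipped to
    [1, length], into maximal disjoint intervals per protein.

    Regions of one protein come out sorted and pairwise disjoint; member
    central-lysine positions and the union of their PTM types are kept.
    """
    by_protein: dict[str, list[PTMSite]] = {}
    for s in sites:
        by_protein.setdefault(s.protein_id, []).append(s)

    regions: list[PTMRegion] = []
    for pid in sorted(by_protein):
        length = protein_lengths[pid]
        members = sorted(by_protein[pid], key=lambda s: s.position)
        cur_start = cur_end = None
        cur_members: list[PTMSite] = []
        for s in members:
            start = max(1, s.position - window)
            end = min(length, s.position + window)
            if cur_start is None:
                cur_start, cur_end, cur_members = start, end, [s]
            elif start <= cur_end:  # windows overlap -> merge
                cur_end = max(cur_end, end)
                cur_members.append(s)
            else:
                regions.append(_make_region(pid, cur_start, cur_end, cur_members))
                cur_start, cur_end, cur_members = start, end, [s]
        if cur_start is not None:
            regions.append(_make_region(pid, cur_start, cur_end, cur_members))
    return regions


def _make_region(pid: str, start: int, end: int, members: list[PTMSite]) -> PTMRegion:
    types = frozenset().union(*(s.types for s in members))
    return PTMRegion(protein_id=pid, start=start, end=end,
                     member_positions=tuple(s.position for s in members),
                     types=types)


def region_masks(regions: Iterable[PTMRegion],
                 protein_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Per-protein boolean arrays (0-based) marking PTM-region residues."""
    masks = {pid: np.zeros(length, dtype=bool)
             for pid, length in protein_lengths.items()}
    for r in regions:
        masks[r.protein_id][r.start - 1:r.end] = True
    return masks


def classify_offset(offset: int,
                    proximal=(1, 2), distal=(3, 7)) -> str:
    """Category of a mutation at absolute offset ``offset`` from the
    nearest modified lysine."""
    o = abs(int(offset))
    if o == 0:
        return "direct"
    if proximal[0] <= o <= proximal[1]:
        return "proximal"
    if distal[0] <= o <= distal[1]:
        return "distal"
    return CATEGORY_NONE


def classify_mutations(mutations: pd.DataFrame,
                       sites: Iterable[PTMSite],
                       regions: Optional[list[PTMRegion]] = None,
                       protein_lengths: Optional[Mapping[str, int]] = None,
                       proximal=(1, 2), distal=(3, 7),
                       window: int = 7) -> pd.DataFrame:
    """Annotate every mutation with its PTM category.

    Returns the input frame plus columns: ``category`` (direct / proximal /
    distal / none), ``offset`` (signed distance to the nearest site, NaN if
    no site on the protein), ``nearest_site`` (1-based position),
    ``site_types`` (comma-joined union over all tied nearest sites), and
    ``region_id`` (the merged region containing the mutation, if any).

    Classification uses the minimal |position - site| over same-protein
    sites; equidistant flanking sites have their types unioned.
    """
    sites = list(sites)
    site_pos: dict[str, np.ndarray] = {}
    site_types: dict[str, list[frozenset]] = {}
    for pid, group in _group_sites(sites).items():
        group.sort(key=lambda s: s.position)
        site_pos[pid] = np.array([s.position for s in group])
        site_types[pid] = [s.types for s in group]

    if regions is None:
        if protein_lengths is None:
            # regions only needed for region_id; infer lengths loosely
            protein_lengths = {}
        regions = merge_regions(sites, protein_lengths, window=window) \
            if protein_lengths else []
    region_lookup: dict[str, list[PTMRegion]] = {}
    for r in regions:
        region_lookup.setdefault(r.protein_id, []).append(r)

    n = len(mutations)
    category = np.full(n, CATEGORY_NONE, dtype=object)
    offset = np.full(n, np.nan)
    nearest = np.full(n, np.nan)
    types_col = np.full(n, "", dtype=object)
    region_col = np.full(n, "", dtype=object)

    for i, row in enumerate(mutations.itertuples(index=False)):
        pid = row.protein_id
        pos = int(row.position)
        positions = site_pos.get(pid)
        if positions is not None and positions.size:
            dists = np.abs(positions - pos)
            dmin = int(dists.min())
            tied = np.flatnonzero(dists == dmin)
            offset[i] = int(pos - positions[tied[0]])
            nearest[i] = int(positions[tied[0]])
            category[i] = classify_offset(dmin, proximal, distal)
            union = frozenset().union(*(site_types[pid][j] for j in tied))
            types_col[i] = ",".join(sorted(union))
        for r in region_lookup.get(pid, ()):
            if r.start <= pos <= r.end:
                region_col[i] = r.region_id
                break

    out = mutations.copy()
    out["category"] = category
    out["offset"] = offset
    out["nearest_site"] = nearest
    out["site_types"] = types_col
    out["region_id"] = region_col
    return out


def _group_sites(sites: Iterable[PTMSite]) -> dict[str, list[PTMSite]]:
    grouped: dict[str, list[PTMSite]] = {}
    for s in sites:
        grouped.setdefault(s.protein_id, []).append(s)
    return grouped


@dataclass
class FilterReport:
    """Outcome of hypermutated-sample filtering."""

    rule: str
    parameter: float
    flagged_samples: list = field(default_factory=list)
    flagged_burdens: dict = field(default_factory=dict)
    threshold: float = float("nan")
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_mutations_removed: int = 0


def filter_cohort(mutations: pd.DataFrame,
                  rule: str = "mad",
                  parameter: float = 3.0) -> tuple[pd.DataFrame, FilterReport]:
    """Remove hypermutated samples before analysis.

    The default rule flags samples whose log10 mutation burden exceeds the
    cohort median by more than ``parameter`` median absolute deviations
    (strict inequality, so a constant-burden cohort flags nothing).
    ``rule='none'`` returns the input unchanged.
    """
    report = FilterReport(rule=rule, parameter=parameter)
    burdens = mutations.groupby("sample_id").size()
    report.n_samples_in = len(burdens)
    if rule == "none" or burdens.empty:
        report.n_samples_out = report.n_samples_in
        return mutations, report
    if rule != "mad":
        raise DegenerateInputError(f"unknown hypermutation rule: {rule!r}")
    lb = np.log10(burdens.to_numpy(dtype=float))
    med = float(np.median(lb))
    mad = float(np.median(np.abs(lb - med)))
    threshold = med + parameter * mad
    report.threshold = threshold
    flagged = burdens.index[lb > threshold]
    report.flagged_samples = sorted(flagged)
    report.flagged_burdens = {s: int(burdens[s]) for s in report.flagged_samples}
    keep = ~mutations["sample_id"].isin(flagged)
    report.n_mutations_removed = int((~keep).sum())
    report.n_samples_out = report.n_samples_in - len(report.flagged_samples)
    return mutations.loc[keep].reset_index(drop=True), report
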