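"""Gene-set level Poisson exact enrichment of PTM-region mutations.

Only proteins with PTM sites take part. The background per-residue rate
is total PTM-region mutations divided by total PTM-region length over
the union of all pathway-annotated, PTM-bearing proteins; each set's
expected count is that rate times the set's summed PTM-region length,
and significance is the exact upper-tail Poisson probability. Sets are
dropped when they have fewer than ``geneset_min`` or more than
``geneset_max`` PTM-bearing members, or fewer than
``min_mutated_proteins`` separately mutated member proteins (guarding
against single-driver artefacts). Benjamini-Hochberg FDR is applied over
the tested sets.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import FormatError
from .stats_util import bh_fdr, poisson_upper_tail


def poisson_exact_test(observed: int, lam: float) -> float:
    """Exact upper-tail Poisson probability P(X >= observed | lam)."""
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    return poisson_upper_tail(observed, lam)


def _per_protein_region_stats(annotations: pd.DataFrame, regions
                              ) -> tuple[dict, dict]:
    region_len: dict[str, int] = {}
    for r in regions:
        region_len[r.protein_id] = region_len.get(r.protein_id, 0) + r.length
    in_region = annotations[annotations["region_id"] != ""]
    region_muts = in_region.groupby("protein_id").size().to_dict()
    return region_len, region_muts


def test_gene_sets(gene_sets: Mapping[str, list],
                   annotations: pd.DataFrame,
                   regions,
                   geneset_min: int = 3,
                   geneset_max: int = 1000,
                   min_mutated_proteins: int = 2,
                   rate_mode: str = "length",
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every gene set for enrichment of PTM-region mutations.

    ``rate_mode='length'`` uses the per-residue background rate times set
    PTM-region length (default); ``'protein'`` uses a per-protein rate
    times the number of PTM-bearing members.

    Returns (results, dropped): results has one row per tested set with
    observed, expected, p, fdr and n_mutated_proteins; dropped lists the
    sets that failed a filter together with the reason.
    """
    if not gene_sets:
        raise FormatError("gene-set collection is empty")
    region_len, region_muts = _per_protein_region_stats(annotations, regions)
    bearing = set(region_len)

    effective: dict[str, list] = {}
    dropped_rows = []
    for set_id, members in gene_sets.items():
        eff = sorted(set(members) & bearing)
        if len(eff) < geneset_min:
            dropped_rows.append({"set_id": set_id,
                                 "reason": "fewer PTM-bearing members than "
                                           f"geneset_min={geneset_min}"})
            continue
        if len(eff) > geneset_max:
            dropped_rows.append({"set_id": set_id,
                                 "reason": f"more than geneset_max={geneset_max}"
                                           " PTM-bearing members"})
            continue
        effective[set_id] = eff

    universe = sorted(set().union(*effective.values())) if effective else []
    total_len = sum(region_len[p] for p in universe)
    total_mut = sum(region_muts.get(p, 0) for p in universe)
    if total_len == 0 or total_mut == 0:
        return (pd.DataFrame(columns=["set_id", "n_members", "observed",
                                      "expected", "n_mutated_proteins", "p",
                                      "fdr"]),
                pd.DataFrame(dropped_rows, columns=["set_id", "reason"]))
    bg_rate = total_mut / total_len
    bg_rate_per_protein = total_mut / len(universe)

    rows = []
    for set_id, eff in effective.items():
        observed = int(sum(region_muts.get(p, 0) for p in eff))
        n_mutated = int(sum(1 for p in eff if region_muts.get(p, 0) > 0))
        if n_mutated < min_mutated_proteins:
            dropped_rows.append({"set_id": set_id,
                                 "reason": "fewer than "
                                           f"{min_mutated_proteins} separately"
                                           " mutated proteins"})
            continue
        if rate_mode == "length":
            lam = bg_rate * sum(region_len[p] for p in eff)
        elif rate_mode == "protein":
            lam = bg_rate_per_protein * len(eff)
        else:
            raise ValueError(f"unknown rate_mode {rate_mode!r}")
        rows.append({"set_id": set_id, "n_members": len(eff),
                     "observed": observed, "expected": lam,
                     "n_mutated_proteins": n_mutated,
                     "p": poisson_exact_test(observed, lam)})
    results = pd.DataFrame(rows, columns=["set_id", "n_members", "observed",
                                          "expected", "n_mutated_proteins",
                                          "p"])
    if len(results):
        results["fdr"] = bh_fdr(results["p"].to_numpy())
        results = results.sort_values(["p", "set_id"],
                                      kind="stable").reset_index(drop=True)
    else:
        results["fdr"] = pd.Series(dtype=float)
    dropped = pd.DataFrame(dropped_rows, columns=["set_id", "reason"])
    return results, dropped


def overlap_coefficient(a: set, b: set) -> float:
    """|A ∩ B| / min(|A|, |B|); 1.0 for nested sets, 0.0 when disjoint."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def enrichment_map_export(results: pd.DataFrame,
                          gene_sets: Mapping[str, list],
                          alpha: float = 0.05,
                          threshold: float = 0.5
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the enrichment map.

    Nodes are significant sets (FDR < alpha); edges connect pairs whose
    overlap coefficient reaches ``threshold``.
    """
    sig = results[results["fdr"] < alpha]
    nodes = sig[["set_id", "n_members", "observed", "expected", "p",
                 "fdr"]].reset_index(drop=True)
    ids = list(nodes["set_id"])
    member_sets = {sid: set(gene_sets[sid]) for sid in ids}
    edge_rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sim = overlap_coefficient(member_sets[a], member_sets[b])
            if sim >= threshold:
                edge_rows.append({"set_a": a, "set_b": b,
                                  "similarity": round(sim, 6)})
    edges = pd.DataFrame(edge_rows, columns=["set_a", "set_b", "similarity"])
    return nodes, edges
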