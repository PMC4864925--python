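"""Per-gene active-site mutation significance and related gene-level tests.

The gene model regresses per-residue mutation counts on the protein's
disorder track under a Poisson log-link null (no PTM terms). The expected
PTM-region count E is the sum of fitted per-residue means over region
residues, the observed count O is the number of mutations falling in the
regions, and the gene p value is the exact upper-tail Poisson probability
P(X >= O | E). Degenerate designs (constant disorder) and non-converging
fits fall back to the uniform per-residue rate total/length, flagged in
the output.

Also here: recurrent PTM hotspot detection (regions with more than five
mutations) and the mutation-frequency-binned permutation test for
enrichment of known cancer genes among detected genes.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import (CancerGeneEnrichment, GeneModel, ProteinRecord,
                        PTMSite)
from .errors import ConsistencyError
from .mapping import merge_regions, region_masks
from .stats_util import bh_fdr, empirical_p, poisson_upper_tail

_TINY_P = 5e-324  # smallest subnormal double; flagged when used


def fit_gene_model(record: ProteinRecord,
                   sites: Iterable[PTMSite],
                   mutations: pd.DataFrame,
                   window: int = 7,
                   central_only: bool = False,
                   proximal=(1, 2), distal=(3, 7)) -> GeneModel:
    """Fit the disorder-only Poisson null for one gene and score its
    PTM-region mutation count.

    ``central_only`` restricts the scored residues to the modified lysines
    themselves (the flanking-window-free variant of the analysis).
    """
    sites = [s for s in sites if s.protein_id == record.protein_id]
    if not sites:
        raise ConsistencyError(f"{record.protein_id}: gene has no PTM sites")
    L = record.length
    positions = mutations.loc[mutations["protein_id"] == record.protein_id,
                              "position"].to_numpy(int)
    y = np.bincount(positions - 1, minlength=L).astype(float)
    n_mut = int(len(positions))

    if central_only:
        region = np.zeros(L, dtype=bool)
        for s in sites:
            region[s.position - 1] = True
    else:
        lengths = {record.protein_id: L}
        region = region_masks(merge_regions(sites, lengths, window=window),
                              lengths)[record.protein_id]
    region_len = int(region.sum())

    disorder = record.disorder
    uniform = disorder is None or len(np.unique(disorder)) < 2 or n_mut == 0
    note = ""
    mu = None
    if not uniform:
        X = sm.add_constant(disorder.astype(float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            if np.isfinite(fit.params).all():
                mu = fit.mu
            else:
                uniform, note = True, "fit produced non-finite coefficients"
        except Exception as exc:  # non-convergence, separation, etc.
            uniform, note = True, f"fit failed: {type(exc).__name__}"
    if mu is None:
        mu = np.full(L, n_mut / L)
        if not note and not uniform:
            note = "uniform fallback"
    expected = float(mu[region].sum())

    observed = int(region[positions - 1].sum()) if n_mut else 0
    site_pos = np.array(sorted(s.position for s in sites))
    obs_cat = {"direct": 0, "proximal": 0, "distal": 0}
    for pos in positions:
        d = int(np.abs(site_pos - pos).min())
        if d == 0:
            obs_cat["direct"] += 1
        elif proximal[0] <= d <= proximal[1]:
            obs_cat["proximal"] += 1
        elif distal[0] <= d <= distal[1]:
            obs_cat["distal"] += 1

    p = gene_ptm_pvalue(observed, expected)
    if expected == 0 and observed > 0:
        note = (note + "; " if note else "") + "E=0 with O>0"
    return GeneModel(gene=record.protein_id, length=L, n_mutations=n_mut,
                     region_length=region_len, expected=expected,
                     observed=observed, obs_direct=obs_cat["direct"],
                     obs_proximal=obs_cat["proximal"],
                     obs_distal=obs_cat["distal"], p=p,
                     uniform_fallback=uniform, note=note)


def gene_ptm_pvalue(observed: int, expected: float) -> float:
    """Upper-tail Poisson probability P(X >= observed | expected), exact."""
    if observed <= 0:
        return 1.0
    if expected <= 0:
        return _TINY_P
    return poisson_upper_tail(observed, expected)


def run_activedriver(proteome_records: Mapping[str, ProteinRecord],
                     sites: Iterable[PTMSite],
                     mutations: pd.DataFrame,
                     window: int = 7,
                     central_only: bool = False,
                     proximal=(1, 2), distal=(3, 7)) -> pd.DataFrame:
    """Score every eligible gene (>=1 PTM site and >=1 mutation) and adjust
    with Benjamini-Hochberg across tested genes. Sorted by p."""
    sites = list(sites)
    site_genes = {s.protein_id for s in sites}
    mutated = set(mutations["protein_id"].unique()) if len(mutations) else set()
    eligible = sorted(site_genes & mutated & set(proteome_records))
    rows = []
    for gene in eligible:
        model = fit_gene_model(proteome_records[gene], sites, mutations,
                               window=window, central_only=central_only,
                               proximal=proximal, distal=distal)
        rows.append({
            "gene": model.gene, "length": model.length,
            "n_mutations": model.n_mutations,
            "region_length": model.region_length,
            "expected": model.expected, "observed": model.observed,
            "obs_direct": model.obs_direct,
            "obs_proximal": model.obs_proximal,
            "obs_distal": model.obs_distal,
            "p": model.p, "uniform_fallback": model.uniform_fallback,
            "note": model.note})
    df = pd.DataFrame(rows, columns=["gene", "length", "n_mutations",
                                     "region_length", "expected", "observed",
                                     "obs_direct", "obs_proximal",
                                     "obs_distal", "p", "uniform_fallback",
                                     "note"])
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


def find_hotspots(regions, annotations: pd.DataFrame,
                  min_snvs: int = 6) -> pd.DataFrame:
    """Merged PTM regions with at least ``min_snvs`` mutations (the default
    6 encodes 'more than five'), with per-cancer-type counts and a
    combinatorial flag for regions whose sites carry both PTM types."""
    region_by_id = {r.region_id: r for r in regions}
    in_region = annotations[annotations["region_id"] != ""]
    rows = []
    for region_id, sub in in_region.groupby("region_id"):
        n = len(sub)
        if n < min_snvs:
            continue
        region = region_by_id.get(region_id)
        per_type = sub.groupby("cancer_type").size().sort_index()
        rows.append({
            "region_id": region_id,
            "protein_id": region.protein_id if region else region_id.split(":")[0],
            "start": region.start if region else -1,
            "end": region.end if region else -1,
            "n_snvs": n,
            "per_cancer_type": ";".join(f"{k}:{v}" for k, v in per_type.items()),
            "combinatorial": bool(region and len(region.types) == 2),
        })
    df = pd.DataFrame(rows, columns=["region_id", "protein_id", "start", "end",
                                     "n_snvs", "per_cancer_type",
                                     "combinatorial"])
    return df.sort_values(["n_snvs", "region_id"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)


def cancer_gene_permutation_test(detected: set, known: set,
                                 mutation_counts: pd.Series,
                                 n_bins: int = 100,
                                 n_permutations: int = 100_000,
                                 rng: Optional[np.random.Generator] = None
                                 ) -> CancerGeneEnrichment:
    """Mutation-frequency-matched permutation test of |detected ∩ known|.

    Genes are binned into ``n_bins`` equal-size quantile groups by their
    mutation count; each permutation draws, per bin, as many genes
    uniformly without replacement as the bin holds known genes, and the
    statistic is the overlap of the draw with ``detected``. Within a bin
    the overlap of a uniform without-replacement draw is exactly
    hypergeometric, so the permutation distribution is sampled from the
    per-bin hypergeometric laws directly. One-sided add-one p value.
    """
    rng = rng or np.random.default_rng()
    universe = list(mutation_counts.index)
    if not set(known) <= set(universe):
        raise ConsistencyError("known gene list contains genes outside the "
                               "mutation-count universe")
    merged = False
    n_bins_eff = min(n_bins, len(universe))
    if n_bins_eff < n_bins:
        merged = True
    ranks = mutation_counts.rank(method="first")
    bins = pd.qcut(ranks, q=n_bins_eff, labels=False, duplicates="drop")
    if bins.nunique() < n_bins_eff:
        merged = True

    detected = set(detected)
    known = set(known)
    observed = len(detected & known)
    null = np.zeros(n_permutations, dtype=np.int64)
    for _, members in pd.Series(universe, index=bins.values).groupby(level=0):
        genes = set(members)
        k_draw = len(genes & known)
        if k_draw == 0:
            continue
        n_good = len(genes & detected)
        n_bad = len(genes) - n_good
        if n_good == 0:
            continue
        null += rng.hypergeometric(n_good, n_bad, k_draw, size=n_permutations)
    p = empirical_p(int((null >= observed).sum()), n_permutations)
    return CancerGeneEnrichment(observed_overlap=observed,
                                null_mean=float(null.mean()),
                                empirical_p=p, n_bins=n_bins_eff,
                                n_permutations=n_permutations,
                                merged_bins=merged)
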