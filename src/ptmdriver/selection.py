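"""Proteome-wide positive-selection statistics for PTM-site mutations.

All four resampling tests share the same one-sided bootstrap scheme: the
null redistributes each protein's observed mutations uniformly at random
over that protein's eligible residues (preserving per-protein mutation
totals, which avoids gene-level burden confounding), and the empirical
p value is the add-one upper tail over ``n_shuffles`` resamples. Because
resampled positions are independent and uniform within each protein, the
per-protein null in-class count is exactly Binomial(m_i, f_i) with f_i
the protein's eligible-class residue fraction; the null total is sampled
as the sum of these binomials, which is the bootstrap distribution
itself, not an approximation.

Fold changes are per-residue mutation rates inside the tested sequence
class divided by the rate outside it.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import PTM_TYPES
from .datatypes import (ContingencyResult, EnrichmentResult, ProteinRecord,
                        PTMSite)
from .errors import DegenerateInputError
from .mapping import merge_regions, region_masks
from .stats_util import bh_fdr, empirical_p, fisher_one_sided


def _binomial_null_total(rng: np.random.Generator, ms: np.ndarray,
                         fs: np.ndarray, n_shuffles: int) -> np.ndarray:
    """Null distribution of the total in-class count: sum over proteins of
    Binomial(m_i, f_i)."""
    total = np.zeros(n_shuffles, dtype=np.int64)
    for m, f in zip(ms, fs):
        if m > 0 and f > 0:
            total += rng.binomial(int(m), float(f), size=n_shuffles)
    return total


def _rate_fold_change(obs: int, n: int, len_in: int, len_out: int) -> float:
    if len_in == 0 or len_out == 0:
        return float("nan")
    rate_in = obs / len_in
    rate_out = (n - obs) / len_out
    if rate_out == 0:
        return float("inf") if rate_in > 0 else float("nan")
    return rate_in / rate_out


def _not_applicable(label: str, note: str, n_shuffles: int,
                    stratum: Optional[str] = None) -> EnrichmentResult:
    return EnrichmentResult(label=label, observed=0, expected=float("nan"),
                            fold_change=float("nan"), p_empirical=float("nan"),
                            n_shuffles=n_shuffles, stratum=stratum,
                            applicable=False, note=note)


def bootstrap_region_enrichment(proteome: Mapping[str, ProteinRecord],
                                sites: Iterable[PTMSite],
                                mutations: pd.DataFrame,
                                ptm_type: str,
                                n_shuffles: int = 100_000,
                                rng: Optional[np.random.Generator] = None,
                                window: int = 7) -> EnrichmentResult:
    """Enrichment of mutations in ±window PTM regions of one PTM type.

    Restricted to proteins carrying at least one site of ``ptm_type``
    (non-modified proteins are excluded from both numerator and
    denominator). Observed is the count of mutations inside the merged
    regions of that type; the null reassigns each protein's mutations
    uniformly over that protein's residues.
    """
    rng = rng or np.random.default_rng()
    label = f"region_enrichment[{ptm_type}]"
    typed = [s for s in sites if ptm_type in s.types]
    scope = sorted({s.protein_id for s in typed})
    if not scope:
        return _not_applicable(label, "no proteins with this PTM type",
                               n_shuffles)
    lengths = {pid: proteome[pid].length for pid in scope}
    masks = region_masks(merge_regions(typed, lengths, window=window), lengths)

    muts = mutations[mutations["protein_id"].isin(scope)]
    counts = muts.groupby("protein_id").size()

    ms, fs = [], []
    observed = 0
    len_in = len_out = 0
    for pid in scope:
        mask = masks[pid]
        L = lengths[pid]
        reg = int(mask.sum())
        len_in += reg
        len_out += L - reg
        m = int(counts.get(pid, 0))
        ms.append(m)
        fs.append(reg / L)
        if m:
            pos = muts.loc[muts["protein_id"] == pid, "position"].to_numpy(int)
            observed += int(mask[pos - 1].sum())
    n = int(sum(ms))
    if n == 0:
        return EnrichmentResult(label=label, observed=0, expected=0.0,
                                fold_change=float("nan"), p_empirical=1.0,
                                n_shuffles=n_shuffles, applicable=True,
                                note="no mutations in scope")
    if len_out == 0:
        return _not_applicable(label, "regions cover all assessed sequence",
                               n_shuffles)
    null = _binomial_null_total(rng, np.array(ms), np.array(fs), n_shuffles)
    p = empirical_p(int((null >= observed).sum()), n_shuffles)
    return EnrichmentResult(label=label, observed=observed,
                            expected=float(null.mean()),
                            fold_change=_rate_fold_change(observed, n, len_in,
                                                          len_out),
                            p_empirical=p, n_shuffles=n_shuffles)


def central_lysine_enrichment(proteome: Mapping[str, ProteinRecord],
                              sites: Iterable[PTMSite],
                              mutations: pd.DataFrame,
                              ptm_type: str,
                              n_shuffles: int = 100_000,
                              rng: Optional[np.random.Generator] = None
                              ) -> EnrichmentResult:
    """Mutation-rate contrast of modified vs non-modified lysines.

    Both groups are restricted to K residues of proteins carrying at
    least one site of ``ptm_type``; proteins without any non-modified
    lysine are excluded. The null reassigns each protein's lysine
    mutations uniformly over that protein's lysine positions.
    """
    rng = rng or np.random.default_rng()
    label = f"central_lysine_enrichment[{ptm_type}]"
    typed: dict[str, set] = {}
    for s in sites:
        if ptm_type in s.types:
            typed.setdefault(s.protein_id, set()).add(s.position)
    if not typed:
        return _not_applicable(label, "no proteins with this PTM type",
                               n_shuffles)

    ms, fs = [], []
    observed = 0
    n_mod_total = n_unmod_total = 0
    n_total = 0
    muts = mutations[mutations["protein_id"].isin(typed)]
    by_protein = dict(tuple(muts.groupby("protein_id"))) if len(muts) else {}
    for pid, mod_positions in sorted(typed.items()):
        seq = proteome[pid].sequence
        k_pos = {i + 1 for i, aa in enumerate(seq) if aa == "K"}
        mod = set(mod_positions) & k_pos
        unmod = k_pos - mod
        if not unmod:
            continue  # no within-protein contrast possible
        n_mod_total += len(mod)
        n_unmod_total += len(unmod)
        sub = by_protein.get(pid)
        if sub is None:
            ms.append(0)
            fs.append(len(mod) / len(k_pos))
            continue
        pos = sub["position"].to_numpy(int)
        on_k = np.fromiter((p in k_pos for p in pos), dtype=bool,
                           count=len(pos))
        mk = int(on_k.sum())
        obs = int(sum(1 for p in pos if p in mod))
        observed += obs
        n_total += mk
        ms.append(mk)
        fs.append(len(mod) / len(k_pos))
    if n_mod_total == 0 or n_unmod_total == 0:
        return _not_applicable(label,
                               "no within-protein modified/non-modified "
                               "lysine contrast", n_shuffles)
    if n_total == 0:
        return EnrichmentResult(label=label, observed=0, expected=0.0,
                                fold_change=float("nan"), p_empirical=1.0,
                                n_shuffles=n_shuffles,
                                note="no lysine mutations in scope")
    null = _binomial_null_total(rng, np.array(ms), np.array(fs), n_shuffles)
    p = empirical_p(int((null >= observed).sum()), n_shuffles)
    return EnrichmentResult(label=label, observed=observed,
                            expected=float(null.mean()),
                            fold_change=_rate_fold_change(
                                observed, n_total, n_mod_total, n_unmod_total),
                            p_empirical=p, n_shuffles=n_shuffles)


def domain_enrichment(proteome: Mapping[str, ProteinRecord],
                      annotations: pd.DataFrame,
                      n_shuffles: int = 100_000,
                      rng: Optional[np.random.Generator] = None,
                      window: int = 7,
                      sites: Optional[Iterable[PTMSite]] = None
                      ) -> EnrichmentResult:
    """Concentration of PTM-associated mutations in protein domains.

    Scope: mutations with a PTM category (direct/proximal/distal). The
    null redistributes each protein's PTM-associated mutations uniformly
    over that protein's PTM-region residues, so the tested contrast is
    domain vs non-domain sequence *within* PTM regions.
    """
    rng = rng or np.random.default_rng()
    label = "domain_enrichment"
    ptm_muts = annotations[annotations["category"] != "none"]
    if not len(ptm_muts):
        return _not_applicable(label, "no PTM-associated mutations", n_shuffles)
    if sites is None:
        return _not_applicable(label, "sites required to build region masks",
                               n_shuffles)
    scope = sorted(set(ptm_muts["protein_id"]))
    lengths = {pid: proteome[pid].length for pid in scope}
    scoped_sites = [s for s in sites if s.protein_id in lengths]
    masks = region_masks(merge_regions(scoped_sites, lengths, window=window),
                         lengths)
    if not any(proteome[pid].domains for pid in scope):
        return _not_applicable(label, "no domain annotations in scope",
                               n_shuffles)

    ms, fs = [], []
    observed = 0
    len_in = len_out = 0
    for pid, sub in ptm_muts.groupby("protein_id"):
        rec = proteome[pid]
        reg = masks[pid]
        dom = rec.domain_mask()
        reg_len = int(reg.sum())
        in_dom = int((reg & dom).sum())
        len_in += in_dom
        len_out += reg_len - in_dom
        pos = sub["position"].to_numpy(int)
        observed += int(dom[pos - 1].sum())
        ms.append(len(pos))
        fs.append(in_dom / reg_len if reg_len else 0.0)
    n = int(sum(ms))
    null = _binomial_null_total(rng, np.array(ms), np.array(fs), n_shuffles)
    p = empirical_p(int((null >= observed).sum()), n_shuffles)
    if len_out == 0:
        # domains cover every assessed residue: rates coincide by construction
        return EnrichmentResult(label=label, observed=observed,
                                expected=float(null.mean()), fold_change=1.0,
                                p_empirical=1.0, n_shuffles=n_shuffles,
                                note="domains cover all assessed sequence")
    return EnrichmentResult(label=label, observed=observed,
                            expected=float(null.mean()),
                            fold_change=_rate_fold_change(observed, n, len_in,
                                                          len_out),
                            p_empirical=p, n_shuffles=n_shuffles)


def conservation_ratio(values_ptm: np.ndarray, values_other: np.ndarray,
                       n_shuffles: int,
                       rng: np.random.Generator) -> tuple[float, float]:
    """Ratio of group means with a one-sided label-permutation p value.

    Raises on an empty group (degenerate stratum).
    """
    a = np.asarray(values_ptm, dtype=float)
    b = np.asarray(values_other, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("degenerate stratum: one group is empty")
    if b.mean() == 0:
        return float("nan"), float("nan")
    observed = a.mean() / b.mean()
    pooled = np.concatenate([a, b])
    n1, n = a.size, pooled.size
    hits = 0
    chunk = max(1, min(n_shuffles, int(2e7 // max(1, n))))
    done = 0
    while done < n_shuffles:
        c = min(chunk, n_shuffles - done)
        keys = rng.random((c, n))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        g1 = np.take(pooled, idx).mean(axis=1)
        g2 = (pooled.sum() - g1 * n1) / (n - n1)
        ratio = np.divide(g1, g2, out=np.full(c, np.inf), where=g2 != 0)
        hits += int((ratio >= observed).sum())
        done += c
    return float(observed), empirical_p(hits, n_shuffles)


def conservation_contrast(annotations: pd.DataFrame,
                          proteome: Mapping[str, ProteinRecord],
                          n_shuffles: int = 100_000,
                          rng: Optional[np.random.Generator] = None
                          ) -> list[EnrichmentResult]:
    """Mean conservation of PTM-region mutations vs non-PTM mutations,
    disordered and structured residues analysed separately.

    The null permutes the PTM/non-PTM labels over mutated residues within
    each stratum. Strata with fewer than two mutations in either group
    are reported as not applicable.
    """
    rng = rng or np.random.default_rng()
    cons = np.empty(len(annotations))
    dis = np.empty(len(annotations), dtype=bool)
    for i, row in enumerate(annotations.itertuples(index=False)):
        rec = proteome[row.protein_id]
        cons[i] = rec.conservation[row.position - 1]
        dis[i] = bool(rec.disorder[row.position - 1])
    is_ptm = (annotations["category"] != "none").to_numpy()

    results = []
    for stratum, mask in (("structured", ~dis), ("disordered", dis)):
        label = "conservation_contrast"
        a = cons[mask & is_ptm]
        b = cons[mask & ~is_ptm]
        if a.size < 2 or b.size < 2:
            results.append(_not_applicable(
                label, "degenerate stratum: fewer than two mutations in a "
                "group", n_shuffles, stratum=stratum))
            continue
        fc, p = conservation_ratio(a, b, n_shuffles, rng)
        results.append(EnrichmentResult(
            label=label, observed=int(a.size), expected=float(b.mean()),
            fold_change=fc, p_empirical=p, n_shuffles=n_shuffles,
            stratum=stratum))
    return results


def impact_scores(predictors: pd.DataFrame,
                  annotations: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join predictor calls to annotated mutations and score each SNV
    0..n_predictors by counting deleterious calls.

    Returns (scored frame, n_excluded) where excluded mutations lacked a
    complete set of calls.
    """
    call_cols = [c for c in predictors.columns if c.startswith("call_")]
    if not call_cols:
        raise DegenerateInputError("predictor table has no call_* columns")
    key = ["sample_id", "protein_id", "position"]
    merged = annotations.merge(predictors[key + call_cols], on=key, how="left")
    complete = merged[call_cols].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    scored = merged.loc[complete].copy()
    scored["impact_score"] = scored[call_cols].astype(int).sum(axis=1)
    scored["consensus"] = scored["impact_score"] == len(call_cols)
    return scored, n_excluded


def impact_association(predictors: pd.DataFrame,
                       annotations: pd.DataFrame
                       ) -> tuple[pd.DataFrame, ContingencyResult]:
    """Association between consensus deleteriousness and PTM regions.

    Builds the 2x2 table {consensus, non-consensus} x {PTM-region,
    non-PTM} and tests it one-sided (consensus enriched in PTM regions)
    with Fisher's exact test.
    """
    scored, _ = impact_scores(predictors, annotations)
    in_ptm = (scored["category"] != "none").to_numpy()
    consensus = scored["consensus"].to_numpy()
    a = int((consensus & in_ptm).sum())
    b = int((consensus & ~in_ptm).sum())
    c = int((~consensus & in_ptm).sum())
    d = int((~consensus & ~in_ptm).sum())
    table = np.array([[a, b], [c, d]])
    odds, p, corrected = fisher_one_sided(table)
    return scored, ContingencyResult(table=table, odds_ratio=odds, p=p,
                                     sidedness="greater",
                                     continuity_corrected=corrected)


def run_selection_stats(dataset, config, annotations: pd.DataFrame
                        ) -> pd.DataFrame:
    """All Fig.-1-style proteome-wide tests as one tidy result table."""
    rng = np.random.default_rng([int(config.seed), 10])
    proteome = dataset.proteome.records
    sites = dataset.proteome.sites
    rows = []

    def push(res: EnrichmentResult):
        rows.append({
            "label": res.label, "stratum": res.stratum or "",
            "observed": res.observed, "expected": res.expected,
            "fold_change": res.fold_change, "p_empirical": res.p_empirical,
            "n_shuffles": res.n_shuffles, "applicable": res.applicable,
            "note": res.note})

    for ptm_type in PTM_TYPES:
        push(bootstrap_region_enrichment(proteome, sites, dataset.mutations,
                                         ptm_type, config.n_shuffles, rng,
                                         window=config.window))
        push(central_lysine_enrichment(proteome, sites, dataset.mutations,
                                       ptm_type, config.n_shuffles, rng))
    push(domain_enrichment(proteome, annotations, config.n_shuffles, rng,
                           window=config.window, sites=sites))
    for res in conservation_contrast(annotations, proteome,
                                     config.n_shuffles, rng):
        push(res)

    if len(dataset.predictors):
        try:
            _, cont = impact_association(dataset.predictors, annotations)
            rows.append({"label": "impact_consensus_association", "stratum": "",
                         "observed": int(cont.table[0, 0]),
                         "expected": float("nan"),
                         "fold_change": cont.odds_ratio,
                         "p_empirical": cont.p, "n_shuffles": 0,
                         "applicable": True,
                         "note": "odds ratio; one-sided Fisher exact"})
        except DegenerateInputError as exc:
            rows.append({"label": "impact_consensus_association", "stratum": "",
                         "observed": 0, "expected": float("nan"),
                         "fold_change": float("nan"),
                         "p_empirical": float("nan"), "n_shuffles": 0,
                         "applicable": False, "note": str(exc)})
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    ok = table["applicable"] & table["p_empirical"].notna()
    if ok.any():
        table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p_empirical"].to_numpy())
    return table
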