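"""Stage orchestration: each analysis stage is self-contained (it computes
its own prerequisites from the loaded bundle) and writes TSV result tables
plus a JSON run manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bundle import Dataset, read_bundle
from .config import AnalysisConfig
from .drivers import cancer_gene_permutation_test, find_hotspots, run_activedriver
from .mapping import classify_mutations, filter_cohort
from .netsurv import hypermodules_search, modules_frame, permutation_filter
from .pathways import enrichment_map_export, test_gene_sets
from .selection import run_selection_stats

log = logging.getLogger("ptmdriver")


def prepare(dataset: Dataset, config: AnalysisConfig):
    """Hypermutator filtering + mutation classification, shared by all
    stages. Returns (filtered mutations, annotations, regions, report)."""
    mutations, filter_report = filter_cohort(dataset.mutations,
                                             rule=config.hypermutation_rule,
                                             parameter=config.hypermutation_param)
    regions = dataset.proteome.merged_regions(window=config.window)
    annotations = classify_mutations(mutations, dataset.proteome.sites,
                                     regions=regions,
                                     proximal=config.proximal_range,
                                     distal=config.distal_range,
                                     window=config.window)
    return mutations, annotations, regions, filter_report


def regions_frame(regions) -> pd.DataFrame:
    rows = [{"region_id": r.region_id, "protein_id": r.protein_id,
             "start": r.start, "end": r.end, "length": r.length,
             "member_positions": ",".join(map(str, r.member_positions)),
             "ptm_types": ",".join(sorted(r.types))}
            for r in regions]
    return pd.DataFrame(rows, columns=["region_id", "protein_id", "start",
                                       "end", "length", "member_positions",
                                       "ptm_types"])


def _write(df: pd.DataFrame, out: Path, name: str) -> None:
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / name, sep="\t", index=False)


def write_manifest(out: Path, config: AnalysisConfig, counts: dict,
                   stage: str) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {k: int(v) for k, v in counts.items()},
    }
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def stage_map(dataset: Dataset, config: AnalysisConfig, out: Path) -> dict:
    mutations, annotations, regions, filt = prepare(dataset, config)
    _write(annotations, out, "annotations.tsv")
    _write(regions_frame(regions), out, "regions.tsv")
    counts = {"mutations": len(mutations), "annotations": len(annotations),
              "regions": len(regions),
              "hypermutated_samples_removed": len(filt.flagged_samples)}
    write_manifest(out, config, counts, "map")
    return counts


def stage_select_stats(dataset: Dataset, config: AnalysisConfig,
                       out: Path) -> dict:
    _, annotations, _, _ = prepare(dataset, config)
    table = run_selection_stats(dataset, config, annotations)
    _write(table, out, "selection_stats.tsv")
    counts = {"tests": len(table)}
    write_manifest(out, config, counts, "select-stats")
    return counts


def stage_drivers(dataset: Dataset, config: AnalysisConfig, out: Path) -> dict:
    mutations, annotations, regions, _ = prepare(dataset, config)
    table = run_activedriver(dataset.proteome.records, dataset.proteome.sites,
                             mutations, window=config.window,
                             proximal=config.proximal_range,
                             distal=config.distal_range)
    _write(table, out, "drivers.tsv")
    hotspots = find_hotspots(regions, annotations,
                             min_snvs=config.hotspot_min_snvs)
    _write(hotspots, out, "hotspots.tsv")
    enrichment = {}
    if dataset.truth is not None and len(table):
        detected = set(table.loc[table["fdr"] < config.fdr_alpha, "gene"])
        known = set(dataset.truth.driver_genes)
        gene_counts = mutations.groupby("protein_id").size()
        gene_counts = gene_counts.reindex(dataset.proteome.protein_ids,
                                          fill_value=0)
        known &= set(gene_counts.index)
        if known:
            rng = np.random.default_rng([int(config.seed), 20])
            res = cancer_gene_permutation_test(
                detected, known, gene_counts, n_bins=config.n_bins,
                n_permutations=config.n_gene_permutations, rng=rng)
            enrichment = {
                "observed_overlap": res.observed_overlap,
                "null_mean": res.null_mean,
                "empirical_p": res.empirical_p,
                "n_bins": res.n_bins,
                "n_permutations": res.n_permutations,
                "merged_bins": res.merged_bins,
            }
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "cancer_gene_enrichment.json", "w") as fh:
        json.dump(enrichment, fh, indent=1, sort_keys=True)
        fh.write("\n")
    counts = {"genes_tested": len(table),
              "genes_significant": int((table["fdr"] < config.fdr_alpha).sum())
              if len(table) else 0,
              "hotspots": len(hotspots)}
    write_manifest(out, config, counts, "drivers")
    return counts


def stage_pathways(dataset: Dataset, config: AnalysisConfig, out: Path) -> dict:
    _, annotations, regions, _ = prepare(dataset, config)
    results, dropped = test_gene_sets(
        dataset.gene_sets, annotations, regions,
        geneset_min=config.geneset_min, geneset_max=config.geneset_max,
        min_mutated_proteins=config.min_mutated_proteins)
    _write(results, out, "pathways.tsv")
    _write(dropped, out, "pathways_dropped.tsv")
    nodes, edges = enrichment_map_export(results, dataset.gene_sets,
                                         alpha=config.fdr_alpha,
                                         threshold=config.overlap_threshold)
    _write(nodes, out, "em_nodes.tsv")
    _write(edges, out, "em_edges.tsv")
    counts = {"sets_tested": len(results), "sets_dropped": len(dropped),
              "sets_significant": int((results["fdr"] < config.fdr_alpha).sum())
              if len(results) else 0}
    write_manifest(out, config, counts, "pathways")
    return counts


def stage_modules(dataset: Dataset, config: AnalysisConfig, out: Path) -> dict:
    _, annotations, _, _ = prepare(dataset, config)
    modules = hypermodules_search(dataset.network, annotations,
                                  dataset.survival,
                                  max_size=config.max_module_size,
                                  min_seed_carriers=config.min_seed_carriers,
                                  min_patients=config.min_patients_per_type)
    rng = np.random.default_rng([int(config.seed), 30])
    modules = permutation_filter(modules, dataset.network, annotations,
                                 dataset.survival,
                                 n_permutations=config.n_network_permutations,
                                 alpha=config.fdr_alpha,
                                 max_size=config.max_module_size,
                                 min_seed_carriers=config.min_seed_carriers,
                                 min_patients=config.min_patients_per_type,
                                 rng=rng)
    table = modules_frame(modules)
    _write(table, out, "modules.tsv")
    carrier_rows = []
    sample_type = dict(zip(dataset.survival["patient_id"],
                           dataset.survival["cancer_type"]))
    assoc = annotations[annotations["category"] != "none"]
    for m in modules:
        carriers = sorted({s for s, g, ct in zip(assoc["sample_id"],
                                                 assoc["protein_id"],
                                                 assoc["cancer_type"])
                           if g in m.nodes and sample_type.get(s) == m.cancer_type})
        carrier_rows.append({"cancer_type": m.cancer_type, "seed": m.seed,
                             "carriers": ",".join(carriers)})
    _write(pd.DataFrame(carrier_rows, columns=["cancer_type", "seed",
                                               "carriers"]),
           out, "module_carriers.tsv")
    counts = {"modules": len(table),
              "modules_significant": int(table["significant"].sum())
              if len(table) else 0}
    write_manifest(out, config, counts, "modules")
    return counts


STAGES = {
    "map": stage_map,
    "select-stats": stage_select_stats,
    "drivers": stage_drivers,
    "pathways": stage_pathways,
    "modules": stage_modules,
}


def run_all(bundle_dir, out_dir, config: AnalysisConfig) -> dict:
    """Run every analysis stage on a bundle directory."""
    dataset = read_bundle(bundle_dir, window=config.window)
    out = Path(out_dir)
    counts: dict[str, int] = {}
    for name, stage in STAGES.items():
        log.info("running stage %s", name)
        counts.update({f"{name}:{k}": v
                       for k, v in stage(dataset, config, out).items()})
    write_manifest(out, config, counts, "all")
    return counts
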