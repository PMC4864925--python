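"""Readers and writers for the interchange bundle.

A bundle directory holds plain-text files: ``proteins.fasta`` plus TSV
tables with header rows (``sites.tsv``, ``mutations.tsv``,
``disorder.tsv``, ``conservation.tsv``, ``domains.tsv``,
``predictors.tsv``, ``network.tsv``, ``survival.tsv``), a standard GMT
file (``genesets.gmt``: set id, description, member ids), and, for
simulated data, ``truth.json``. All positions are 1-based and intervals
closed.

``read_bundle`` cross-validates everything it loads: site positions must
fall inside the sequence on a lysine, mutation reference residues must
match the sequence (mismatching records are dropped and counted, the run
continues), annotation tracks must cover every residue, and survival
patients absent from the mutation cohort are flagged but kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import AA20
from .datatypes import ProteinRecord, PTMSite, SyntheticTruth
from .errors import FormatError
from .mapping import map_sites, MappingReport
from .simulate import Bundle, Proteome

log = logging.getLogger("ptmdriver")

FILES = {
    "fasta": "proteins.fasta",
    "sites": "sites.tsv",
    "mutations": "mutations.tsv",
    "disorder": "disorder.tsv",
    "conservation": "conservation.tsv",
    "domains": "domains.tsv",
    "predictors": "predictors.tsv",
    "network": "network.tsv",
    "survival": "survival.tsv",
    "genesets": "genesets.gmt",
    "truth": "truth.json",
}

_AA_SET = set(AA20)


# ---------------------------------------------------------------- writing

def write_bundle(bundle: Bundle, outdir) -> None:
    """Write a simulated bundle to ``outdir`` (created if needed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    proteome = bundle.proteome

    records = [SeqRecord(Seq(rec.sequence), id=pid, description="")
               for pid, rec in proteome.records.items()]
    SeqIO.write(records, out / FILES["fasta"], "fasta")

    proteome.sites_frame().to_csv(out / FILES["sites"], sep="\t", index=False)
    bundle.mutations.to_csv(out / FILES["mutations"], sep="\t", index=False)
    bundle.predictors.to_csv(out / FILES["predictors"], sep="\t", index=False)
    bundle.network.to_csv(out / FILES["network"], sep="\t", index=False)
    bundle.survival.to_csv(out / FILES["survival"], sep="\t", index=False)

    dis_rows, cons_rows, dom_rows = [], [], []
    for pid, rec in proteome.records.items():
        for j in range(rec.length):
            dis_rows.append((pid, j + 1, int(rec.disorder[j])))
            cons_rows.append((pid, j + 1, round(float(rec.conservation[j]), 4)))
        for start, end in rec.domains:
            dom_rows.append((pid, start, end))
    pd.DataFrame(dis_rows, columns=["protein_id", "position", "disordered"]) \
        .to_csv(out / FILES["disorder"], sep="\t", index=False)
    pd.DataFrame(cons_rows, columns=["protein_id", "position", "score"]) \
        .to_csv(out / FILES["conservation"], sep="\t", index=False)
    pd.DataFrame(dom_rows, columns=["protein_id", "start", "end"]) \
        .to_csv(out / FILES["domains"], sep="\t", index=False)

    write_gmt(bundle.gene_sets, out / FILES["genesets"])
    with open(out / FILES["truth"], "w") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for set_id in gene_sets:
            members = gene_sets[set_id]
            fh.write("\t".join([set_id, set_id] + list(members)) + "\n")


def read_gmt(path) -> dict:
    """Standard GMT: two leading columns (id, description), then members."""
    sets: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT rows need id, description, "
                    f"and at least one member")
            sets[parts[0]] = parts[2:]
    return sets


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(driver_genes=tuple(d["driver_genes"]),
                          planted_module=frozenset(d["planted_module"]),
                          planted_enrichment=float(d["planted_enrichment"]),
                          planted_hazard_ratio=float(d["planted_hazard_ratio"]))


# ---------------------------------------------------------------- reading

@dataclass
class ValidationReport:
    """Counts of records dropped or flagged while loading a bundle."""

    counts: dict = field(default_factory=dict)
    messages: list = field(default_factory=list)
    site_mapping: Optional[MappingReport] = None

    def add(self, key: str, n: int = 1) -> None:
        self.counts[key] = self.counts.get(key, 0) + n

    def note(self, msg: str) -> None:
        self.messages.append(msg)
        log.info(msg)


@dataclass
class Dataset:
    """A validated in-memory bundle ready for analysis."""

    proteome: Proteome
    mutations: pd.DataFrame
    predictors: pd.DataFrame
    network: pd.DataFrame
    survival: pd.DataFrame
    gene_sets: dict
    report: ValidationReport
    truth: Optional[SyntheticTruth] = None


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    return sequences


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: line 1: missing column(s) {', '.join(missing)}")
    return df


def _attach_tracks(records: dict, disorder: pd.DataFrame,
                   conservation: pd.DataFrame, domains: pd.DataFrame,
                   report: ValidationReport) -> None:
    for pid, rec in records.items():
        rec.disorder = np.zeros(rec.length, dtype=bool)
        rec.conservation = np.full(rec.length, 0.5)
    for name, df, col in (("disorder", disorder, "disordered"),
                          ("conservation", conservation, "score")):
        for pid, group in df.groupby("protein_id"):
            rec = records.get(pid)
            if rec is None:
                report.add(f"{name}_unknown_protein", len(group))
                continue
            pos = group["position"].to_numpy(dtype=int)
            ok = (pos >= 1) & (pos <= rec.length)
            if not ok.all():
                report.add(f"{name}_out_of_bounds", int((~ok).sum()))
            vals = group[col].to_numpy()
            if name == "disorder":
                rec.disorder[pos[ok] - 1] = vals[ok].astype(bool)
            else:
                v = vals[ok].astype(float)
                if ((v < 0) | (v > 1)).any():
                    raise FormatError("conservation scores must lie in [0,1]")
                rec.conservation[pos[ok] - 1] = v
    for row in domains.itertuples(index=False):
        rec = records.get(row.protein_id)
        if rec is None:
            report.add("domain_unknown_protein")
            continue
        start, end = int(row.start), int(row.end)
        if start < 1 or end > rec.length or start > end:
            report.add("domain_out_of_bounds")
            continue
        rec.domains.append((start, end))
    for rec in records.values():
        rec.domains.sort()


def read_bundle(directory, window: int = 7) -> Dataset:
    """Load and cross-validate a bundle directory.

    Invalid records (out-of-bounds sites, non-lysine site positions,
    reference-mismatch mutations) are dropped and counted in the report;
    structural problems (missing files, duplicate FASTA ids, malformed
    headers) raise immediately.
    """
    d = Path(directory)
    report = ValidationReport()

    sequences = read_fasta(d / FILES["fasta"])
    records = {pid: ProteinRecord(protein_id=pid, sequence=seq)
               for pid, seq in sequences.items()}

    disorder = _read_tsv(d / FILES["disorder"],
                         ["protein_id", "position", "disordered"])
    conservation = _read_tsv(d / FILES["conservation"],
                             ["protein_id", "position", "score"])
    domains = _read_tsv(d / FILES["domains"], ["protein_id", "start", "end"])
    _attach_tracks(records, disorder, conservation, domains, report)

    sites_df = _read_tsv(d / FILES["sites"], ["protein_id", "position"])
    site_rows = []
    for row in sites_df.itertuples(index=False):
        types = getattr(row, "ptm_types", "")
        mer = getattr(row, "source_15mer", "") or None
        if isinstance(mer, float):
            mer = None
        for t in str(types).split(","):
            t = t.strip()
            if t:
                site_rows.append({"protein_id": row.protein_id,
                                  "position": int(row.position),
                                  "ptm_type": t,
                                  "source_15mer": mer})
    site_table = pd.DataFrame(site_rows, columns=["protein_id", "position",
                                                  "ptm_type", "source_15mer"])
    sites, mapping_report = map_sites(site_table, records, window=window)
    report.site_mapping = mapping_report
    dropped = (mapping_report.rejected_bad_position
               + mapping_report.rejected_non_central_k
               + mapping_report.rejected_no_match)
    if dropped:
        report.note(f"dropped {dropped} site record(s) during validation")
    report.add("sites_loaded", len(sites))

    mutations = _read_tsv(d / FILES["mutations"],
                          ["sample_id", "protein_id", "position", "ref_aa",
                           "alt_aa"])
    if "cancer_type" not in mutations.columns:
        mutations["cancer_type"] = "NA"
    keep = np.ones(len(mutations), dtype=bool)
    for i, row in enumerate(mutations.itertuples(index=False)):
        rec = records.get(row.protein_id)
        pos = int(row.position)
        if rec is None or pos < 1 or pos > rec.length:
            keep[i] = False
            report.add("mutation_out_of_bounds")
            continue
        if row.ref_aa == row.alt_aa:
            keep[i] = False
            report.add("mutation_silent")
            continue
        if row.ref_aa not in _AA_SET or row.alt_aa not in _AA_SET:
            keep[i] = False
            report.add("mutation_nonstandard_aa")
            continue
        if rec.residue(pos) != row.ref_aa:
            keep[i] = False
            report.add("mutation_ref_mismatch")
    n_dropped = int((~keep).sum())
    if n_dropped:
        report.note(f"dropped {n_dropped} mutation record(s) during validation")
    mutations = mutations.loc[keep].reset_index(drop=True)
    report.add("mutations_loaded", len(mutations))

    predictors_path = d / FILES["predictors"]
    predictors = (_read_tsv(predictors_path, ["sample_id", "protein_id",
                                              "position"])
                  if predictors_path.exists() else pd.DataFrame())

    network_path = d / FILES["network"]
    network = (_read_tsv(network_path, ["protein_a", "protein_b"])
               if network_path.exists()
               else pd.DataFrame(columns=["protein_a", "protein_b"]))
    if len(network):
        loops = network["protein_a"] == network["protein_b"]
        if loops.any():
            report.add("network_self_loops", int(loops.sum()))
            network = network.loc[~loops]
        canon = pd.DataFrame({
            "protein_a": network[["protein_a", "protein_b"]].min(axis=1),
            "protein_b": network[["protein_a", "protein_b"]].max(axis=1)})
        before = len(canon)
        network = canon.drop_duplicates().reset_index(drop=True)
        if len(network) < before:
            report.add("network_duplicate_edges", before - len(network))

    survival_path = d / FILES["survival"]
    if survival_path.exists():
        survival = _read_tsv(survival_path,
                             ["patient_id", "time", "event", "cancer_type"])
        bad = (survival["time"] <= 0) | (~survival["event"].isin((0, 1)))
        if bad.any():
            report.add("survival_invalid", int(bad.sum()))
            survival = survival.loc[~bad].reset_index(drop=True)
        if len(mutations):
            known = set(mutations["sample_id"])
            unknown = ~survival["patient_id"].isin(known)
            if unknown.any():
                report.add("survival_patients_without_mutations",
                           int(unknown.sum()))
    else:
        survival = pd.DataFrame(columns=["patient_id", "time", "event",
                                         "cancer_type"])

    genesets_path = d / FILES["genesets"]
    gene_sets = read_gmt(genesets_path) if genesets_path.exists() else {}

    truth_path = d / FILES["truth"]
    truth = read_truth(truth_path) if truth_path.exists() else None

    proteome = Proteome(records=records, sites=sites)
    return Dataset(proteome=proteome, mutations=mutations,
                   predictors=predictors, network=network, survival=survival,
                   gene_sets=gene_sets, report=report, truth=truth)
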