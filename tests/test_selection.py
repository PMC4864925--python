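"""Proteome-wide selection statistics: nulls, fold changes, Fisher exact."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ptmdriver.config import ACETYL, UBIQ
from ptmdriver.datatypes import ProteinRecord, PTMSite
from ptmdriver.errors import DegenerateInputError
from ptmdriver.mapping import classify_mutations
from ptmdriver.selection import (bootstrap_region_enrichment,
                                 central_lysine_enrichment,
                                 conservation_contrast, conservation_ratio,
                                 domain_enrichment, impact_association,
                                 impact_scores)
from ptmdriver.stats_util import empirical_p, fisher_one_sided

from oracles import fisher_greater_oracle


def _protein(pid, seq, **kw):
    return ProteinRecord(protein_id=pid, sequence=seq, **kw)


def _muts(rows):
    return pd.DataFrame(rows, columns=["sample_id", "protein_id", "position",
                                       "ref_aa", "alt_aa", "cancer_type"])


class TestBootstrapRegionEnrichment:
    def test_all_mutations_in_regions_gives_add_one_minimum_p(self, rng):
        seq = "A" * 50 + "K" + "A" * 49
        proteome = {"P1": _protein("P1", seq)}
        sites = [PTMSite("P1", 51, frozenset((ACETYL,)))]
        rows = [("S%d" % i, "P1", 51 - 3 + (i % 7), "A", "V", "T")
                for i in range(30)]
        res = bootstrap_region_enrichment(proteome, sites, _muts(rows),
                                          ACETYL, n_shuffles=999, rng=rng)
        assert res.observed == 30
        assert res.p_empirical == pytest.approx(1.0 / 1000.0)
        assert res.fold_change > 1

    def test_zero_mutations_gives_p_one(self, rng):
        proteome = {"P1": _protein("P1", "A" * 20 + "K" + "A" * 20)}
        sites = [PTMSite("P1", 21, frozenset((ACETYL,)))]
        res = bootstrap_region_enrichment(proteome, sites, _muts([]),
                                          ACETYL, n_shuffles=100, rng=rng)
        assert res.observed == 0 and res.p_empirical == 1.0

    def test_whole_protein_region_is_not_applicable(self, rng):
        seq = "AAAAKAAAAA"  # window covers all 10 residues
        proteome = {"P1": _protein("P1", seq)}
        sites = [PTMSite("P1", 5, frozenset((ACETYL,)))]
        rows = [("S1", "P1", 2, "A", "V", "T")]
        res = bootstrap_region_enrichment(proteome, sites, _muts(rows),
                                          ACETYL, n_shuffles=100, rng=rng)
        assert not res.applicable

    def test_empirical_p_respects_add_one_floor(self):
        assert empirical_p(0, 1000) == pytest.approx(1 / 1001)
        assert empirical_p(1000, 1000) == 1.0


class TestCentralLysine:
    def test_all_lysines_modified_not_applicable(self, rng):
        seq = "AKAAAAAAKA"
        proteome = {"P1": _protein("P1", seq)}
        sites = [PTMSite("P1", 2, frozenset((UBIQ,))),
                 PTMSite("P1", 9, frozenset((UBIQ,)))]
        res = central_lysine_enrichment(proteome, sites, _muts([]), UBIQ,
                                        n_shuffles=50, rng=rng)
        assert not res.applicable

    def test_equal_rates_give_fold_change_near_one(self, rng):
        """Mutations uniform over lysines: modified vs non-modified rates
        agree within sampling error."""
        n_prot = 40
        proteome, sites, rows = {}, [], []
        rs = np.random.default_rng(7)
        for i in range(n_prot):
            pid = f"P{i}"
            seq = "".join(rs.choice(list("AK"), p=[0.8, 0.2], size=200))
            proteome[pid] = _protein(pid, seq)
            k_pos = [j + 1 for j, aa in enumerate(seq) if aa == "K"]
            mod = k_pos[::2]
            sites += [PTMSite(pid, p, frozenset((UBIQ,))) for p in mod]
            chosen = rs.choice(k_pos, size=min(60, len(k_pos)), replace=False)
            rows += [(f"S{j}", pid, int(p), "K", "R", "T")
                     for j, p in enumerate(chosen)]
        res = central_lysine_enrichment(proteome, sites, _muts(rows), UBIQ,
                                        n_shuffles=500, rng=rng)
        assert res.fold_change == pytest.approx(1.0, abs=0.15)


class TestDomainEnrichment:
    def _setup(self, domain_whole=False):
        seq = "A" * 40 + "K" + "A" * 59
        domains = [(1, 100)] if domain_whole else [(34, 48)]
        rec = _protein("P1", seq, domains=domains)
        rec.disorder = np.zeros(100, dtype=bool)
        rec.conservation = np.full(100, 0.5)
        sites = [PTMSite("P1", 41, frozenset((ACETYL,)))]
        rows = [("S%d" % i, "P1", 34 + (i % 15), "A", "V", "T")
                for i in range(20)]
        ann = classify_mutations(_muts(rows), sites,
                                 protein_lengths={"P1": 100})
        return {"P1": rec}, sites, ann

    def test_domains_covering_everything_gives_fc_one(self, rng):
        proteome, sites, ann = self._setup(domain_whole=True)
        res = domain_enrichment(proteome, ann, n_shuffles=100, rng=rng,
                                sites=sites)
        assert res.fold_change == 1.0 and res.p_empirical == 1.0

    def test_no_ptm_mutations_not_applicable(self, rng):
        proteome, sites, _ = self._setup()
        rows = [("S1", "P1", 90, "A", "V", "T")]
        ann = classify_mutations(_muts(rows), sites,
                                 protein_lengths={"P1": 100})
        res = domain_enrichment(proteome, ann, n_shuffles=100, rng=rng,
                                sites=sites)
        assert not res.applicable

    def test_planted_domain_concentration_recovered(self, rng):
        """PTM mutations placed inside domains at 1.5x the outside rate:
        the in/out rate ratio estimate lands within ±0.1 of 1.5."""
        rs = np.random.default_rng(3)
        seq = "A" * 100 + "K" + "A" * 99
        rec = _protein("P1", seq, domains=[(94, 101)])  # half the region
        sites = [PTMSite("P1", 101, frozenset((UBIQ,)))]
        # region spans 94..108: 8 in-domain, 7 outside
        in_dom = list(range(94, 102))
        out_dom = list(range(102, 109))
        weights = np.array([1.5] * len(in_dom) + [1.0] * len(out_dom))
        weights /= weights.sum()
        positions = rs.choice(in_dom + out_dom, size=120_000, p=weights)
        rows = [(f"S{i}", "P1", int(p), "A" if p != 101 else "K", "V", "T")
                for i, p in enumerate(positions)]
        ann = classify_mutations(_muts(rows), sites,
                                 protein_lengths={"P1": 200})
        res = domain_enrichment({"P1": rec}, ann, n_shuffles=10, rng=rng,
                                sites=sites)
        assert res.fold_change == pytest.approx(1.5, abs=0.1)


class TestConservationContrast:
    def test_identical_conservation_gives_fc_one_p_near_one(self, rng):
        values = np.full(50, 0.5)
        fc, p = conservation_ratio(values[:25], values[25:], 200, rng)
        assert fc == 1.0
        assert p == 1.0  # every permutation ties the observed ratio

    def test_empty_group_raises_degenerate_stratum(self, rng):
        with pytest.raises(DegenerateInputError):
            conservation_ratio(np.array([0.5]), np.array([]), 10, rng)

    def test_shifted_means_detected(self, rng):
        """PTM-site mutations drawn from a Beta with mean shifted +0.1 are
        flagged at alpha = 0.05 in at least 90% of replicates (n = 2000)."""
        rs = np.random.default_rng(42)
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            a = rs.beta(0.6 * 8, 0.4 * 8, size=1000)   # mean 0.6
            b = rs.beta(0.5 * 8, 0.5 * 8, size=1000)   # mean 0.5
            fc, p = conservation_ratio(a, b, 400, rng)
            hits += (p < 0.05 and fc > 1)
        assert hits / n_rep >= 0.9

    def test_degenerate_stratum_reported_not_applicable(self, small_bundle,
                                                        rng):
        proteome = small_bundle.proteome
        ann = classify_mutations(small_bundle.mutations.head(3),
                                 proteome.sites,
                                 regions=proteome.merged_regions())
        results = conservation_contrast(ann, proteome.records,
                                        n_shuffles=50, rng=rng)
        assert len(results) == 2
        assert {r.stratum for r in results} == {"disordered", "structured"}


class TestImpactAssociation:
    def _predictors(self, ann, p_by_row):
        rows = []
        for (_, row), prob in zip(ann.iterrows(), p_by_row):
            calls = {f"call_{k+1}": int(prob) for k in range(5)}
            rows.append({"sample_id": row.sample_id,
                         "protein_id": row.protein_id,
                         "position": row.position, **calls})
        return pd.DataFrame(rows)

    def test_fisher_matches_enumeration_on_balanced_table(self):
        odds, p, corrected = fisher_one_sided([[5, 0], [0, 5]])
        from math import comb
        assert p == pytest.approx(1 / comb(10, 5), rel=1e-12)
        assert corrected  # zero cells trigger the 0.5 substitution

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8),
           st.integers(0, 8))
    def test_fisher_matches_enumeration_oracle(self, a, b, c, d):
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        _, p, _ = fisher_one_sided([[a, b], [c, d]])
        assert p == pytest.approx(fisher_greater_oracle(a, b, c, d),
                                  abs=1e-12)

    def test_scores_count_true_calls(self, small_bundle):
        proteome = small_bundle.proteome
        ann = classify_mutations(small_bundle.mutations, proteome.sites,
                                 regions=proteome.merged_regions())
        scored, n_excluded = impact_scores(small_bundle.predictors, ann)
        call_cols = [c for c in small_bundle.predictors.columns
                     if c.startswith("call_")]
        assert scored["impact_score"].between(0, len(call_cols)).all()
        assert (scored["consensus"]
                == (scored["impact_score"] == len(call_cols))).all()
        assert n_excluded == 0

    def test_association_detects_planted_consensus_excess(self, small_bundle):
        proteome = small_bundle.proteome
        ann = classify_mutations(small_bundle.mutations, proteome.sites,
                                 regions=proteome.merged_regions())
        _, cont = impact_association(small_bundle.predictors, ann)
        assert cont.table.sum() == len(ann)
        assert cont.sidedness == "greater"
        assert 0 < cont.p <= 1
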