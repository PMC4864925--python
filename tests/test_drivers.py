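"""Per-gene active-site model, hotspots, and the binned permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ptmdriver.config import ACETYL, UBIQ
from ptmdriver.datatypes import ProteinRecord, PTMSite
from ptmdriver.drivers import (cancer_gene_permutation_test, find_hotspots,
                               fit_gene_model, gene_ptm_pvalue,
                               run_activedriver)
from ptmdriver.mapping import classify_mutations, merge_regions
from ptmdriver.stats_util import bh_fdr

from oracles import bh_oracle, poisson_upper_tail_oracle


def _gene(pid="G1", length=100, disorder=None):
    seq = ["A"] * length
    seq[49] = "K"
    rec = ProteinRecord(protein_id=pid, sequence="".join(seq))
    rec.disorder = (np.zeros(length, dtype=bool) if disorder is None
                    else disorder)
    rec.conservation = np.full(length, 0.5)
    return rec


def _muts(pid, positions):
    return pd.DataFrame([{"sample_id": f"S{i}", "protein_id": pid,
                          "position": int(p), "ref_aa": "A", "alt_aa": "V",
                          "cancer_type": "T"}
                         for i, p in enumerate(positions)])


class TestGeneModel:
    def test_uniform_rate_closed_form(self):
        """Constant disorder, 10 mutations, regions covering 20% of the
        gene: E = 10 * 0.2 = 2."""
        length = 75  # single site => region 43..57 = 15 residues = 20%
        rec = _gene(length=length)
        sites = [PTMSite("G1", 50, frozenset((ACETYL,)))]
        muts = _muts("G1", np.linspace(1, length, 10).astype(int))
        model = fit_gene_model(rec, sites, muts)
        assert model.region_length == 15
        assert model.expected == pytest.approx(2.0, rel=1e-9)
        assert model.uniform_fallback

    def test_zero_region_mutations_gives_p_one(self):
        rec = _gene(length=100)
        sites = [PTMSite("G1", 50, frozenset((ACETYL,)))]
        muts = _muts("G1", [1, 2, 3, 90, 95])
        model = fit_gene_model(rec, sites, muts)
        assert model.observed == 0
        assert model.p == 1.0

    def test_disorder_covariate_shifts_expectation(self):
        """Mutations concentrated in the disordered half: the fitted null
        assigns more expectation to a disordered region than the uniform
        rate would."""
        length = 200
        disorder = np.zeros(length, dtype=bool)
        disorder[:100] = True  # first half disordered; region inside it
        rec = _gene(length=length, disorder=disorder)
        rec.sequence = "A" * 49 + "K" + "A" * 150
        sites = [PTMSite("G1", 50, frozenset((ACETYL,)))]
        rs = np.random.default_rng(0)
        positions = np.concatenate([rs.integers(1, 101, 80),
                                    rs.integers(101, 201, 20)])
        model = fit_gene_model(rec, sites, _muts("G1", positions))
        assert not model.uniform_fallback
        uniform_e = len(positions) * model.region_length / length
        assert model.expected > uniform_e

    def test_planted_threefold_region_rate_recovered(self):
        """A gene whose PTM region carries 3x the background per-residue
        rate: O/E within ±20% of 3 for small region fractions."""
        length = 400
        rec = _gene(length=length)
        rec.sequence = "A" * 199 + "K" + "A" * 200
        sites = [PTMSite("G1", 200, frozenset((UBIQ,)))]
        region = set(range(193, 208))
        rs = np.random.default_rng(5)
        weights = np.array([3.0 if (i + 1) in region else 1.0
                            for i in range(length)])
        weights /= weights.sum()
        positions = rs.choice(length, size=200, p=weights) + 1
        model = fit_gene_model(rec, sites, _muts("G1", positions))
        ratio = model.observed / model.expected
        # the null expectation absorbs part of the planted signal:
        # E[O/E] = 3/(1+2f) ~ 2.8 at f = 15/400
        assert ratio == pytest.approx(3.0, rel=0.2)

    def test_central_only_mode_scores_lysines_alone(self):
        rec = _gene(length=100)
        sites = [PTMSite("G1", 50, frozenset((ACETYL,)))]
        muts = _muts("G1", [50, 50, 48, 53, 10, 20])
        model = fit_gene_model(rec, sites, muts, central_only=True)
        assert model.region_length == 1
        assert model.observed == 2  # only the two direct hits


class TestPoissonTail:
    @pytest.mark.parametrize("observed,lam", [(0, 1.0), (3, 3.0), (10, 1.0)])
    def test_examples_match_direct_summation(self, observed, lam):
        assert gene_ptm_pvalue(observed, lam) == pytest.approx(
            poisson_upper_tail_oracle(observed, lam), abs=1e-12)

    def test_ten_observed_on_expectation_one_is_extreme(self):
        assert gene_ptm_pvalue(10, 1.0) < 1e-6

    def test_grid_agreement_with_oracle(self):
        """Exact agreement (1e-10) with term-by-term summation over a grid
        of observed <= 200, lambda <= 100."""
        for lam in (0.1, 0.5, 1.0, 5.0, 20.0, 50.0, 100.0):
            for obs in (0, 1, 2, 5, 10, 50, 120, 200):
                assert gene_ptm_pvalue(obs, lam) == pytest.approx(
                    poisson_upper_tail_oracle(obs, lam), abs=1e-10)

    def test_super_uniform_under_null(self):
        """Discrete Poisson p values are stochastically >= uniform under
        the null (conservative gene test)."""
        rs = np.random.default_rng(8)
        lam = 4.0
        draws = rs.poisson(lam, size=4000)
        pvals = np.array([gene_ptm_pvalue(int(o), lam) for o in draws])
        for alpha in (0.01, 0.05, 0.1, 0.25):
            assert (pvals <= alpha).mean() <= alpha + 0.01


class TestBH:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=400))
    def test_bh_matches_from_definition_oracle(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_oracle(pvals),
                                   rtol=0, atol=1e-12)

    def test_bh_on_large_random_vector(self):
        rs = np.random.default_rng(9)
        p = rs.random(10_000)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=0,
                                   atol=1e-12)


class TestRunActivedriver:
    def test_central_only_ignores_flank_signal(self):
        """A cohort whose planted signal sits entirely in flanking residues
        yields no significant gene in central-lysine-only mode."""
        length = 300
        genes, sites, frames = {}, [], []
        rs = np.random.default_rng(11)
        for i in range(30):
            pid = f"G{i:02d}"
            rec = _gene(pid, length=length)
            rec.sequence = "A" * 149 + "K" + "A" * 150
            genes[pid] = rec
            sites.append(PTMSite(pid, 150, frozenset((ACETYL,))))
            # flank-only enrichment: hits at offsets 3..7, never offset 0
            flank = np.concatenate([rs.integers(143, 148, 12),
                                    rs.integers(153, 158, 12)])
            background = rs.integers(1, length + 1, 30)
            background = background[background != 150]
            positions = np.concatenate([flank, background])
            df = _muts(pid, positions)
            df["sample_id"] = [f"S{i}_{j}" for j in range(len(df))]
            frames.append(df)
        muts = pd.concat(frames, ignore_index=True)
        central = run_activedriver(genes, sites, muts, central_only=True)
        assert (central["fdr"] >= 0.05).all()
        full = run_activedriver(genes, sites, muts)
        assert (full["fdr"] < 0.05).any()

    def test_output_sorted_with_fdr_column(self, small_bundle):
        table = run_activedriver(small_bundle.proteome.records,
                                 small_bundle.proteome.sites,
                                 small_bundle.mutations)
        assert (table["p"].to_numpy()[:-1] <= table["p"].to_numpy()[1:]).all()
        assert (table["fdr"] >= table["p"] - 1e-15).all()


class TestHotspots:
    def _annotations(self, n_snvs):
        sites = [PTMSite("P1", 50, frozenset((ACETYL, UBIQ)))]
        muts = _muts("P1", [47 + (i % 7) for i in range(n_snvs)])
        muts["cancer_type"] = ["T%d" % (i % 2) for i in range(n_snvs)]
        regions = merge_regions(sites, {"P1": 100})
        ann = classify_mutations(muts, sites, regions=regions)
        return regions, ann

    def test_five_snvs_excluded_six_included(self):
        regions, ann5 = self._annotations(5)
        assert len(find_hotspots(regions, ann5, min_snvs=6)) == 0
        regions, ann6 = self._annotations(6)
        hot = find_hotspots(regions, ann6, min_snvs=6)
        assert len(hot) == 1
        assert hot["n_snvs"].iloc[0] == 6
        assert hot["combinatorial"].iloc[0]  # both PTM types on the site
        assert "T0:3" in hot["per_cancer_type"].iloc[0]

    def test_disjoint_regions_never_double_count(self, small_bundle):
        regions = small_bundle.proteome.merged_regions()
        ann = classify_mutations(small_bundle.mutations,
                                 small_bundle.proteome.sites, regions=regions)
        hot = find_hotspots(regions, ann, min_snvs=2)
        in_regions = ann[ann["region_id"] != ""]
        assert hot["n_snvs"].sum() <= len(in_regions)


class TestCancerGenePermutation:
    def _counts(self, n=200, seed=0):
        rs = np.random.default_rng(seed)
        return pd.Series(rs.poisson(20, n),
                         index=[f"G{i:03d}" for i in range(n)])

    def test_detected_equals_universe_gives_p_one(self, rng):
        counts = self._counts()
        known = set(counts.index[:10])
        res = cancer_gene_permutation_test(set(counts.index), known, counts,
                                           n_bins=10, n_permutations=500,
                                           rng=rng)
        assert res.observed_overlap == 10
        assert res.empirical_p == 1.0

    def test_disjoint_sets_give_p_one(self, rng):
        counts = self._counts()
        res = cancer_gene_permutation_test(set(counts.index[:20]),
                                           set(counts.index[50:60]), counts,
                                           n_bins=10, n_permutations=500,
                                           rng=rng)
        assert res.observed_overlap == 0
        assert res.empirical_p == 1.0

    def test_detected_containing_known_is_significant(self, rng):
        counts = self._counts()
        known = set(counts.index[:8])
        detected = known | set(counts.index[100:104])
        res = cancer_gene_permutation_test(detected, known, counts,
                                           n_bins=10,
                                           n_permutations=10_000, rng=rng)
        assert res.empirical_p <= 1e-2

    def test_single_bin_reduces_to_hypergeometric(self, rng):
        """With one bin the permutation distribution is hypergeometric;
        the empirical p matches the exact tail within Monte-Carlo error."""
        counts = self._counts(n=60)
        detected = set(counts.index[:15])
        known = set(counts.index[10:22])  # overlap 5
        res = cancer_gene_permutation_test(detected, known, counts, n_bins=1,
                                           n_permutations=40_000, rng=rng)
        exact = stats.hypergeom.sf(res.observed_overlap - 1, 60, 15, 12)
        assert res.observed_overlap == 5
        assert res.empirical_p == pytest.approx(exact, abs=0.01)
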