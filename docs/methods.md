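# Methods

This note documents the statistical models, the numerical and design
choices, and what the synthetic-data experiments do and do not
demonstrate. Positions are 1-based, intervals closed, and every
resampling test reports the one-sided add-one empirical p value
p = (1 + #{null ≥ observed}) / (1 + n_shuffles), which is never 0 and
never below 1/(n_shuffles + 1).

## Site mapping and mutation classification

PTM sites arrive either position-resolved or as 15-mer windows (the
modified lysine with seven flanking residues on each side; `_` pads
windows that run past a terminus). 15-mers are matched as exact
substrings of the padded sequence: every exact occurrence yields a
site, partial matches are discarded, and records whose central residue
is not K are rejected and counted. Duplicate (protein, position)
records union their PTM types; a site carrying both acetylation and
ubiquitination is a shared (combinatorial) site.

PTM regions are maximal merged intervals of overlapping per-site
windows [p−7, p+7] clipped to [1, length]; windows that touch without
overlapping remain separate regions, so regions of one protein are
pairwise disjoint and sorted. Region membership is checked in tests
against a brute-force per-residue marking oracle, and merging is
idempotent.

A mutation's category comes from its minimal absolute offset to a
same-protein modified lysine: 0 = direct, 1–2 = proximal, 3–7 = distal,
otherwise none. When two sites are equidistant on both flanks, the
category is unchanged (it depends only on distance) and the tied sites'
PTM types are unioned — chosen for determinism. Silent (ref = alt)
records are rejected at load.

Hypermutated samples are removed before analysis. The default rule
flags samples with log₁₀ burden > median + 3·MAD (strict inequality, so
constant-burden cohorts flag nothing); the rule is pluggable
(`hypermutation_rule: none` disables it) and the filter report lists
flagged samples, burdens, and the threshold, since no canonical
cutoff exists for "extreme" burden.

## Bootstrap selection statistics

All four proteome-wide contrasts share one null: each protein's
mutations are reassigned uniformly at random over that protein's
eligible residues, preserving per-protein mutation totals. The
per-protein choice (rather than pooling across the proteome) avoids
confounding by gene-level mutation-rate heterogeneity — a heavily
mutated gene contributes equally heavy null draws. Because resampled
positions are independent and uniform within a protein, the protein's
null in-class count is *exactly* Binomial(m_i, f_i) with f_i its
eligible-class residue fraction; the null total is therefore sampled as
a sum of independent binomials. This is the bootstrap distribution
itself computed without materializing positions, not an approximation.

- **Region enrichment** (per PTM type): scope is proteins with ≥1 site
  of that type; the statistic is the count of mutations inside the
  type's merged regions; the fold change is the per-residue rate inside
  regions over the rate outside. Proteins whose regions cover the whole
  sequence contribute no complement; if no complement exists anywhere
  the result is marked not applicable.
- **Central-lysine enrichment**: both groups restricted to K residues;
  null reassigns each protein's lysine mutations over its lysine
  positions; proteins with no unmodified lysine are excluded (no
  within-protein contrast exists).
- **Domain concentration**: among PTM-associated mutations, observed
  in-domain count vs redistribution over the protein's PTM-region
  residues, so the contrast is domain vs non-domain *within* PTM
  sequence and PTM association is preserved under the null. If domains
  cover every assessed residue the rates coincide trivially and the
  result is FC = 1, p = 1.
- **Conservation contrast**: statistic = mean conservation of
  PTM-region mutations / mean of non-PTM mutations, separately for
  disordered and structured residues; the null permutes the PTM/non-PTM
  labels over mutated residues within the stratum. Means rather than
  medians are used (the contrast of interest is a shift in average
  constraint); a stratum with fewer than two mutations in either group
  is reported not applicable, and the low-level two-group routine
  raises on an empty group.

Predictor ensemble scores count deleterious calls per SNV (0 to the
number of predictors; "consensus" = all predictors agree). The 2×2
association of consensus × PTM-region membership is tested one-sided
with Fisher's exact test (hypergeometric upper tail); the reported odds
ratio applies a 0.5 continuity substitution only when a zero cell
occurs, and says so.

Type-I error of the bootstrap machinery is measured, not assumed: under
the generator's own null the region-enrichment test at α = 0.05 rejects
in ~5–6% of 400 replicate cohorts (1000 shuffles each).

## Gene-level driver model

For one gene, per-residue mutation counts y (length L) are regressed on
the disorder track under a Poisson log-link null — deliberately
excluding any PTM term, so PTM-region excess shows up in the tail test
rather than the fit. E is the sum of fitted means over PTM-region
residues, O the observed region count, and

  p = P(X ≥ O | E), exact (via the regularised incomplete gamma).

An exact tail on the null expectation was chosen over a
likelihood-ratio test because single genes have small counts where the
χ² asymptotics of an LRT are unreliable; the cost is conservatism: the
null fit absorbs part of a real signal, so for a planted rate ratio r
over a region fraction f, E[O/E] ≈ r/(1 + (r−1)f) < r. Genes with a
constant disorder track (or failed fits) fall back to the uniform rate
total/L, flagged in the output; p values under the null are
super-uniform (discreteness), verified by simulation. An alternate mode
scores only the central lysines themselves, which removes any signal
living purely in flanking residues. BH FDR is applied across tested
genes (≥1 site and ≥1 mutation). A site-density covariate is
deliberately not in the default null — with one predictor track per
residue the disorder-only model is identifiable on single genes —
though the per-category counts (direct/proximal/distal) are reported
for inspection.

Hotspots are merged regions with more than five mutations (≥6), with
per-cancer-type counts and a combinatorial flag when a region's sites
carry both PTM types.

The known-cancer-gene permutation test bins all genes into equal-size
quantile groups by mutation count (quantile bins because "groups by
mutation frequency" admits many constructions and equal occupancy keeps
every bin drawable); each permutation draws, per bin, as many genes as
the bin holds known genes, uniformly without replacement, and the
statistic is the draw's overlap with the detected set. Within a bin
that overlap is exactly hypergeometric, so the permutation distribution
is sampled from per-bin hypergeometric laws directly — identical in law
to label permutation and orders of magnitude faster, which is what
makes the 10⁷-permutation configuration feasible. The default is 10⁵
permutations; with n_bins = 1 the test provably reduces to the
hypergeometric tail (verified against the exact tail in tests).

## Pathway enrichment

Only PTM-bearing proteins participate. After size filtering (3–1000
modified members), the background rate is total PTM-region mutations /
total PTM-region length over the union of all filtered sets' members —
the pathway-annotated universe, matching the expected-rate definition
over "all pathway-associated protein sequence"; a per-protein-rate
alternative is exposed as an option. Each set's expected count is
rate × set PTM-region length; p is the exact Poisson upper tail; sets
with fewer than two separately mutated member proteins are dropped
(single-driver guard) with machine-readable reasons; BH FDR over tested
sets. Both filters are pure predicates of the set, so filter order
cannot change the reported rows. The enrichment-map export connects
significant sets whose overlap coefficient |A∩B| / min(|A|,|B|) reaches
0.5 (the conventional enrichment-map default); thematic curation of the
resulting network is a human step on the exported tables.

## Survival modules

The two-group log-rank statistic uses the shared-risk-set convention
for ties: all d events at a time contribute with the common risk set n,
variance term d·(n₁/n)(1−n₁/n)(n−d)/(n−1). It is implemented as a
vectorized routine over a pre-sorted cohort because the greedy search
evaluates it millions of times (the tests check it against both a
from-definition oracle and lifelines). Each module records the sign of
O−E for carriers, so the direction of the survival effect is reported,
never enforced.

Greedy growth starts from a seed gene, and at each step adds the
neighbouring gene whose carrier patients most reduce the log-rank p,
requiring strict improvement; a neighbour contributing no new carriers
cannot change p and is never added. Ties break to the smallest p, then
the lexicographically smallest gene id, making the search fully
deterministic. Carriers are patients with ≥1 PTM-associated
(direct/proximal/distal) mutation in a module gene; cancer types are
analysed separately (types under 10 patients are skipped); seeding is
restricted to mutated network genes (an unmutated seed defines an empty
carrier group), optionally to genes with at least `min_seed_carriers`
carriers, and duplicate node sets are deduplicated keeping the best p.
The default size cap is 20 genes; cap and stopping rule are
configurable.

Significance control: each of the (default 100) permutations applies a
uniform random relabeling of the network's nodes — topology and
per-gene carrier sets are preserved, only their pairing is broken —
reruns the full search, and records its best (minimum) module p. A
module's empirical p is the add-one fraction of permutations whose best
p is at least as small. Using the min-p distribution absorbs the
selection effect of the greedy search, which raw per-module BH would
not; the cost is conservatism, because the permuted data retain the
survival signal inside carrier sets, and on small networks shuffled
signal genes occasionally reassemble into competitive modules. This
trade-off shapes the validation scenario below.

## The synthetic-data generator

The generator emulates, at reduced scale, the statistical structure of
a pan-cancer missense cohort over lysine-modified proteins. Defaults
(SimulationConfig): 200 proteins of mean length 450 (Poisson, floor
60); lysine frequency 0.058 (human proteome average); site rate 0.15
per lysine with mild sequence clustering around anchor lysines (real
PTM sites cluster); 11% of sites shared between acetylation and
ubiquitination and a 25% acetylation share among the rest (the
approximate proportions of curated site collections); two-state
disorder segments (stationary fraction 0.25, mean disordered segment 30
residues); conservation ~ Beta with concentration 8, mean 0.5
background and +0.10 inside PTM regions (so conservation contrasts are
recoverable by construction); domain intervals of 40–120 residues at ~3
per 1000 residues. Cohort: per-sample burden ~ NegBin(mean 40,
dispersion 2) — the over-dispersion of real cohorts; no burden model is
canonical — with a 3% hypermutator tail at 20× burden; mutation
positions uniform over residues except PTM-region residues of planted
driver genes, which carry `driver_ptm_enrichment`-fold weight (so the
planted in/out rate ratio equals the configured fold exactly); the
alternate amino acid is uniform over the 19 non-reference residues
(nucleotide-level substitution signatures are out of scope at protein
level); predictor calls are independent Bernoulli with higher success
probability inside PTM regions. Network and survival: nodes are
modified proteins plus a 10% sample of unmodified "enzyme" proteins;
background edges ~ Bernoulli(0.02); the planted module is wired like a
protein complex (spanning path plus internal edges at 0.4) and placed
on the most heavily modified proteins (largest total PTM-region length,
excluding drivers) — mirroring the histone/ligase hubs that anchor real
survival modules; survival is exponential with median 1000 days,
carriers of PTM-region mutations in module genes have their hazard
multiplied by `module_hazard_ratio`, and a `censoring_rate` fraction of
patients is censored uniformly before their event. Every stage draws
from an independent stream seeded by (seed, stage index), so bundles
are byte-identical across runs and stages can be regenerated
independently.

What the generator does *not* emulate: trinucleotide mutation
signatures and codon structure, correlated predictor errors,
cancer-type-specific burden or survival baselines, scale-free network
topology, isoform structure, and expression. Passing the validation
suite therefore demonstrates the statistical machinery is correct and
calibrated under the stated generative assumptions — not that effect
sizes on real cohorts will match.

## Validation scenarios (calibration module)

Scenario sizes were chosen to give the experiments adequate power on a
single CPU in minutes; they are fixed in `ptmdriver/calibration.py`.

- **Bootstrap calibration**: 40-protein proteome, 400 null cohorts,
  1000 shuffles — rejection fraction at α = 0.05 lands in [0.02, 0.08].
- **Effect recovery**: every gene a driver at 1.5× regional rate,
  ~10⁵ mutations — the in/out rate-ratio estimate lands within ±0.1.
- **Driver recovery**: 500 genes, 5 planted drivers at 3×, 600 samples
  at burden 100. The cohort size follows a power calculation: with the
  exact-tail-on-null-expectation design the per-gene detection z-score
  is ≈ √(m·f)·2(1−f)/(1+2f) for m gene mutations and region fraction f;
  planted drivers here have f ≈ 0.1–0.2, so m ≈ 130 gives ≥90%
  per-driver power at the BH threshold. Recovery is ≥4/5 with 0 false
  positives; pure-null cohorts yield a median of 0 significant genes.
- **Pathway signal**: one 20-gene set at 2× among 200 null sets,
  400 samples — ranks first and passes FDR < 0.05 in ≥90% of 20
  replicate cohorts; null cohorts yield a median of 0 significant sets.
- **Module recovery**: 150 proteins, 200 patients, 8-gene module,
  hazard ratio 3, censoring 0.1, sparse background (edge p = 0.005),
  burden 18 — a few carriers per background gene and tens for the
  module, the regime the method targets. Success = some
  permutation-significant module with Jaccard ≥ 0.5 against truth;
  measured ≥90% over 20 replicates, with null cohorts (hazard ratio 1)
  at a median of 0 significant modules. On denser networks or heavier
  cohorts the min-p permutation control grows markedly more
  conservative (see above), which is the main practical caveat for
  applying the module search at very small network scale.
- **Exact tests**: Poisson tails, Fisher, BH, and log-rank agree with
  independent from-definition oracles to 10⁻¹⁰–10⁻⁸ over the tested
  grids; log-rank null p values are uniform (KS).

## Known limitations

- The gene test's conservatism grows with the PTM-region fraction of a
  gene; genes that are almost entirely PTM region are nearly
  untestable by design (the null absorbs the signal).
- The pathway background treats all regional sequence as exchangeable;
  covariate-adjusted backgrounds (expression, replication timing) are
  out of scope.
- The module permutation control is family-wise and conservative; on
  small or dense networks true modules with modest hazard ratios will
  often fail it. Raw log-rank p values are reported alongside so users
  can inspect sub-threshold modules.
- Genomic (DNA-level) coordinates, isoform selection, and external
  database retrieval are out of scope; inputs are protein-level tables.
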