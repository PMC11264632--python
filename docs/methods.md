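# Methods

This note documents the models, algorithms, numerical conventions and design
choices behind gutscape, and what the synthetic-data validation does and
does not demonstrate.

## Null-model partitioning of community assembly

For a pair of communities *x*, *y* the observed statistic is the
abundance-weighted β-mean-nearest-taxon distance

βMNTD(x,y) = ½ [ Σᵢ fᵢ·min_{j∈y} d(i,j) + Σⱼ fⱼ·min_{i∈x} d(j,i) ],

with fᵢ relative abundances (1/S when unweighted; flag exposed, default
weighted) and d the patristic distance on the rooted phylogeny. **βNTI** is
the z-score of βMNTD against a null built by shuffling taxon labels across
all tree tips; **RC** (Raup–Crick on Bray–Curtis) re-assembles both samples
under a neutral null that preserves each sample's richness and total
abundance, draws taxa without replacement with probability proportional to
regional occupancy (via Gumbel-top-k keys, equivalent to sequential
weighted sampling), seeds one individual per drawn taxon and fills the
remainder multinomially in proportion to regional relative abundance;
RC = 2·[(#{BC_null<BC_obs} + ½#{BC_null=BC_obs})/n_rand − ½] ∈ [−1,1].
Ties use an absolute tolerance of 1e−10, adequate because Bray–Curtis on
integer counts is rational. The classification is βNTI < −2 homogeneous
selection, βNTI > 2 variable selection, then RC > 0.95 dispersal
limitation, RC < −0.95 homogenizing dispersal, else drift; boundary values
fall to the less extreme class. Both null models are verified against
exhaustive enumeration on tiny instances in the test suite.

**Matrix-wide nulls.** Each of the (default 1,000) randomizations draws one
tip permutation / one set of null communities shared by every pair, the
convention of the standard R implementations of these statistics. The null
distribution per pair is identical to per-pair independent nulls; sharing
makes all-pairs runs scale with n_rand rather than n_rand × n_pairs, and
results remain order-independent because nulls depend only on the run seed.

**Degenerate pairs.** When two samples contain exactly the same taxa, every
shuffled βMNTD equals the observation (shared taxa sit at distance zero
regardless of labels), so the z-score is undefined. If *every* pair is
degenerate (star phylogeny, identical membership throughout) this is an
error; isolated degenerate pairs are set to βNTI = 0 with a logged warning
— the observation carries no evidence of deviation from its null.

## Enterotyping

Genus-collapsed relative abundances → Jensen–Shannon *distance* (square
root of the divergence, natural logarithm, 0·log 0 := 0) so the quantity is
a metric; PAM with deterministic BUILD initialisation and greedy SWAP (the
seed only breaks exact ties); k chosen by the Calinski–Harabasz index
computed from the distance matrix through the medoid-based pseudo
sum-of-squares decomposition, searched over k = 2…6; mean silhouette width
reported alongside, with a "weak structure" flag below 0.25 — a CH argmax
always exists, so the flag is what distinguishes genuine cluster structure
from forced partitions. Low-abundance genus removal before clustering is
available but off by default. Between-enterotype contrasts use
Kruskal–Wallis with tie correction and Benjamini–Hochberg adjustment
across genera.

## Diversity

chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)). Faith's PD
includes the path from the induced subtree to the root, matching the
convention of the widely used core-metrics pipelines; the toy-tree hand
values in the tests pin this choice. Rarefaction is a single
without-replacement draw (multivariate hypergeometric) at a fixed seed, not
an average over draws; samples below depth are dropped and logged.
PERMANOVA p-values carry the +1 correction in numerator and denominator, so
999 permutations give a floor of 0.001; pairwise group contrasts are
BH-adjusted (the choice of correction was open; BH matches the rest of the
package).

## Environmental association

VIF_j = 1/(1−R²_j) with perfect collinearity reported as +inf rather than
an error. The marginal adonis-style screen uses the distance-based linear
model: for a centred covariate x, SS_model = xᵀGx/xᵀx with G the
Gower-centred −½D² matrix; permutations act on the covariate. Alpha–GLMs
use Poisson/log for chao1 (values rounded for the likelihood) and
Gaussian/identity for Faith's PD — PD is continuous, so a Poisson model
would be misspecified even though both indices are often fitted together.
Distance–decay regression reports the OLS slope/intercept/r of similarity
(1 − Bray–Curtis) on great-circle distance (haversine, R = 6,371 km) but
takes its p-value from a Mantel-style permutation of sample identities,
because pairwise points are not independent. CCA is the classical
chi-square form: q̄ᵢⱼ = (pᵢⱼ − rᵢcⱼ)/√(rᵢcⱼ), weighted regression on
standardized covariates, SVD; total inertia equals the table's chi-square
statistic over its grand total (asserted in tests), and the permutation
ANOVA permutes covariate rows and recomputes the constrained-inertia
pseudo-F. A "CCA on Bray–Curtis" is not a defined operation — CCA implies
chi-square distances; the package implements the classical form and leaves
distance-based RDA out of scope. envfit fits each covariate onto the first
two ordination axes; r² is the fraction of covariate variance explained
and the arrow is the unit-norm coefficient vector.

## Synthetic data

The generator emulates the post-denoising state of a landscape survey: 58
sites × 3–20 samples by default, 200 taxa, 4,530 reads per gut (test and
acceptance runs use 12–20 sites and depths of 1,000–2,000 to keep the
suite fast; these sizes are stated in the relevant tests and in
`scripts/acceptance.py`). Trees are ultrametric pure-birth (Yule) trees —
ultrametricity makes βMNTD hand-checkable. Traits evolve by Brownian
motion with an optional early-burst decay (step variance scaled by
exp(−c·depth/T), default c = 3 in community simulation): with change
concentrated near the root, traits are clade-distinct, i.e. strongly
conserved — the regime in which habitat filtering produces a genuine βNTI
signature. Plain BM traits carry detectable signal (tested against
label-shuffled traits) but too little tip-level clustering for reliable
βNTI < −2 at these community sizes.

Abundances start from a heavy-tailed lognormal regional pool (σ = 2; σ = 1
under selection so the niche filter, not the pool, sets dominance). The
five regimes:

* **neutral_drift** — shared pool, per-sample lognormal noise σ = 0.45,
  calibrated so observed Bray–Curtis sits inside the Raup–Crick null band;
* **homogenizing_dispersal** — one fully mixed pool, residual noise 0.05;
* **dispersal_limited** — independent site pools (mixing weight 0 between
  global and site pools; the weight is exposed for intermediate coupling);
* **homogeneous_selection** — a Gaussian filter anchored on the trait mean
  of the most trait-distinct moderate-sized clade (purity-scored), width
  0.6 × the clade's trait SD, plus a per-sample colonization lottery
  (establishment probability 0.5) and optimum jitter. The lottery is what
  creates presence-level turnover *within* the selected clade — without
  it all samples share their dominant taxa and the βNTI signal vanishes;
* **variable_selection** — site optima spread ±1.5 trait SD with the same
  filter machinery.

`simulate_spatial_survey` composes the forces into a survey-like scenario:
global pool, mild site differentiation (σ = 0.30), small within-site noise
(0.15), and a weak niche filter (strength 0.08) whose site optima track
standardized site temperature — so community structure is genuinely
associated with the environmental covariates. An optional richness
gradient truncates each site pool to its top-K taxa with K increasing in
temperature and precipitation and decreasing in latitude, elevation and
(doubly weighted) human footprint, giving alpha diversity the canonical
geographic signs under marginal fits despite covariate correlations.
Metadata covariates are built with explicit couplings (temperature falls
with latitude and elevation, precipitation tracks temperature, human
pressure falls with elevation) and noise amplitudes chosen so that the
six-covariate VIF screen passes at its threshold of 10.

**What passing tests show — and don't.** The generator produces
multinomial counts from smooth expected compositions; real amplicon data
add compositional artefacts, contamination, variable read depth far below
or above the rarefaction target, and phylogenetic error. Regime recovery
therefore demonstrates that the statistics respond to the forces they
claim to measure under favourable signal-to-noise, not that any particular
real dataset's process fractions are correct. The enterotype mixture uses
well-separated Dirichlet components; recovery there validates the
clustering machinery, not the biological reality of discrete enterotypes.

## Numerical conventions

Seeds: every stochastic routine takes an explicit seed; the pipeline
derives stage seeds as seed ⊕ CRC32(stage name), so toggling one stage
never changes another's results. Permutation p-values always use the
(1 + count)/(1 + n_perm) correction. Silhouette widths of singleton
clusters are 0; identical points give width 0 via the a = b = 0 convention.
PAM swap iterations require an improvement of at least 1e−12 to continue.
CCA drops axes with singular values below 1e−10.

## Known limitations

Per-clade (binned) process partitioning, incidence-based Raup–Crick, βNRI,
and Mantel-correlogram tests of phylogenetic signal — recommended practice
before interpreting βNTI on real data — are not implemented. The assembly
stage streams all pairs in memory; at ~500 samples (130k pairs) the
matrices are still small, but the 1,000-randomization βNTI run is
compute-bound and benefits from a long-running batch job. QIIME2 archives
(.qza) are not parsed; export to TSV/Newick first.
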