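# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `micreco`, and what the synthetic ground truth does and does not
establish about real data.

## Data model

An `OtuTable` is a samples × OTUs matrix of non-negative integer counts with a
per-sample metadata frame (mandatory `group`, optional `sex`, `season`).
Counts are required because the assembly null models resample individuals;
relative abundances are derived views. Zero-total samples are rejected at
load. Trees are rooted Newick with mandatory branch lengths (Faith's PD and
betaMNTD are undefined without them); tree/table mismatches are reconciled by
pruning/dropping with a warning, and become an error below 50 % OTU coverage.
Pooled samples (several hosts per sample) are opaque: one row is one sample.

## Diversity and permutation tests

* **Alpha.** Observed species; Chao1 in the bias-corrected form
  `S + F1(F1−1)/(2(F2+1))` so doubleton-free samples are defined; Shannon in
  log base 2 (the convention of the QIIME-1 tool family; the base is an
  argument); Faith's PD as the branch-length sum of the subtree spanning the
  root and the observed tips. Rarefaction is off by default: none of the
  analyses here require equalized depth, and discarding reads is not a
  decision the library should take silently.
* **Beta.** Bray–Curtis on relative abundances; Jaccard on presence/absence
  (the unqualified term "Jaccard distance" means the binary index, not the
  abundance-weighted Ružička variant).
* **PERMANOVA.** Distance-based sums of squares via the Gower-centered matrix
  `G = −½ J D² J`; terms enter sequentially (grand mean, main effects,
  interaction), each term's SS is `tr((H_k − H_{k−1}) G)` with H the
  projection onto the expanding design; pseudo-F uses the residual from the
  full model. p-values come from free permutation of whole samples —
  permuting raw data is the simplest defensible scheme for a crossed design,
  and its known limitation (interaction tests are only approximate under
  main effects) is accepted and documented rather than hidden behind
  restricted permutation schemes. One-factor results agree with an
  independent implementation to machine precision (tested).
* **ANOSIM / Mantel.** Implemented directly (rank form of R; Pearson r of
  off-diagonal vectors with simultaneous row/column permutation) so that
  every p-value is a pure function of an explicit seed. All permutation
  p-values use `(1 + #{perm ≥ obs}) / (n_perm + 1)`.
* **NMDS.** Nonmetric MDS on the precomputed distance matrix (Kruskal
  stress-1), eight random restarts by default, best stress reported,
  deterministic per seed.

Type-I error of PERMANOVA and Mantel is calibrated empirically: over
thousands of null datasets (i.i.d. multinomial samples with arbitrary
labels) the rejection rate at α = 0.05 sits at ~0.048 (tested at 2,000
simulations; the binomial standard error at that size, ~0.005, is small
against the 0.03–0.07 acceptance band, so the check discriminates real
miscalibration from estimator noise).

## Abundance categories

Classification is per group, on each OTU's minimum and maximum per-sample
relative abundance (zeros included — absence is "rare here"). With
`r = 0.1 %` and `a = 1 %`: RT `max ≤ r`; AT `min ≥ a`; MT strictly inside in
every sample; CRT `min ≤ r` and `r < max < a`; CAT `r < min < a` and
`max ≥ a`; CRAT `min ≤ r` and `max ≥ a`. These six predicates are mutually
exclusive and jointly exhaustive on the feasible (min ≤ max) plane —
boundaries follow the ≤ / ≥ conventions exactly, and an exhaustive grid test
(including values one ulp either side of both cutoffs) enforces the
partition. Group percentages divide by the group's own observed OTU count,
since groups observe different OTU subsets. Evaluating per sample rather
than on group means is deliberate: group means would collapse the
conditional categories.

## Assembly processes

* **betaMNTD** is abundance-weighted by default ("weighted" refers to the
  abundance weighting of both betaMNTD and the Bray–Curtis companion).
  Conspecifics count as distance zero, so identical membership contributes
  nothing — the signal lives entirely in the taxa private to one sample of a
  pair.
* **betaNTI** shuffles OTU labels across all tree tips of the metacommunity
  (999 shuffles by default) and z-scores the observed betaMNTD. A zero null
  standard deviation (star phylogeny; pairs with identical membership) is a
  hard error with a diagnostic rather than a silent zero: a z-score is
  meaningless there. Note this means *exactly* identical samples are not
  classifiable — turnover of at least one taxon is required.
* **RC_bray** uses the richness- and abundance-preserving null: each null
  sample keeps the observed richness and total count, draws membership with
  probability proportional to occurrence frequency across the table's
  samples, seeds each member with one individual and fills the remainder in
  proportion to regional (table-wide) relative abundance. The observed
  dissimilarity's tie-corrected quantile within 999 null draws is rescaled
  to [−1, 1]. Null pools are per group by default (each group's table is
  its own metacommunity); a global pool is a caller choice by passing the
  whole table.
* **Classification rule** (strict inequalities; values exactly at ±2 or
  ±0.95 fall to the next tier): betaNTI > +2 heterogeneous selection;
  betaNTI < −2 homogeneous selection; else RC > +0.95 dispersal limitation;
  RC < −0.95 homogenizing dispersal; else undominated. The positive-RC
  direction follows the standard convention (more turnover than expected =
  limited dispersal); `rc_positive_is_dispersal_limitation=False` flips it
  for comparison with sources that transpose the two dispersal labels.
* **Group summaries** are means of within-group pairwise values (median
  available); the verdict is "determinism" when the modal pair label is a
  selection label, else "stochasticity". The observed-vs-null similarity
  test is a permutation F-test comparing per-pair observed similarities
  with per-pair null means.

## Synthetic communities

The generator exists to give every downstream stage a known answer. One
metacommunity = an ultrametric pure-birth (Yule) tree (height normalized to
1), a log-normal regional pool (`σ = 2`, normalized — reproducing the
rare-taxon-dominated category spectra of real amplicon tables), and a
Brownian habitat trait (rate 1).

Samples are drawn by a **colonization lottery**: candidate taxa get weights,
membership is drawn without replacement in proportion to expected occupancy
under a finite number of colonization events (`colonists = 300`; occupancy
`1 − (1 − w)^colonists`), and individuals are filled multinomially in
proportion to the weights raised to an `evenness` exponent (0.3) — local
interactions flatten realized abundances relative to the extremely skewed
regional pool. Richness is capped at 90 % of the candidate set so two
samples can never be forced into identical membership.

The five processes differ only in the weights:

* **Homogeneous selection** — one shared Gaussian niche filter
  (`exp(−Δ²/2σ²)`, σ = `trait_sigma` = 0.15, hard fundamental-niche cutoff
  at 5 % of the peak). The niche value of a taxon is its Brownian trait *as
  of a conserved ancestral depth* (`niche_depth` = 0.6 of tree height), so
  whole deep clades share a niche. The optimum is anchored at the niche of a
  well-populated resident clade (≥ 30 admitted taxa, chosen by pool mass).
  This matters: with tip-level traits, plain Gaussian filtering does not
  confine membership to clades on a 300-tip tree, and the beta nearest-taxon
  signal never clears −2 — deep niche conservatism is precisely the
  assumption that makes betaNTI informative, and the generator makes it
  explicit and tunable rather than hoping it emerges.
* **Heterogeneous selection** — the same filter with sample-specific optima
  spread over the niche quantiles, so turnover crosses deep clades.
* **Neutral drift** — the unfiltered pool: random assembly by colonization
  and extinction only. Its expected classification is *undominated* (the
  pairwise vocabulary has no drift label).
* **Dispersal limitation** — isolated but established populations:
  membership stays pool-driven (with `dispersal_colonists = 1200`, since
  extinction in an established community is slow) while each sample's fill
  weights are an independent Dirichlet draw with total mass
  `drift_concentration = 3` around the pool, so realized abundances diverge
  far beyond random assembly. Membership divergence alone is not used: at
  small richness the Raup–Crick null's dissimilarity distribution has a long
  right tail and no membership pattern can clear its 97.5 % quantile.
* **Homogenizing dispersal** — one realized common community per group; each
  sample exchanges a fraction `1 − migration` (migration = 0.9) of
  individuals against the pool. Samples are then far more similar than
  random assembly predicts (RC → −1) while still differing in a few taxa
  (betaNTI remains defined).

All defaults were fixed by mechanism-design experiments at the study scale
(12 samples per group, 300 OTUs, depth 20,000) and then frozen; at those
conditions the modal within-group pair label recovers the simulated process
in ≥ 4 of 5 seeds for every scenario (tested, 999 nulls), and per-seed
success is ~14–15/15 in wider scans. The six-group study bundle
(3 sexes × 2 seasons, 4 samples each, 24 samples per season-batch) assigns
per-group processes (configurable), perturbs the pool per season by a
log-normal shift (σ = 0.3), cuts the tree into nested pseudo-phylum /
class / genus clades for taxonomy-aware summaries, and draws per-fish growth
records from log-normal weight models whose daily-growth-coefficient medians
differ by sex (female 0.65, all-female 0.68, male 0.55 % day⁻¹; initial
weight 26.6 g; condition factor ~N(19, 1)).

What the generator does **not** emulate: compositional (closure) artifacts
beyond multinomial sampling, sequencing error and chimeras, overdispersion
from PCR bias, phylogenetic signal in the regional abundances, temporal
autocorrelation, and true per-host covariates. Passing ground-truth recovery
therefore shows the estimators respond to the processes as defined by these
mechanisms — not that every real dataset carries signals this clean.

## Networks

OTUs present in ≥ 50 % of a group's samples (the "majority" convention of
molecular ecological network analysis) are kept; zeros are filled with
0.01 × the smallest nonzero relative abundance before log10 transform;
pairwise Pearson correlations between OTU profiles follow.

The **RMT threshold scan** (default 0.30 → 0.90, step 0.01) thresholds the
correlation matrix at each candidate cutoff, drops isolated rows, computes
eigenvalues, unfolds the spectrum with a cubic smoothing spline fitted to
the cumulative eigenvalue density, and tests the nearest-neighbour spacing
distribution against the Poisson form `e^(−s)` by chi-square (20 equal bins
on [0, 3], expected counts renormalized to the window, bins with expected
count < 1 merged away). The chosen threshold is the smallest whose Poisson
fit (p > 0.05) persists for three consecutive steps — dense correlated noise
shows Wigner–Dyson repulsion and fails the test; modular structure yields
uncorrelated (Poisson) spacings. Duplicate eigenvalues contribute zero
spacings; spectra under 20 distinct eigenvalues or 30 spacings are not
tested (the trace records an NaN p). All three conventions (zero-fill
factor, unfolding, binning) are arguments.

Edges use `|r| ≥ threshold` (boundary inclusive), signed by the correlation;
isolated nodes are dropped. Modules come from networkx's deterministic
fast-greedy (CNM) modularity maximization on the unsigned skeleton — its
internal deterministic tie-handling replaces a bespoke lexicographic
tie-break. Topology indices: avgK = 2E/N (exact identity, asserted), average
clustering, average geodesic on the largest component, degree-distribution
power-law R² (least squares of log10 frequency on log10 degree over observed
degrees — the regression form whose R² network pipelines conventionally
report), modularity, module count and largest-module size. Random baselines
rewire with Maslov–Sneppen double edge swaps (10 successful swaps per edge,
capped attempts); the degree multiset is preserved exactly, and rigid graphs
(cliques) come back unchanged instead of erroring. Zi/Pi use within-module
degree z-scores (0 where a module's degrees have no spread) and
`Pi = 1 − Σ (k_is/k_i)²`; role thresholds Zi = 2.5 and Pi = 0.6 are strict,
with exact-boundary values assigned to the lower tier.

With four samples per group, correlations are extremely noisy; the pipeline
warns below six samples, and the synthetic defaults for network work use
more. The RMT scan needs ≥ ~25 connected nodes to test spacings at all; on
small synthetic groups the pipeline falls back to a fixed 0.80 threshold
with a logged warning.

## Growth indices

Fulton's condition factor `K = 10³·BW/BL³` (BW g, BL cm) and the daily
growth coefficient `DGC = 100·(BW_f^⅓ − BW_i^⅓)/t` (% day⁻¹). A final
weight below the initial weight warns and returns a negative DGC rather
than erroring. Group summaries report mean ± SE in the conventional layout.
Published growth tables print only group means ± SE, so per-fish records
are validation surfaces for the synthetic cohorts, not reproduction targets.

## Pipeline

`run_pipeline` executes data → diversity → categories → assembly → networks
→ growth from one `PipelineConfig` (YAML-loadable), with 999 permutations /
null draws by default, per-stage structured log lines, TSV reports plus JSON
mirrors, and a manifest with the config echo and SHA-256 checksums of every
output; identical configs produce identical checksums. Any stage failure
aborts with the stage name; empty results are never written silently.

## Known limitations

* Free permutation for the PERMANOVA interaction term (see above).
* betaNTI is undefined for identical-membership pairs and star phylogenies
  (hard error by design).
* The RC_bray null conditions on observed richness; processes that express
  themselves purely through richness changes are invisible to it.
* The RMT scan assumes enough OTUs survive the prevalence filter to form a
  testable spectrum; tiny groups fall back to a fixed threshold.
* "Undominated" is not decomposed into weak selection vs drift vs
  diversification.
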