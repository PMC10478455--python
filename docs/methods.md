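# Methods

This note documents the models, numerical choices and known limitations of
`snowassembly`, in the order the pipeline applies them.

## Input handling and filtering

Counts are non-negative integers, taxa as rows (a flag accepts the
transpose). Two filtering rules are applied before analysis: taxa whose
total read count is 1 (singletons) and taxa with nonzero counts in only
one sample are removed. The filter is idempotent. No contaminant removal
is performed — negative-control-based procedures vary between studies and
are left to upstream processing. Counts are not rarefied to even depth:
both null models condition on each sample's observed richness and read
total, so rarefying would discard information without changing the
conditioning; the choice is documented here because results on real data
can shift with it. Alignment prunes the tree to the count table's taxa
(silently — a supertree is expected to carry extra tips) and drops count
taxa missing from the tree with a warning, because every analysed taxon
needs a phylogenetic position.

## Phylogenetic binning

Per-bin null models assume within-bin relatedness. No universally
accepted binning algorithm exists, so the package uses the simplest
deterministic, order-independent construction consistent with the
bin-based framework: single-linkage clustering of the cophenetic distance
matrix cut at height `ds` (default 0.2 tree-distance units), followed by
iterative merging of clusters smaller than `nmin` taxa (default 12) into
the cluster at the smallest average inter-cluster distance, ties broken
toward the lower bin index. Bins are canonically renumbered by their
lexicographically smallest member, which makes the partition and the
indices invariant to input order. Both parameters are surfaced in the run
configuration; on real data `ds` should be tuned to the scale at which
the phylogeny carries ecological signal (the original framework tunes it
by maximizing within-bin phylogenetic signal of environmental optima —
out of scope here because the synthetic data controls that signal
directly).

## Null models

**βNRI.** The beta net relatedness index standardizes the
abundance-weighted β mean pairwise distance βMPD = Σᵢⱼ pᴬᵢ pᴮⱼ dᵢⱼ (the
index's standard basis; β mean *nearest taxon* distance is available
behind the `metric` switch for users who prefer terminal-clustering
sensitivity). Abundances are renormalized within the bin. The null
shuffles the bin's taxon labels across the bin's tip positions — one
permutation applied consistently to both samples — preserving bin
membership and the abundance structure while randomizing phylogenetic
placement. With 1000 randomizations (the default; configurable) the ±1.96
standard-effect-size thresholds are stable. If the null distribution has
(numerically) zero spread the index is undefined and the pair × bin entry
is excluded.

**Modified Raup–Crick.** Bray–Curtis dissimilarity on counts, rank-scaled
against a null that reassembles each of the two samples independently:
membership is a weighted draw without replacement of the sample's
observed within-bin richness with probability proportional to occurrence
frequency across all samples; abundance fills the sample's observed
within-bin read total multinomially in proportion to regional relative
abundance. Ties between null and observed dissimilarity (common in
sparse bins, where both saturate at 1) carry half weight; the score is
2·[(#null<obs) + ½(#null=obs)]/n_rand − 1. A bin reduced to a single
taxon region-wide yields RC = 0 with a warning. Membership draws use the
Gumbel top-k construction so the whole null batch is vectorized; the tie
tolerance is 10⁻¹².

A pair × bin entry is undefined when either sample has no reads in the
bin or the pair spans fewer than two taxa; undefined entries are excluded
and their bin weight redistributed proportionally, so process fractions
always sum to 1 (to 10⁻⁹ in the conservation tests). Null streams are
keyed by (seed, pair index, bin index), making results independent of
evaluation order and bit-reproducible under a fixed seed.

## Process classification and aggregation

The decision rules use strict inequalities for selection (βNRI = ±1.96
falls through to the Raup–Crick rules) and a drift bucket that, per the
framework's definition, aggregates drift, diversification, weak selection
and weak dispersal. Bin weight for a pair is the mean of the two
samples' bin relative abundances — symmetric in the pair; pooled-count
weighting would bias toward the deeper-sequenced sample. Interval
summaries (IntN = global sampling dates N vs N+1 within a site) report
mean ± sample sd (ddof = 1) across sites, matching a "mean ± sd over 4
sites" presentation; single-site intervals report sd = 0 and carry an
`n_sites` column so they can be flagged. Averaging across sites (rather
than pooling all within-interval pairs) is the default because the
motivating design has exactly one pair per site per interval.

## Supporting statistics

Shannon–Wiener uses natural log by default (nats; configurable base).
Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined
when no doubletons exist. Rarefaction is the analytic hypergeometric
expectation E[Sₙ] = Σᵢ[1 − C(N−Nᵢ, n)/C(N, n)], computed with log-gamma.
RDA centres the Hellinger-transformed response, projects it onto the
centred constraints by least squares and eigen-decomposes the fitted
values; collinear constraint columns are dropped with a warning. The
marginal permutation test uses F = (SS_term/1)/(SS_res/(n−q−1)) and
permutes residuals of the reduced model (the model without the tested
term), the standard scheme for marginal tests in constrained ordination;
p = (1 + #{F* ≥ F})/(n_perm + 1) with 999 permutations by default. The
Mantel statistic is the Pearson correlation between the condensed
Hellinger distance vector and Euclidean distances on the first two
constrained axes. Co-occurrence matrices are Pearson correlations with
two-sided t-tests, masked at p < 0.05 without multiple-testing correction
(a correction flag would be trivial to add; the uncorrected presentation
matches common practice for exploratory co-occurrence screens);
zero-variance profiles are masked with a warning.

## Synthetic communities

The generator's default design is the motivating survey: 4 sites × 12
dates, 60 taxa, J = 2000 individuals per sample (J plays the role of
sequencing depth; 2000 keeps multinomial noise realistic while desk-scale
fast).

**Tree.** Two-level pure-birth: a Yule backbone over ⌈n_taxa/10⌉ deep
clades spanning the top half of the (height-1, ultrametric) tree, each
clade running down a bare stem into a tight Yule "bush" occupying the
last 0.1. Amplicon phylogenies have exactly this shape — tight clusters
of sequence variants inside deeply separated clades — and it gives
distance-threshold binning a well-defined scale: within-bush distances
are ≤ 0.2, between-bush distances ≥ 1.0, so the default `ds = 0.2` cut
groups bushes and `nmin = 12` merges each with its phylogenetically
nearest neighbours. Trait optima evolve by Brownian motion along the
tree (rate σ_bm = 1) and are standardized; bushes therefore carry
well-separated trait modes with small within-bush spread.

**Selection scenarios.** Sample counts are multinomial with taxon weight
∝ exp(−(traitᵢ−env_s)²/2σ_w²), σ_w = 0.2 (about the within-bush trait
spread, so a filter admits roughly one bush). Environments sit in the
*tails* of the trait distribution (10%/90% quantiles): under Brownian
evolution extreme trait values are clade-concentrated, whereas
middle-of-the-range values occur convergently across the whole tree and
carry no phylogenetic signal — an environment at the trait mean produces
communities whose dominant taxa are phylogenetically random, which is
exactly what the homogeneous-selection scenario must not be. A 5%
"everything is everywhere" background follows the same filter at broad
width σ = 1.0, keeping every clade represented at trace abundance (as in
real surveys); without it, cross-environment pairs share no bin at all
and are undefined. Homogeneous selection uses one environment for all
sites; heterogeneous selection alternates the low/high environment
between sites.

**Neutral scenarios.** Zero-sum Wright–Fisher dynamics: each generation
every site is resampled from (1−m)·its own frequencies + m·the pooled
metacommunity (equal-weight mixture of current site communities), with
snapshots every T generations. Regional abundances are lognormal
(σ = 1). The scenarios differ in founders and (m, T):

- *drift*: independent weighted-random founder subsets (30 of 60 taxa)
  per site, m = 0, T = 30. Random assembly from the shared pool is the
  Raup–Crick null's own notion of chance, so neither index should be
  extreme — this is what "drift" means operationally.
- *dispersal limitation*: each site dominated (90%) by its own disjoint
  block of taxa with a 10% trickle of the rest, m = 0, T = 5. The short
  inter-date drift keeps the trickle alive; otherwise rare lineages go
  extinct, every observed dissimilarity saturates at exactly 1, the null
  ties there too, and the rank statistic loses resolution.
- *homogenizing dispersal*: shared full-pool founders, m = 1, T = 100.
  Sites track the common pool (similarity at resampling level) while the
  pool itself drifts across dates, so the time-pooled null reassembly is
  systematically more dissimilar than same-date pairs.

**Metadata.** Snow colour follows the observed bloom phenology (white →
light-green → green, with alternate sites turning red late). Nutrient
concentrations are lognormal with mean/sd equal to the field measurements
for green blooms (NH₄⁺ 3.7 ± 3.9, NO₃⁻ 1.0 ± 1.0, PO₄³⁻ 4.3 ± 3.6 mg/L)
and red blooms (5.4 ± 8.5, 0.5 ± 0.5, 6.2 ± 6.6 mg/L). DOC is clipped to
[0, 20] mg/L (the quantification method's reporting range) and, in
selection scenarios, linearly coupled to the site environment so a
constrained ordination has exactly one truly active covariate;
chlorophyll *a* rises lognormally from ~2 to ~900 µg/L across the series.

**What the generator does not emulate:** sequencing error, chimeras,
compositional/primer bias, taxonomy, real nutrient dynamics, or
within-site spatial structure. Passing the recovery tests shows the
inference machinery is correct and calibrated under its own assumptions,
not that any particular real community was assembled by a given process.

## Validation experiments and problem sizes

The acceptance experiments (mirrored in `tests/test_acceptance.py` and
`scripts/acceptance.py`) use desk-scale sizes chosen as a deliberate
compromise between statistical resolution and a single-CPU run of a few
minutes: classifier truth table on a 99-point threshold grid; 1000 fuzzed
tables for mass conservation; brute-force oracle agreement to 10⁻⁹ on
≤10-taxon inputs (tree distances are cross-checked against an independent
phylogenetics library); null self-calibration with 500 pairs × 1000
randomizations (expected ≈5% beyond ±1.96 / ±0.95); scenario recovery
with 20 replicates per scenario at 60 taxa, 4 sites × 6 dates, J = 2000,
300 randomizations, requiring the true process to be the largest
community fraction in ≥80% of replicates; and permutation-test
calibration over 400 null and 100 planted-effect simulations at n = 40.
Recovery is evaluated on same-date between-site pairs: dispersal signals
are inherently between-site contrasts, and the selection and drift
scenarios apply equally to any pair. The ~15% of homogeneous-selection
replicates that fail are geometry edge cases in which the sampled
environment's niche happens to cover an entire bin uniformly, leaving no
within-bin contrast for the phylogenetic index — a real limitation of
bin-based inference, not a sampling artefact.

## Known limitations

- Bin-based inference is blind to selection acting exactly at (or above)
  the bin scale; the binning parameters matter and should be tuned per
  dataset.
- The Raup–Crick null conditions on occurrence frequencies computed from
  the analysed table itself; with few samples these are noisy.
- βNRI's normal-theory thresholds assume an approximately Gaussian null;
  extremely concentrated abundance vectors (one or two effective taxa)
  produce heavy-tailed nulls and conservative inference.
- Interval summaries treat sites as replicates; with one pair per site
  per interval the sd columns rest on four values, as in the motivating
  design.
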