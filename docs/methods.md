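# Methods

This note documents the statistical procedures coregrad implements, the
design choices made where conventions diverge, the synthetic-data model used
for validation, and the limits of what passing tests demonstrate.

## SRS depth normalization

Scaling with ranked subsampling maps a sample's counts c (total N) to a
vector summing exactly to the target depth C_min: scale each count by
C_min/N, keep the integer parts, then hand the remaining
r = C_min − Σ⌊scaled⌋ reads one each to the r features with the largest
fractional parts. The output is entrywise ≤ the input and ranking by output
count refines the input ranking. The reference algorithm breaks
fractional-part ties randomly; our default resolves them deterministically
(larger scaled value first, then input order) so a pipeline is reproducible
without a seed — a seeded random mode is available for fidelity to the
original. Samples with N < C_min are excluded and reported, never silently
dropped; published analyses of this design normalized fly samples to 5,000
reads and the sparser fruit-pulp samples to 500, and those are the pipeline
defaults.

## Unweighted UniFrac and PCoA

For two communities reduced to presence/absence, each tree edge is marked by
a community if any leaf below it is present; the distance is the marked
branch length unique to one community over the branch length marked by
either. The rooted convention is used (edges above the union's most recent
common ancestor count when marked), matching the implementation lineage
common in amplicon work, and unrooted input trees are rejected rather than
auto-rooted because rooting changes the distances. The whole matrix is
computed from an edge × leaf incidence matrix, so tables of hundreds of
samples take milliseconds; tests verify exact agreement (< 1e−12) with a
brute-force per-edge oracle and with scikit-bio's implementation.

PCoA double-centers the squared distances, B = −½·J·D²·J, and
eigendecomposes B. Coordinates use only positive eigenvalues (scaled by
√λ); negative eigenvalues — present whenever the distances are
non-Euclidean, as UniFrac typically is — are reported for diagnostics but
excluded from both the coordinates and the variance denominator. The
alternative convention (normalizing by the sum of absolute eigenvalues)
would report smaller fractions; no Lingoes/Cailliez correction is applied
by default.

## PERMANOVA

One covariate at a time, continuous or categorical. With G the
Gower-centered matrix of squared distances and H the hat matrix of the
centered design,

    pseudo-F = (tr(HGH)/m) / (tr((I−H)G(I−H))/(n−m−1)),  R² = tr(HGH)/tr(G),

which for a single categorical factor coincides exactly with Anderson's
sums-of-squares formulation (verified to 1e−9 on random instances).
Significance comes from permuting covariate rows; the default 999
permutations report p = (1 + #{F* ≥ F})/(1 + 999) so p is never zero, and an
exhaustive mode enumerates all n! permutations for small n (reporting the
plain tail fraction). Under a null covariate the rejection rate at α = 0.05
is calibrated (0.05 ± 0.02 over 1,000 simulations in the test suite). The
pipeline tests each gradient and the inferred cluster partition separately;
no multi-factor or stratified models are fitted, so cluster R² values are
not adjusted for stage composition.

## Gap statistic

For k = 1..k_max, W_k is the pooled within-cluster dispersion (equal to the
k-means SSE) of the best of several k-means++ restarts;
Gap(k) = mean_b log W*_kb − log W_k over b reference datasets drawn
uniformly over each feature's observed range (original feature space, not
the PCA-rotated box — simpler and exposed as a choice), and
s_k = sd_b(log W*)·√(1+1/b). The selected k̂ is the smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1} (the original one-standard-error rule; the
commonly used clusGap function defaults to a slightly different
"firstSEmax" rule). b = 1 cannot estimate the null spread; s_k is set to 0
and the result flagged low-confidence. Following the literal published
usage, the default input is the rows of the distance matrix treated as
feature vectors; clustering PCoA coordinates instead is available via
`gap_embed: pcoa`. The pipeline default is b = 100 reference datasets (the
clusGap default) with k-means restarts kept small; both are configurable
upward, and the package-level `gap_statistic` accepts the b = 1,000 used in
large published analyses.

## Gradient associations

Genus-collapsed counts are total-sum scaled; each feature's zeros are
shifted by a pseudocount equal to half its smallest nonzero relative
abundance (the documented behavior of the MaAsLin2-style LOG transform);
log₂ abundance is regressed on the gradient by OLS with a two-sided t-test
on the slope, and Benjamini–Hochberg q-values are computed across tested
features. Features below 10% prevalence, all-zero features, and
constant-response features are reported as untested rather than dropped, so
the output always has one row per feature. Each fly stage is fitted
separately against its transect's gradient; no multi-covariate or
mixed-effects models are attempted.

## LDA effect size (biomarkers)

Stage one screens each feature with a tie-corrected Kruskal–Wallis test at
α (default 0.05; the fully degenerate all-identical case is defined as
H = 0). Stage two, over 30 bootstraps of ⅔ of each class, fits a one-axis
linear discriminant on the surviving features (unit-normalized axis w) and
scores each feature as the mean over bootstraps of
|w_j·(w·Δμ) + Δμ_j| / 2 for the pair of class means, averaged over class
pairs; the reported score is log₁₀ of that effect on the per-million
abundance scale, and a biomarker needs score > 2 (and, with more than two
classes, the same enriched class in every pairwise mean comparison — strict
mode). Bootstraps in which any class would fall below two samples are
skipped; if all are skipped the input is too small and an error names the
cause. The within-class subclass stage of the original procedure is not
implemented because the target design has no subclasses.

## Bootstrap core microbiota

In each of n_boot = 1,000 replicates every sample is rarefied with
replacement — a multinomial redraw at the sample's own (post-SRS) depth, or
a fixed `depth` — and a feature passes the replicate when its prevalence
(fraction of samples with count > 0) reaches the prevalence threshold. The
support of a feature is the fraction of replicates passed, and the core is
{f : support ≥ 0.95}. Presence means count > 0 after rarefaction, with no
minimum-count floor. Prevalence thresholds follow the published settings:
0.75 for fly groups and 0.65 for the leakier pulp communities. The phrase
"sub-sampling" can also be read as resampling specimens; a
`mode="samples"` column bootstrap is provided and the mode is recorded in
the result. The support statistic is effectively an indicator smoothed by
the detection process: at depth 500 a feature at relative abundance 10⁻⁴
is detected with probability 1−(1−10⁻⁴)⁵⁰⁰ ≈ 0.049 and can never reach a
75% prevalence bar, while abundance 0.1 is detected almost surely — both
limits are verified analytically in the tests. Group-wise cores derive
per-group seeds by hashing, so adding a group never changes another
group's result, and Venn regions partition the union of the group cores.

## Synthetic-community generator

The generator emulates the two-transect field design: 6 latitudinal sites
(17.5–22.5 °N at 50 masl) and 10 altitudinal sites (100–1,900 masl at the
median latitude), stages larva/female/male plus host-fruit pulp, 5
replicates per stage and site (320 samples), 300 ASVs of which 5 carry
chloroplast/mitochondria lineages, sequencing depth Poisson with mean
20,000 (fly) or 2,000 (pulp). Counts are Dirichlet-multinomial
(concentration 200, a moderate overdispersion typical of amplicon data)
around an expected composition assembled from:

- a log-normal base composition (log-sd 1.5) shared across stage groups,
  plus an independent per-group shift (log-sd 1.5) separating larval,
  adult and pulp communities;
- planted core features — by default 7 larva-exclusive, 3 adult-exclusive
  and 2 shared ASVs drawn from acetic-acid-bacteria and rhizobial genera,
  each pinned at 2% expected abundance with occupancy 0.95 in its core
  group, and a 5-member pulp core at occupancy 0.70 (deliberately between
  the 0.65 and 0.75 prevalence thresholds, mirroring a "leaky" pulp
  community); occupancy is an independent Bernoulli presence mask applied
  before abundance, so core ground truth is controlled separately from
  depth;
- genus–latitude log-linear slopes (defaults: Acetobacter +0.3,
  Gluconobacter +0.2, Lactobacillus +0.15, Phyllobacterium −0.3 log₂ units
  per degree, fly stages only). Effects are planted share-wise — a planted
  genus's expected share scales as 2^(β·Δlat) and unplanted features
  absorb the complement — so log₂ relative abundance is *exactly* linear
  in latitude and the association estimator is correctly specified;
  recovery tests therefore test the estimator, not model mismatch.
  Planted-gradient genera are floored at a 2% base share, since
  gradient-responsive genera in these surveys are among the abundant
  community members; a rare planted genus would make recovery
  depth-limited rather than estimator-limited.

Background features have occupancy 0.5 everywhere (organelle contaminants:
0.9 in pulp, 0.3 in flies). All randomness flows from a single config seed
through hashed substreams; identical configs give byte-identical outputs.

What the generator does **not** model: specimen pooling within samples,
taxonomic misclassification, chimeras, occupancy–latitude interactions
(presence patterns are gradient-free, so unweighted UniFrac carries only a
weak, detection-mediated gradient signal), phylogenetic signal in
abundances (the tree is random), and spatial autocorrelation between
sites. Passing recovery tests therefore shows the estimators work when
their assumptions hold at realistic noise levels — not that real
communities satisfy those assumptions.

## Problem sizes and numerical choices

The validation suite uses: 100 random trees (≤ 20 leaves) for the UniFrac
oracle; 200 random instances for the PERMANOVA formulation equivalence and
1,000 null simulations (n = 20, 199 permutations) for its calibration;
1,000 random vectors for the SRS invariants; 50 seeds with b = 100
references for gap-statistic recovery (three 10σ-separated Gaussians, and
a single blob); 100 seeds of a 90-sample design for slope recovery plus
200 global-null simulations for FDR control; 20 seeds of a 30-sample
larval design at n_boot = 1,000 for core recovery; 50 seeds for biomarker
recovery. The end-to-end run uses the full 320-sample default design.

Ties and degenerate inputs: SRS fractional ties break toward the larger
scaled value then input order; k-means reseeds empty clusters (delegated
to scikit-learn); eigenvalues below a relative 1e−12 tolerance count as
zero in PCoA; a constant covariate, a singleton group, an all-excluded
normalization and an empty class are errors that name the offending input;
an all-features-filtered table is a warning, not an error. Permutation
p-values use the +1 correction except in the exhaustive mode, where the
full enumeration already contains the identity.

## Known limitations

- PERMANOVA is single-covariate; reported cluster R² is unadjusted for
  covariates such as developmental stage.
- The LDA effect size reproduces the published procedure's structure but
  not its exact legacy numerics (random-number stream, jitter constants),
  so scores should be compared against its cutoff conventions, not
  digit-for-digit against other implementations.
- The gap statistic on distance-matrix rows inherits the literal published
  usage; it is statistically cleaner to cluster PCoA coordinates, which is
  available but not the default.
- Functional (e.g. nitrogen-fixation gene) prediction is out of scope;
  `annotate_core` only joins externally supplied trait tables onto core
  members.
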