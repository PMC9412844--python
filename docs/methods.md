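# Methods

`kcmnet` implements a correlation-network protocol for integrating three
omics layers measured on the same stool samples in a nutritional
intervention trial — 16S microbial taxa (relative abundances), SPME–GC–MS
volatile compounds (relative abundances) and binned 1H NMR spectra — and
for reading the result through overlapping k-clique communities.  This
note records the model, the tunable parameters and their defaults, the
numerical choices, what the synthetic cohorts do and do not emulate, and
the places where the design was genuinely open.

## 1. Preprocessing

**Median relative-abundance filter.**  Taxa and volatiles below a median
relative abundance of 0.5 % (per feature, in percent) are removed.  The
median is evaluated per timepoint; a feature is kept when it passes at
baseline *or* endpoint (`per_timepoint_union`, the default), so baseline
and endpoint networks share one node set and communities can be compared
feature-by-feature.  Intersection and pooled variants are available.  The
0.5 % threshold is deliberately hard: it produces a compact network whose
communities stay readable.  With an even number of samples the median is
the mean of the two central order statistics.

**Log transform.**  Kept relative abundances are natural-log transformed
(abundance distributions are approximately log-normal).  The base is
irrelevant downstream — Spearman correlation is invariant to any strictly
increasing transform — it only standardises the stored values.  Zeros are
handled by a pseudocount, by default half the smallest positive value of
the table; a zero encountered with a zero pseudocount is a hard error.

**Regional PQN.**  NMR spectra are normalised by the probabilistic
quotient method applied separately to user-specified chemical-shift
regions (typically aromatic / hydroxylic / aliphatic; the ppm bounds are
configuration, not constants).  Within each region every spectrum is
first divided by its regional integral, the reference is the point-wise
median of those profiles, and each spectrum is divided by the median of
its point-wise quotients against the reference.  The initial integral
step makes the operation *exactly* invariant to per-sample, per-region
dilution: a spectrum diluted by any factor normalises to precisely the
profile of its undiluted twin.  The price is that outputs live on the
cohort's consensus scale rather than the raw intensity scale — harmless
here, again because the network step is rank-based.

**Binning.**  Normalised spectra are pooled into consecutive windows of a
fixed number of points (150 by default; a 60,000-point profile becomes
400 buckets) using the window mean.  A trailing partial window is kept
when it holds at least half a window's points, otherwise dropped and
logged.  Bucket ids carry their ppm interval.

## 2. NMR dimensionality reduction

Binned spectra are redundant by construction — adjacent buckets ride the
same peak, and all resonances of one molecule move together.  Without
reduction those buckets form a giant, densely connected spectral
component that dominates network topology while encoding nothing beyond
"a molecule correlates with itself".  Reduction has two steps.

**Step 1 — L1 selection.**  A multinomial logistic regression with L1
penalty is fit on z-scored buckets against a class label taken from the
sample design (by default the intervention arm, using endpoint samples).
The inverse penalty strength C is chosen by stratified 5-fold
cross-validated accuracy over a 10-point log-spaced grid (1e-3…1e3)
under the one-standard-error rule: the sparsest model within one SE of
the best wins.  Buckets whose coefficients are ≤ 1e-8 in absolute value
for every class are dropped (solvers rarely return exact zeros).
Constant buckets are removed up front, using a relative tolerance of
1e-12 on the column standard deviation (floating-point accumulation can
leave a ~1e-16 residue on exactly-constant columns).

Two *no-information guards* make the selection honest.  Before any model
is fit, a Westfall–Young max-F permutation screen (200 label
permutations, α = 0.01, seeded) asks whether the strongest bucket–label
association exceeds chance; and after cross-validation the best model
must beat the majority-class rate by more than its standard error.
Either failure returns an empty selection.  Without the screen, an L1
path tuned by CV will happily keep dozens of buckets for label vectors
that are predictable only by chance (we observed CV accuracies up to 0.60
for permuted labels at n = 200 with 51 features) — a selector that keeps
more under permuted labels than under true ones is not doing feature
selection.

**Step 2 — cophenetic agglomeration.**  Selected buckets are clustered
by average-linkage hierarchical clustering on the distance d = 1 −
Pearson r (not 1 − |r|: anti-correlated buckets are not the same
molecule).  The dendrogram is cut at the smallest merge height that
leaves no singleton cluster, clipped to a cap of 0.7; when no
singleton-free cut exists below the cap, the cap is used (with a warning)
and stray singletons remain.  Each cluster is pooled to a single feature
by the per-sample median of its buckets.  Average linkage pairs naturally
with cophenetic pruning: cutting at height h bounds every intra-cluster
cophenetic distance by h.

The pipeline fits the agglomeration on *baseline* samples only.
Intramolecular correlation is an intrinsic property of the spectra; when
the fit spans both endpoint arms, the intervention shift acts as a shared
binary component that inflates the apparent correlation between
unrelated molecule blocks and can chain-merge them (we observed exactly
this in pilot simulations).

## 3. Network construction

For each subject group the merged table (log taxa + log volatiles +
pooled NMR agglomerates) is reduced to its Spearman correlation matrix
(average ranks for ties; zero-variance features get zero correlations
with a warning) and binarised: an undirected, unweighted edge joins two
features whose correlation strictly exceeds a threshold t.  The adjacency
is the binary Nfeats × Nfeats matrix with zero diagonal; isolated nodes
are retained.

Groups follow the trial design: at baseline, one network per sex with
arms pooled (t = 0.5 by default); at endpoint, one network per sex × arm
cell (t = 0.7).  The harder endpoint threshold compensates for the
smaller per-group sample size — the significance of a correlation is a
function of n.  Thresholding is *signed* by default (ρ > t, reading
"correlation greater than t" literally); an absolute mode (|ρ| > t) is a
flag, because anti-correlations are biologically meaningful.

Two alternative threshold policies are provided:

* **significance** — t is the smallest ρ whose two-sided p-value under
  the t-approximation (t-statistic ρ√((n−2)/(1−ρ²)), df = n−2) falls
  below α (default 0.05), found by Brent root-finding to ≤ 1e-9.  For
  n ≤ 8 an exact permutation null is available (the t-approximation is
  crude for tiny n).
* **soft** — WGCNA-style: correlations are raised to the smallest power
  β whose weighted connectivity k_i = Σ_j |ρ_ij|^β yields a scale-free
  fit index R² ≥ 0.8 (log-log regression of binned connectivity
  frequencies; full fit table recorded).  Because this framework's
  networks are binary, the soft policy maps a pre-power cut (default
  0.5) through the chosen power, t = 0.5^(1/β) — a package
  operationalisation, recorded in provenance.

## 4. Topology and communities

Per network we report nodes, edges, density, average degree, average
local clustering (triangles over deg·(deg−1)/2, zero for degree < 2),
connected components, isolated nodes and the degree histogram, plus a
descriptive scale-freeness diagnostic: an ordinary least-squares fit of
log10(count) on log10(degree) — i.e. y = a·x^b with its R².  Degree-0
nodes are excluded from the fit (log 0); the fit needs at least three
distinct positive degrees or is omitted.  This is the plotted-histogram
curve fit, not a maximum-likelihood exponent estimate, and `a` is
reported on both the frequency and the probability scale.

**k-clique communities.**  A k-clique community is the union of all
k-cliques reachable from one another through chains of adjacent
k-cliques, adjacency meaning k−1 shared nodes.  We percolate over
*maximal* cliques of size ≥ k (Bron–Kerbosch with pivoting), joining two
whenever they share ≥ k−1 nodes, via union-find; this is equivalent to
percolating all k-cliques directly, and the test suite verifies the
equivalence against a brute-force definitional oracle on hundreds of
random graphs.  A cap (10^6) on the number of maximal cliques aborts
cleanly on pathologically dense graphs.  Nodes in no k-clique belong to
no community; communities may overlap, and nodes in ≥ 2 communities are
reported as *bridge nodes* — features tying distinct biochemical
mechanisms together.  k is a zooming parameter; the pipeline exposes
k = 3 and 4 by default with no claim of optimality.

**Comparison.**  Two groups are compared through topology deltas,
edge-set Jaccard, a greedy maximum-Jaccard one-to-one matching of their
community sets (ties by larger intersection, then canonical order; pairs
below 0.5 Jaccard stay unmatched; greedy is transparent and the tests
check it against exhaustive assignment), the per-pair "missing element"
node lists, a completeness score (fraction of the partner's nodes
present), and per-node membership-count differences.  Community
"extension" is operationalised as node-set size.  Cross-k comparisons are
refused.

## 5. Synthetic cohorts

The generator produces feature tables with the statistical shape the
framework assumes, so every stage is testable without any download.

* Subjects sit in sex × arm cells (default 22 per cell ≈ a 90-subject
  trial), each sampled at baseline and endpoint.
* Taxa (default 50) and volatiles (16) have log-normal marginals
  (log-scale σ = 0.6) renormalised to 100 % per sample; a handful of rare
  features (8 taxa, 2 volatiles, log offset −4.5) fall below the 0.5 %
  filter, leaving ≈ 42 taxa and 14 volatiles in the merged set.
* NMR buckets (default 400) contain 34 four-bucket "molecule blocks"
  sharing a latent per-molecule intensity (intra-block correlation 0.95);
  the remaining buckets are noise.  Block buckets respond to the
  intervention (log-scale shift 0.5 ≈ 1.65-fold at endpoint in the
  active arm, random sign per block), so the L1 step keeps roughly the
  structured third of the spectrum.
* Planted consortia are latent Gaussian factors: member features load as
  √ρ·g + √(1−ρ)·ε with ρ = 0.95 and values exp-transformed, so planted
  *rank* correlations are exact in expectation (Gaussian copula).  The
  default design plants two taxa+volatile consortia bridged by a single
  shared molecule block loading on both factors, whose correlation with
  either community is capped at √(ρ(1+r)/2) by the factor coupling r
  (default 0.6).

Three generator choices deserve their rationale.  (i) *Bridged consortia
share only a spectral block, and consortia own no other NMR blocks*: any
spectral feature correlated with a community is, transitively, correlated
with the shared block, and the 0.7-cophenetic agglomeration would
(correctly) chain-merge them into one pooled feature — planting separate
per-consortium blocks makes the planted bridge topology unrecoverable by
construction, not by defect.  (ii) *Consortium members are minor
community members* (log offset −1, ≈ 1 % relative abundance): the
compositional closure couples every feature to the sample total, and when
correlated members form a large share of it, renormalisation attenuates
their pairwise Spearman by up to 0.3–0.4 (measured in pilots) and induces
spurious negative cross-correlations.  Biologically, specialised
cross-feeding consortia are not the dominant genera.  (iii) *Factor
coupling 0.6*: a bridge feature can only be detected above the endpoint
threshold 0.7 if its population correlation with both mechanisms clears
that threshold with margin; the √(ρ(1+r)/2) ceiling makes r ≥ ~0.5 a
precondition for a detectable bridge, and 0.6 leaves cross-community
member correlations (ρ·r ≈ 0.57) safely below threshold.

What the generator does **not** emulate: read-count noise and sparsity of
real 16S data, chromatographic co-elution, chemical-shift drift and
peak-shape effects in spectra, subject-level longitudinal correlation
(baseline and endpoint draws are independent apart from the design
structure), and any taxonomy.  Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes when that structure is
present at realistic strength — not that real cohorts contain such
structure.

## 6. Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline fans a single
top-level seed out to per-stage seeds by CRC-32 hashing of the stage
name, so stages are independently reproducible and a rerun with the same
config and seed is byte-identical (manifests contain no timestamps).

The recovery experiment used by the tests and the acceptance script runs
the full chain at 100 subjects per cell with the spectral dimension
scaled to 60 buckets / 8 molecule blocks; cohort structure, thresholds
and all defaults are unchanged.  The scaled spectral axis keeps the
selection step light while preserving the structured-to-noise ratio of
the default profile.

## 7. Known limitations

* The t-approximation significance threshold is inaccurate below n ≈ 10;
  the exact permutation option covers n ≤ 8 only.
* Greedy community matching can differ from the optimal assignment on
  adversarial overlap patterns (not observed on realistic ones; the
  exhaustive oracle in the tests covers ≤ 5 communities).
* The outlier screen is a plain per-feature z-score flag and is off by
  default; the upstream protocol discards outliers by an unspecified
  rule.
* Missing values are a hard error at the correlation step; no imputation
  is provided.
* Clique percolation is exponential in the worst case; the clique cap
  trades completeness for a clear failure on dense graphs.
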