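# Methods

`gutnet` reimplements, as tested code, an integrated analysis of paired gut
microbiome (16S OTU) and stool metabolome (GC-MS volatile and NMR
non-volatile metabolite) profiles from a small lung-cancer case/control
cohort: a feature-screening cascade, an FDR-thresholded cross-omics
correlation network with topology statistics and Louvain communities, and
a weighted co-expression (WGCNA-style) module analysis with module-trait
association. Because no cohort data are publicly deposited, a synthetic
generator with planted ground truth stands in for the study data; every
stage is validated against that ground truth or against independent
brute-force oracles.

## Data model

A `FeatureTable` is a dense features x samples matrix of non-negative
abundances (OTU counts or relative abundances; metabolites in ppm or
µmol/g — per-feature standardization makes the scale irrelevant), tagged
per feature with its omics kind. A `TraitTable` carries two binary
per-sample traits: `condition` (0 = control, 1 = case) and `treatment`
(0 = non-responder, 1 = responder to anti-PD1 therapy), with treatment
structurally missing for controls. A `MergedDataset` stacks OTUs and
metabolites row-wise and orders samples patients-first.

## Screening cascade (`gutnet.preprocess`)

Each feature is z-scored across all N subjects with the population
standard deviation (divisor N). Five per-feature filters are computed on
the full table and combined by conjunction, so the cascade order affects
only the audit report, never the survivor set:

1. **Presence**: retain iff the feature is non-zero in >= 25% of samples.
   (The underlying description reads as an inclusion rule for <25%
   presence; we read it as an exclusion rule — an inclusion rule would
   keep only near-absent features, contradicting the abundant taxa the
   analysis retains.)
2. **IQR**: retain iff the feature's interquartile range, ranked among
   all features with average-rank ties, reaches the 11th percentile.
   Under a full tie every feature sits at one shared percentile and
   passes.
3. **Degenerate rows**: constant features cannot be standardized and are
   excluded (flagged, never NaN-propagated). Constancy uses a relative
   tolerance (sd <= 1e-9·(|mean|+1)) so transformed constants with
   roundoff-level spread are caught.
4. **Fold change**: retain iff |log2((mean_case + c)/(mean_ctrl + c))| >=
   3.4, boundary inclusive, with pseudocount c = half the smallest
   non-zero value in the table. Log base 2 is our choice; the source
   states only "the logarithm of the ratio" and a cutoff of 3.4.
5. **Permutation test + FDR**: two-sided label-permutation test of the
   difference of group means on the z-scored feature. All C(N, n_case)
   label assignments are enumerated when there are at most 20,000
   (exact tail fraction); otherwise 10,000 Monte-Carlo permutations with
   the add-one correction p = (1 + hits)/(B + 1). Benjamini-Hochberg
   across features; retain iff q <= 0.05.

The permutation statistic (difference of group means) and the two-sided
alternative are implementation choices; both are config-switchable. Null
calibration is verified: the type-I error at alpha = 0.05 lies in
[0.03, 0.07] over 2000 null simulations, and the realized false-discovery
proportion of the q-screen averages ~0.04 on cohorts with 10% planted
shifts.

## Correlation network (`gutnet.corrnet`)

Survivors' z-score profiles are cross-correlated (Pearson, across
subjects; at least 4 subjects required). P-values use the Student-t
transform t = r·sqrt(n-2)/sqrt(1-r²) with n-2 degrees of freedom; BH
correction runs over the feature-pair upper triangle only. Pairs with
q <= 0.05 become edges of a binarized adjacency; the correlation value
and sign are kept as edge attributes (significant negative correlations
are retained — the reference analysis *observed* only positive ones, it
did not impose that). Nodes without any surviving edge are pruned, and
connected components are reported largest-first. Nodes carry 1-based
numeric labels in feature order for export (GraphML with attributes, or a
plain edge list).

## Topology (`gutnet.topology`)

All metrics treat the network as unweighted:

- **Degree** d(i): adjacency row sum.
- **Betweenness** b(i): sum over *ordered* node pairs (t, s), t != s != i,
  of the fraction of geodesics between them passing through i — raw, not
  normalized (the path A-B-C gives b(B) = 2). Disconnected pairs
  contribute 0. A normalized variant (divide by (n-1)(n-2)) is exposed
  but off by default.
- **Clustering coefficient** C(i): triangles at i over connected triples
  d(i)(d(i)-1)/2, with C(i) = 0 whenever d(i) <= 1.
- **Communities**: seeded Louvain modularity maximization (networkx
  implementation; resolution fixed at 1). Modularity
  Q = Σ_c [e_c/m − (d_c/2m)²] is computed by our own implementation and
  cross-checked in tests against networkx and against exhaustive
  partition search on small graphs.
- **Participation ratio**: per community, OTU count over metabolite
  count; communities without metabolites are flagged infinite rather
  than dropped.

Degree, betweenness and clustering are verified exactly against
brute-force enumeration (all-geodesic counting, triangle counting) on
hundreds of random graphs.

## Co-expression modules (`gutnet.wgcna`)

**Sample screen.** Average-linkage hierarchical clustering of samples on
Euclidean distance; samples merging above a cut are flagged and the
largest cluster kept. The default cut is median + 8·MAD of the merge
heights — conservative enough to keep every sample of a homogeneous
cohort while isolating a sample with several-fold inflated noise. An
explicit cut height can be supplied instead.

**Variance stabilization.** The co-expression pipeline correlates
log2-transformed abundances (half-minimum pseudocount), then z-scores.
Raw-scale Pearson correlation of log-normal abundance data is attenuated
and outlier-driven at n = 19; log transformation before correlation is
the standard practice for abundance data and is required for reliable
module recovery (see Limitations). The screening cascade, by contrast,
operates on the raw-scale z-scores as specified.

**Soft power.** Candidate powers beta = 1..20 build unsigned weighted
adjacencies a_ij = |cor(i,j)|^beta. For each, connectivities k_i = Σ_j
a_ij are binned (exact values when <= 10 distinct, else 10 equal-width
bins) and log10 frequency is regressed on log10 mean connectivity; the
scale-free index is the squared correlation, sign-flipped when the slope
is positive. The smallest beta with signed R² > 0.8 is chosen; if none
reaches the target the argmax is used with a warning, and a published
power (e.g. 5) can be forced as an override. Mean connectivity is
reported per power and is non-increasing in beta.

**Module detection.** Unsigned topological overlap
TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij); features are
clustered on 1 − TOM with average linkage and a static tree cut. A plain
single cut at a user height is available, but by default detection is
hardened for the very small sample size: a small grid of cut heights
(0.93–0.99) produces candidate core sets (clusters >= 12 features), each
candidate is refined by (a) merging modules whose eigengenes correlate
above 0.8 and (b) reassigning every feature to the module carrying its
largest joint-regression loading across all eigengenes, gated by a
marginal module membership of |kME| >= 0.5, iterated to a fixed point;
the candidate maximizing eigengene-explained member variance minus a
per-module penalty (15, roughly the chance contribution of a spurious
20-member module) is kept. The joint regression is what makes assignment
robust when eigengenes correlate by chance at n = 19; the penalty stops
the grid from favouring over-split solutions. Modules below
`min_module_size` (default 20; the reference analysis' smallest module
has 33 members) are relabeled gray, and colors are assigned by
decreasing size (turquoise, blue, brown, ...), ties broken by the first
member's position.

**Eigengenes and association.** The module eigengene (ME) is the first
right-singular vector of the module's centered feature x sample
submatrix, unit norm, sign-oriented so the mean member-ME correlation is
positive; it provably explains at least as much member variance as any
single member profile. Module membership (MM) is the Pearson correlation
of a feature with an ME; biomarker significance (BS) is its correlation
with a trait; module-trait association correlates MEs with traits.
All use the t transform with n−2 df for p-values, with pairwise dropping
of missing trait values (treatment is missing for all controls by
design) and an undefined status for traits constant over their
non-missing samples.

## Synthetic cohorts (`gutnet.simulate`)

`generate_study` draws, per feature and sample, log2 abundance
mu_i + signal + shift_i·g(k), exponentiated to a non-negative abundance,
with mu_i ~ U(2, 8):

- module members: signal = loading·f_m + sqrt(1−loading²)·noise_sd·e,
  with f_m a per-module standard-normal latent factor; within-module
  correlation is approximately loading² when noise_sd = 1;
- non-members: signal = noise_sd·e;
- structural zeros injected cell-wise with probability `zero_inflation`
  (default 0.1 — a compromise; real OTU tables are considerably
  sparser, metabolite panels less so);
- the planted case/control shift (default 4 log2 units on 44 features)
  covers one whole module — the largest whose size fits inside
  `n_shifted` — plus non-module spillover, so the shift never cuts a
  module into two correlation blocks, and exactly one module carries the
  condition signal.

Defaults mirror the emulated study: 11 patients vs 8 controls, 198 OTUs +
223 VOCs + 49 non-volatile metabolites, four modules with sizes spanning
33–121. Everything is seeded; identical configs are byte-identical.

`fixture_44` is a constructed screening fixture: 15 OTUs and 29
metabolites receive ~6.5 log2 units of case/control shift against ~0.6
log2 units of within-group spread plus block-wise latent factors, giving
wide margins on every filter; every other feature is engineered to fail
a *deterministic* filter (present in at most 4 of 19 samples, or
expressed everywhere with equal group means). No non-survivor depends on
the stochastic permutation screen — BH deliberately admits a ~5% share
of false discoveries, so a fixture relying on q-values alone could not
pin the survivor count — which keeps the outcome at exactly 44 for any
seed.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the pipeline assumes
— planted co-varying blocks, case/control mean shifts on the log scale,
zero inflation, a tiny unbalanced cohort — so passing tests demonstrate
that each stage recovers the structure it targets at the study's sample
size. It does not emulate compositionality (OTU counts summing to a
fixed sequencing depth), taxon-specific zero patterns, batch effects, or
measurement error models of GC-MS/NMR, so the tests say nothing about
robustness to those.

Two consequences of the small cohort are worth stating plainly. First,
any feature that passes a stringent two-group mean test at n = 19
necessarily correlates strongly with the group indicator, hence with
every other such feature; `fixture_44`'s 44 survivors therefore form a
near-complete correlation network (945 of 946 possible pairs become
edges in the worked example, a single community), denser than a real cohort's, where within-group biological
variability decouples features. Second, with 19 samples the realized
correlation between independent latent factors is frequently 0.3–0.5, so
module detection must tolerate correlated eigengenes; this drove the
joint-regression reassignment step.

## Numerical choices and degenerate inputs

- Population (divisor N) SD everywhere the z-score is defined; sample SD
  (n−1) inside Pearson correlations, where it cancels.
- Permutation tail comparisons use |T_perm| >= |T_obs| − 1e-12 to keep
  exact ties counted under floating-point noise.
- BH is delegated to statsmodels (`fdr_bh`) behind `bh_fdr`, with range
  validation; hand-computed step-up examples are frozen in tests.
- |r| is clipped to 1 before the t transform; |r| = 1 maps to p = 0.
- Empty survivor sets, edgeless networks, all-gray module assignments
  and traits constant over non-missing samples are reported statuses,
  never exceptions.
- The pipeline's global seed fans out to per-stage child seeds through a
  seeded generator, and JSON summaries round floats and sort keys, so a
  rerun is byte-identical.

## Problem sizes used in validation

Calibration and recovery checks run at the emulated study scale (470
features x 19 samples): 2000 null simulations for type-I error, 50
cohorts for the FDR screen, 25 cohorts for module recovery, 200 random
graphs (<= 7 nodes) for the exact topology oracles, and 50 planted
partition graphs (60 nodes) for Louvain. A full validation pass takes
about a minute on one CPU.

## Known limitations

- Module recovery is scored against planted blocks over the planted
  features; with 170 unstructured features at n = 19, chance module
  membership unavoidably pulls a handful of noise features into modules
  (an oracle knowing the true factors shows the same), so all-feature
  partition accuracy is bounded well below 1 at this sample size.
- The scale-free fit on 470-feature correlation networks of modular data
  often peaks below the 0.8 target — modular correlation structure is
  not scale-free — in which case the argmax power is used with a
  warning, or a published power can be forced.
- The screening cascade's raw-scale permutation test loses power when
  within-group multiplicative spread is large (heavy-tailed raw
  z-profiles); the generator documents this regime rather than hiding
  it.
- Participation ratios are descriptive; no uncertainty is attached.
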