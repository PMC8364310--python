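# Methods

## Model and assumptions

The search treats the brain as a node–edge graph: grey-matter ROIs carry
a scalar node signal (tau-PET SUVR, or amyloid centiloid for the
variant), white-matter connections carry per-subject diffusion metrics.
A pathway hypothesis is a chained pair of cross-sectional linear models —
upstream tau predicting the connecting tract's diffusion metric, and
that metric predicting downstream tau — each adjusted for age and sex.
Both "generalized linear regressions" are implemented as ordinary least
squares with Gaussian errors and two-sided t-tests: the responses are
continuous and the reported statistic (adjusted R²) is OLS-native.
Acceptance is the conjunction of the two tests at a common α, with no
multiple-testing correction inside the search (a per-iteration
Benjamini–Hochberg option exists in the engine but defaults off);
stability under subject resampling is the intended safeguard, provided
by the bootstrap voting layer.

The directionality of the two models is an interpretive device for the
iterative propagation, not a causal claim: on cross-sectional data the
method detects association structure only.

## Search mechanics and numerical choices

- Candidates at each iteration are backbone edges whose up endpoint is a
  current seed and whose down endpoint is not; seed–seed connections are
  never considered. Each directed (up, down) pair is tested at most once
  per run — a rejected connection would yield the identical p-value on
  the same data, so caching cannot change the result but guarantees
  termination.
- Hemispheres are searched independently by default
  (`hemisphere_mode="separate"`), which drops inter-hemispheric backbone
  edges from the candidate set; `pooled` disables this. Iteration labels
  restart per hemisphere and patterns are merged with hemisphere tags.
- Candidates are processed in sorted (up id, down id) order and all
  output tables are sorted, so identical inputs give byte-identical
  files.
- Backbone binarization keeps an edge iff its group-mean normalized
  count is **≥** threshold × maximum entry (inclusive, so the maximal
  edge always survives and the threshold is scale-invariant). The
  ROI-size correction divides each count by the mean of the two endpoint
  sizes; `sum` and `none` variants are exposed as config switches since
  the convention varies between connectome pipelines.
- Tau positivity uses the strict comparator (SUVR **>** 1.23); the
  boundary has measure zero for continuous SUVR, and the comparator is
  configurable. Seed selection is likewise strict (prevalence > 0.80).
- A connection whose fit is degenerate (constant predictor,
  rank-deficient design, or fewer than max(5, p+1) complete
  observations after listwise deletion of missing edge-metric values) is
  rejected with a logged reason; it never aborts the run. Listwise
  deletion per connection is this package's choice for missing
  per-edge metric values.
- `r²_diff` is reported from model (b) — the extra adjusted variance of
  downstream tau explained by the metric beyond age and sex — because
  that is the quantity of substantive interest; the model-(a) analogue
  is stored alongside. Sign agreement between the two models is recorded
  but not required for acceptance.
- Bootstrap replicates draw n subjects with replacement and rerun
  prevalence, seeding and the search. The backbone is *not* rebuilt per
  replicate by default: it is a one-time group construction, and fixing
  it isolates the resampling variability of the association pattern;
  `resample_backbone=True` rebuilds it per replicate for sensitivity
  analysis. Pathway identity for voting is directed and ignores
  iteration labels (labels vary across resamples); an undirected
  aggregation is available for display. Per-replicate RNG streams are
  spawned from (seed, replicate index), so results are independent of
  worker-pool size.

## The synthetic generator

The generator emulates exactly the structure the search assumes and is
the package's calibration instrument, not a biophysical simulator.

- **Template graph**: two hemispheres, each a connected random geometric
  graph, with optional homotopic inter-hemispheric edges; the
  `desikan84` template uses the standard 84-region cortical/subcortical
  naming with the four basal-ganglia off-target regions flagged per
  hemisphere. ROI sizes are lognormal (median ≈ 3000, log-SD 0.25).
- **Covariates**: age ~ N(70, 8²) years, sex ~ Bernoulli(0.5), both
  written into every node signal and edge metric (tau: 0.05/0.03 SUVR
  per SD of age / for sex; metrics: 0.30/0.20 latent-SD units), so the
  covariate adjustment is load-bearing.
- **Severity gradient**: a subject-level tau severity ~ Gamma(4, 0.15)
  SUVR is added to elevated ROIs (chain roots, medial temporal regions
  and off-target basal ganglia in the default template), producing a
  tau+ prevalence near 0.9 there against a ~2–5% background — the
  gradient that makes prevalence-based seeding meaningful.
- **Planted chains**: links are generated sequentially; each link's
  slope is set from a standardized effect (default 0.55 — chosen once so
  that a single link at the default cohort size of n = 62 yields t ≈ 4.5,
  the magnitude implied by the strongest reported real-data link-level
  p-values ~3×10⁻⁵) by propagating predictor variances analytically
  along the chain. The resulting raw slopes, in each metric's natural
  units (e.g. MD ≈ 8×10⁻⁴ ± 0.6×10⁻⁴ mm²/s), are recorded per link so
  OLS confidence-interval coverage can be verified against ground truth.
  Only the configured metric channel carries planted signal; the other
  five are covariates + noise, mirroring per-metric independent runs.
- **Counts**: true-edge streamline counts are negative binomial
  (dispersion 20) with means proportional to endpoint ROI size
  (base factor uniform 0.75–1.25), so size-corrected normalized means
  are homogeneous across true edges and all of them clear relative
  thresholds in the 4–11% range; spurious counts (Poisson, mean 3, on
  5% of non-edges) sit orders of magnitude below threshold. Off-target
  ROIs receive elevated tau but no planted downstream effects — they
  seed the search and act as built-in negative controls.
- **Amyloid channel**: a subject-level burden ~ Gamma(2, 10) centiloid
  times a per-ROI loading, plus noise, with no planted relation to any
  diffusion metric. Prevalence-based amyloid seeding (default cutoff
  20 centiloid, a conventional positivity point on that scale) therefore
  usually yields few or no seeds on synthetic data; the explicit
  seed-list override is the intended route for the amyloid variant.
- **Null cohorts** keep the template, severity and confounding but zero
  every planted slope.

What passing tests on this generator shows: correct arithmetic of every
stage, exact agreement with a brute-force search oracle, nominal
false-positive calibration (per-candidate acceptance ≈ α² under the
null), high power and correct ordering at the stated effect sizes, and
deterministic, pool-size-invariant bootstrap behavior. What it does not
show: robustness to tractography biases, spatially correlated PET noise,
partial-volume effects, non-Gaussian metric distributions, or
site/tracer heterogeneity — none of which the generator models.

## Problem sizes

Default test and script sizes are chosen to characterize the method at
desk scale: acceptance-style checks use 100 replicates at n = 200
(recovery), 100 null cohorts at n = 100 (calibration), 200 bootstrap
replicates (stability), and the headline script uses the default study
conditions n = 62 with 200 bootstrap replicates. The bootstrap layer
itself defaults to 1000 replicates for real analyses.

## Known limitations

- Group labels (CN/SCD/MCI) are metadata only; group-stratified or
  group-adjusted searches are not a supported claim (an extra-covariate
  hook exists but is unvalidated).
- The acceptance rule ignores effect signs; discordant-sign pathways are
  flagged in the output, not filtered.
- α-monotonicity of the discovered set holds on typical data but is not
  a theorem: because seed–seed connections are excluded, a destination
  reached earlier at a looser α can, in contrived graphs, mask a
  connection that a stricter run would have tested.
- `n_components` in the threshold sweep counts isolated ROIs, so it is
  an upper bound on meaningful fragmentation.
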