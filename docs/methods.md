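# Methods

This note documents the models, estimators and numerical choices behind
`seedtrans`, and what the synthetic-data generators do and do not
emulate.

## Study design and data model

The package targets longitudinal amplicon studies of a plant host:
compartments (bulk soil BS, rhizosphere RS, root R, stem sections
S1–S9, leaf sections L1–L3, flag leaf FL, seed Se), sampling ages in
days after transplanting, two consecutive seed generations
(parent-generation harvest seeds, sowing-stage seeds "Se0" at age 0,
progeny seeds from heading through harvest), and 3 biological × 3
technical replicates per condition. Counts are non-negative integers
(OTU × sample) with positive column sums; metadata and taxonomy
(kingdom…genus) join on sample and OTU ids.

## Normalization and community statistics

**CSS.** Per sample, the scaling factor is the cumulative sum of counts
up to the q-th quantile of that sample's *nonzero* counts (default
q = 0.5, counts equal to the quantile included), followed by
`log2(x/s·1000 + 1)`. With q = 1 this reduces to total-sum scaling. The
adaptive-quantile variant used by some implementations is deliberately
omitted: q is a plain, configurable parameter.

**CLR.** `log((x + 0.5)/g)` with g the geometric mean of the
pseudocounted column; columns sum to zero by construction.

**Dissimilarity.** Bray-Curtis on abundances, Jaccard on
presence/absence. A pair of all-zero profiles gets distance 0 with a
logged warning (the alternative — NaN — poisons ordination). Community
distances are computed from the mean abundance tables of technical
replicates by default (`mean_technical_replicates`); raw-replicate mode
is available.

**PERMANOVA.** One-factor pseudo-F on squared dissimilarities with
R² = SS_between/SS_total and permutation p = (1 + #{F\* ≥ F})/(1 + n_perm);
an exhaustive mode enumerates all distinct relabelings for small n. The
F statistic is cross-checked against scikit-bio's implementation in the
test suite. Sequential multi-factor partitioning is out of scope.

**Kruskal-Wallis + Dunn.** Tie-corrected H; pairwise Dunn z with the
pooled tie correction; BH adjustment across pairs; compact letter
display by insert-and-absorb. Constant data short-circuits to H = 0,
p = 1.

**Taxa aggregation.** Groups at a rank with mean relative abundance
strictly below 0.5% pool into "other" (a group exactly at the threshold
is kept).

## Transmission and succession

An OTU is **vertically transmitted** when it is detected in all three
seed generation groups; detection operates on the across-replicate mean
count (default rule mean > 0, mirroring averaging over plant
replicates; a min-count rule is exposed because robustness to
sequencing noise is a judgment call). All other seed OTUs are
transient. **Successional modes** come from OLS of relative abundance
on age across progeny seed samples (parent seeds excluded by default):
Early (t < 0, p < 0.05), Late (t > 0, p < 0.05), Mid/no-trend
otherwise; a perfect zero-residual fit classifies by the slope sign; an
all-zero OTU is Mid/no-trend with p = 1 and a `degenerate` flag.
Regression is on relative abundance (CLR mode available).
**Core OTUs** use inclusive prevalence (≥ threshold); the default is
0.8 per compartment with a 0.9 preset — both conventions appear in the
literature for this analysis and neither is privileged here.

## Niche responsiveness (h²)

Host age is treated as the niche analog of a genetic effect. Per OTU,
a linear mixed model on CLR abundance with age as a categorical fixed
effect and a random intercept per biological replicate (REML, via
statsmodels `MixedLM`) gives

h² = V̂_age / (V̂_age + σ̂²_replicate + σ̂²_residual),

where V̂_age is the variance of the fitted age effects **minus its
sampling inflation** σ̂²·(p−1)/n, clipped at zero — the usual unbiased
variance-component estimate for a fixed factor. Without that
correction the estimator's null median is ≈ 0.13 with 7 ages × 3
replicates and a "Low ≤ 0.2" classification would be wrong for a
quarter of genuinely null OTUs.

Uncertainty comes from a **parametric bootstrap** (the lme4 `bootMer`
convention): n_boot response vectors are simulated from the
bias-corrected fitted model (shrunken age effects + fresh replicate
intercepts + residual noise) and refit. Resampling whole plants with
replacement is available (`bootstrap='cluster'`) but is not the
default: with three plants the duplicated series collapse the residual
variance and inflate h². Classes follow the mean of the bootstrap
distribution: High (> 0.4), Moderate (0.2–0.4], Low (≤ 0.2); the
boundary values 0.4 and 0.2 fall into Moderate and Low respectively.
Singular mixed fits fall back to OLS with σ²_replicate = 0 and are
counted in `singular_frac`.

## Sloan's neutral model

Local communities default to the progeny seed communities across
sampling times (sowing-stage seeds excluded). N is the mean read depth
(arithmetic; geometric exposed), d = 1/N, p_i the mean relative
abundance, freq_obs the detection fraction. The classical prediction is
the threshold approximation `freq = 1 − I_d(Nmp, Nm(1−p))`; m minimizes
the sum of squared occurrence residuals over (1e-6, 1) by bounded
scalar optimization, with a flag when the optimum sits at a bound.
Per-OTU 95% bands use the Wilson score interval with n = number of
communities (normal approximation exposed); occurrence above/below the
band partitions OTUs as niche-flagged. Speciation/diversification terms
are excluded — over a single growing season they cannot contribute
meaningfully.

**Detection-model caveat.** When communities are *read-sampled* (counts
~ Binomial(N, x)), the exact detection probability is the
beta-binomial zero term `1 − B(Nmp, Nm(1−p)+N)/B(Nmp, Nm(1−p))`, not
the threshold approximation; for rare taxa the approximation
undershoots detection and the fitted m compensates upward by ~20–25%
at N = 1000. Both predictions are implemented
(`prediction='beta_cdf' | 'beta_binomial'`); the threshold form is the
default for fitting real data (it is the field's convention), and the
beta-binomial form is the statistical dual of the package's own
generator, used for parameter-recovery checks. The joint niche call
(`niche_consensus`) flags OTUs that are High by h² *and* non-neutral by
the occurrence partition.

## Source tracking

Mixture of multinomials with K named sources plus one Unknown
component; EM with responsibilities `r_ij ∝ α_j γ_j(i)` and
`α_j = Σ_i y_i r_ij / Σ_i y_i`. By default the named-source profiles
are updated jointly (pooling observed source counts with assigned sink
reads — the exact M-step, which keeps the full-data log-likelihood
monotone; asserted every iteration); a fixed-profile mode is exposed.
The **Unknown** component is restricted to taxa absent from every named
source. This is a deliberate identifiability choice: a free-profile
unknown can explain the entire sink by itself (the degenerate ML
optimum), silently draining mass from real sources; restricting its
support makes "Unknown" mean exactly "sink mass no source can supply".
The free-profile (FEAST-like) mode remains available
(`unknown_support='free'`, initialized at the residual). Convergence is
`max|Δα| < 1e-6` with max_iter = 1000 and best-of-5 jittered restarts;
a strict single-iteration mode (`max_iter=1`) reproduces the published
hyper-parameterization of the FEAST tool, which is kept only for
replication — one EM step is not a converged estimate. Technical
replicates of a source group are summed; per-sink fits aggregate by
source compartment and compartment × age, so compartment totals equal
the sum of their age-resolved parts identically. With joint profile
updates, α is invariant to sink-depth rescaling only approximately
(the pooling weights shift); exact depth invariance holds in
fixed-profile mode and is tested there.

## Networks

**SparCC.** Per resample, per-sample taxon fractions are drawn from
Dirichlet(counts + 1); the log-ratio variation matrix
T_ab = Var[log(x_a/x_b)] feeds the basis system
(D−1)ω_a + Σ_{b≠a} ω_b = Σ_b T_ab, solved exactly (the D = 3 case
reduces to ω_a = (T_ab + T_ac − T_bc)/2). Up to 10 exclusion iterations
remove the strongest |ρ| > 0.1 pair from the system (never
disconnecting a taxon entirely); non-positive basis variances are
replaced by the smallest positive T entry and flagged. The estimate is
the element-wise median over 20 resamples, clipped to [−1, 1]. SparCC
consumes raw counts: its Dirichlet layer is defined on counts, so
CSS-transformed input (available behind a flag) is a documented
divergence, not the default. Significance: column-independent
permutation of each taxon across samples, two-sided pseudo-p with a
1/(n_perm+1) floor, BH over the upper triangle. Note the floor
interacts with BH: detecting a single true edge among P pairs needs
n_perm ≳ P/0.05.

**Edges and meta-network.** An edge requires |ρ| strictly above 0.3
and BH q below 0.05. Edge identity across contexts is the unordered
OTU pair, sign-agnostic (sign-aware mode exposed); merging keeps every
contributing context and its ρ in the edge's provenance, with the mean
ρ as the edge value. Louvain modules (seeded, deterministic) come from
networkx; per-module composition counts provenance entries of
within-module edges by compartment and by age. Hubs are the 10
highest-degree nodes with ties at the cut broken lexicographically.
Complexity indices over the degree sequence: ABC = Σ_(u,v)
√((d_u+d_v−2)/(d_u d_v)), GA = Σ 2√(d_u d_v)/(d_u+d_v), and Bertz
B = 2m·log₂(2m) − Σ_v d_v·log₂ d_v — an information-content
formulation over the degree sequence; published variants differ and
the formula is swappable.

**Enrichment.** For labels (A, B) at class or order rank: population =
all edges, draws = edges touching A, successes = edges touching B,
k = edges joining A and B; upper-tail hypergeometric p, BH across
pairs, flagged overrepresented when q < 0.05 and k exceeds
draws·successes/N_e. The edge-population construction is one of two
defensible readings (node-pair population exposed as an option).
Sign bias per pair is Binomial(n_total, π₀) with π₀ the global
positive-edge fraction; the two-sided p doubles the smaller tail,
capped at 1.

## Synthetic data

Each generator is the sampling dual of one estimator, and its defaults
are the package's study conditions:

- **Neutral communities**: per community and OTU, abundance ~
  Beta(Nmp, Nm(1−p)), counts ~ Binomial(N, ·); metacommunity
  abundances default to log-uniform on [1e-4, 0.1] (normalized) —
  spanning three decades down to the conventional 1e-4 abundance
  filter. Recovery checks use N = 1000, m = 0.1, 200 OTUs,
  126 communities.
- **Trend injection**: expected relative abundance ramps linearly in
  age (default slope 0.002/day from a 0.001 baseline, Gaussian noise
  sd 5e-4), truncated at zero, renormalized, multinomially resampled
  at the original depths. Closure compresses but preserves the sign of
  planted trends provided the trending mass does not dominate the
  community; recovery studies therefore plant trends in ≲ 1/5 of taxa
  per community.
- **Source mixtures**: sink ~ Multinomial(depth, Σ α_j γ_j) with a
  default Unknown profile on fresh taxa disjoint from all sources
  (identifiability is then exact); an overlapping-unknown stress mode
  is available by passing any profile.
- **Correlated counts**: latent log-normal basis with a given
  correlation matrix (PSD-checked), closure, multinomial sampling.
- **Full study**: composes everything — three seed generation groups
  sharing a transmitted core (each transient OTU zeroed out of one of
  the first two groups), progeny seed communities interpolating from
  an early-colonizer profile to the harvest community (making
  transmitted OTUs late successors and parent-progeny dissimilarity
  fall with age), harvest seeds drawn exactly from a planted source
  mixture (default 0.4 stem + 0.3 parent seed + 0.3 unknown), and
  two co-fluctuating OTU guilds per non-seed compartment (shared
  log-normal factor, sd 0.8) to give the network stage genuine
  associations. Default depth 10⁴ reads (Poisson-varied), the
  amplicon scale at which all recovery checks stay fast.

What the generators do *not* emulate: sequencing error and chimeras,
taxonomic misassignment, compositional overdispersion beyond the
log-normal/multinomial layers, year-to-year environmental drift, and
real cross-compartment covariance structure. Passing recovery tests
therefore demonstrates the estimators' correctness under the stated
models, not robustness to every artifact of field data.

Recovery studies that include developing-seed sources face a designed
identifiability limit: intermediate-age seed communities interpolate
toward the harvest community, so they are partial copies of the sink
and EM may lawfully attribute sink mass to them. Source-recovery checks
therefore exclude developing-seed sources; on real data this is the
same judgment the analyst makes when the sink's own earlier timepoints
are near-duplicates.

## Problem sizes and orchestration

The test suite and the acceptance script use desk-scale sizes chosen as
the package's own defaults: 126–1000 local communities, 50 taxa × 200
samples for SparCC, 500 planted trend OTUs across five panels, 150-OTU
null panels with 15 bootstrap draws for h², 200 null datasets × 499
permutations for PERMANOVA calibration, 101 synthetic network contexts.
The pipeline (`seedtrans run` or `seedtrans.run(PipelineConfig(...))`)
executes stages in dependency order, validates every threshold range,
rejects unknown configuration keys, and writes a manifest (version,
seed, parameters, input checksums) that makes reruns byte-identical for
a fixed seed. Network contexts inside the pipeline keep the 30 most
abundant taxa at ≥ 50% prevalence per (compartment, age) group — a
stability floor for the basis system, configurable upstream.

## Known limitations

- The h² estimator is a variance-ratio heuristic, not narrow-sense
  heritability; with 3 biological replicates the replicate variance
  component is weakly identified and singular fits are common (they
  fall back to OLS and are flagged, not hidden).
- Sloan-model fits on data with saturated occupancy (every taxon seen
  everywhere) push m to its upper bound; the fit is flagged rather
  than failed.
- SparCC's diagonal-dominance assumption degrades below ~15–20 taxa;
  estimates attenuate (visible in `examples/05`).
- Permutation p-value floors bound the achievable FDR; network edges
  in small panels need either dense true structure or large n_perm.
- The meta-network treats context networks as fixed inputs; no
  uncertainty propagates from edge inference into module statistics.
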