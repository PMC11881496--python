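# Methods

This note documents the models, priors, numerical choices and simulation
design behind `gsarch`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Genotype codings and GRMs

All models operate on an N × M dosage matrix with values in [0, 2]
(fractional dosages from imputation are allowed; missing calls are
mean-imputed per marker before any computation).  Allele frequencies
`f_j` are estimated once from the full supplied matrix — reference and
target individuals combined — before any split, matching the situation
where a single merged imputed dataset is annotated and then divided for
validation.

Two codings are supported.  The *centered* coding `Z = D − 2f` implies
that SNP effect sizes are independent of allele frequency, so common
variants carry most of the genetic variance; the corresponding GRM is
`G = ZZ'/Σ 2f_j(1−f_j)`.  The *standardized* coding
`X = Z / sqrt(2f(1−f))` makes every variant contribute equally, giving
rare alleles larger effects; its GRM is `G = XX'/M`.  Which coding fits a
population is an empirical question tied to its selection history
(directional selection favours the centered architecture); both are
first-class throughout the package.

QC follows the usual imputed-WGS defaults: MAF ≥ 0.01, a 1-df chi-square
Hardy–Weinberg test at p ≥ 0.001 (fractional dosages hard-called to the
nearest genotype for the test only, no continuity correction;
monomorphic markers return p = 1 with a flag), call rate ≥ 0.95.

LD pruning is a greedy left-to-right scan within each chromosome: a
marker is dropped when its r² with any retained marker within the window
(default 1 Mb) exceeds the threshold.  No algorithm is canonical for this
step; the greedy positional scan is the common convention and is
deterministic.  LD scores are windowed sums of r² including the self
term, again with a 1 Mb default window since the original tooling's
window is not standardized.

## REML and (M)GFBLUP

The mixed model is `y = 1μ + Σ_s g_s + e` with `g_s ~ N(0, G_s σ²_s)`,
one term per genomic feature (annotation group).  Estimation is
average-information REML with expectation–maximization fallback whenever
an AI proposal leaves the parameter space; convergence requires
|Δ log-likelihood| < 1e-6 and a maximum relative parameter change
< 1e-4, with at most 200 iterations.  Starting values split `var(y)`
equally across components.  Variances are floored at `1e-8 · var(y)`;
a component pinned at the floor for three consecutive iterations is
reported as exactly zero (annotation groups with genuinely null variance
occur in practice, e.g. exon-associated elements).  The number of
simultaneous GRMs is capped at eight — with more groups the likelihood
surface becomes too flat for reliable convergence on typical annotation
structures.

For a single GRM the likelihood, score and AI matrix are evaluated in the
GRM eigenbasis (one O(n³) decomposition, O(n) per iteration); the dense
path handles the multi-GRM case.  A near-singular AI matrix (condition
number above 1e10, e.g. a GRM proportional to the identity, which
confounds genetic and residual variance) raises a `flat_likelihood` flag
rather than failing silently.

Prediction is the conditional mean of the target individuals' polygenic
terms given the reference phenotypes, `Σ_s σ²_s G_s[t,r] V_rr⁻¹ (y_r −
μ̂)` with μ̂ the GLS mean — equivalent to Henderson's mixed-model
equations and to the SNP-ridge formulation, both of which are asserted as
test oracles.

Heritability is partitioned as `pct_h2_s = 100·σ²_s/Σσ²_s`, and the
enrichment of a group is its heritability share divided by its variant
share; by construction the variant-share-weighted enrichments average
to 1.

## Bayesian samplers

All four samplers are single-site Gibbs with the residual vector
maintained incrementally and markers updated in fixed ascending order, so
a fixed seed reproduces a chain bit for bit.  (Optional update-order
shuffling was considered and dropped; fixed order keeps runs exactly
reproducible and mixes adequately at the scales targeted here.)  Default
chain length is 5000 iterations with a 2000-iteration burn-in, the
convention for the grouped mixture model's reference implementation;
tests and the pipeline default to shorter chains at desk scale.

Priors are the conventional weakly-informative choices: Dirichlet(1,…,1)
on mixture proportions (Beta(1,1) for the BayesCπ null proportion) and
scaled inverse chi-square (ν = 4) on variances, with scales derived from
an even split of half the phenotypic variance (for the BayesCπ slab, half
the phenotypic variance spread over an expected 1% of markers).  Genotype
coding defaults to standardized, the coding the mixture models are
defined on; centered is available as an option.

* **BayesCπ**: `β_j ~ π δ₀ + (1−π) N(0, σ²_β)`; π and σ²_β estimated.
  Implemented as the single-group, single-component case of the grouped
  kernel, which makes the spike-slab conjugate updates shared and
  well-tested.  Hyperparameters can be fixed through the config, which is
  how the closed-form ridge check operates.
* **BayesR**: spike plus three Gaussians with relative variances
  10⁻⁴/10⁻³/10⁻² of the group (= genetic) variance; the group variance
  scale and mixture proportions are estimated.  Per-iteration counts of
  markers in the medium and large components are recorded.
* **BayesRR-RC**: one mixture (proportions + variance scale) per
  annotation group, at most 96 groups; empty groups are dropped with a
  warning, groups under 10 markers warn about unstable hyperparameters.
  Reported per-group variances are posterior means of the *realized*
  variance of each group's genetic values (not the scale parameter),
  which is the quantity comparable across groups under LD.  A known
  caveat of this model family: with annotation, the largest-component
  variance is 1% of the *group* variance rather than of the total genetic
  variance, which shrinks large effects in small groups.
* **BSLMM**: every marker contributes through a polygenic term with
  covariance `σ²_g G` (sampled exactly in the GRM eigenbasis at O(n²) per
  iteration) and a sparse subset carries additional effects
  `N(0, σ²_a)` with proportion π.  π has a log-uniform prior on [1/M, 1]
  updated by random-walk Metropolis on log π (step 0.3); the variances
  use conjugate inverse-chi-square updates.  Parameterizing directly in
  (σ²_a, σ²_g, σ²_e) rather than in (h, ρ) keeps every variance update
  conjugate while leaving the model unchanged.  With the sparse component
  disabled the sampler is a Bayesian GBLUP, and its predictions match
  REML-BLUP to Monte-Carlo error — an asserted limit.

Prediction uses posterior-mean effects with the training-set allele
frequencies and coding; the BSLMM polygenic posterior mean is converted
to marker-space pseudo-effects `α = W_r'(G_rr⁺ ḡ)/denom`, so target
individuals are scored from genotypes alone and the conditional-mean
identity `E[g_t|ḡ_r] = G_tr G_rr⁺ ḡ_r = W_t α` holds exactly.

## Evaluation layer

Validation is a forward split by birth date (born strictly before the
cutoff → reference; on or after → target, the conservative choice for the
unstated boundary case).  Reliability is `cor²(GEBV, trait deviation)/h²`.
The h² in the denominator is configurable; synthetic validations use the
realized simulated h², since the estimator-vs-truth distinction is
immaterial for real data but matters for calibration tests.

Method comparisons bootstrap the target individuals with replacement —
one index draw per replicate reused across all method columns, the paired
design implied by building a single GEBV table.  95% intervals are the
2.5/97.5 percentiles; a difference is significant when one method is
higher in ≥ 97.5% of resamples.  Dispersion bias is the OLS slope of
trait deviations on predictions (1 = correctly scaled).  Cumulative-PIP
regions sum PIPs over a fixed, non-overlapping 1 Mb grid anchored at
position 1 (a fixed grid, not sliding, keeps windows disjoint and the sum
interpretable as a per-region inclusion count).

The overall muscling score combines the four component scores with
weights (1, 1, 2, 2), normalized by the weight sum so equal inputs return
that value.

## Synthetic-data generator

The generator emulates the statistical structure the models assume:

* **MAF spectrum**: density ∝ 1/f on [0.01, 0.5] (log-uniform), the
  post-QC shape of imputed WGS data with a 0.01 floor; realized MAFs
  below the floor are redrawn.
* **LD**: founder-haplotype pools per block (default 200 founders,
  blocks of 50 kb at 2 kb marker spacing).  Founder haplotypes are
  Markov chains along the block (persistence 0.95), individuals copy two
  founders per block with per-marker fidelity 0.98, and blocks recombine
  freely.  This yields adjacent-marker r² around 0.6–0.9 inside blocks
  and ~1/n across blocks — enough LD structure to exercise pruning, LD
  scores, and GRM behaviour.  It is not a coalescent: no recombination
  hotspots, no LD decay within a block, no population-history signatures.
* **Annotation**: categories drawn multinomially with genome-realistic
  proportions (intergenic 51.9%, intronic 26.5%, the three regulatory
  classes 14.4% together, exon-associated 6.5%, eQTL 0.28%, coding
  0.37%), encoded as the id-set and interval tracks the annotation module
  consumes; muscle flags on 21% of eQTLs/regulatory intervals (the
  observed muscle share of the eQTL catalogue).  Array marker sets are
  sampled with probability ∝ MAF, mimicking common-variant array design.
* **Effects**: within each group a 2% causal fraction receives effects
  from the three-Gaussian mixture; group effects are rescaled so realized
  group-variance shares follow a target enrichment profile (default:
  coding 16×, eQTL 20×, regulatory 2–3×, intergenic ≈ 0.42×, the profile
  estimated for muscularity).  Traits share 80% of causal variants.
  Noise is drawn, orthogonalized against the genetic values and scaled to
  the realized genetic variance, so the target h² (default 0.35 per
  trait; a typical conformation-trait value) is exact given the
  genotypes.
* **Cohort**: birth dates uniform over 2012–2021 with the cutoff at the
  81.5% quantile, reproducing an ~81.5/18.5 reference/target split.

Because annotation tracks are point intervals at the markers they
annotate, the simulated FAN1 assignment is exact; real tracks overlap
imperfectly and contain errors, so passing recovery tests here bounds
model correctness, not real-data annotation quality.

## Desk-scale problem sizes

The test suite and the acceptance script run the full protocol at reduced
sizes chosen to keep statistical power while staying cheap: REML h²
recovery at n = 2000, M = 5000 over 10–20 seeds; two-feature variance
recovery at n = 500; grouped-mixture share recovery at n = 600,
M = 2000; sampler cross-checks at n = 500, M = 1000 with 600–1000
iteration chains; bootstrap calibration over 300 simulated cohorts of 400
individuals at 2000 resamples; and the directional BSLMM-vs-array-GBLUP
comparison at n = 700, M = 2000 over 6–10 seeds.  At these sizes the
directional and equivalence results are stable; absolute reliabilities
are noisier than in a 16k-cow cohort and should not be read as estimates
of real-data performance.

## Known limitations

* The REML fast path covers one GRM; multi-GRM fits use dense O(n³)
  iterations and are practical to a few thousand individuals.
* The BayesR medium/large-component counts lose meaning under pure-noise
  data at small n, where the group variance collapses and mixture labels
  become nearly exchangeable; at realistic n the counts behave as
  expected.
* Samplers hold the dosage matrix dense in memory (~8 bytes × N × M);
  the intended scale is pre-selected panels up to a few tens of
  thousands of markers, not the full 11M-variant sequence.
* Indel overlap is judged by start position; multi-allelic variants and
  sex chromosomes are out of scope.
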