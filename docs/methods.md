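# Methods

## Attribute diversity as effective numbers

The package treats taxonomic, functional and phylogenetic diversity in
one frame: each is the effective number of equally weighted, maximally
distinct "entities" — taxa, units of pairwise trait distance, branch
segments — obtained from a generalised entropy of order *q*. The order
trades off rarity against dominance: *q* = 0 counts entities regardless
of abundance, *q* = 1 weights them by relative abundance, *q* = 2 by
dominance. Effective numbers (rather than raw entropies) obey the
replication principle — pooling N equally weighted, completely distinct
communities multiplies diversity by exactly N — which makes ratios and
regressions of the values interpretable.

**Taxonomic.** `qD = (Σ p_i^q)^{1/(1−q)}`. The sum is evaluated in log
space (log-sum-exp) because tropical plot data carry long tails of tiny
relative abundances; *q* = 0 returns the integer richness exactly, and
orders within 1e-8 of 1 use the Shannon limit `exp(−Σ p ln p)` (the
power-mean form is numerically singular there). Values at q = 1 ± 1e-6
agree with the limit to < 1e-4.

**Phylogenetic.** A single post-order traversal aggregates tip
abundances onto branches. The reference duration is the
abundance-weighted mean depth `T̄ = Σ L_i a_i`, not a fixed crown age: on
an ultrametric tree with all tips present the two coincide, and `T̄` stays
well defined for arbitrary (non-ultrametric, partially sampled) inputs.
Both the mean diversity `qD̄` (effective number of lineages) and the
total `T̄·qD̄` (effective branch length) are returned; the pipeline
reports the **total**, because that is the quantity whose *q* = 0 case is
Faith's PD and therefore the one that behaves like "number of
phylogenetic entities" across orders. Zero-length branches are retained
(they contribute nothing); multifurcations are supported. Pruning a tree
to a taxon subset collapses unbranched internal nodes with lengths summed
and keeps every retained root-to-tip depth, so computing on a pruned tree
or on the full tree with zero-abundance tips gives identical results
(tested to 1e-9).

**Functional.** Distances default to Gower (per-trait range
normalisation, mean over traits, d ∈ [0,1]) over SLA (mm²/mg), leaf
thickness (mm) and wood density (g/cm³); Euclidean-on-z-scores is a
config option. The choice is recorded in the run configuration because
no single convention dominates field practice. `qD(Q)` is reported as the
"functional entities" response (the equally-distinct-species equivalent);
the total `Q·qD(Q)²` is also emitted. `qD(Q)` is invariant to rescaling
all distances by a constant. One point deserves care: the identity
"equidistant matrix ⇒ functional = taxonomic Hill number" is exact only
for **equal abundances**. The framework's reference community of D
equally distinct species fixes every pairwise distance at Q *including
the diagonal*; a real matrix has a zero diagonal, so for uneven p the
equidistant functional Hill number exceeds the taxonomic one (at *q* = 0
it is √(S(S−1)/(1−Σp²))). Tests assert the exact uniform-abundance
identity and validate uneven-abundance behaviour against an independent
double-loop evaluation instead. When Rao's Q is 0 (all taxa functionally
identical) the convention is 1 effective entity carrying zero total
distance.

## Handling mismatched inputs

Trait tables and phylogenies rarely cover every inventoried taxon.
Rather than failing, each attribute is computed on the plot's usable
taxon subset (community ∩ traits for FD, community ∩ tips for PD) with
relative abundances renormalised over that subset, and a per-plot
coverage report is emitted. A (plot, attribute) cell with fewer than two
usable taxa is flagged missing, not fatal. Counts are never modified.
Trait values per taxon are unweighted arithmetic means over specimens
with all three traits measured (SLA = leaf area / leaf dry mass, WD =
branch dry mass / fresh volume, LT measured directly); specimens missing
any trait are dropped, and taxa with no complete specimen are excluded
with a warning. No outlier trimming, no name standardisation beyond
whitespace trimming.

## The inference layer

**NB GLM.** NB2 with log link; β and the dispersion θ are jointly
ML-estimated (statsmodels' discrete negative-binomial, which
parametrises overdispersion as α = 1/θ). Diversity responses are
real-valued effective numbers; the NB likelihood is evaluated through
its gamma-function continuous extension, matching what the standard
field implementations silently do with non-integer responses (a warning
is logged; strict round-half-even integer mode is available). On
near-equidispersed data θ is capped at 1e8 and flagged — the fit then
matches a Poisson GLM to < 1e-3 in the coefficients. All-zero design
columns are dropped before fitting (they make the observed information
singular) and reported with zero slope, which keeps the pseudo-R²
invariant to padding the design.

**Pseudo-R².** Cragg–Uhler: `[1 − (L0/L1)^{2/n}] / [1 − L0^{2/n}]`,
clamped to [0, 1]. Significance stars on slopes come from the Wald
z-test at α = 0.05/0.01/0.001 with no multiple-testing correction; when
the observed information is singular (boundary dispersion) the
likelihood-ratio test is the fallback.

**NB GLMM.** A single Gaussian random intercept per region. The marginal
likelihood integrates the intercept with *adaptive* Gauss–Hermite
quadrature: per group, a Newton search (closed-form first and second
derivatives of the integrand in the random effect) locates the mode, the
integrand is re-centred and re-scaled there, and 15 nodes (default;
1 node = Laplace; 15 vs 31 nodes agree in log-likelihood to < 1e-4 on
the study-sized fixtures) evaluate the integral in log space. β, log θ
and log σ_α are optimised jointly by L-BFGS-B with a derivative-free
polish on non-convergence; starting values come from the fixed-effects
GLM. σ̂_α below 1e-4 is reported as 0 with a boundary flag; the GLMM
likelihood can never fall below the nested GLM's, and at the boundary the
two agree. Standard errors come from the numerical observed information.

**AICc and selection.** `AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1)`, with *k*
counting every ML-estimated parameter — the coefficients, θ, and σ_α for
mixed models. This convention is applied uniformly to every candidate so
comparisons are internally consistent. Candidates are all 2⁴ main-effect
subsets of temperature seasonality, annual precipitation, soil pH and
bulk density (no interactions; random intercept always present).
Selection: drop candidates with ΔAICc ≥ 2 from the minimum; among the
rest select the one with the most fixed-effect terms, ties broken by
lower AICc. The rule deliberately prefers complexity inside the AICc
window; a test logs how often the full model is selected on pure-noise
data as a property of the rule. Latitude itself is excluded from the
GLMM candidates — it acts only through the climate variables, and is
analysed separately with signed-latitude NB GLMs (positive slope =
increase toward the Equator for these southern-hemisphere designs).

**Nakagawa R².** On the latent scale: `R²m = σ²_f/(σ²_f+σ²_α+σ²_d)` and
`R²c = (σ²_f+σ²_α)/(...)`, where σ²_f is the (ddof = 1) variance of the
fixed-effect linear predictor and the NB distribution-specific variance
uses the lognormal approximation `ln(1 + 1/μ̄ + 1/θ)` with
`μ̄ = exp(β₀ + σ²_α/2)`; a trigamma variant `ψ₁((1/μ̄ + 1/θ)⁻¹)` is
available by argument.

**Collinearity screen.** Pairwise Pearson correlations over latitude and
the four predictors; pairs with |r| ≥ 0.7 (configurable) are reported in
the log and the matrix is written out. The screen is advisory only — it
never drops variables, mirroring how such screens are used to justify a
predictor set rather than to automate one.

## The synthetic-study generator

The generator emulates a five-region, 50-plot inventory spanning
latitudes −13° to −3°:

- **Environment.** Region latitudes evenly spaced; plots jitter ±0.15°.
  Temperature seasonality is linear in |latitude| spanning 4.16–9.30 °C,
  plus Gaussian noise projected orthogonal to latitude and scaled so the
  realised Pearson |r| with latitude equals the 0.97 target exactly
  (an explicit noise SD can replace the calibration; SD 0 gives
  |r| = 1). Precipitation (1756–3948 mm/yr), pH (3.78–5.46) and bulk
  density (0.61–1.00 g/cm³) combine region-level draws and plot jitter,
  decorrelated from latitude by the same projection and affinely mapped
  into those observed field ranges.
- **Phylogeny and traits.** A constant-rate birth–death tree (birth 1.0,
  death 0.3) with 800 extant tips, rescaled to depth 100. Three traits
  evolve independently by Brownian motion on the log scale
  (variance 0.002 per depth unit, so tip log-traits have SD ≈ 0.63) and
  are exponentiated around field-plausible medians (SLA 15 mm²/mg, LT
  0.25 mm, WD 0.60 g/cm³) — close relatives get similar traits, which is
  what couples FD and PD downstream.
- **Communities.** Per plot, target richness is NB-distributed with
  log-mean `4.5 − 0.25·seas_z + 0.10·precip_z − 0.10·pH_z − 0.05·bd_z +
  u_region`, `u ~ N(0, 0.1²)`, θ = 10 — about 90 species and ~270
  individuals per 0.1-ha plot, sized to a dense tropical inventory with
  a low diameter cutoff. Species are drawn without replacement with
  Gaussian-kernel weights (breadth 1.5 °C) matching a trait-derived
  niche optimum (leading axis of log-trait variation mapped onto the
  seasonality scale) to plot seasonality, so environmental filtering
  drives FD/PD as well as TD. Counts per selected species come from a
  zero-truncated log-series (p = 0.85, mean ≈ 3 individuals/species,
  ~45% singletons — most species rare); a lognormal allocation is a
  config option. Ground truth (β, σ_α, θ, region effects, per-plot
  expected log richness, niche optima) is serialisable to JSON.

Everything flows from one seed through spawned generator streams;
identical configurations are bit-identical, including the newick output.

What the generator does **not** emulate: spatially explicit dispersal or
within-region spatial structure (region is the only grouping, matching
the fitted model), temporal dynamics, trait measurement error,
detection/identification error, and taxon-set mismatches between inputs
(its traits and tree cover the full pool; the alignment layer is
exercised separately in tests). Passing the end-to-end checks therefore
shows the estimation chain recovers known effects under the assumed
data-generating process — not that real inventories satisfy those
assumptions.

## Problem sizes and runtime

The default analysis (50 plots, 800-species pool, 9 responses × 16 GLMM
candidates at 15 quadrature nodes) completes in about a minute on one
CPU. The test suite scales some fixtures down — a 120–200-species pool
and 3–5 quadrature nodes for pipeline-shape and determinism checks,
25–200 Monte-Carlo replicates for recovery checks — sizes chosen to make
the statistical assertions stable while keeping the suite quick; the
end-to-end gradient check runs 20 full-default replicates.

## Known limitations

- The GLMM supports exactly one scalar random intercept (the design
  needs no more); no crossed or nested effects, no spatial covariance.
- FD handles exactly the three quantitative traits; no categorical
  traits, no imputation, no dendrogram-based FD variant.
- Confidence intervals for diversity values (bootstrap or asymptotic)
  are not provided; the workflow treats the computed plot values as
  data for the regression layer.
- The Cragg–Uhler pseudo-R² is likelihood-based and not comparable
  across different response transformations.
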