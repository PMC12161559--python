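# Methods

This note documents the models and procedures implemented in
`estuarydiet`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate.

## Data model and exclusions

A dataset is three flat tables: fish (one row per sampled fish), prey
(one row per fish × taxon × life stage, with a count and a blotted wet
weight in grams), and an energy table (taxon → kJ per g wet mass, with a
configurable default for unlisted taxa). Taxon labels are canonicalized
case-insensitively with a small alias list; unidentified categories
(e.g. "Unidentified Dipterans") are deliberately kept distinct from
identified families. A separate taxon→group mapping aggregates fine
labels to coarse groups (Amphipoda, Diptera, Cladocera, Hemiptera, …)
for ordination-level summaries. Dates are reduced to (year, month);
no statistic in the package uses day-of-month.

Two exclusion rules are applied before analysis: fish with no prey rows
(empty stomachs), and fish with fork length ≥ 100 mm. The cutoff is a
closed bound at 100 because the upper length bin is labelled 66–99 mm:
99 mm is the last included integer length. The filter is idempotent and
reports counts removed per rule.

Fork-length bins come in two schemes, both with inclusive printed
endpoints partitioning [30, 100): the two-bin *model* scheme (30–65,
66–99) used as a regression covariate, and the three-bin *ordination*
scheme (30–59, 60–79, 80–99) used when building diet matrices.

## Diet metrics

For a group of stomachs, per-taxon composition is

- %N_i = 100 · (Σ counts of i) / (Σ all counts),
- %G_i = 100 · (Σ weights of i) / (Σ all weights),
- F_i = (# stomachs containing i) / (# stomachs in the group),
- IRI_i = F_i · (%N_i + %G_i)  ∈ [0, 200],
- %IRI_i = 100 · IRI_i / Σ_j IRI_j.

F is a proportion while %N and %G are percentages; that asymmetry is
intentional and makes 200 the IRI ceiling. Life stages are summed within
taxon by default (a stage-resolved mode exists) because stage shares are
reported separately from taxon importance. All taxa observed anywhere in
a dataset appear in every group's table, with zeros where absent.

Per-fish scores: IR = Σ prey weight / fish mass (dimensionless),
ER = Σ (prey weight × taxon energy density) / fish mass (kJ per g fish),
and maintenance metabolism Jm = jm₀ · e^(d·t) · W with defaults
jm₀ = 0.003 and d = 0.68. Jm's units are carried abstractly ("model
units"): only ratios and orderings of Jm are interpreted, and the
package's analyses use it as a covariate-driven cost score, not as an
absolute energy budget. Note that d = 0.68 per °C implies Jm roughly
doubles per degree, far steeper than typical bioenergetics temperature
coefficients (~0.05–0.08 per °C); it is retained as the model's stated
default and exposed as a parameter (`MetabolismParams.d`) so users can
substitute a literature value.

Energy densities for taxa missing from the energy table fall back to a
configured default; the bundled per-taxon values are round placeholders
(amphipods 4.0, chironomids 3.0, cladocerans 2.0 kJ g⁻¹, …) chosen to
preserve the qualitative ranking (insects and amphipods energy-rich,
cladocerans energy-poor), not calibrated measurements.

## Multivariate comparisons

The diet matrix has one row per group (site × year, optionally × length
bin), one column per taxon, cells %IRI, each row summing to 100.
Bray–Curtis dissimilarity d(a,b) = Σ|a_i − b_i| / Σ(a_i + b_i) is the
distance throughout — appropriate for percentage data; two all-zero rows
get d = 0 by convention.

**NMDS.** Kruskal stress-1,
√(Σ(d̂ − d*)² / Σ d̂²), is minimized over k-dimensional configurations
(k = 2 default), where d̂ are configuration distances and d* the
isotonic regression of d̂ on the rank order of the input
dissimilarities. Ties in the input follow Kruskal's primary approach:
within a tie block the fit is unconstrained. Optimization is analytic
gradient descent with a step-halving line search, so accepted iterates
never increase stress; convergence is declared when the relative stress
drop falls below 1e-6 (default), capped at 300 iterations. Restarts
(8 by default) start from classical (Torgerson) scaling plus seeded
jitter, and the winner must improve stress strictly, so the
classical-scaling start wins ties. The final configuration is centered
and rotated to principal axes; runs are therefore comparable up to
reflection, and tests compare configurations via distances, not raw
coordinates. Non-convergence is flagged, never raised.

**ANOSIM.** All off-diagonal dissimilarities are ranked with midranks;
R = (mean between-group rank − mean within-group rank) / (n(n−1)/4).
p-values use seeded uniform label permutations with the add-one
estimator (1 + #{R_perm ≥ R_obs}) / (1 + n_permutations), which cannot
return zero; an exact mode enumerates all distinct label assignments
when n is small. Pairwise tests re-rank each pair's submatrix and
multiply p by the number of pairs (Bonferroni, capped at 1). Both a
global and a pairwise entry point are provided.

**SIMPER.** For each between-group row pair, taxon i contributes
|a_i − b_i| / Σ_j(a_j + b_j); averaging over pairs gives contributions
that sum exactly to the mean between-group Bray–Curtis dissimilarity
(an identity the tests check to 1e-9). The reported head list is the
smallest descending-contribution prefix reaching 70% of the total.
SIMPER is used descriptively; no significance test is attached.

**Species vectors.** Each taxon column is least-squares-projected onto
the ordination axes; strength is the squared multiple correlation and
the p-value a seeded row-permutation test, with taxa at p ≤ 0.05 flagged
for plotting. Constant columns get R² = 0, p = 1.

## Ration models

IR, ER and Jm are positive, continuous and right-skewed, and are modeled
as gamma with log link, parameterized by mean μ and dispersion α
(shape 1/α, scale μα, variance αμ²). β is maximum likelihood via IRLS;
α is then profiled by one-dimensional ML given the fitted means. The
Wald covariance of β is α(XᵀX)⁻¹ — the gamma/log-link Fisher information
has unit working weights. AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) counts β
plus α in k.

Year-to-year (and optionally month-within-year) variation enters as
fixed blocking dummies rather than random intercepts. The estimands of
interest — factor-level marginal means and their contrasts — are
unchanged by that choice at these sample sizes, competing blocking
structures can be ranked by AICc, and no variance components need to be
reported. A true random-intercept fit is out of scope. Aliased design
columns (unsampled site × month cells make interactions and some blocks
collinear) are detected by pivoted QR and dropped with a note on the
fit object; main effects survive.

Estimated marginal means average the linear predictor over the observed
distinct combinations of the other model factors, equally weighted —
never-observed cells carry no weight, and levels absent from the data
are flagged non-estimable and excluded from pairs. Pairwise contrasts
report the link-scale difference with a Wald 95% CI; whether link- or
response-scale differences are reported is a genuine choice, and the
link scale was chosen for consistency with standard marginal-means
software defaults.

Cohen's d divides the link-scale difference by a population SD. The
package's default σ_pop is the model's link-scale residual SD,
√trigamma(1/α) — the exact SD of log x for a gamma variate — because a
standardizer must live on the same scale as the difference; it is a
pluggable argument (`sigma_pop`) since other standardizers are
defensible. A contrast is flagged when the d interval excludes zero.
No multiplicity adjustment is applied to these CIs (Bonferroni is used
only for pairwise ANOSIM).

## Synthetic-data generator

The generator emulates the monitoring design: per-(site, month) fish
counts matching the design table cells (the cells are internally
consistent with every per-site total; the two printed margins that
disagree with their own cells are ignored in favor of the cells), years
2008–2021 with each cell spread across years as evenly as possible
(remainder to the earliest years), per-site length-bin and mark-status
proportions from the design table's per-site rows, and fork lengths
uniform within bin with mass from the allometry W = aL^b (a = 1e-5 g
mm⁻³, b = 3, ×8% lognormal noise).

Stomachs draw a negative-binomial total prey count (mean 20, size 5)
split across taxa by a multinomial with the site's prey profile; the
site profiles are Dirichlet draws concentrated on corophiid amphipods
downstream (Ilwaco, Welch, Whites), cladocerans plus dipterans at
Campbell, and dipterans at Franz — the qualitative spatial pattern the
design targets. Per-(site, year) profiles are re-drawn around the site
profile (Dirichlet precision 25) to emulate interannual shifts in which
taxon dominates; without this, all within-site dissimilarities rank
below all between-site ones and NMDS collapses to the degenerate
zero-stress cluster solution. Item weights are lognormal around
per-taxon medians (0.4–2 mg, σ_log = 0.6); chironomid counts split
across larva/pupa/adult-emergent stages (0.36/0.20/0.44) with pupae
2.5× heavier. Water temperatures interpolate linearly between per-site
February and July endpoints (across-site ranges 4.4–10.9 °C and
18.9–23.3 °C) plus Gaussian noise (σ = 1 °C default; within-month
variance is a free parameter as no empirical value is available), with
a 17.5 °C exceedance flag. Ordinal fullness categories 2–6 are IR
quintiles, with 20% left uncategorized. Empty stomachs are inserted on
top of the design counts at rate 18/1383 of all generated fish, so the
design cells are exactly what survives the empty-stomach exclusion.

Ground truth (site profiles, per-fish expected IR/ER, the gamma β/α for
directly simulated responses, seeds) is returned alongside every
dataset, so recovery tests can compare estimates against what was
simulated. A separate helper draws gamma responses with known β and α
from an arbitrary design matrix for regression recovery tests.

What the generator does **not** emulate: prey availability and
selectivity (diet is drawn directly, not filtered from an environment),
tidal and hydrological dynamics, fish movement or repeated captures,
within-month temperature autocorrelation, measurement error in weights,
and digestion-state effects on weights. Passing recovery tests
therefore demonstrates that the estimators recover the generating
structure under the design's sample sizes — not that real diets satisfy
the generating assumptions.

## Numerical choices and degenerate inputs

- Permutation p-values use the add-one estimator everywhere (never 0).
- ANOSIM rank ties use midranks; NMDS target ties use the primary
  approach.
- Composition of a group with fish but no prey rows raises (cannot occur
  post-exclusion); a group where every taxon weight is zero reports
  %G = 0 for all taxa rather than dividing by zero.
- Bray–Curtis of two all-zero rows is 0.
- Gamma fits reject non-positive responses by row; α search is bounded
  on the log scale in [e⁻¹², e⁸].
- Excluding every fish yields an empty dataset plus a warning, not an
  error.
- All stage seeds derive from one root seed via seed-sequence spawning,
  so pipeline stages are independently reproducible.

## Problem sizes in the test suite

The statistical checks run at deliberately modest scale: permutation
oracles enumerate 6-sample/2-group designs; type-I-error checks use 500
simulated datasets with 199 permutations each; gamma recovery uses 200
simulated fits at n = 500; end-to-end taxon recovery uses 100 generated
datasets at the full 1365-fish design. These sizes give binomial error
bars comfortably inside the asserted bands.

## Known limitations

- Random effects are approximated by fixed blocking dummies; variance
  components are not estimated.
- The NMDS optimizer is a local method; restarts mitigate but do not
  guarantee the global stress optimum.
- SIMPER head lists depend on the %IRI scale and inherit its
  sensitivity to rare-but-heavy taxa.
- Energy densities and the Jm parameterization are score-level inputs,
  not calibrated bioenergetics; absolute ER/Jm values should not be
  compared across studies without recalibration.
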