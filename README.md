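# estuarydiet

Diet-composition and bioenergetics analysis of juvenile (subyearling)
Chinook salmon stomach contents, built for long-term estuarine monitoring
designs: five sites sampled February–July across many years, with fish
described by site, date, fork length, mass, hatchery-mark status, capture
water temperature, and an ordinal stomach-fullness category, and stomach
contents recorded as per-taxon counts and blotted wet weights.

The package is aimed at fish ecologists who need the full chain from raw
flat tables to publication-style outputs: prey-importance indices,
per-fish energetic scores, multivariate diet comparisons among sites,
years and size classes, and regression-based contrasts of the scores —
plus a seeded synthetic-data generator that emulates the sampling design
for power checks and method validation.

## The statistics

**Index of Relative Importance.** For taxon *i* within a group of
stomachs,

    IRI_i = F_i · (%N_i + %G_i)

where %N_i is the taxon's percentage of all prey counts, %G_i its
percentage of all prey wet weight, and F_i the proportion of stomachs
containing it (0–1), so 0 ≤ IRI ≤ 200. %IRI normalizes IRI to sum to 100
within the group and feeds the multivariate machinery.

**Per-fish scores.** Instantaneous ration IR = Σ prey weight / fish mass
(a stomach-fullness proxy); energy ration ER = Σ (prey weight × taxon
energy density, kJ g⁻¹ wet) / fish mass; maintenance metabolism

    Jm = jm₀ · e^(d·t) · W

for a fish of mass W (g) at water temperature t (°C), with defaults
jm₀ = 0.003 (mass-specific maintenance cost at 0 °C) and d = 0.68
(temperature coefficient).

**Multivariate comparisons.** Bray–Curtis dissimilarity between %IRI
rows; nonmetric multidimensional scaling minimizing Kruskal stress-1 with
isotonic (pool-adjacent-violators) regression; ANOSIM (rank-based R with
seeded permutation p-values, Bonferroni-corrected pairwise tests); SIMPER
decomposition of between-group dissimilarity with the taxa that account
for ≥ 70% of the difference; and permutation-tested species vectors for
ordination overlays.

**Ration models.** Gamma log-link regression (mean μ, dispersion α,
variance αμ²) of IR, ER and Jm on site, month, and length bin or mark
status, with year blocking, AICc model ranking, estimated marginal means,
and pairwise contrasts reported with 95% CIs and Cohen's d (link-scale
difference divided by the model's residual SD on the log scale).

## Worked example

```python
from estuarydiet import (GeneratorConfig, generate_dataset, apply_exclusions,
                         composition, ration_table, diet_matrix, bray_curtis,
                         nmds, pairwise_anosim, fit_gamma_loglink, ModelSpec,
                         estimated_marginal_means, pairwise_comparisons)

ds, truth = generate_dataset(GeneratorConfig(seed=42))
ds, report = apply_exclusions(ds)   # drops empty stomachs and 100+ mm fish
comp = composition(ds, ("site",))
mat = diet_matrix(ds, ("site", "year"))
ord_res = nmds(bray_curtis(mat), seed=0)
anosim_table = pairwise_anosim(bray_curtis(mat),
                               mat.index.get_level_values("site"),
                               n_permutations=999, seed=0)
fit = fit_gamma_loglink(ration_table(ds),
                        ModelSpec("ir", ("site", "month", "length_bin")))
contrasts = pairwise_comparisons(
    estimated_marginal_means(fit, "length_bin"), fit)
```

Output (seed 42):

```
retained 1365 fish (17 empty stomachs removed)
           site          taxon  iri_pct
Campbell Slough        Daphnia     60.4
     Franz Lake   Chironomidae     84.4
  Ilwaco Slough Americorophium     81.6
   Welch Island Americorophium     69.4
  Whites Island Americorophium     71.2
NMDS stress: 0.047
ANOSIM Campbell Slough vs Welch Island: R = 1.00, p_bonf = 0.010
ANOSIM Welch Island vs Whites Island: R = 0.01, p_bonf = 1.000
level_a level_b  difference  lower  upper  cohens_d  flagged
  30-65   66-99       1.863  1.772  1.953     2.073     True
alpha = 0.597, AICc = -8355.5
```

Reading it: the exclusion filter leaves exactly the designed 1365 fish;
the top-%IRI taxon per site reflects each site's prey profile (cladoceran
*Daphnia* at Campbell Slough, chironomid dipterans at Franz Lake,
corophiid amphipods downstream); the two amphipod-dominated islands are
statistically indistinguishable (R ≈ 0) while the cladoceran-dominated
slough separates completely (R = 1); and small fish (30–65 mm) carry a
higher instantaneous ration than large fish (66–99 mm) relative to body
mass — the link-scale marginal-mean difference of 1.86 (95% CI 1.77–1.95)
corresponds to a large standardized effect (d = 2.07).

A command-line interface mirrors the library:

```sh
estuarydiet generate --seed 1 --out data/
estuarydiet run --seed 1 --out results/
estuarydiet composition --fish data/fish.csv --prey data/prey.csv --energy data/energy.csv
```

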