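# microstrat

Stratification of gut-microbiota profiles and dietary patterns, and their
association with health markers, in two-time-point cohort studies — with a
bundled synthetic-cohort generator so every stage is testable without access
to protected cohort data.

## What it does

Paediatric-cohort microbiome studies commonly ask three linked questions:
does the gut community fall into a discrete set of recurrent configurations
("steady states"); which groups of genera rise and fall together
(co-abundance groups, CAGs); and how do those community configurations relate
to diet patterns, inflammation and weight gain?  `microstrat` implements that
full downstream analysis as a library plus CLI:

- **Community diversity** — relative abundance, taxonomy aggregation
  (phylum/family/genus), Shannon (log₂), observed richness, Faith's PD
  ("whole tree" convention), and unweighted/weighted UniFrac
  (`d_u = Σ b_unique / Σ b_either`, `d_w = Σ_i b_i |p_A(i) − p_B(i)|`, with
  the Lozupone normalizer optionally applied).
- **Ordination & permutation statistics** — PCoA (Gower centering
  `B = −½ J D² J`), correspondence analysis (SVD of standardized residuals),
  PERMANOVA with pseudo-F and label permutation, envfit-style vector fitting
  of external variables with permutation r² tests.
- **Stratification** — steady states by Ward clustering of the
  inter-sample Spearman-correlation distance `(1 − ρ)/2` of
  prevalence-filtered OTU proportions, with intra-cluster correlation
  verification and PERMANOVA; CAGs by Kendall τ-b association networks with
  Storey q-values (FDR ≤ 0.05) and Ward clustering; diet groups D1..Dm by
  Ward/Euclidean clustering of the first CA axis of the FFQ; genus
  over-abundance ("Wiggum") ratios per steady state; a within-subject
  pairing permutation statistic.
- **Associations** — FFQ category → daily-consumption conversion; the
  Healthy Food Diversity index `HFD = (Σ hvᵢ sᵢ)(1 − Σ sᵢ²)`; macronutrient
  kcal shares (4/9/4) and fibre per 1000 kcal; age-adjusted median (τ = 0.5)
  regression of markers on ordination axes, solved by exact linear
  programming with bootstrap or rank-score inference; Fisher's exact
  enrichment of diet × microbiota combinations in a phenotype; rank-based
  group tests with Benjamini–Hochberg correction.
- **Synthetic cohort** — a Dirichlet-multinomial generator for a 70-subject,
  two-time-point cohort with latent community states along a diversity
  gradient, correlated latent diet groups over a 50-item food list, and
  inflammatory markers tracking the community gradient; ground-truth labels
  are returned for recovery testing.

## Worked example

```bash
microstrat run --seed 1 --outdir out/
```

runs the whole analysis on the default synthetic cohort (140 samples, 200
OTUs, 50 foods) and writes every intermediate (UniFrac matrices, PCoA
coordinates, state/diet labels, CAG edge list, regressions, enrichment) plus
`report.md`/`report.json` to `out/`.  In Python:

```python
from microstrat import (SyntheticConfig, generate_cohort,
                        identify_steady_states, identify_diet_groups,
                        combination_enrichment, hfd_index)
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(SyntheticConfig(seed=1))
states = identify_steady_states(cohort.otu_table, k=4, seed=1)
diets  = identify_diet_groups(cohort.ffq.consumption, m=5)

print(adjusted_rand_score(cohort.truth["state"], states.labels))   # 0.970
print(states.permanova_result.statistic)                           # 50.89
print(states.permanova_result.p_value)                             # 0.001
print(adjusted_rand_score(cohort.truth["diet_group"], diets.labels))  # 1.0
print(hfd_index(cohort.ffq).groupby(diets.labels).mean().round(3))
# D1 0.315, D2 0.430, D3 0.571, D4 0.691, D5 0.748
```

The four latent community states are recovered almost perfectly
(ARI 0.97) and are strongly separated in the Spearman-distance space
(pseudo-F ≈ 50.9, permutation p = 0.001 with 999 permutations).  The five
diet templates are recovered exactly, and the Healthy Food Diversity index
rises monotonically from the least healthy diet group (D1, lowest CA axis-1
score) to the healthiest (D5) — in this cohort the axis-1 ordering coincides
with the health-value gradient the generator plants.  Subject-level
enrichment of the low-diversity × low-HFD combination in the obese phenotype
gives an odds ratio of 4.9 (one-sided Fisher p ≈ 0.002).

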