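# Methods

`microstrat` re-implements, as a reusable and tested pipeline, the downstream
statistical analysis of a two-time-point prospective gut-microbiome cohort:
community stratification into steady states, co-abundance groups of genera,
diet-pattern discovery from food-frequency questionnaires (FFQs), and the
association of clinical/inflammatory markers and diet with community
structure.  This note documents the models, the defaults and why they were
chosen, and what the bundled synthetic cohort does and does not emulate.

## Community diversity

**Alpha diversity.** Shannon entropy is computed in log base 2 (the
convention of the QIIME-era toolchain this pipeline mirrors; the base is an
argument).  Observed richness counts features with nonzero counts.  Faith's
phylogenetic diversity follows the "PD whole tree" convention: the summed
branch length of the minimal rooted subtree spanning the observed tips *and
the root*, so a single-tip community already has positive PD.  No rarefaction
is applied — metrics are computed on full counts, with a warning when library
sizes vary more than ten-fold.

**UniFrac.** Unweighted UniFrac is the fraction of branch length unique to
one of the two samples, over the branch length leading to tips observed in
either.  Weighted UniFrac is `sum_i b_i |p_A(i) - p_B(i)|` over branches,
where `p_X(i)` is the proportion of sample X's reads descending through
branch i; the normalized variant divides by the Lozupone normalizer
`sum_j d_j (p_A(j) + p_B(j))` with `d_j` the tip-to-root distance.  Requesting
`"weighted"` resolves to the normalized variant (the common toolchain
default); the raw variant is retained and both are checked against a
brute-force per-branch oracle in the tests.  Multifurcating trees are
handled: the computation runs over all branches, not just bifurcations.

## Ordination and permutation statistics

**PCoA** uses Gower double-centering `B = -1/2 J D^2 J` and an
eigendecomposition; coordinates are eigenvectors scaled by the square root of
the positive eigenvalues.  Negative eigenvalues (non-Euclidean distances) are
reported by magnitude and their axes dropped; explained proportions use the
positive-eigenvalue sum as denominator.  Eigenvector signs are fixed by
making the largest-magnitude loading positive, so results are reproducible
across linear-algebra backends.

**Correspondence analysis** is the SVD of the standardized residuals
`Dr^-1/2 (P - r c^T) Dc^-1/2`; row principal coordinates are returned for the
samples and column coordinates for the foods.  Total inertia equals the
independence chi-square over the grand total, which the tests verify against
an independent chi-square computation.

**PERMANOVA** computes the pseudo-F ratio from the squared-distance
decomposition (`SS_total = sum d^2 / N`, within-group analogues per group)
and permutes group labels.  All permutation p-values use the
`(exceedances + 1) / (permutations + 1)` convention and can never be zero.
Defaults: 999 permutations, explicit seeds.

**Environmental vectors** (vegan's envfit): each variable is least-squares
fitted on chosen ordination axes; r-squared is tested by permuting the
variable.  When two or more variables are fitted together their p-values
receive Benjamini–Hochberg q-values; the pipeline's "highly significant
foods" threshold is q ≤ 0.01.

## Stratification

**Steady states.** OTUs are filtered at 20 % sample prevalence (default),
relative abundances are rank-correlated between samples (Spearman), and the
correlation is mapped to a distance by `(1 - rho) / 2` — the signed map from
[-1, 1] to [1, 0].  An absolute-value variant `1 - |rho|` is available behind
a flag because the protocol this follows is ambiguous on that point.  Ward
linkage uses the modern squared-update (Ward.D2) form, with a legacy Ward.D
flag.  The cluster count is chosen by maximum mean silhouette over k = 2..8
unless fixed by the caller — the pipeline deliberately does not hard-code the
four microbiota / five diet clusters reported for any particular cohort.
Clusters are renamed C1..Ck by *descending* mean Shannon diversity (C1 most
diverse), giving labels a stable meaning across runs.  Each clustering is
verified two ways: the per-cluster fraction of intra-cluster sample pairs
with BH-significant positive correlation, and a PERMANOVA of the labels
against the same distance matrix.

**Co-abundance groups (CAGs).** Genus-level relative abundances are filtered
(> 0.1 % in at least two samples, defaults), all pairs are tested with
Kendall's tau-b, and significance is controlled with Storey q-values at a
fixed lambda of 0.5 (`pi0 = #{p > 0.5} / (0.5 m)`, capped at 1), with a BH
fallback flag.  The reserved "Unclassified" pool is excluded from CAG
detection by default.  Clustering is Ward on the Spearman-correlation
distance between genus profiles (a Kendall-derived distance is exposed as an
alternative, since the source protocol can be read either way).  Each CAG is
named by its dominant genus — the member with the highest cohort-wide mean
relative abundance.  The network export keeps all pairs with q ≤ FDR along
with the correlation sign; "Wiggum" over-abundance ratios are cluster mean
over cohort mean per genus, so cluster-size-weighted ratios average to one.

**Diet groups** come from Ward/Euclidean clustering of the *first* CA axis of
the samples-by-foods consumption matrix only, renamed D1..Dm by ascending
axis-1 mean.  This reproduces the one-dimensional construction the pipeline
mirrors; the tests assert that the labels depend on the FFQ only through the
axis-1 scores.

**Within-subject pairing.** Cohort analyses often report that a subject's
two samples cluster together in the dendrogram, without a standard test
attached.  This package uses an explicit permutation statistic: the number
of subjects whose two samples are mutual nearest neighbours in the
Spearman-distance matrix, with subject assignments permuted for the null.

## Associations

**FFQ conversion.** Frequency categories map to daily consumption through a
declared dialect: "never or less than once a week" → 0, daily categories map
to their count ("2 times per day" → 2), the open top category "4 or more
times per day" → 4, and weekly ranges use the range midpoint divided by 7
("1–3 times per week" → 2/7).  Unknown categories are an error that lists
them.

**Median regression.** Markers are regressed on an ordination axis with age
as a linear covariate at the median:
`min sum rho_0.5(y - b0 - b1 axis - b2 age)`, solved exactly as a linear
program (HiGHS).  Coefficients are reported on two scales: `rc_range = b1 ×
(axis span)` and `rc_sd = b1 × sd(axis)`.  Inference on `b1` (default 2000
resamples, seeded) is a multiplier (wild) *score* bootstrap: the tau = 0.5
score of the age-restricted fit, `S = sum psi(r_i) x~_i` with `x~` the axis
residualized on (1, age), is sign-randomized; the p-value is the fraction of
randomized |S*| at or above the observed |S|, floored at 1/B.  Because
residual signs are exchangeable under the null, this is calibrated in finite
samples.  Two alternatives are exposed: the xy-pair percentile bootstrap of
the slope (`method="pairs"`) — measured here to over-estimate the slope's
sampling spread by ~8 % at n = 100 because resample duplicates make the LAD
solution jumpy, hence mildly conservative null p-values — and the
normal-reference rank-score test (`method="rankscore"`).  Age enters only
linearly; no further covariates are added.

**Fisher's exact test** uses the hypergeometric distribution with the
minimum-likelihood two-sided rule (tables whose probability is at most the
observed table's, with a 1e-7 relative slack for floating-point ties); odds
ratios apply the Haldane 0.5 correction when a cell is zero.  Combination
enrichment (diet group × steady state vs phenotype) uses the *subject* as the
unit of analysis: a subject is in the combination if any of its samples
carries both labels simultaneously, and counts once.

**Group tests** on relative abundances apply a 20 % prevalence filter, then
Mann–Whitney (two groups), Wilcoxon signed-rank (two groups with a complete
subject pairing), or Kruskal–Wallis (three or more), with BH adjustment
across features.  Zero-variance features are flagged with NaN rather than
tested.

**Healthy Food Diversity.** `HFD = (sum hv_i s_i) × (1 - sum s_i^2)` with
consumption shares `s_i` and per-food health values `hv_i` in [0, 1]; the
second factor is the Berry evenness index.  The functional form is the
standard health-value-weighted Berry construction; since no canonical
health-value table exists for this food list, the packaged values are an
interpretable default and fully overridable.  Macronutrient energy shares use
the Atwater 4/9/4 kcal/g factors against each food's declared kcal; fibre is
reported per 1000 kcal; unattributed energy appears as a remainder.

## The synthetic cohort

The generator emulates the study design the pipeline targets: 70 subjects ×
2 time points (140 samples), four latent community states, five latent diet
groups, and a 50-item FFQ.  All generators are pure functions of
`(config, seed)`.

- **Counts** are Dirichlet-multinomial: each state has a genus profile drawn
  from `Dirichlet(c_s)` where `c_s` is that state's entry of
  `state_diversity_gradient` (default 0.3, 1, 3, 10) — larger concentration
  gives a more even profile and hence higher expected Shannon diversity, so
  state 0 is the low-diversity, "dysbiotic" end.  Genus profiles are spread
  over OTUs through a fixed within-genus split, per-sample proportions are
  re-drawn from `Dirichlet(50 × profile)` (overdispersion), and library sizes
  are lognormal around 5 000 reads with the coefficient of variation observed
  in real 16S runs (~0.4).  The default depth is a scaled-down stand-in for
  real sequencing depth; the stratification statistics are rank-based and
  insensitive to it.
- **Subjects** keep their state between time points with probability 0.75
  (a free parameter — within-subject stability is not empirically known) and
  otherwise resample uniformly.
- **Diet** templates lie along a single healthy↔unhealthy gradient:
  `base × exp(g_d × spread × (hv - mean hv))` with group scores `g_d` equally
  spaced in [-1, 1]; sample consumptions add Gamma noise (shape 25).  The
  diet label is drawn from the community state through a configurable
  confusion matrix (default 0.55 on the diagonal mapping), so diet and
  microbiota are correlated but not identical, as in real cohorts.
- **Metadata**: every inflammatory/clinical marker is
  `baseline + scale × (effect × z_state + noise)` with `z_state` the
  standardized low-diversity score of the sample's state, and follow-up
  obesity is logistic in the subject's mean score — so inflammation and the
  obese phenotype are enriched at the low-diversity end, the association the
  pipeline is designed to detect.

What the generator does **not** emulate: taxonomy-assignment error, chimeras
or raw reads; realistic phylogenetic signal (the tree is a random coalescent
over OTUs, so UniFrac behaves correctly but without ecological tree
structure); subject-level microbiome individuality beyond state membership;
longitudinal age trends in diet; missing data.  Passing recovery tests
therefore show the estimators work under the declared generative model, not
that real cohorts are this easy.

## Numerical choices and problem sizes

- Silhouette-based `k` selection scans 2..8 and requires at least 2 clusters.
- Correlation distances are clipped to be non-negative and symmetrized before
  linkage; linkage uses scipy's condensed form.
- Spearman significance inside the steady-state verification uses the
  t-approximation, appropriate for the hundreds of OTUs involved.
- Simulation-based tests run at reduced sizes (e.g. 99-199 permutations or
  bootstrap resamples inside 500-replicate calibration loops); these sizes
  are stated in the tests themselves.
- `scripts/acceptance.py` regenerates the default 140-sample cohort at the
  given seed, runs the full analysis with the generator's known state and
  diet-group counts (k = 4, m = 5), and writes the headline quantities as
  JSON.

## Known limitations

- Silhouette selection on the signed-correlation distance tends to merge
  adjacent community states on smooth gradients; supply a fixed `k` when an
  external criterion exists.
- The xy-pair bootstrap option for median regression is mildly conservative
  even at cohort-scale n; the default score bootstrap is the calibrated
  choice and the pair variant is kept for slope confidence intervals.
- Storey's estimator with fixed lambda = 0.5 is unstable for fewer than ~50
  tests; the BH fallback is preferable for small genus panels.
- The Fisher enrichment of diet × microbiota combinations is descriptive:
  labels are estimated on the same samples, so its p-values ignore label
  uncertainty.
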