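# comorbnet

Race/ethnicity-stratified deep phenotyping of Alzheimer's dementia (AD)
from electronic medical records: propensity-score-matched case-control
cohorts, phecode-level differential comorbidity analysis, 2-D embeddings
of phenotype profiles, disease co-occurrence networks, and two-site
validation — packaged as a tested pipeline driven by a synthetic EMR
generator, so every stage is verifiable without access to patient data.

## Who this is for

Clinical informatics and epidemiology groups who want to run (or audit)
stratified comorbidity analyses on OMOP-style EMR extracts. Real patient
tables of this kind are access-restricted, so the package ships a
generator that emulates their structure — four racialized strata (Asian,
Black, Latine, White), a 1:2 case:control design, confounded demographics,
and per-phenotype prevalences with configurable stratum- and site-specific
odds ratios — giving every downstream statistic a known ground truth.

## The method

1. **Cohort selection.** Propensity scores e(x) = P(case | x) are fit by
   maximum-likelihood logistic regression on sex, estimated age, death
   status (and care site for multi-site cohorts). Controls are matched
   1:2 by greedy nearest-neighbor on |e(x_i) − e(x_j)| without
   replacement, one round per ratio unit, cases in descending-score
   order; optional common-support trimming restricts matching to the
   overlapping score range. A second, stratum-wise round re-estimates
   scores within each racialized stratum and equalizes stratum sizes.
   Balance is reported as standardized mean differences
   (SMD = |x̄₁ − x̄₂| / √((s₁² + s₂²)/2); < 0.1 is considered balanced).
2. **Phenotyping.** ICD-9-CM/ICD-10-CM codes are joined exactly against a
   phecode map; phecodes without a category are excluded; each patient
   becomes a binary phenotype vector (the AD-defining phenotype removed).
3. **Differential analysis.** Per stratum, each phenotype's 2×2 table
   (cases/controls × with/without) is tested two-sided — Fisher's exact
   (full hypergeometric enumeration, point-probability rule) when any
   cell < 5, else Pearson χ² with 1 df — with odds ratio
   OR = ad/bc (Haldane–Anscombe +0.5 when a cell is 0) and Bonferroni
   correction over the phenotypes tested in that stratum. Significant
   sets are partitioned into exact UpSet intersections across strata.
4. **Embedding.** One-hot phenotype profiles are embedded in 2-D with
   UMAP; component distributions are compared by Mann-Whitney U (two
   groups) or Kruskal-Wallis plus two-sided Dunn post-hoc z tests
   (Bonferroni-corrected), all tie-corrected with midranks.
5. **Networks.** Per stratum × AD status (8 networks), phenotypes shared
   by > 5% of the cohort are nodes and pairs shared by > 5% are edges
   (> 25% for the visualization export). Ten per-node topology metrics
   (degree, average shortest path length, closeness, eccentricity,
   radiality, stress, betweenness, clustering coefficient, neighborhood
   connectivity, topological coefficient) are computed per connected
   component and compared across networks with the same rank tests.
6. **Two-site validation.** Discovery-significant phenotypes are looked
   up at the validation site; replication fractions, Spearman rank
   correlations of log-OR pairs (replicated vs discovery-only subsets),
   and z-scored network-metric concordance quantify agreement.

## Worked example

```bash
cat > config.yaml <<EOF
n_cases_per_stratum: 100
control_pool_multiplier: 5
n_phenotypes: 40
fraction_null: 0.7
confounding_strength: 0.5
run_embedding: false
two_site: true
seed: 1
output_dir: demo_out
EOF
comorbnet run-all --config config.yaml
# -> run complete: 16 networks, artifacts in demo_out
```

The run directory then contains, per site, the matched-cohort balance
table, per-stratum differential CSVs, UpSet intersection JSON, Manhattan
data table, 8 GraphML networks with node-metric CSVs, and a cross-site
report. Selected numbers from this exact run:

Balance (mean over strata) — matching removes the injected confounding:

```
covariate      smd_before  smd_after
death_status        0.302      0.041
estimated_age       0.221      0.048
sex                 0.113      0.042
```

Top of `demo_out/discovery_differential_Asian.csv` (100 AD cases vs 200
matched controls, Bonferroni family = 40 tested phenotypes):

```
                      phenotype   a   c test_used  p_bonferroni  odds_ratio
Gastroesophageal reflux disease  42  29      chi2      0.000005        4.27
        Inflammation of eyelids  38  26      chi2      0.000025        4.10
      Major depressive disorder  29  18      chi2      0.000281        4.13
```

`a`/`c` are carrier counts among cases/controls; an OR ≈ 4 on an injected
effect in the 3–6 range at this sample size is the expected recovery.

Cross-site report (`demo_out/crosssite_report.json`): replication
fractions per stratum of 1.00 / 0.82 / 1.00 / 1.00 (10/10, 9/11, 12/12,
11/11), and network-metric concordance ρ = 0.78 (p = 2.4e-17) across the
8 networks × 10 metrics — the behaviour expected when both sites share
the same effect structure.

## Layout

- `src/comorbnet/simulate.py` — synthetic OMOP-lite cohort generator
- `src/comorbnet/phecodes.py` — ICD→phecode mapping, phenotype matrix
- `src/comorbnet/matching.py` — propensity scores, matching, balance
- `src/comorbnet/differential.py` — 2×2 tests, ORs, UpSet partition
- `src/comorbnet/ranktests.py` — MWU, Kruskal-Wallis, Dunn, Spearman
- `src/comorbnet/embedding.py` — UMAP embedding + comparisons
- `src/comorbnet/network.py` — co-occurrence networks, 10 node metrics
- `src/comorbnet/crosssite.py` — replication and concordance
- `src/comorbnet/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for model details, parameter defaults, numerical
conventions, and known limitations.
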