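# Methods

## The synthetic EMR model

The generator emulates the structure of a de-identified OMOP-style EMR
extract for an elderly case-control study of Alzheimer's dementia (AD).

**Person table.** Four racialized strata (Asian, Black, Latine, White),
each with `n_cases_per_stratum` cases and
`n_cases_per_stratum × control_pool_multiplier` candidate controls.
Covariates: sex (70% female at baseline), estimated age (normal, mean 85,
SD 6, truncated to ≥ 65 and capped at 90 — the cap mirrors the common
de-identification convention of recording all ages above 90 as 90), death
status (12% deceased at baseline) and care site (uniform over the
configured sites). With `confounding_strength = c > 0`, case covariates
are tilted (age mean +3c years, deceased +0.25c, female −0.08c), so the
candidate pool is demonstrably imbalanced and matching is non-trivial.

**Diagnosis model.** Each patient acquires each phenotype independently
with probability

    P = logit⁻¹( logit(baseline) + is_case·log(OR) + c·z(covariates) )

where `baseline` and `OR` come from the ground-truth effect table (per
phenotype and stratum) and `z` is a mean-centred score of age, death
status and sex. With `c = 0` the injected OR is exactly the marginal
odds ratio the differential stage estimates; with `c > 0` the same
covariates drive both case status and prevalence, so an unmatched
analysis is biased and matching removes the bias (verified by the
balance tests). Each acquired phenotype emits 1–3 of its mapped ICD
codes (duplicates intentional — they exercise downstream
de-duplication); cases additionally emit a case-defining AD code
(G30.9). A fraction `fraction_null` of phenotypes has OR = 1; the rest
draw OR uniformly from `effect_or_range`. Per-phenotype
`shared_across_sites` flags control whether an effect is present at a
second (validation) site; non-shared effects revert to OR = 1 there.

**Defaults** (the study conditions the tests run under): 422 cases per
stratum with a five-fold control pool at the discovery scale, 994 per
stratum over four sites at the validation scale; `fraction_null = 0.8`;
`effect_or_range = (3, 6)`; baseline prevalences uniform on
(0.05, 0.40); `confounding_strength = 0.5` wherever matching is part of
the exercise. One global integer seed; all stochastic stages derive
child seeds deterministically from it via `numpy.random.SeedSequence`.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: visit timelines and coding-intensity
differences, correlated phenotype blocks (phenotypes are independent
given case status; a deliberate simplification since the downstream
tests are marginal), miscoding, stratum-dependent utilization, and any
time axis (the lookback window of real extracts has no analogue here).

## Phecode mapping

ICD codes are matched by exact string equality after trimming (the
published phecode maps enumerate codes explicitly; no prefix rollup and
no parent/child phecode aggregation). Phecodes with an empty category
are excluded from all analyses; unmapped codes are counted per code and
never fatal. Phenotype identity is the phenotype-name string; one ICD
code may map to several phecodes and all are retained. The bundled
`data/synthetic_phecode_map.csv` is a deliberately miniature *synthetic*
map (generated by `synthetic_phecode_map`, which can produce a map of
any size) — loading real phecode map files is supported through
`load_phecode_map`'s column-mapping argument.

## Matching

Propensity scores are maximum-likelihood logistic regression fits
(intercept plus main effects; categoricals one-hot expanded against a
fixed first-level reference; constant columns dropped with a warning).
Fitting uses IRLS (GLM with binomial family), which degrades gracefully
under quasi-separation; *complete* separation (every case outscoring
every control) is reported as an error advising covariate review or
common-support trimming.

Matching is greedy nearest-neighbor without replacement at ratio R
(default 2): cases in descending score order, one control per case per
round, R rounds, each case taking the remaining control closest in
absolute score difference. Ties break on (score, person_id), making the
procedure fully deterministic for a fixed input. Common support trims to
the closed interval [max of group minima, min of group maxima]; the
`common_support_discard` option selects whether both groups or only the
candidate-control pool lose patients outside the overlap — trimming only
controls keeps the case cohort (and hence the estimand) intact, which is
the mode used for the exact-arithmetic validation runs. The stratified
round re-estimates scores within each stratum (the stratum label is
never a covariate there) and, when equalizing, subsamples every
stratum's complete-match case set (seeded) to the minimum across strata,
so all strata have identical case and control counts.

SMD conventions: continuous covariates use the pooled-SD formula;
categorical covariates take the maximum level-wise proportion SMD; zero
variance in both groups defines SMD = 0.

## Differential analysis

Tested set per stratum: every phenotype with ≥ 1 carrier among that
stratum's matched cases and controls, minus the configured exclusions
(the AD-defining phenotype by default — dementia phenotypes are
retained). The Bonferroni family is exactly this tested set, per
stratum. "Any cell < 5" routes a table to the two-sided Fisher exact
test, computed by full enumeration of the hypergeometric support with
the point-probability rule (tables whose probability is ≤ the observed
table's, within relative tolerance 1e-7 to guard floating-point ties);
zero margins give p = 1 by convention. Larger tables use Pearson χ²
(1 df) without continuity correction — the small-cell rule has already
diverted the tables where the correction matters. Odds ratios apply the
Haldane–Anscombe +0.5 correction only when a cell is zero. Intersections
of significant sets use exact-subset (UpSet) semantics.

## Rank statistics

One shared implementation (`ranktests.py`) serves the embedding,
network, and cross-site stages. All statistics use midranks; variances
are tie-corrected. Mann-Whitney U is reported for the first sample with
a normal-approximation p (0.5 continuity correction); an
exact-enumeration p is available for n₁+n₂ ≤ 20. Kruskal-Wallis uses
the χ²(k−1) approximation. Dunn's z for groups i, j is
(meanrank_i − meanrank_j) / √([N(N+1)/12 − Σ(t³−t)/(12(N−1))](1/n_i + 1/n_j)),
two-sided, Bonferroni-multiplied by C(k, 2). Spearman's ρ is the Pearson
correlation of midranks with a t(n−2) p-value; a constant vector makes ρ
undefined (NaN), reported as such.

## Embedding

The 2-D embedding consumes UMAP as published (umap-learn); the package's
own contract is the feature construction (binary phenotype matrix with
the AD phenotype excluded — enforced, since including the case-defining
phenotype would trivially separate the groups) and the component
comparisons. Defaults `n_neighbors = 15`, `min_dist = 0.1` are the
library's; the original analysis does not pin these, so they are
recorded in the result object rather than asserted as comparable.
Passing a seed forces single-threaded execution, which is what makes
repeated runs byte-identical.

## Co-occurrence networks

Nodes are phenotypes with prevalence strictly above the node threshold
(default 0.05) in the network's own cohort; edges are phenotype pairs
with co-prevalence strictly above the edge threshold (0.05; 0.25 for the
visualization export). Graphs are simple and unweighted; prevalences are
attributes. Eight networks per site: 4 strata × {AD, control}.

The ten node metrics follow the classic network-analyzer definitions,
computed per connected component: degree; clustering coefficient
2e/(k(k−1)) (0 for k < 2); neighborhood connectivity (mean neighbor
degree; 0 if isolated); average shortest path length (aspl) over the
component; closeness 1/aspl; eccentricity (max distance); radiality
(Δ + 1 − aspl)/Δ with Δ the component diameter; stress (number of
shortest paths between other node pairs passing through the node, all
paths per pair counted, unordered pairs); betweenness (Brandes-style
pair fractions, normalized by (N_c−1)(N_c−2)/2 within the component);
topological coefficient (mean over neighbor-sharing partners m of
(shared neighbors + adjacency)/k). Degenerate conventions: an isolated
node has aspl = closeness = eccentricity = 0 and radiality = 1; these
are this package's documented choices — the GUI tool whose metric suite
this mirrors does not publish its disconnected-graph behaviour, so
cross-tool agreement is only guaranteed on connected graphs. All ten
metrics are verified against a brute-force path-enumeration oracle on
every connected graph with ≤ 7 nodes and on random graphs up to 40
nodes.

## Cross-site validation

Replication restricts to phenotypes tested (≥ 1 carrier) at both sites.
OR concordance is Spearman's ρ on log-OR pairs, computed separately for
the replicated and the discovery-only subsets; strata with < 3 pairs are
reported as not computable. Metric concordance reduces each network to
one value per metric — the **median over nodes** (mean available via the
`statistic` argument; the reduction used in the original analysis is
unstated, so this is a package choice) — z-scores the 8 networks within
each site per metric, and correlates the paired cells across sites.

## Pipeline

`run_full` executes generate/load → map → stratified match → matrix →
embedding comparisons → per-stratum differential → 8 networks with
metrics and comparisons → cross-site (when a two-site synthetic run is
configured), writing every stage artifact as a plain file plus a
manifest (config hash, seed, version, artifact list). Stage logs carry
patient/phenotype counts so filter attrition is auditable. The CLI
(`comorbnet`) exposes `simulate`, `map`, `match`, `diff`, `embed`,
`network`, `validate-sites`, `run-all`; exit codes are 0/1/2 for
success/validation error/runtime error.

## Problem sizes used in the test suite

The statistical property tests run at the design's stated sample sizes
(422 cases / 844 controls per stratum) with simulation depths chosen as
the package's own trade-off between resolution and runtime: 200
replicates × 200 phenotypes for family-wise error under the global null;
50 replicates × 20 injected effects for power and OR recovery; 20 seeds
for the two-site contrasts (30 shared effects with OR ∈ (2, 8), chosen a
priori so the replicated subset carries a clear rank signal); the
matching arithmetic runs at both full scales (422 and 994 cases per
stratum). The end-to-end pipeline tests use smaller cohorts (40–100
cases per stratum) since they check structure, not power.

## Known limitations

- Independent phenotypes given case status: no comorbidity correlation
  structure, so network *topology* under the generator is driven by
  marginal prevalences; topology comparisons validate the metric
  machinery, not epidemiological network structure.
- Greedy matching is order-dependent by design (documented determinism
  over optimality); no calipers, optimal/full matching, or weighting.
- Fisher enumeration is exact but O(support) per table; the pipeline
  routes only small-cell tables to it.
- UMAP determinism holds only in seeded single-threaded mode, and
  embedding geometry is not comparable across umap-learn versions.
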