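# Methods

This note documents the models, parameter choices, numerical details
and known limitations of the `adiposcan` pipeline.

## Scope and data contract

The pipeline consumes a log2-scale expression matrix (genes × samples),
a sample table (group ∈ {control, case}; the study labels NGT/T2D are
accepted aliases; optional sex; 16 numeric intermediate traits), a
disease gene list, an undirected protein-interaction edge list with
optional confidence scores, and GMT gene-set collections. Expression
values are log2 by contract everywhere — fold-change thresholds and DE
effect sizes are only meaningful on a fixed scale — with an optional
log2(x+1) transform at ingest for raw-scale files. Gene identifiers
are matched case-sensitively after whitespace stripping; alias
resolution is a data-curation step outside the method. Raw microarray
preprocessing (CEL parsing, gcrma, probe collapsing) and database
retrieval are out of scope: gene lists, networks and gene sets arrive
as files.

## Trait comparisons

Group differences in the intermediate traits use the Welch
(unequal-variance) two-sample t with Welch–Satterthwaite degrees of
freedom, from raw vectors or from (mean, SD, n) summaries. Welch
rather than pooled variance was chosen because recomputing the study
cohort's published male-column summaries (n = 15 per sex stratum per
group) reproduces the printed p-values under Welch but not pooled df —
most sharply for fasting glucose (Welch 0.00063 vs pooled 0.00016
against a printed 0.0006). Several published female-column rows are
not reproducible from their printed summaries under either flavor
(plausibly unequal per-cell n); they are not used as checks.
Degenerate inputs: two zero-SD groups give t = 0, p = 1 when means
agree and p = 0 with a warning otherwise; a trait absent from one
group yields a row with the test marked unavailable.

## Differential expression

A non-specific filter first removes genes with log2 intensity above
`filter_min_intensity` (default 6.0) in fewer than
`filter_min_fraction` (default 0.25) of samples, or interquartile
range below `filter_min_iqr` (default 0.5) — the usual microarray
pre-filter that discards unexpressed and near-constant probes.

Testing uses the empirical-Bayes moderated t. With per-gene pooled
variance s_g² on d_g = n₁+n₂−2 df, the prior (d₀, s₀²) is estimated by
closed-form moment matching on e_g = log s_g² − ψ(d_g/2) + log(d_g/2):
the excess of Var(e) over ψ′(d_g/2) equals ψ′(d₀/2), inverted by
Newton iteration on the trigamma function (relative tolerance 1e-8,
with the standard 1/√y and 1/y asymptotes). When no excess variance
exists (homoscedastic data, as produced by the default simulator) the
fit returns d₀ = ∞ and every gene uses s₀ — the correct limit, in
which the statistic is a common-variance z-test. Then
s²_post = (d₀s₀² + d_g s_g²)/(d₀+d_g) and p comes from a t on d₀+d_g
df (normal when infinite). With moderation off the procedure is the
ordinary equal-variance two-sample t. The design is a plain two-group
contrast without covariates. DEG selection uses unadjusted p < 0.05
(α configurable); BH-FDR q-values are reported alongside but are not
the selection criterion. Genes with zero variance and zero mean
difference get t = 0 (no change, no evidence) rather than NaN.

## Network prioritization

The disease neighborhood is the induced subgraph on the seed genes
present in the network plus their first-degree neighbors; seed
attrition (seeds absent from the network) is reported, mirroring the
130-of-138 / 121 / 111 attrition the motivating analysis reports at
successive stages rather than reconciling those counts. DEG overlap is
|DEGs ∩ subnetwork| with its percentage of the DEG list (the package
reports both the count and the arithmetic percentage; for the study's
own counts, 675/2537, the arithmetic gives 26.6% while the source
text prints "~18%" — the package reports, it does not adjudicate).
Reduction repeats the neighborhood construction seeded by the
overlapping DEGs.

Degree centrality is the incident edge count. Bottleneck centrality
builds, for every root s, a BFS shortest-path tree T_s; node v scores
p_s(v) = 1 iff its subtree (counting v) contains more than |V(T_s)|/4
nodes — equivalently, more than a quarter of the root-to-node paths
pass through v — and BN(v) = Σ_s p_s(v). Determinism requires a parent
rule: each node's tree parent is the lowest-ID shortest-path
predecessor (implemented by scanning each BFS level in ascending node
order). The root counts itself (its subtree is the whole tree), and in
disconnected graphs each tree spans only the root's component. Both
centralities are verified against an independent path-walking oracle
on the complete non-isomorphic graph atlas up to 7 nodes and on random
8- and 40-node graphs. Prioritization takes the union of the top-k
(default 100) nodes per metric, ties broken by node ID ascending,
exactly k per metric; k is clamped to the node count with a warning.

## Over-representation analysis

For input list ∩ reference of size n, a set with K members in the
reference and overlap k scores p = P(X ≥ k), X ~ Hypergeometric(N, K, n)
(one-sided over-representation only), with expect = nK/N and
enrichment ratio k/expect; BH-FDR across all tested sets. The
reference universe defaults to the union of all set members when not
supplied — the original web-tool reference is unrecoverable, and the
choice is recorded in the run log. Sets with K < 3 after reference
intersection are skipped (degenerate expect values); input genes
outside the reference are dropped with a logged count.

## Co-expression

Run separately per group on the disease-gene submatrix (the motivating
analysis studies modules *of* the disease genes; full-transcriptome
co-expression is out of scope). Unsigned adjacency a_ij = |cor|^β with
β = 15 (the soft threshold chosen in the source analysis for
scale-free topology; a scale-free fit R² of the binned log-log
connectivity distribution is reported). Topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), unit diagonal.
Modules come from average-linkage hierarchical clustering of 1−TOM
with a *static* height cut — a deliberate simplification of dynamic
tree cutting that keeps the procedure deterministic (SciPy linkage
with index-order tie-breaking). Because β = 15 compresses TOM values
toward zero (within-block TOM ≈ 0.04–0.06 for pairwise correlation
0.8), genuine clusters sit just below dissimilarity 1, so the default
cut height is 0.995; clusters below `min_module_size` (default 10)
are grey. Colors follow the conventional size-ordered palette
(turquoise, blue, …). Module eigengenes are the first principal
component of the standardized module expression, scaled to unit sample
variance and sign-oriented to correlate positively with the module
mean profile; grey gets an eigengene too, since the motivating
analysis correlates it with traits. Eigengene–trait association uses
Pearson r with p = 2·P(T_{n−2} > |r|√((n−2)/(1−r²))),
pairwise-complete over missing trait values with per-pair n in the df;
constant traits (or < 4 complete pairs) are marked undefined.

## Individualization

Per disease gene, the control envelope is (mean, sample SD) over the
controls; a zero SD is floored at `min_control_sd` (1e-6) rather than
triggering unconditional flags. A case is flagged up/down for a gene
when its value leaves the envelope. The source describes the rule both
as ±2 SD (methods) and ±2-fold (results); both modes are implemented —
sd mode is the default and the run report records the mode. Fold
comparisons act on log2 differences (|Δ| > log2(threshold)); at
σ_c = 0.5 the two rules coincide at threshold 2. Flag sets are nested
decreasing in the threshold. With an envelope *estimated* from n
controls, the per-cell false-positive rate is
2·P(t_{n−1} > 2·√(n/(n+1))) ≈ 5.9% at n = 30, converging to
2·Φ(−2) = 4.55% for large n; the calibration tests assert the exact
finite-sample value.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at the study's scale: 30 controls + 30 cases (sex-balanced, alternating
M/F), 5,000 genes with per-gene baselines ~N(8, 0.8) on the log2 scale
(the baseline spread gives the non-specific filter realistic work) and
noise SD σ = 0.5. Planted features, all recorded in a truth object:

* **DE genes** (default 200): ±1.0 log2 shift in cases, half up and
  half down (the motivating result is mixed-direction: 7 up, 9 down
  disease-gene DEGs, which are the generator's default overlap counts).
* **Co-expression blocks** (default 2 × 30 genes): gene = loading·F_b +
  noise with loading √0.8 ≈ 0.894, i.e. within-block pairwise
  correlation 0.8; each latent factor F_b couples to one named trait
  ("Cell size", "LDL") at 0.6, the other 13 traits are independent
  noise. Module genes are part of the disease gene list, so the
  per-group co-expression stage sees them.
* **Disease gene list** (default 138): the module genes, the planted
  DE overlap, and random non-DE filler.
* **Network**: Barabási–Albert preferential attachment (m = 2) over
  all genes with the disease genes added first, so they are
  high-degree-prone — the hub-prioritization stage then has signal.
* **Gene sets**: one set per planted block plus random decoys.
* **Outliers**: by default 1–4 disease genes in 25 of the 30 cases
  (the study individualizes 25/30 patients), at ±3 control SDs.
  Outlier cells are *placed* at control mean + shift·(control sample
  SD) — not additively perturbed — so the planted deviation is exact
  in control-SD units and recovery is deterministic.

All randomness flows from a single integer seed through one generator;
identical configs are bitwise reproducible. What the generator does
**not** model: probe/batch effects, heteroscedastic per-gene variances
(hence the moderated-t prior df is typically infinite on synthetic
data, exercising the shrinkage limit rather than intermediate
shrinkage — the prior-recovery unit test covers the finite-d₀ path
with explicitly heteroscedastic draws), sex-specific effects, trait
group differences, and correlation between the network topology and
the expression correlation structure. Passing recovery tests therefore
demonstrate correctness of the machinery under the assumed model, not
performance on real microarray data.

## Orchestration

`run_pipeline` executes traits → DE → network → ORA → co-expression →
individualization from one config (file paths or a simulation block —
exactly one). Stages not selected but required by a selected stage run
in memory without writing outputs. The JSON run report is versioned,
contains every headline count, and is byte-identical for identical
seed + config (sorted keys, no timestamps; non-finite values serialize
as null). Caching is whole-run: a report whose config hash (excluding
the output directory) matches is reused unless `--force`.

## Problem sizes in tests

The test suite uses the study-scale defaults where the check concerns
recovery under study conditions (60 samples, 138 disease genes, 100
replicates for module recovery), and smaller cohorts (400–2,000 genes)
for schema and plumbing checks. Calibration pools 200 null replicates
of 2,000 genes × 60 samples for the type-I error of the moderated t,
and 2,000 random draws for ORA null calibration. Centrality oracles
run exhaustively over the ≤ 7-node graph atlas plus 300 random 8- and
40-node graphs.

## Known limitations

* Static tree cut instead of dynamic tree cutting; no module merging
  by eigengene similarity, no consensus modules across groups, no
  biweight midcorrelation.
* Bottleneck centrality's tie handling in the original tool is
  undocumented; the lowest-ID parent rule is this package's fixed,
  documented convention, so scores can differ from other
  implementations on graphs with shortest-path ties.
* ORA absolute results depend on the annotation release and reference
  universe; only the statistics' definitions are fixed here.
* The published dataset-specific headline numbers (2537 DEGs, 675-gene
  overlap, 3956/3613-node subnetworks, 25/30 patients) depend on the
  deposited cohort and database snapshots; the pipeline reproduces the
  report shape and is validated on planted-truth synthetic data
  instead.
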