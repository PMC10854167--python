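# Methods

## Problem and model

A tumor's tissue of origin is inferred from a vector of CpG methylation
β values (methylated signal / total signal, in [0, 1]). The pipeline has
two statistical stages — a univariate differential-methylation filter and
a multivariate random-forest selection — followed by a penalized
multinomial classifier. Everything downstream of the β matrix assumes
samples are independent and classes are fixed, known labels.

### Stage 1: differential filter

For each probe, a one-way fixed-effects ANOVA compares β across the k
classes: F = MSB/MSW with (k−1, N−k) degrees of freedom, computed on β
values directly (not M-values), with per-probe complete-case handling of
missing entries. Probes with ANOVA p < α receive Tukey's HSD post hoc
test: for classes a, b the studentized statistic is
q = |μ̂_a − μ̂_b| / √(MSW/2 · (1/n_a + 1/n_b)) (the Tukey–Kramer standard
error, required because real cohorts are unbalanced), referred to the
studentized range distribution with k groups and N−k df. The post hoc
test is evaluated only for ANOVA-significant probes; this cannot change
any pass/fail decision because passing requires ANOVA significance, and
it keeps the vectorized whole-matrix scan fast.

A probe passes under the default `one_vs_all` criterion when some class c
satisfies, against every other class d, adjusted p(c,d) < α and
|Δβ(c,d)| > δ (defaults α = 0.01, δ = 0.2). "Differentially methylated in
at least one cancer type" is read as one type separated from all others;
the weaker `any_pair` reading is available for sensitivity analysis. No
multiple-testing correction is applied across probes: the thresholds are
deliberately per-probe, as is conventional for this filter, and the
type-I consequences are measured empirically (null-cohort pass fraction
≈ the per-probe α of the full one-vs-all rule, far below the marginal α).

Degenerate cases: a probe whose groups are all constant has F = 0/0 and
is reported unevaluable (never a candidate); zero within-group variance
with distinct means yields F = ∞, p = 0; a probe is also unevaluable when
any class has fewer than two non-missing samples.

### Stage 2: two-step random-forest selection

Forests use the randomForest-style defaults: 500 trees, node size 1,
mtry = ⌊√p⌋ recomputed whenever the feature count p changes, one CPU.

*Importance.* OOB permutation importance (mean decrease in accuracy): for
each tree, the feature's values are permuted among that tree's out-of-bag
samples only, and the rise in the tree's OOB error is averaged over
trees. scikit-learn draws each tree's bootstrap as `randint(0, n, n)`
from the tree's seeded RNG; the OOB rows are reconstructed from the same
draw, so no refitting or private API is needed. Rankings order by score
descending with probe-id ascending as the tie-break, making them
deterministic across platforms.

*Forward selection.* The kept set starts with the top-ranked feature and
its aggregated OOB error (per-sample majority vote over trees where the
sample was out of bag). Each subsequent candidate, in rank order, is
accepted iff retraining on kept ∪ {candidate} lowers the OOB error by
more than `min_improve` (default 0: literal strict decrease; a small
positive value damps OOB noise, e.g. to reject exact duplicate columns).
The accepted-error trace is therefore strictly decreasing by
construction. Evaluation stops once the current error ≤ `min_improve`,
since a strict improvement is then impossible — an exact shortcut, not an
approximation.

*Multi-run union.* The two-step procedure is repeated n_runs times
(default 5), re-randomizing only the forest seed (base + run index).
Each run contributes its top `per_run_top` features; by default these are
taken from the run's importance ranking over all candidates
(`rank_source="all_candidates"`), which guarantees each run contributes
exactly `per_run_top` features and hence
`per_run_top ≤ |union| ≤ n_runs · per_run_top`. The alternative
`rank_source="kept"` draws them from a forest retrained on the run's
forward-selected kept set; strict-decrease selection saturates once the
OOB error reaches zero, so kept sets are typically far smaller than
`per_run_top` and runs then contribute fewer features. The union is
re-ranked by a final forest and truncated to `final_k` (warning when the
union is smaller). A panel-size sweep utility retrains the classifier on
top-k panels over a grid and reports validation accuracy, skipping k
values beyond the available features.

### Classifier

Elastic net and lasso are multinomial logistic regressions with penalty
λ[(1−α_mix)/2·‖β‖² + α_mix·‖β‖₁], fitted by SAGA on internally
standardized features; coefficients are reported back on the β scale.
λ is selected by 5-fold cross-validated multinomial deviance over a
log-spaced grid (10 points, the scikit-learn default span); α_mix
defaults to 0.5, the conventional midpoint, and 1.0 gives the lasso
exactly (asserted as an identity in the tests). These hyperparameter
choices are recorded in model metadata as defaults, since nothing in the
method prescribes them. Folds are reduced with a warning when the
smallest class is smaller than the fold count. The random forest
classifier reports per-class probabilities as the fraction of trees
voting for each class; penalized models report softmax probabilities.
Calls are argmax with exact ties broken toward the lexicographically
first class name and flagged.

Trained models carry their ordered probe list and per-probe training
means. Prediction requires the input to be harmonized to that probe
list; probes missing on the assay platform (450K vs EPIC vs targeted
panel) are imputed with the stored training means by default — a
class-agnostic choice that biases toward no class — with `constant` and
`fail` policies available. Imputed cells are recorded in the
harmonization result.

### Evaluation

Splits are stratified: per class, ⌈train_frac·n_c⌉ samples (clamped to
[1, n_c−1]) go to training, so every class appears in both partitions —
the minimal assumption that makes k-class training on a random split
well-defined. Confusion matrices are reported as counts and row percents
(true class in rows). Per-class one-vs-rest sensitivity, specificity,
PPV and NPV; 0/0 ratios are NaN, never 0, to avoid silently deflating
summaries. Accuracy equals the prevalence-weighted mean of per-class
sensitivities (asserted as an identity).

### Quantification of targeted sequencing

Bismark coverage records are normalized to 1-based forward-strand CpG
cytosine positions (a dialect flag accepts 0-based half-open input).
CpG methylation is symmetric, so by default the reverse-strand cytosine
at position+1 of a manifest CpG is summed onto the forward position
(idempotent; conserves total reads); array-trained models expect
strand-merged β. β = M/(M+U) exactly; probes with merged coverage below
`min_coverage` (default 10, a standard targeted-panel floor; set 1 for
no filtering) come out missing and flow through training-mean
imputation. Duplicate records at one position are summed with a warning.

### Annotation

Island = inside a CGI interval; Shore ≤ 2 kb from a CGI edge; Shelf
≤ 4 kb; Open Sea beyond — the Illumina 450K convention, with boundary
distances inclusive toward the nearer category. Gene regions are
resolved strand-aware from the TSS (TSS200 = 1–200 bp upstream, TSS1500
= 201–1500 bp) with containment checks for 5'UTR / first exon / body /
3'UTR and the priority TSS200 > TSS1500 > 5'UTR > FirstExon > 3'UTR >
Body; Intergenic otherwise. BED input (0-based half-open) is converted
to 1-based inclusive at the module boundary. Both the promoter split
(TSS200/TSS1500) and their union are recoverable from the per-probe
table.

## Synthetic data generator

The generator emulates the structure this pipeline exploits in real
array cohorts. Per-sample β at probe j is Beta(mφ, (1−m)φ) with mean m
and precision φ (default 30, giving SD ≈ 0.09 at m = 0.5 and shrinking
toward the boundaries, comparable to array noise). Background probe
means are drawn from a low/high mixture (60% near 0.15, 40% near 0.85 by
default) matching the global bimodality of methylation arrays. For each
class, `informative_per_class` disjoint probes are shifted by
`effect_delta` in that class only (sign chosen to stay in range,
preferring hypermethylation; means clipped to [0.02, 0.98]).
`effect_delta = 0` produces exact null data for type-I checks. Platform
dropout removes a seeded uniform probe subset. Sequencing counts use
Poisson coverage (floor 1; the simplest defensible model absent coverage
statistics) and Binomial(coverage, β) methylated reads.

Not emulated: probe cross-reactivity, batch effects, FFPE deamination
artifacts, incomplete bisulfite conversion, tumor purity variation, and
correlated neighboring CpGs. Tests passing on these cohorts therefore
demonstrate the machinery's correctness and its behavior under the
modeled noise, not clinical-grade performance on real specimens.

## Study-scale test conditions

The end-to-end checks run an 8-class cohort, 40 samples per class, 5000
probes, 20 informative probes per class (160 planted), effect size 0.35,
precision 30, split 30% training / 70% validation, selection with
n_runs = 5 and per_run_top = final_k = 160 at ntree = 500. Under these
conditions the filter and panel recover ≥90% (empirically all) of the
planted probes and the elastic net classifies the held-out 70% near
perfectly. Structural properties (union cardinality bounds, strictly
decreasing OOB traces) are additionally checked across 20 random seeds
at a reduced size (3 classes × 12 samples, 150 probes, ntree = 60),
since they are seed-robustness properties rather than effect-size
properties. The panel-size sweep uses the grid 50–300; grid points
beyond the available union are skipped by contract, so comparisons use
the largest available panel.

## Numerical choices and edge cases

- ANOVA within-group sum of squares is computed as Σ(x²) − n·mean² per
  class and clamped at 0 against round-off.
- Studentized-range p-values come from `scipy.stats.studentized_range`;
  the test suite cross-checks them against an independent quadrature
  implementation of the distribution's defining double integral, and
  against `scipy.stats.tukey_hsd`, to 1e-6.
- Harmonization output order always equals the requested panel order.
- Model files are versioned joblib archives; loading rejects truncated
  files, missing versions, and newer major versions.
- The CLI derives per-stage seeds from the global seed by CRC32 of the
  stage name, below 2³¹, and echoes the effective configuration into
  every output directory.

## Known limitations

- Forward selection refits a forest per evaluated candidate; for
  candidate sets far larger than a few hundred probes the per-run cost
  grows linearly (the early-stop only helps once the OOB error floors).
- The elastic-net λ grid is the generic log-spaced default; no warm-start
  path or 1-SE rule is implemented.
- Annotation scans gene models linearly per probe — adequate for panels
  of hundreds of probes, not for genome-wide manifests.
- Probabilities are not calibrated and there is no reject option: the
  argmax class is always called.
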