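# Methods

This note records the statistical model behind `regact`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not demonstrate.

## Regulator activity score

For one sample with normalized expression profile e = (e_1 … e_n) over n
genes and a regulator with target indicator g ∈ {0,1}^n, genes are sorted
by expression in decreasing order (ties broken by gene symbol so results
are reproducible). Two cumulative distribution functions are accumulated
along that order:

- foreground F(j): the |e|-weighted fraction of total target weight among
  the first j genes,
- background B(j): the same quantity over non-target genes.

The preliminary score is F(j*) − B(j*) at the position j* maximizing
|F − B| (earliest position on ties). It lies in [−1, 1]; +1 iff targets
exclusively occupy a prefix of the sorted order, −1 iff a suffix. The
running sums are weighted by |e| so that the score reflects expression
magnitude, not only rank; an unweighted KS-style variant is available via
`weighted=False`.

The preliminary score is normalized by the mean absolute score over
random re-assignments of the k target labels across all genes
(`n_perm`, default 1000), sampled without replacement, one fresh draw per
permutation. Each (regulator, sample) cell has its own RNG substream
derived from the master seed and keyed by the regulator's sorted-name rank
and the sample position, so results do not depend on evaluation order or
parallelism. Because a uniform random k-subset of genes is exchangeable,
permuted indicators are drawn directly in the sorted order, which lets
all `n_perm` null scores be computed as one vectorized cumulative sum.

Sign convention: TF activity is reported as positively associated with
target expression; miRNA scores are negated after normalization, since
miRNAs repress their targets — an active miRNA shows low target
expression. Transcriptional repressors and activating miRNAs violate the
convention and need per-regulator interpretation.

### Expression normalization

Samples are quantile-normalized (columns mapped onto the vector of
rank-wise means; ties receive the average of the reference values at the
tied ranks). Single-channel intensity data is additionally centered by
each gene's across-sample median, so scores measure relative expression;
two-channel log-ratio data is already relative to a common reference and
is left uncentered. Probe-level preprocessing imputes missing values with
the probe's across-sample mean (probes observed in no sample cannot be
imputed and are dropped with a warning) and collapses multiple probes per
gene by the per-sample median; probes annotated to several genes
contribute to all of them.

## Intrinsic regulator selection

The within-between score of an activity vector x under subset labels is
WB = SSW/SSB with SSW = Σ_k Σ_{s∈k}(x_s − x̄_k)² and
SSB = Σ_k n_k (x̄_k − x̄)². Low WB marks activity that is consistent
within subsets but differs between them. WB is invariant to affine
transforms of x; when SSB = 0 the score is reported as +∞ (no subset
signal). The citation trail for this score gives no closed formula, so
this ratio definition is pinned here and validated by parameter recovery
on the generator.

Significance uses a plug-in permutation estimator: subset labels are
permuted jointly for all regulators per iteration (preserving
inter-regulator correlation), and FDR(r) = E_perm[#{null WB ≤ WB_r}] /
#{observed WB ≤ WB_r}, capped at 1 and made monotone nondecreasing in WB
by a cumulative minimum from loose to strict thresholds (SAM-style).
Defaults: 1000 label permutations (analysis drivers use 200). A regulator
is "intrinsic" when FDR < 2% (strict) in at least 3 cohorts.

Heatmap ordering z-scores each regulator row (zero-variance rows excluded
with a warning) and applies complete-linkage agglomerative clustering on
Euclidean distances to rows and columns — the defaults of the standard R
heatmap routine with row scaling.

## Severity correlation and ranking

Within one intrinsic subset, each regulator's activity is Pearson-
correlated with the MRSS over the subset's samples (≥3 samples with known
MRSS required; zero-variance vectors excluded with a warning). Per-cohort
correlations are aggregated by the mean (the median is available — the
source material is ambiguous between the two, so both are exposed and the
mean is the default) and ranked in decreasing order; the top and bottom k
(default 50 each) are flagged. Each biopsy sample counts as an
independent observation by default; a per-patient collapse (mean
activity, first MRSS) is available but off by default because no pooling
rule is stated for repeated biopsies.

## Quadrant subgroups

For a pair of regulators, samples split into four groups by the signs of
the two activity scores with cutoff 0 (a score of exactly 0 is
non-positive): group 1 double positive, group 2 first-positive, group 3
double negative, group 4 second-positive. Group 1 is compared with each
other group on MRSS by a two-sided Mann-Whitney-Wilcoxon test — exact
enumeration when m+n ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections. All p-values of a scan
(3 per tested pair) are pooled and Benjamini–Hochberg adjusted; "FDR"
language implies BH even though the adjustment method is not named in the
source. A pair is significant when all three q-values are below the
cutoff (1% for subset scans, 5% for the smaller ILD cohorts) AND group 1
has the strictly greatest median MRSS. Whether the original criterion
applied to all three contrasts jointly was unstated; the all-three rule
is declared here. Groups smaller than `min_group` (default 3) make the
rank test meaningless, so such pairs are reported untested.

The pair universe defaults to the top-50 positively MRSS-correlated
regulators from the ranking stage, configurable to any list.

Contingency contrasts (dcSSc fraction, early-stage, treatment) compare
group 1 against each comparator group with fold changes of fractions
(infinite sentinel when the comparator fraction is 0) and two-tailed
Fisher exact tests on the 2×2 tables.

The ILD scan reruns the severity scan at q < 5%, computes for each
significant pair the fold change of the ILD fraction in group 1 versus
the pooled groups 2–4 (the pooled comparator is a declared choice; the
per-group fractions are also reported), and retains pairs with fold
change strictly greater than 1.5, sorted by fold change.

FVC decline: per patient, baseline FVC %predicted is the first point of
the series and follow-up the latest point at ≥ `min_months` (default 36);
patients without a qualifying follow-up are excluded, and each patient is
assigned the quadrant group of their earliest sample. The paired t
statistic is computed on decline = baseline − follow-up, so positive t
means decline. Groups with fewer than two complete pairs are untestable;
zero-variance differences are flagged degenerate rather than producing an
infinite statistic.

## Interaction network

Motif sets are mapped to gene symbols (token before the first underscore,
uppercased, with a configurable alias table such as NMYC→MYCN); sets
whose name yields no symbol, or matches a configurable exclusion pattern,
are "unclassified motifs" and are dropped. Same-symbol sets are
amalgamated by target union. A directed edge A→B exists when B's symbol
is in A's amalgamated targets; self-loops mark self-regulating feedback.
Both endpoints are restricted to the selected regulators (edges from
unselected regulators are not kept). Node degree counts a self-loop once.
Nodes carry a correlation-sign category combining the fibroproliferative
and inflammatory rankings (positive-both, negative-both, the two mixed
categories, and one-subset-only). Exports: GraphML (lossless), SIF
(`A targets B`), and a TSV edge list. No layout is computed.

## Synthetic data generator

The generator emulates a multi-cohort skin expression study with known
ground truth; its defaults are the study conditions under which the
recovery claims below are made.

- Expression: per-gene Gaussian noise with sd `sigma` (default 1, log2
  units). Two-channel cohorts are centred at 0; single-channel cohorts
  are emitted as positive log2 intensities around 8.
- Gene universe: the first genes carry the regulator symbols themselves
  (regulators are expressed genes), so target lists can contain other
  regulators and the network stage is non-trivial; the rest are
  anonymous fillers.
- Target sets: `targets_per_regulator` genes drawn without replacement.
  Regulators carrying planted effects draw first and their targets are
  reserved — withheld from unplanted regulators' draws. With fully
  independent draws an unplanted regulator shares several targets with
  planted ones and becomes genuinely subset-active, which makes the
  planted/unplanted distinction unmeasurable; reserving keeps the ground
  truth identifiable while unplanted sets still overlap each other
  freely, as real motif sets do.
- Intrinsic structure: 10 planted regulators (3/3/2/2 across the four
  subsets) whose targets are shifted by `delta` (default 2) in their own
  subset's samples — upward for TFs, downward for miRNAs.
- Severity: two "driver" regulators receive a per-sample N(0,1)
  activation dose that shifts their targets by `delta`·dose;
  MRSS = 14 + 5·Σ doses + 8·[double-positive quadrant] + N(0,4), rounded
  and clipped to [0,51] (a noise floor of 0.5 avoids an all-constant
  MRSS). The severe pair's dose signs define the true quadrants.
- ILD: Bernoulli with probability 0.5 in the true double-positive
  quadrant, 0.2 elsewhere. dcSSc: 0.6 vs 0.35.
- FVC: baseline N(95,10) %predicted, slope −0.25 %/month in the
  double-positive quadrant and 0 elsewhere, follow-up at 42 months with
  N(0,2) measurement noise — about a 10-point decline in group 1.
- Patient = sample by default; the FVC series carries the longitudinal
  information (two time points per patient).

Everything derives from the config seed via one generator in fixed order,
so equal seeds give byte-identical cohorts; multi-cohort simulation with
shared truth draws the regulator universe once and re-simulates samples
per cohort.

What the generator does not emulate: probe-level artifacts (dye bias,
spatial effects), correlated gene-gene noise, batch effects between
cohorts, non-Gaussian expression tails, informative missingness, or
treatment-outcome feedback. Recovery results on this generator therefore
demonstrate the pipeline's correctness and calibration under its stated
model, not performance on real microarray cohorts.

## Problem sizes and numerical choices

The bundled studies (analysis drivers, test suite, acceptance script) use
600 genes, 60–100 regulators with 30 targets each, 4 cohorts × 60
samples, 60 scoring permutations and 200 within-between label
permutations — sizes chosen so that a full multi-cohort run completes in
minutes on one core while leaving the planted effects at the study's
stated magnitudes (δ = 2, σ = 1; MRSS coefficient 5; quadrant shift +8,
MRSS noise 4). The library defaults for real data remain 1000
permutations for both stages.

Tie handling is deterministic throughout: expression ties sort by gene
symbol, ranking ties break by regulator name, quantile-normalization ties
average the tied reference values, and argmax ties take the earliest
position. Degenerate inputs (constant activity, empty quadrants,
zero-variance FVC differences, regulators without scored targets) are
excluded or flagged with warnings rather than silently propagated.

## Known limitations

- The exact weighting of the original running-sum reference is not
  restated in the source material; the |e|-weighted reading is an
  assumption, validated against brute-force enumeration of this
  definition, not against the original implementation.
- The permutation FDR is a plug-in estimator; for very small cohorts the
  label-permutation space is small and the FDR granular.
- The quadrant analysis treats activity signs as meaningful zero points;
  this is inherited from the normalization, which centers scores only
  under the null.
- Multiple biopsies per patient are treated as independent observations
  in correlation and rank tests unless per-patient collapsing is enabled.
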