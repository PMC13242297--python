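# Methods

This note documents the models and procedures implemented in `drpscreen`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the design decisions taken where more than one
reasonable choice existed.

## Response representation

All drug sensitivities are carried as pIC50 = −log10(IC50 in molar).
Readers must declare the source unit (`pIC50_molar` or `IC50_micromolar`;
1 µM ⇔ pIC50 6), after which a single sensitivity threshold — pIC50 ≥ 6,
"active at or below 1 µM" — applies everywhere downstream (selective-drug
calling, screening-efficiency labels). Missingness is explicit: a boolean
`observed` mask accompanies every response matrix and unobserved entries
are stored as NaN, never read as numbers.

Consolidating multiple screens uses three filters:

- **Fingerprint dedup.** Drugs with bit-identical 166-bit MACCS keys are
  collapsed onto one canonical id (first in a stable sort). Exact identity
  (Tanimoto 1.0) rather than a similarity cutoff is the conservative
  reading of "redundant entries"; near-duplicates stay distinct.
- **Coverage.** Drugs observed in strictly more than 90% of cell lines are
  kept first; then cell lines observed for at least 90% of the retained
  drugs. The asymmetry (strict ">" vs "≥") mirrors the wording the filter
  is modelled on ("over" vs "at least"). The filter is idempotent.
- **Merging.** Cell-line aliases are resolved through an explicit alias
  table (no name-matching heuristics); when two sources report the same
  (cell, drug) pair the earliest-listed source wins and the conflict count
  is logged. Source precedence is configurable because screening
  repositories do not state a canonical tie-break.

## Panel selection

The same greedy procedure serves both axes (reference drug panels and
compact cell-line panels):

1. draw a random 70% subsample of the *observation* axis (prevents
   identical selections across replicate experiments);
2. exclude samples in the bottom half of response variance (variance over
   observed entries, ties at the median retained);
3. compute the pairwise-complete Pearson correlation matrix among
   survivors; pairs sharing fewer than `min_overlap` (default 10)
   observations get r := 0 with a warning;
4. rank survivors ascending by median correlation to the other survivors
   (stable tie-break on identifier);
5. iteratively select the lowest-ranked remaining sample and remove every
   remaining sample whose correlation with it exceeds the threshold *t*.

Design choices: the removal rule uses *signed* r > t — anti-correlated
samples carry information and are kept (an absolute-value mode exists);
the ranking is fixed upfront (a re-ranking mode after each removal round
exists but is off by default); the 70% subsample applies to the
observation axis, so drug panels are selected on a subsample of cell lines
and vice versa. `threshold_for_size` bisects *t* on a 0.005 grid for the
smallest threshold reaching a requested panel size — panel size is
non-decreasing in *t*, which makes the bisection exact.

## Descriptors

**DRP features.** A cell line's descriptor for target drug *d* is its
pIC50 vector over the panel drugs with *d* removed — the model never sees
its own target column, by construction (a poisoned-column test enforces
this). Residual missing entries are imputed with per-drug medians computed
only over the caller's training lines, and imputation flags are kept.

**Expression features.** Raw TPM is transformed to log2(TPM+1); PCA is
fitted on training cell lines only (centring, no unit scaling — the
default of standard implementations on log-scale expression; a scaling
flag exists) and the minimal number of components reaching 90% cumulative
explained variance is retained.

**Fingerprints.** MACCS keys via RDKit; the leading dummy bit of RDKit's
167-position vector is dropped to give the canonical 166 bits.
Unparseable SMILES are returned in a rejects list, never silently dropped.

## Models and evaluation

Per-drug response models are scikit-learn `GradientBoostingRegressor`
instances with 50 trees, depth 2, learning rate 0.1 (the learning rate is
the common default; tree count and depth are deliberately small because
training panels hold only tens of lines; a sweep helper covers depths 2–4
× 50/100 trees). QSAR models use 100 trees, depth 4 — their training sets
(hundreds of compounds per line) support more capacity.

Cell lines split 80/10/10 into train/validation/test (floor sizes for the
two holdouts, remainder to train). Metrics: Pearson, Spearman, MSE, RMSE,
MAE. Correlations on a constant vector are flagged undefined and excluded
(with a count) from per-drug aggregation rather than imputed as zero.
Global (pooled-pair) correlations systematically exceed the mean of
per-drug correlations because between-drug potency offsets inflate pooled
correlation; the evaluation reports both. The benchmark protocol repeats
the full pipeline (split → panel selection on training data → per-drug
fits → test metrics) over independent replicates and compares descriptor
arms with a two-sided paired t-test on replicate RMSEs.

The screening-efficiency statistic walks a predicted-sensitivity ranking
until ceil(recall × positives) actives are recovered and reports the
fraction of lines screened; under exchangeable (random) rankings its
expectation approaches the recall target, which the tests verify by Monte
Carlo.

## Biomarker discovery

For a drug of interest, the selected cell-line panel is enriched with the
top and bottom 10 predicted responders (union semantics, id-order
tie-breaks), maximising response contrast. Within that cohort the 500
genes with highest |Pearson r| to sensitivity are pre-selected
(zero-variance genes excluded), and a 200-tree random forest (default
depth) is fitted. Gene rankings come from impurity importances
(normalised to sum 1) *and* from SHAP values; the two are reported side by
side rather than replaced by one another.

SHAP values are computed by an exact path-dependent TreeSHAP
implementation for scikit-learn tree ensembles (`drpscreen.treeshap`):
conditional expectations over feature subsets follow the tree's own
training cover, and local accuracy (attributions + expected value =
prediction) holds to floating precision — asserted in tests against a
brute-force Shapley enumeration on small trees. SHAP is evaluated only on
held-out cell lines reserved *before* panel enrichment; overlap between
SHAP holdout and training cohort is a hard error. How many lines to
reserve is a design choice (the workflow default reserves 20%).

## QSAR harmonisation and prioritisation

When the reference panel is measured on only some lines (e.g. one anchor
line with full coverage), per-line QSAR models predict the missing panel
entries from MACCS bits. Measured values are never overwritten; every
entry carries a measured/qsar_predicted source label, and the measured
count is conserved exactly. Model quality is estimated on an internal 20%
drug holdout before refitting on all drugs; quality below Pearson 0.3
triggers a warning. Library drugs overlapping the panel are a leakage
error, mirroring the target-column exclusion rule.

Differential activity between two lines is Δ = pIC50(A) − pIC50(B);
|Δ| > 2 (100-fold) is called preferential, |Δ| < 1 no preference, and the
band between is explicitly *indeterminate* — the two published cutoffs
leave the interval uncovered, so the package refuses to guess. Validation
sets take the top 4 by Δ plus 2 no-preference controls. Viability uses
%V = (RLU − mean positive control)/(mean negative control − mean positive
control) × 100 (0 at the kill control, 100 at vehicle; values outside
[0, 100] are legitimate), and "IC50 reached" is the simple crossing rule —
any tested concentration at or below 50% viability — rather than a 4PL
fit, since only reached/not-reached at the top concentration is called.

## Synthetic data

One latent truth drives every generated table. Cell lines carry L = 5
standard-normal latent pathway activities u; drugs belong to 10 mechanism
clusters whose loading centres have equal magnitude 1/√L on every factor
with a random sign pattern per cluster (each drug integrates all modelled
pathway axes, so every factor — and hence every planted biomarker gene —
is identifiable from any single drug's response), plus within-cluster
jitter. Responses are value(i,j) = offset_j + u_i·v_j + N(0, 0.3), with
per-cluster potency offsets around a 5.5 pIC50 baseline. Defaults are 200
lines × 100 drugs — large enough for stable panel selection and
train/test splits, small enough that every study runs in about a minute
on one CPU.

Expression: 2000 genes, of which 10 informative genes track single latent
factors with effect size ~1 on the log2 scale over a noise sd of 0.5;
output is exponentiated to TPM so the log2(TPM+1) contract round-trips.
Fingerprints: each cluster owns 8 dedicated bits (set with probability
0.9 in members) whose additive weights sum to the cluster's potency
effect, making fingerprint→activity regression learnable by construction;
remaining bits are random background. Missingness is masked uniformly at
random.

What the generator does *not* emulate: empirical IC50 distributions
(censoring at screen concentration limits, heavy tails), batch effects
between screens, tissue-of-origin structure, correlated missingness, or
realistic gene-gene covariance. Passing synthetic tests therefore shows
the *algorithms* recover signal under the model's own assumptions
(low-rank shared pharmacology), not that the assumptions hold in any
particular public screen.

## Numerical details

- Variances use ddof = 1; medians over survivor variances define the
  variance cutoff, with ties retained.
- Correlation matrices are computed once and mirrored, so they are exactly
  symmetric (pairwise `corrcoef` calls are order-sensitive in the last
  ulp).
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every stochastic operation records its seed, and workflow reruns
  are byte-identical.
- Table round-trips parse with `float_precision="round_trip"` so observed
  values survive write/read bit-identically.
- Degenerate inputs (constant targets, zero-variance genes, <2 observed
  values per sample, empty coverage passes) are either flagged, warned and
  excluded, or hard errors — never silent.

## Known limitations

- Panel selection is greedy; no optimal-design alternative is provided.
- The per-line QSAR quality gate (internal 20% drug holdout, warning below
  r = 0.3) is this package's own device; published workflows report no
  per-line validation to compare against.
- Reproduction of results on the public GDSC/CCLE screens requires those
  datasets as local tables; no download clients are included.
- TreeSHAP here supports regression trees, random forests and gradient
  boosting from scikit-learn only, and runs in pure Python — adequate for
  500-gene forests on panel-sized cohorts, but not tuned for
  genome-wide feature spaces.
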