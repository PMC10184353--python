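# Methods

## The classification model

Tumor transcriptional subtypes are represented as K marker-gene classes
(K = 5 by default, named A–E). The signature is a set of per-class marker
gene lists with no quantitative weights; the union of the lists is the
feature space of every classifier in the package.

### Nearest-template prediction (NTP) and multi-label extension

Expression (CPM) is restricted to the signature space and Z-scored per gene
across the dataset (sample standard deviation, n−1; constant genes map to
all-zero rows — a documented convention, since any finite value would be
arbitrary). Each class has a binary template over the feature space
(markers = 1). A sample's distance to class k is the cosine distance

    d_k = 1 − (x·t_k) / (‖x‖‖t_k‖) ∈ [0, 2],      s_k = 1 − d_k

with d = 1 for an all-zero profile by convention. Significance comes from a
permutation null: templates with the same marker count whose positions are
drawn uniformly at random (without replacement) within the feature space;
the p-value is the ties-inclusive estimator

    p_k = (1 + #{d_null ≤ d_obs}) / (1 + n_perm),    n_perm = 1000 by default,

so p is never zero and is bounded below by 1/(1+n_perm). Within each sample,
the K class p-values are Benjamini–Hochberg adjusted (per-sample scope
matches per-sample classification semantics; a cohort-wide scope is
available via `fdr_scope="cohort"`). The primary class is the minimal-
distance class when its FDR is below the threshold (default 0.2); otherwise
the sample is not classified (NC).

Secondary classes extend the call to a label set: class k ≠ primary is a
secondary class when its FDR is below the threshold **and** its score s_k
reaches the class-specific threshold θ_k, defined as the 5th percentile
(linear interpolation between order statistics; the convention is a
parameter) of s_k over the cohort's primary-k samples. Thresholds are
cohort-specific; classes without primary samples get θ = +∞, disabling
secondary calls for them. Secondary membership is therefore "confident and
at least as strong as the weakest five percent of primary members".

### Numerical determinism

The oracle-exactness tests require bit-reproducible results, so the binary-
template cosine is computed through one canonical op sequence: marker sums
by sequential addition over ascending gene indices (numpy's `cumsum`, which
is exact sequential accumulation), the denominator as a single
`sqrt(‖x‖²·m)` (this keeps d exactly 0 for a template profile), and the
permutation tie count in marker-sum space (`S_null ≥ S_obs`), which is
algebraically equivalent to `d_null ≤ d_obs` and immune to division
round-off. BH adjustment uses stable sorting, `(p·K)/rank`, a backward
running minimum and a clip at 1. Each sample draws its permutations from an
RNG keyed on `(seed, CRC32(sample_id))`, so results are invariant to sample
order and to batch composition.

### Single-sample classifiers and multi-label adaptation

NTP needs a cohort (for Z-scores and for θ). The single-sample path trains
conventional classifiers — linear / polynomial / RBF-kernel SVMs, random
forest, gradient boosting, and a one-hidden-layer neural network — on the
NTP primary classes of a reference cohort, using the signature genes'
log1p(CPM) values as features. No cohort statistics enter the feature map,
so a fitted model classifies one sample in isolation.

Feature transform: log1p is the default. Raw CPM magnitudes (order 10⁴,
heavy-tailed) make the SVM's regularization path degenerate — the selected C
pins to the grid edge and held-out agreement drops measurably — whereas
log-scale expression is the standard representation for margin-based models
in this domain. `log1p=False` restores raw-CPM features.

Training uses a stratified 70/30 split, hyperparameter selection by 10-fold
stratified cross-validation on the training fraction over small fixed grids
(SVM C over 4 log-spaced values; kernel degree 2–3; RBF gamma;
forest feature fractions; boosting rounds; hidden-layer width 16/64), then a
final refit on the whole training set. Multiclass SVM scores are
one-vs-rest decision values; probabilistic models use class probabilities.
Ties in the argmax resolve to the first class in signature order.

The multi-label adaptation (mla) keeps the single-label argmax as primary
and adds class k as secondary when its model score reaches τ_k, the 5th
percentile of score_k over training samples whose reference primary is k —
the same construction as the NTP θ rule transplanted to model scores, with
the percentile and score type configurable. τ is stored with the model, so
prediction needs no cohort. Unlike NTP, the adapted classifier always emits
a primary class; an optional minimum-score cutoff can re-enable NC but is
off by default.

Linear models expose per-class feature rankings by coefficient magnitude
(signed direction reported); collinear duplicated genes split their weight
and appear with attenuated coefficients — a documented caveat.

### Evaluation metrics

Single-label: accuracy, per-class precision/recall/F1, macro-F1, MCC, and
one-vs-rest AUROC/AUPRC when scores are available. Multi-label, over a
K-class universe: relaxed accuracy (reference primary contained in the
predicted set), Hamming loss (|symmetric difference|/K averaged over
samples), subset accuracy (exact set equality), multi-label accuracy (mean
Jaccard; empty vs empty counts 1), and label-ranking average precision
(classes ranked by descending score, ties broken by class order; averaged
over true labels, then over samples with non-empty reference).

### Clinical association

Survival uses the Kaplan–Meier product-limit estimator and the two-group
log-rank test after a horizon recoding: any follow-up time strictly beyond
the horizon (36 months by default) is set to the horizon and censored, so
patients event-free past the horizon count as event-free at the endpoint.

Enrichment uses the exact two-sided Fisher test (point-probability method)
on 2×2 tables built from four cohort constructions per target class:
single-label (primary vs all other primaries); primary-only excluding
secondary carriers from the control group; secondary-only (excluding
primary carriers from both groups); and primary-plus-secondary. Controls
are always samples not assigned to the target class at all; NC samples
enter no group. The sample odds ratio (a·d)/(b·c) gets the Haldane–Anscombe
0.5 correction on all cells when any cell is zero (flagged in the output),
with a log-OR normal-approximation 95% CI. Because "effect size" admits two
framings, both are reported: the in-group positive rate relative to the
overall rate (lift) and relative to the out-group rate (risk ratio). Drug
response dichotomizes as sensitive vs {stable, resistant}; the boundary is
a parameter.

## The synthetic cohort generator

The generator emulates the data regimes the classifier stack is designed
for; its defaults define the study conditions used by the tests and the
acceptance script.

Count model. Each of the 600 genes (5 classes × 40 markers + 400
background) has a log-normal baseline mean (log-mean log 5, log-sd 1). A
cell of class k has its class's markers elevated by `marker_effect = 2.0`
on the natural-log scale (≈ 7.4-fold); per-cell per-gene log-normal noise
of `noise_sd = 1.0` (half the marker effect) multiplies the mean; counts
are Poisson draws thinned binomially by `capture_rate` (0.2 by default,
emulating single-cell dropout; bulk totals remain deep because they sum
cells). Hybrid cells elevate two marker blocks at half effect each — one
interpretable knob for "hybrid phenotype".

Bulk composition. Real cohorts show a continuum of class membership, and
the 5th-percentile secondary threshold is only meaningful over such a
continuum. Each bulk therefore combines:

- a planted design — pure (one class) or, with probability
  `mixture_fraction = 0.5` (about half of samples multi-class, as in real
  tumor cohorts), a two-class cell mixture with minority proportion
  Uniform(0.2, 0.5) (or fixed via `mixture_minority`);
- a diffuse/ambiguous fraction (`diffuse_fraction = 0.2`, Dirichlet α = 3
  composition over all classes) representing tumors with no dominant
  programme; these anchor the weak tail of every class's primary-score
  distribution;
- a per-sample membership leak (up to `membership_leak_max = 0.2`,
  Dirichlet over the non-planted classes) — low-level activity of other
  class programmes;
- a tumor purity drawn Uniform(0.5, 0.95): the remaining cells are
  non-tumor background with baseline expression, emulating stromal
  dilution.

Cells are allocated to classes by deterministic largest-remainder rounding,
so a planted 50/50 mixture is realized exactly; major classes are balanced
across the cohort (shuffled round-robin) so every class accumulates enough
primary samples for a stable threshold. Each bulk is the exact column sum
(pseudo-bulk) of its own generated cells; cell-level truth, composition,
purity and planted classes are all recorded.

Clinical outcomes. Survival times are exponential with hazard
`baseline (1/60 per month) × max hazard ratio over the sample's substantial
composition classes` (membership below 15% of the tumor component does not
count, so leak does not confer risk; the max rule lets secondary membership
carry full risk). Administrative censoring applies beyond 60 months.
Default links: hazard ratio 3 on class B and sensitive-response probability
0.6 on class C versus 0.3 baseline; the remainder of the response mass
splits evenly between stable and resistant.

What the generator does not model: transcriptome-wide covariance, batch and
platform effects, gene length and GC bias, doublets, and any real marker
co-expression structure. Passing recovery tests therefore demonstrate the
internal consistency and statistical behaviour of the pipeline under the
stated generative assumptions, not clinical performance on real cohorts.

## Problem sizes used by the test and acceptance harness

Cohorts of 200 samples × 100 cells (the mixture-recovery experiment uses
400 samples because the per-class 5th-percentile threshold is an order
statistic whose estimate stabilises with cohort size), permutation counts
of 300–1000, ten null cohorts, and fifty clinical cohorts. Oracle
equivalence runs 1000 random instances of at most 20 genes × 8 samples
with up to 200 permutations.

## Degenerate inputs and edge policies

- Missing values in expression input are an error, never imputed.
- A single-sample matrix cannot be Z-scored (error directs to the
  single-sample classifier).
- Zero-total samples cannot be CPM-normalized (error names the sample).
- Deduplication ties break to the lexicographically smaller sample id.
- An all-zero profile is at cosine distance 1 from every template.
- Classes without primary samples get infinite secondary thresholds.
- Fisher tables with an empty margin are an error; zero cells are
  Haldane-corrected and flagged.
- The log-rank test refuses groups with no events anywhere.
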