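# Methods

This document records the statistical model behind each `motifkit` component,
the defaults and their rationale, the scope of the synthetic generator, and
the numerical choices that matter for reproducing results. Formulas use m for
the motif alphabet size, subjects indexed by s, motifs by i, j.

## Data model and assumptions

The unit of observation is a **subject session**: a per-frame integer label
sequence (one motif id per video frame, no gaps) plus, optionally, a pose
track (2-D coordinates for a fixed set of body parts per frame, with a
likelihood per point). Cohort metadata assigns each subject a genotype and a
sex; all group inference assumes subjects are independent and sessions are
long relative to the motif timescale. Label sequences are assumed stationary
within a session for the transition and Markov analyses; the time-course
analyses (time-binned usage, habituation) are exactly the tools for checking
that assumption.

Defaults target 25-fps video, a 30-motif alphabet and 25-minute sessions —
typical sizes for rodent open-field segmentation — but every size is a
parameter.

## Temporal binning

Per-frame labels are reduced to one label per bin by majority vote
(`transitions.bin_labels`), with ties resolved to the earliest-appearing
label in the bin for determinism. The default bin is **16 frames = 640 ms at
25 fps**: long enough that consecutive bins are nearly conditionally
independent given the motif (motif dwell times are a few hundred ms), short
enough that brief motifs still win bins. A final partial bin is kept and
voted like any other. All transition, community, Markov and TDI computations
run on binned sequences; usage percentages run on raw frames (binning would
only quantize them).

## Usage statistics

Usage is frames per motif, reported as frames, seconds and percent of
session. Group comparisons run on **relative usage**: each subject's percent
divided by the mean percent of same-sex baseline-group subjects (baseline
subjects included in their own stratum mean, so the baseline group's expected
relative usage is 1). Sex-stratified normalization removes sex main effects
before genotype testing. Motifs whose stratum baseline mean is zero are
flagged, not divided.

Per-motif tests are two-sided Welch t by default (unequal variances are the
norm for proportions near zero); Mann–Whitney is available. Across the m
motifs, p-values get Benjamini–Hochberg step-up correction:
q_(i) = min_{j≥i} ( m · p_(j) / j ), capped at 1. The implementation is
validated against both the direct definition and an independent library
implementation. Motifs with fewer than two subjects per group or zero
variance in both groups are flagged `degenerate` with p = 1 rather than
excluded — excluding them would silently change m. Significant motifs
optionally get a two-factor (group × sex × interaction) fixed-effects ANOVA
follow-up on absolute usage; saturated designs (no residual degrees of
freedom) are skipped with a warning, never reported with fabricated p-values.

Time-binned occupancy (default 5-minute bins) feeds a repeated-measures
ANOVA (subject as the repeated unit, bin as the within factor) and a
habituation classifier: each control subject's occupancy is regressed on bin
index; the control-group mean slope is tested against zero (one-sample t,
α = 0.05) and a significant negative/positive slope labels the motif
habituating/sensitizing, otherwise flat.

## Transition matrices

Consecutive binned labels are counted into C[i, j] = #(bin t in i, bin t+1
in j); the per-motif denominator u[i] counts bins in i that have a
successor. Two normalizations:

- **dwell-inclusive**: P[i, j] = C[i, j] / u[i]; rows of unvisited motifs
  are zero except P[i, i] = 1 (an absorbing-state convention keeping the
  matrix row-stochastic without inventing transitions).
- **switch-only**: diagonal counts are removed and rows renormalized over
  off-diagonal mass; motifs that only ever self-transition get a zero row,
  flagged. This is the input to communities and delta indices, where dwell
  would otherwise dominate.

Cohort-level matrices pool counts over subjects before normalizing (the
maximum-likelihood pooled estimate; averaging per-subject probabilities
would weight short sessions equally with long ones).

**Top edges**: candidates are nonzero off-diagonal entries; the top
⌈quantile · candidates⌉ by probability are kept, and ties at the cutoff are
all retained (logged) so the selection is deterministic and permutation
invariant. Ordering is by descending probability with lexicographic (source,
target) tie-breaks.

**Per-edge group inference** models each subject's pair (transitions i→j,
bins in i) as binomial with logit link, fixed group effect(s) and a Gaussian
subject random intercept. See *Numerical choices* for the likelihood
evaluation. Edges with zero pooled events are skipped and listed; per-edge
p-values (Wald, on the log odds ratio) are BH-corrected across all tested
edges. If the mixed model fails to converge the edge falls back to a Fisher
exact test on pooled counts and is flagged `fallback_exact`.

## Communities

Bottom-up merging on the pooled switch-only matrix. At every level, for
current nodes a, b with pooled bin-usage U and switch-only probabilities P
recomputed from the *merged counts* at that level:

cost(a, b) = (U_a + U_b) / (P_ab + P_ba)

The cheapest pair merges; ties break to the lexicographically smallest pair.
Pairs with zero mutual probability have infinite cost; when only such pairs
remain, they are merged in lexicographic order with cost recorded as
infinity, so the tree always completes with exactly m − 1 merges. Cutting by
`n_communities = k` undoes the last k − 1 merges; cutting by `cost_height`
keeps exactly the merges with recorded cost ≤ height (union-find semantics —
an infinite-cost merge is never applied by a finite height). Communities are
labeled A, B, … in dendrogram leaf order, which makes labels stable across
reruns. Manual overrides reassign individual motifs after the cut and are
recorded in the assignment's provenance.

The default cut of 10 communities suits a 30-motif alphabet (about three
motifs per community); for other alphabets inspect the merge-cost profile or
cut by height.

## Markov order selection

For order k, the maximum-likelihood transition probabilities are estimated
per subject over contexts of k consecutive labels (order 0 = marginal
frequencies). Model comparison is **leave-one-out cross-validation**: the
held-out subject's sequence is scored under parameters formed as the
*unweighted mean of the other subjects' per-subject estimates* — not the
pooled estimate — so each subject contributes equally regardless of session
length, matching the subject-level inference elsewhere in the package. For
contexts the training subjects never visited, the mean is taken over
subjects that did visit; contexts no training subject visited fall back to
the uniform distribution (counted and reported as `uniform_fallbacks`).
Zero-probability events in the held-out sequence are clamped at ε = 1e-10
(counted as `clamps`), so a single unseen transition costs ≈ −23 nats rather
than −∞.

Orders k, l are compared by the log pseudo Bayes factor
log PBF(k, l) = Σ_s [ LL_k(s) − LL_l(s) ], antisymmetric by construction;
positive favors k. Group differences in sequence predictability are tested
by two-factor ANOVA on per-subject held-out log-likelihoods per order;
saturated designs are skipped with a warning.

Order selection is best run on community-level sequences (10 states) rather
than raw motifs (30 states): order-2 contexts over 30 states (27,000) are
hopelessly sparse at realistic session lengths. Note that lumping motifs
into communities does not preserve the Markov property, so a community
sequence can legitimately prefer a higher order than the motif sequence.

## Delta indices

Per-subject scalar summaries of deviation from the control group. With
control-group elementwise means T̄ (switch-only matrix), Ū (usage percent
vector), S̄ (per-motif speed vector, NaN-mean over controls):

- TDI(s) = mean_|ij| |T_s[i,j] − T̄[i,j]|
- UDI(s) = mean_i |U_s[i] − Ū[i]|
- SDI(s) = mean_i |S_s[i] − S̄[i]|, with a subject's unobserved-motif speeds
  imputed to the baseline (zero deviation, flagged `imputed_speed`) rather
  than dropped, which would change the denominator per subject.

Normalized variants divide by the control group's mean raw index, making the
control mean exactly 1; if that mean is zero, normalization is skipped with
a flag. A `scalar` usage-baseline variant (grand-mean baseline) is provided
as a sensitivity check.

Because control subjects are included in their own baseline, a case group
drawn from the *same* distribution as controls has expected normalized index
≈ sqrt((1 + 1/n) / (1 − 1/n)) (≈ 1.13 at n = 8), not exactly 1 — a
finite-sample coupling effect of the shared baseline, not a bias in the
case group. Interpret small elevations accordingly; the indices are designed
for contrasts (which index moves most), not absolute magnitudes.

## Classification and scalar group tests

Forward-stepwise multinomial logistic regression: at each step the candidate
feature with the smallest likelihood-ratio p enters if p ≤ p_enter (default
0.05); after each entry, included features with removal p > p_remove leave.
Complete separation (log-likelihood → 0) stops the scan and is reported as a
flag with the separating model — resubstitution metrics are meaningless
there and say so. Evaluation is by resubstitution confusion matrix,
per-class sensitivity/specificity (one-vs-rest) and AIC; with small cohorts
this is an upper bound on generalization, which is why the report carries
the step log and AIC rather than a single accuracy number.

Scalar group tests: `two_group` is a two-sided Welch t; `two_factor` is a
fixed-effects ANOVA with factor, sex and interaction. The reported estimate
convention everywhere is `levels[1].mean() − levels[0].mean()` with levels
sorted alphabetically (e.g. WT − MUT for genotypes MUT/WT).

## Kinematics

Egocentric alignment is a rigid per-frame transform: translate the center
part to the origin, rotate the center→axis-part vector onto the negative
y-axis. Rigidity (pairwise distances preserved to machine precision) and
idempotence are tested properties. Frames missing either reference part
become fully missing rather than partially transformed. Allocentric speed is
|frame-to-frame displacement| · fps / scale, NaN at the first frame and next
to missing coordinates. Per-motif profiles average egocentric posture and
speed over post-onset windows (default 10 frames = 400 ms), onset defined as
any label change; unseen motifs appear with n_frames = 0 and missing means.

## Synthetic generator: scope and limits

The generator draws motif sequences from a per-subject first-order Markov
chain at the bin level, with a block-structured transition matrix (default
10 blocks of 3 motifs: high self-dwell, strong within-block switching, weak
between-block leakage) and expands each bin to 16 identical frames. Pose
tracks place a 5-part skeleton on a smooth random-walk trajectory whose
center speed matches a per-motif mean. Genotype and sex effects perturb
dwell, block structure, usage and speed multiplicatively; exact per-subject
truth (transition matrix, stationary usage, speeds) is returned for
validation.

Limits, by design: frames within a bin are perfectly correlated (real
segmentations switch mid-bin); dwell times are geometric; pose noise is
isotropic Gaussian; there is no session nonstationarity unless effects are
configured per time bin. The generator exists to give estimators known
answers, not to imitate any particular dataset.

## Numerical choices

**Binomial random-intercept likelihood — adaptive Gauss–Hermite
quadrature.** The marginal likelihood per subject integrates the binomial
likelihood over the Gaussian random intercept. Non-adaptive quadrature
places nodes where the *prior* has mass; with hundreds to thousands of
binomial trials the integrand is far narrower than the prior, the node grid
straddles it, and the likelihood surface acquires spurious optima. We
therefore recenter per subject: a Newton iteration finds the posterior mode
of h(z) = loglik(η + σ_u z) − z²/2, nodes are scaled by
1/sqrt(σ_u²·n·μ(1−μ) + 1) (the Laplace curvature) and the 25-point
Gauss–Hermite sum is evaluated in log space (logsumexp). Optimization uses
L-BFGS-B (BFGS's line search reports spurious precision-loss failures on
this surface; the optima agree). The implementation is validated against an
independent adaptive-quadrature mixed-model implementation (R `lme4::glmer`,
nAGQ = 25) to ~6 significant figures on fixed effects, standard errors and
the random-intercept standard deviation.

**BH step-up** is implemented directly (sorted p, running minimum from the
largest rank) and cross-validated against an independent implementation and
the definition on random inputs.

**Transition-matrix recovery metric.** Estimator accuracy is tracked as the
maximum over rows of the *mean* absolute per-entry error,
max_i ( Σ_j |P̂[i,j] − P[i,j]| / m ): a per-row, per-entry scale makes the
tolerance independent of alphabet size. At 30,000 bins the observed value is
≈ 0.005 against generator truth; the acceptance suite requires ≤ 0.02.

**Determinism.** All randomness flows through `numpy.random.SeedSequence`
with explicit spawn keys per subject and per stage, so any component can be
rerun in isolation with identical results. Every sort that affects output
has a total tie-break (lexicographic on ids/indices). Pipeline outputs are
hashed (SHA-256) into the manifest; two runs with the same config and seed
are byte-identical.

**ε = 1e-10 likelihood clamp** (Markov LOOCV): large enough to avoid -inf
and float underflow in sums over thousands of steps, small enough (−23 nats)
that a clamped event always dominates a model comparison in the right
direction; clamp counts are reported so heavy clamping is visible.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| fps | 25 | common acquisition rate; all timings derive from it |
| bin_frames | 16 (640 ms) | ≈ motif dwell timescale; see *Temporal binning* |
| n_motifs | 30 | typical segmentation alphabet |
| n_communities | 10 | ~3 motifs per community at m = 30 |
| time-course bin | 5 min | 5 bins per 25-min session, enough for slopes |
| α (all tests) | 0.05 | conventional; BH-adjusted where families exist |
| GH nodes | 25 | adaptive recentring makes more nodes redundant |
| LOOCV ε | 1e-10 | see *Numerical choices* |
| stepwise p_enter / p_remove | 0.05 / 0.05 | symmetric, conservative |
| top-edge quantile | 0.2 | sparse enough to read as a network |
| profile window | 10 frames (400 ms) | onset-locked posture before drift |

Every default is overridable at the function or config level.
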