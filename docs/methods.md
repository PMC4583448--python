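# Methods

## The voting model

Let X ∈ ℝ^{m×n} hold log-z-normalized concentrations of m biomarkers for n
subjects with clinical labels λ(k) ∈ {−1 (gingivitis), +1 (periodontitis)}.
One realization r draws a uniform permutation of the n subjects and cuts it
into disjoint test windows of size k₁ (a single remainder window of size
n mod k₁ when k₁ ∤ n). For each window, each unordered marker pair (i, j),
i < j, trains a fresh two-class base classifier on the complement and votes
on every window subject. Votes accumulate in υᵍ(r,k) and υᵖ(r,k) with
υᵍ + υᵖ = m(m−1)/2 for every (r,k) — an invariant asserted after every
realization — and the voting pairs are recorded in ensemble sets σᵍ(r,k),
σᵖ(r,k).

Per-realization labels are λ*(r,k) = sign(υᵖ − υᵍ) with 0 encoding a tie
(possible whenever m(m−1)/2 is even). After N_b realizations:

- proclivity: G_votes(k) = Σᵣ υᵍ(r,k) / (N_b·m(m−1)/2), similarly P_votes;
  each is one integer-sum division, so the pair sums to 1 exactly in
  rational arithmetic (and, empirically, as IEEE doubles);
- aggregate label: sign(P_votes − G_votes), equivalently the sign of the
  total vote difference. This makes "aggregate = −1 ⟺ G_votes > P_votes"
  hold by construction; it can differ from a per-realization-majority
  aggregate only in contrived split-vote configurations;
- persistent sets: σᵍ*(k) = ∩ᵣ σᵍ(r,k), σᵖ*(k) = ∩ᵣ σᵖ(r,k). A pair that
  ever flips belongs to neither.

The consensus map assigns each subject the persistent set of its own
clinical class (σᵍ* for gingivitis-labelled subjects, σᵖ* for
periodontitis-labelled ones) and counts shared pairs:
τ(i,j) = |set(i) ∩ set(j)|. This single rule reproduces the within-group
definitions and the between-group definition (σᵍ* of the gingivitis subject
intersected with σᵖ* of the periodontitis subject) simultaneously.
Consequence worth stating: on an easily separable cohort all own-class
persistent sets are full, so the G×P block is uniformly *bright*, not dark;
between-group darkness appears only when subjects' persistent sets are
depleted or discordant. Diagonal cells hold |set(k)| for display and are
excluded from statistics. A `consistency_fraction` parameter can relax the
strict intersection (a pair qualifying in ≥ that fraction of realizations);
the default 1.0 keeps the strict definition.

## Base classifiers

All four are scikit-learn estimators behind a uniform train/predict
contract; the contract, not the backend, is normative, and brute-force
density oracles in the test suite enforce it.

| kind | backend | notes |
|------|---------|-------|
| lda  | `LinearDiscriminantAnalysis(solver="svd")` | pooled covariance, priors from fold proportions |
| qda  | `QuadraticDiscriminantAnalysis(reg_param=1e-4)` | shrinkage escalated ×10 (≤ 1) on a singular covariance |
| nb   | `GaussianNB(var_smoothing=1e-9)` | relative variance floor, preserving scale equivariance |
| svm  | `SVC(kernel="linear", C=1)` | minimal kernel choice for 2-D pair folds; C exposed |

Ties at the decision boundary (equal posteriors, SVM score exactly 0)
predict +1, a fixed measure-zero convention required for determinism.
Predictions for LDA/QDA/SVM go through the signed decision function and for
NB through the log-posterior difference, so the tie rule is applied
uniformly. Training folds must contain ≥ 2 subjects of each class; a
degenerate fold aborts the realization, which is redrawn with a fresh
permutation (capped at 100 redraws, each logged). At the default 40/40 with
k₁ = 10 a degenerate fold is impossible; tiny synthetic cohorts can hit it.

LDA/QDA/NB predictions are equivariant under per-feature affine rescaling;
the SVM with fixed C is not (margins scale), which is documented rather than
patched.

## Preprocessing

Markers are natural-log-transformed and z-scored (sample SD, n−1
denominator) over all n subjects *before* the cross-validation loop, i.e.
globally. This follows the stated procedure in which normalization precedes
the voting loop; it leaks held-out subjects' first and second moments into
training. With n = 80 the effect is small, but results should be read as
in-cohort scores, not out-of-sample estimates. Boundary clinical
presentations (e.g. exactly 10% of sites with pocket depth ≥ 4 mm) satisfy
neither case definition and are excluded as indeterminate with a logged
reason, never coerced.

## Evaluation

Accuracy, sensitivity and specificity treat periodontitis (+1) as the
positive class (a documented, configurable orientation) and are computed per
realization, then reported as mean ± SD over the N_b realizations. Tie
labels are resolved to ±1 with probability ½ (seed-controlled) before
metric computation only. Mismatch samples are those whose λ*(r,k)
contradicts the clinical label in a strict majority of realizations, with
tie realizations excluded from both sides of the comparison — ties carry no
directional evidence. The traditional baseline runs one classifier on all m
markers under the identical fold-drawing scheme, so with m = 2 it coincides
with the lone pair classifier — an equivalence the tests exploit as an
oracle.

## Synthetic cohorts

The generator emulates a two-group cohort (default 40/40) whose marker
marginals are log-normal, moment-matched to the published group summaries
(gingivitis IL-1β 29.6 ± 49.5, IL-6 3.9 ± 5.9, MMP-8 208.2 ± 194.2, MIP-1α
10.9 ± 14.5; periodontitis 157.6 ± 217, 12.1 ± 10.2, 397.9 ± 302.1,
24.4 ± 29.8, assay units) via σ² = ln(1 + S²/M²), μ = ln M − σ²/2. The
log-normal family is chosen because the real profiles are strictly
positive, strongly right-skewed, have SDs that can exceed the mean, and are
log-transformed downstream; a gamma marginal (shape M²/S², scale S²/M,
drawn through a Gaussian copula) is available behind the `marginal` flag as
an alternative skewed family. Between-marker correlation defaults to the
identity since no covariance information is published; a positive-definite
log-scale correlation matrix can be supplied so that heterogeneity
experiments are not artificially easy. Planted swaps draw a configurable
fraction of each group (0.2 mirrors the reported ~20% heterogeneous
subpopulation) from the opposite group's distribution while keeping the
nominal clinical label, providing ground truth for mismatch recovery.
Optional BOP/PPD/CAL columns are drawn uniformly inside the nominal label's
defining region, solely to exercise clinical labelling.

What the generator does *not* emulate: real between-marker dependence,
covariate structure (age, smoking), assay floor/ceiling effects, or any
within-group substructure beyond the planted swaps. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
structure under the stated distributional assumptions — not clinical
performance on real saliva panels.

## Numerical and design choices

- RNG: `numpy.random.default_rng` seeded once per run; the permutation
  stream and tie resolution derive from recorded seeds, making every output
  bit-reproducible. The pipeline derives one child seed per (classifier,
  mode) stage from the master seed in a fixed order.
- Pair enumeration is lexicographic (i < j); order cannot affect tallies but
  fixes ensemble-set serialization.
- Natural log base (any base cancels in z-scores); sample SD with n−1
  denominator; both fixed so intermediates are bit-comparable.
- Fold-size sanity: k₁ > n/4 only triggers a warning, since the scheme
  presumes a dominant training side but small demonstration cohorts are
  legitimate.
- Heatmap colour scale is linear in τ from 0 to m(m−1)/2 so renders are
  comparable across classifier kinds; only the upper triangle is drawn
  (τ is symmetric), gingivitis subjects first.
- Problem sizes in the test suite are scaled to keep the default run fast:
  property sweeps use N_b = 20 on cohorts up to n = 80, m = 6; recovery and
  comparability checks use N_b = 100 on 40/40 cohorts; the shipped pipeline
  default remains N_b = 1000.

## Limitations

- Strict persistent-set intersection can empty σ*(k) for borderline
  subjects at large N_b; the relaxation knob exists but defaults off.
- The SD-recovery check relies on a large-sample normal approximation to
  the sampling variance of a log-normal SD (via its kurtosis), which is
  heavy-tailed; at n = 10⁵ the approximation is adequate.
- Mismatch detection is defined relative to clinical labels assumed as
  ground truth; with real data the interpretation is heterogeneity, and no
  causal or prognostic claim follows from the machinery itself.
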