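# Methods

## The estimand

For a two-arm randomized trial with outcome `Y` (of arbitrary structure)
and a pre-specified pairwise win/loss/tie rule, the marginal
probabilistic index (MPI) is

    nu = P(Y_ctrl ≺ Y_trt) + ½ P(Y_ctrl ≍ Y_trt),

the probability that a randomly drawn treated subject beats a randomly
drawn control subject, counting ties as half a win. The win odds is its
odds transform, theta = nu / (1 − nu), equal to
(#wins + ½#ties) / (#losses + ½#ties) in expectation, and to the net
benefit Delta = P(win) − P(loss) through theta = (1 + Delta)/(1 − Delta).
theta > 1 favors treatment. No model assumptions enter the estimand: it
is defined directly by the comparison rule and the trial population.

## The hierarchical comparison rule

The built-in rule compares composite time-to-event outcomes in two
layers. Layer 1 (death): the subject whose death occurs later — or who
is known to be alive beyond the other's death — wins; a death is
decidable only against follow-up extending *strictly* beyond it, so
a death occurring after the other subject's censoring time, and equal
death times, fall through. Layer 2 (first nonfatal event): over the
shared window tau = min of the two terminal times, the later (or absent)
first nonfatal event wins; events at or beyond tau, and equal event
times, tie. All inequalities are strict; with continuous event times the
boundary cases have probability zero, and with discrete times the
conventions above (fall-through on equal deaths, ties on equal nonfatal
times) are the deliberate, documented choices. Any user-supplied rule
with the antisymmetry contract `rule(a,b) = −rule(b,a)`, `rule(a,a) = 0`
is accepted; user rules are evaluated in both orders and a violation
raises an error rather than silently producing an asymmetric matrix.

## Estimation

**Direct.** nu-hat is the average of the pairwise win scores
S_ij ∈ {0, ½, 1} over all (control i, treated j) pairs. The net benefit
Delta-hat is a two-sample U-statistic with kernel in {+1, 0, −1}; its
variance is estimated by the usual projection components (sample
variances of per-subject kernel row/column means), and
se(nu-hat) = se(Delta-hat)/2.

**Adjusted.** A probabilistic index model (PIM) with logit link models
the conditional probabilistic index on pairwise differences:

    P(i ≼ j | A, X) = expit(tau_A (A_j − A_i) + tau_X' (X_j − X_i)).

Coefficients solve the logistic-type estimating equations over all
n(n−1) ordered pairs with the fractional scores as responses (ties enter
as ½ directly; no randomization). The adjusted MPI is obtained either by
standardization — averaging the fitted index at arms (0, 1) over all
covariate pairs — or by augmentation — adding to nu-hat-direct a
weighted sum of the fitted index whose weights sum to zero, so that any
*fixed* pair function leaves the estimator consistent and only the
variance changes. Under the logit link and these estimating equations
the two forms are algebraically identical; the implementation computes
both and asserts agreement to 1e-8 as a numerical invariant.
Misspecification of the PIM therefore costs efficiency, never validity.
With an empty adjustment set the equations solve in closed form,
tau_A = logit(nu-hat-direct), and the adjusted estimate collapses
exactly to the direct one.

**Fitting.** Fisher scoring from beta = 0. Because every design row is a
difference of subject-level rows z_k = (A_k, X_k'), the pairwise score
reduces to Z'(colsum − rowsum) of the residual matrix and the expected
information to weighted outer-product sums, giving O(n² p) time and
O(n² + np) memory per iteration without materializing the n(n−1) design.
This reduction makes a separate streaming/row-block mode unnecessary:
the n×n score matrix is the binding memory term (≈0.8 GB at n = 10 000),
comfortably inside modern trial scales. Convergence when the largest
absolute score component is ≤ 1e-8 or the Newton step norm ≤ 1e-10, cap
100 iterations; a coefficient magnitude above 30 raises a separation
error, and a rank-deficient pair-difference design (constant or
collinear covariate columns) is rejected with an explicit error rather
than silently dropped.

**Variance.** The adjusted estimator is an average over ordered pairs of
the kernel h_ij = (1−A_i) A_j (S_ij − H_ij)/(p̂₀ p̂₁) + H_ij with H the
fitted conditional index; its variance is estimated by the Hájek
projection, (4/n) × sample variance of the per-subject projections
g_k = mean over j≠k of (h_kj + h_jk)/2. Estimation of the PIM
coefficients is first-order ignorable for this variance because the
augmentation term is mean-zero for any fixed H. Checks: at p = 0 the
projection SE matches the direct U-statistic SE (relative difference
2.5e-4 at n = 2000), and on simulated trials at n = 500 it agrees with a
500-resample within-arm subject bootstrap to about 2% on average. The
bootstrap (resampling controls and treated separately, refitting the PIM
per resample) is exposed as an alternative variance method.

**Inference.** Wald test of H0: nu = ½ (equivalently theta = 1) on the
nu scale; the (1−alpha) interval nu-hat ± z_{1−alpha/2} se is mapped
through the monotone nu ↦ nu/(1−nu) to theta. Delta-method results on
the log-theta scale (se_logtheta = se_nu / (nu(1−nu))) are reported
alongside; the two tests differ slightly in finite samples and both are
labeled in the output, with the nu-scale test primary. Defaults:
alpha = 0.05 two-sided, 0.025 one-sided. At nu-hat ∈ {0, 1} a boundary
flag is set and no interval is produced; zero estimated variance away
from ½ raises a degenerate-data error.

## Simulation design

Per subject: X_1..X_10 iid N(0,1), A ~ Bernoulli(½), and latent times
T_k = 7500 · exp(0.3·A + gamma'X) · E_k with E_k iid Exponential(1) for
death (k = 1) and first nonfatal event (k = 2) — proportional-hazards
models sharing one linear predictor. Defaults: effect 0.3 (log scale,
treatment delays events), scale 7500 study-time units, n ∈ 500–1500,
allocation ½. Censoring: C is the within-dataset empirical 0.35-quantile
(the ⌈qn⌉-th order statistic, type-1 convention) of min(T1, T2), so the
targeted 35% of subjects have at least one observed event; the strict
observation rule I(T < C) leaves ⌈qn⌉ − 1 subjects with an event —
at n = 2000 this is 699 subjects, 34.95%. Observed outcome:
(min(T1,C), min(T2,T1,C), I(T1<C), I(T2<min(T1,C))) — the semi-competing
structure in which death truncates the nonfatal event but not
conversely.

Scenario coefficient vectors (all unit-normed, so gamma'X ~ N(0,1) and
the marginal outcome law is scenario-invariant): A — equal influence
1/√10; B — linearly decaying 1−(j−1)/10, normalized; C — 1/j² for j ≤ 5
and 0 beyond, normalized. The normalization to Σgamma² = 1 is what makes
the scenarios comparable; it is asserted exactly in the tests.

**Null construction.** "Treatment flip" redraws A ~ Bernoulli(allocation)
independently of outcomes and covariates, severing the
treatment–outcome association while preserving outcome marginals; a
permutation mode (shuffling the existing labels) is available behind a
flag since either reading of "randomly flip" is defensible.

**Operating characteristics.** The runner estimates rejection rates of
the one-sided H0: theta ≤ 1 at alpha = 0.025 over replicated datasets.
All analysis methods are applied to the *same* datasets (paired design),
so method contrasts share the data's Monte-Carlo noise; per-replication
seeds derive from (master seed, replication index) via SeedSequence, so
results are independent of execution order. Analysis failures are
counted and excluded from that method's denominator, never silently
dropped. Default replication count is 1000 — enough to place a type I
error rate within ±1pp and resolve multi-point power differences — with
the count exposed for larger runs.

## What the generator does and does not emulate

It reproduces the qualitative anatomy of cardiovascular outcome trials —
a hierarchical death/nonfatal composite, administrative censoring at a
common event-fraction target, prognostic baseline covariates of varying
concentration — with everything conditionally exponential and all
covariates Gaussian and independent. It does not emulate covariate
imbalance (randomization is exact in distribution), informative or
subject-specific censoring, discrete/tied event times, non-proportional
hazards, or correlated/categorical covariates. Passing operating
characteristics here therefore demonstrate calibration and efficiency
gains *under a correctly specified prognostic structure*; on real data
the gain depends entirely on how prognostic the adjustment covariates
are, and can be nil.

## Numerical and design notes

- Monte-Carlo suite sizes: variance-vs-bootstrap uses 20 trials × 500
  resamples at n = 500; calibration and power use 1000 replications at
  n ≤ 1000. These place every check's MC error well below its assertion
  margin except one documented case: the power gain from adjusting X1
  alone in the equal-influence scenario is ≈0.8pp (X1 carries one tenth
  of the prognostic variance, shrinking the SE by under 2%), below the
  ≈1.3pp paired-MC resolution of 1000 replications, so the strict
  ordering assertion adjust-X1 > unadjusted can fail at this replication
  count even though the ordering holds in expectation. The assertion is
  kept strict rather than weakened; resolving it requires on the order
  of 10 000 replications.
- Equivalence of power between adjustment sets (concentrated scenario)
  is judged against twice the binomial MC standard error of a rate
  difference — the resolution of the experiment — not against the paired
  SE, under which any nonzero-but-negligible true difference would fail
  for large replication counts.
- Categorical covariates must arrive pre-encoded as 0/1 indicators, and
  missing covariate values are rejected (complete-case input expected);
  times carry whatever unit the input uses.
- CSV round-trips are exact: times are written at full precision and
  read with round-trip float parsing.
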