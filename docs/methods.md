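# Methods

## Model and procedure

For a pathway of m genes with expression X = (X¹, …, Xᵐ)′ and
right-censored follow-up (T = min(U, V), Δ = I(U ≤ V)), the package
assumes the Cox proportional-hazards model λ(u|X) = λ₀(u) exp(β′X).
"Predictive power" means that β′X separates patients into groups with
different survival risk **on data not used to estimate β**. Model-fit
criteria evaluated in-sample are biased for this purpose when m is
comparable to n, which is the norm for pathway-level genomics (cohorts
of 58–98 samples against pathways of up to ~50 genes).

Estimation minimizes the scaled objective

    f(β) = −ℓ(β)/n + λ Σⱼ |βⱼ|^γ,   0 < γ < 1,

where ℓ is the Breslow-tie log partial likelihood. The concave (bridge)
penalty produces exact zeros, so noisy genes inside a genuinely
predictive pathway are excluded from the risk score. γ is fixed at 1/2;
the machinery accepts any γ ∈ (0, 1) but only γ = 1/2 has a closed-form
scalar update (below). Dividing ℓ by n makes λ grids transfer across
sample sizes.

Per study and pathway, the predictive index is built from B random
partitions (train fraction 2/3, rounded half toward the training set):

* **OPI**: fit β on the training set with λ chosen by 3-fold
  cross-validated partial likelihood (Verweij–van Houwelingen:
  ℓ_full(β₋f) − ℓ_train(β₋f), folds stratified by event status), score
  the test set with β′X, split at the median score (scores equal to the
  median go to the low-risk group), and record the squared standardized
  two-sample logrank statistic U²/V (hypergeometric observed-minus-
  expected increments, tied event times pooled).
* **PPI**: identical, except (time, event) pairs are jointly permuted
  across samples before each partition, decoupling expression from
  outcome. Permutation per partition (rather than one permutation per
  PPI vector) was chosen after measuring both: the per-vector variant
  has visibly worse null behaviour (excess mass of p-values near 1).

The study-level p-value is the one-sided Wilcoxon rank-sum test of OPI
versus PPI ("OPI stochastically greater"); only larger logrank
statistics can indicate predictive power, so a one-sided alternative is
the natural default (a config flag restores the two-sided test). Exact
enumeration is used for tie-free vectors shorter than 20, otherwise the
tie-corrected normal approximation.

Across D studies, Fisher's statistic s = −2 Σ log p_d is referred to
χ²(2D). Across N pathways, the step-up rule selects the r smallest
meta p-values where r is the largest i with p₍ᵢ₎ ≤ i·q/(N·c(N)).
Under the `overlap` correction, c(N) = Σᵢ₌₁ᴺ 1/i — the dependence-
robust inflation appropriate because overlapping pathways share genes
and their p-values correlate arbitrarily. (The source analysis states
c(N) only via its citation to the dependence-robust FDR literature; the
harmonic-sum form is that literature's standard constant and is the
reading implemented here.) `independence` (c = 1) recovers the plain
Benjamini–Hochberg rule. Default q = 0.2.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| B | 100 | partitions per index; reduce (10–25) for simulation studies |
| train_fraction | 2/3 | training share of each partition |
| cv_folds | 3 | folds for λ selection |
| γ | 1/2 | bridge exponent (closed-form update) |
| n_lambda | 25 | log-spaced λ grid points |
| λ grid range | [0.01, 0.95]·λ_max | see below |
| q | 0.2 | target FDR |
| correction | overlap | harmonic c(N) |
| knn k | 10 | imputation neighbours |

The CV grid offered to the resampling engine starts at 0.95·λ_max, not
λ_max. At λ ≥ λ_max the fit is exactly β = 0, which yields constant risk
scores and hence no test statistic; such partitions are discarded and
redrawn. Offering the no-information model to CV therefore only burns
the redraw budget (under a null pathway CV picks it most of the time,
and the 10·B redraw cap can be exhausted). Excluding it changes nothing
for predictive pathways and keeps null pathways computable; OPI and PPI
receive identical treatment, so the null comparison stays symmetric.
`default_lambda_grid` itself still defaults to the full [0.01, 1]·λ_max
range.

## Optimization

λ_max has a closed form: coordinate j stays at zero iff
λ ≥ aⱼ·b*^(1−γ)(zⱼ − b*)/γ with zⱼ = |gⱼ|/aⱼ from the gradient g and
curvature a of f at β = 0, and b* = 2z(1−γ)/(2−γ); λ_max is the max
over j (inflated by a 1e-9 relative nudge so the zero solution wins the
exact tie at λ = λ_max).

Fitting is IRLS with coordinate descent: an outer loop forms the
diagonal-Hessian quadratic expansion of the partial likelihood at the
current linear predictor; an inner loop cycles coordinates, each solved
exactly by the scalar bridge operator
argmin_b ½a(b − z)² + λ|b|^γ. For γ = 1/2 the nonzero candidate is the
largest root of a depressed cubic (trigonometric solution); for other γ
a bisection on the stationarity condition. The operator was verified
against brute-force scalar minimization over randomized (z, a, λ, γ).
Safeguards: step-halving keeps the true penalized objective
non-increasing (the quadratic model is only local and the penalty is
nonconvex); coefficients are clamped to [−100, 100] against divergence
under quasi-separation (relevant for pathways larger than the training
event count); risk-set sums are floored at 1e-150 before reciprocals so
extreme linear predictors cannot underflow them to zero. Convergence:
max coordinate change < 1e-7, at most 200 outer iterations;
non-convergence is reported, never raised. λ paths are warm-started
from the previous solution. Coefficients below 1e-10 are declared zero.
Kernels are numba-compiled; the identical code runs un-jitted if numba
is absent.

Degenerate partitions — a train or test set without events, β̂ = 0,
an empty median split, or zero logrank variance — are redrawn with
fresh sub-seeds up to 10·B attempts (then an error naming the pathway);
the count is reported per pathway and study. Seeding: partition b of
pathway P uses a child stream derived from (seed, CRC32(P), OPI/PPI
flag, attempt), so results are independent of execution order and of
Python's randomized string hashing, and the whole pipeline is
byte-reproducible from (inputs, config, seed).

## Preprocessing

Each study separately: k-nearest-neighbour imputation (neighbours are
genes; distance is Euclidean over mutually observed samples scaled by
the shared-sample count; a missing value is the unweighted mean of the
k nearest genes' values at that sample — delegated to scikit-learn's
KNNImputer, whose nan-Euclidean metric induces the same neighbour
ordering), then per-gene normalization to zero median and unit unbiased
(n−1) sample variance. Studies are then restricted to the genes
measured in all of them (exact identifier match; identifier-system
conversion is upstream), and pathways are intersected with that set,
dropping pathways that become empty. Formats: genes×samples TSV with a
header row of sample ids, survival TSV (sample_id, time, event), and
standard GMT; readers tolerate CRLF and trailing whitespace, and the
missing-value token set {NA, NaN, ""} is configurable.

## Synthetic data

The generator emulates a multi-study prognosis meta-analysis. Defaults:
four cohorts of 58/78/71/98 samples (typical published breast-cancer
prognosis cohort sizes), 150 genes per study of which 80% form a shared
core, ten pathways with sizes 2–20 (median 7, echoing small curated
pathway collections), three predictive pathways each carried by two
genes at log-hazard ±1 (alternating signs so the joint effect is not a
single-direction average), exchangeable within-pathway correlation 0.3,
and 30% censoring — a moderate level common in methodological survival
simulations. Expression is multivariate normal (block-exchangeable
within pathways, independent across); event times follow the Cox model
with exponential(1) baseline hazard; censoring is independent
exponential with the rate solved by bisection against the target
censoring fraction computed by Gauss–Hermite quadrature over the
analytic marginal of β′X.

What it does not emulate: platform-specific array noise, heavy-tailed
or skewed expression, batch effects, gene-level missingness structure,
or pathway overlap (synthetic pathways are disjoint, so the harmonic
c(N) correction is exercised as a conservative procedure, not validated
against genuinely overlapping dependence). Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated generative
model, not performance on real microarray data.

## Calibration: a known limitation

The Wilcoxon separation p-value is approximate. The B statistics inside
one index are dependent — partitions overlap and, for the OPI, all use
the one observed outcome coupling — which violates the rank-sum test's
independence assumption. Measured over 400 independent null replicates
(n = 100, m = 8, B = 25), the p-value distribution is mildly U-shaped:
about 8% of null p-values fall below 0.05 and 8% above 0.95. The effect
grows with B (more partitions estimate the dataset-conditional level
more precisely) and shrinks as n grows. Practically the method is used
as a ranking-plus-FDR screen, and the FDR stage's harmonic correction
absorbs the overdispersion in the mixtures tested here (empirical
false-discovery proportion ≈ 0.1 at q = 0.2), but individual p-values
near conventional thresholds should not be over-read.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run at n ≤ 200, m ≤ 5 (penalized Cox vs an
unpenalized reference at λ = 0, tolerance 1e-4 per coordinate) and 100
random instances of n ≤ 30 (logrank vs an established implementation,
1e-8). Null calibration uses 200 replicates at n = 100, m = 8, B = 25;
power uses 25 replicates at n = 200 with 2 of 10 genes at effect 1;
false-discovery control uses 20 replicates of a 100-pathway (20 signal)
two-study mixture at n = 150 per study with B = 10 and size-5 pathways
— sizes chosen so the full suite completes in minutes on one CPU while
each check retains statistical resolution.

## Nonparametric evaluation

`clustereval` implements the comparison harness: two-cluster K-means on
a pathway's (already normalized) expression, the two-group logrank
p-value per study, Fisher pooling, and a Wilcoxon comparison of pooled
p-values between two pathway groups (e.g. identified vs not). K-means
uses ten restarts from a fixed seed, keeping the best within-cluster
sum of squares, so results are deterministic; clustering uses all genes
in the pathway, noisy ones included, which makes this evaluation less
efficient than the penalized detector — it is a referee, not a
detection method.

## Non-goals

Efron tie handling (Breslow only), other penalties (lasso/SCAD/MCP),
stratified or time-varying Cox models, multi-sample or supremum logrank
variants, alternative meta-analysis poolers (Stouffer, weighted
Fisher), raw-array normalization, probe summarization, and gene
identifier conversion.
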