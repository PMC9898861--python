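# Methods

This note documents the statistical models implemented in `symptomnet`,
the choices made where conventions diverge, and what the synthetic-data
generator does and does not emulate.

## Data model

The unit of analysis is a panel of n persons answering p symptom items
(by default the nine PGSI problem-gambling items, scored 0–3) at one or
two waves. The PGSI total is the sum of the nine ordinal items (0–27)
and maps onto the usual risk bands: 0 = non-problematic, 1–2 = low
risk, 3–7 = moderate risk, 8+ = severe problem gambling. Because item
endorsement is rare in community samples, network analyses run on
dichotomized items (0 = never, 1 = at least sometimes). Analysis stages
require complete cases; readers flag incomplete rows and
`complete_cases()` drops them with a logged count. No imputation or
survey weighting is attempted.

## Cross-sectional network: Ising model via node-wise EBIC-LASSO

Dichotomized symptoms are modelled as a pairwise Markov random field on
{0,1}^p with thresholds τ and symmetric couplings W:

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} W_ij x_i x_j ).

With {0,1} coding, the conditional of node i given the rest is a
logistic regression whose slopes are exactly the couplings W_i·, so the
network is estimated by p node-wise L1-penalized logistic regressions:

    min  −ℓ(y_i | β_0 + X_{−i} β) + λ n ‖β‖₁,

solved along a 100-point log-spaced grid from λ_max (the smallest λ
with an all-zero solution, computed from the score at the
intercept-only fit) down to 10⁻³ λ_max. Per node, the penalty is chosen
by the extended BIC,

    EBIC(λ) = −2ℓ + k log n + 2 γ k log(p − 1),

with γ = 0.25; ties resolve to the larger λ (the sparser model), in
line with the goal of parsimonious networks. Edges are assembled under
the AND rule — W_ij ≠ 0 only if both directed coefficients are
non-zero — and the retained edge weight is the arithmetic mean of the
two coefficients, the convention of the estimation literature this
procedure comes from (the combination rule is not standardized; OR-rule
assembly is available behind a flag). Predictors are not standardized:
they are binary and the coefficients are interpreted directly as
couplings on the log-odds scale.

Degenerate nodes (all 0 or all 1, likely for ~5%-prevalence symptoms at
n ≈ 335) are kept in the network with zero edges and a warning rather
than aborting the fit.

### Solver

The L1 path is fit by coordinate descent on an IRLS quadratic
approximation with warm starts along the λ grid, the standard sparse-GLM
algorithm. Two numerically identical kernels exist: a dense one, and a
sparse-column kernel for 0/1 predictors that sums gradients over the
one-entries only and carries intercept updates as a scalar residual
offset (the bootstrap and permutation procedures below fit on the order
of 10⁵ penalized paths, so per-path cost matters). Standardized fitting
on binary predictors is implemented exactly, via the equivalence between
the z-scored lasso problem and a raw-binary lasso with per-feature
penalty λ·sd_j. Fitted probabilities inside IRLS are clamped to
[10⁻⁵, 1−10⁻⁵]; the convergence tolerance on coefficient updates is
10⁻⁹ by default, giving KKT stationarity violations below 10⁻⁶
(tested); coefficients below 10⁻¹² in absolute value are snapped to
zero to remove floating-point residue from exact soft-threshold ties at
λ_max. Solutions agree with an independent convex solve (split-sign
L-BFGS-B) to 10⁻⁴ and with unpenalized ML at λ → 0.

## Centrality

For the undirected network: strength is Σ_j |W_ij|; path-based indices
use edge length 1/|W_ij| (the standard transform for psychological
networks — the choice is recorded in output metadata since nothing in
the estimand forces it). Closeness defaults to the inverse-of-summed-
distances form, matching the software convention of the applied
literature, even though verbal definitions often describe the harmonic
(sum-of-inverse-distances) form; both are implemented and the variant
is flagged in every output table. In sparse networks where components
break apart, inverse-sum closeness sums over the node's reachable
component only (keeping the index finite) and isolated nodes get 0.
Betweenness counts, per unordered pair of other nodes, the fraction of
shortest paths through the node, unnormalized. For the directed
network, out-/in-strength are row/column sums of |B| excluding the
autoregressive diagonal by default (configurable), since the usual
interpretation concerns cross-symptom prediction. Standardized
centralities are z-scores across nodes with n−1 SD; constant vectors
standardize to zero with a warning.

## Congruence and invariance of two networks

Edge presence/absence across two networks is compared by the phi
coefficient over the p(p−1)/2 edge slots, with the χ² p-value of the
2×2 table (undefined, and reported as such, when a margin is zero);
edge weights and centralities by Spearman rank correlation. An edge
counts as "present" when its selected weight is exactly non-zero — the
sparse estimator makes zero an exact outcome, so no epsilon threshold
is imposed.

Invariance is tested by permutation on two statistics: M, the maximum
absolute edge-weight difference, and S, the absolute difference in
global strength (sum of |weights|). The null distribution pools the two
samples and repeatedly re-splits them into groups of the original
sizes, re-estimating both networks per split; p = (r+1)/(n_perm+1).
The default independent re-split mirrors common applied practice even
when the samples are two waves of the same people; a paired mode
(random within-person wave swaps) is the exchangeability-correct
alternative for that design and is available behind an explicit flag,
never silently substituted.

## Cross-lagged panel network

Each wave-2 symptom is regressed on all nine wave-1 symptoms (its own
lag giving the autoregressive diagonal) with L1-penalized logistic
regression; predictors are standardized internally and coefficients
returned on the original binary log-odds scale. The penalty comes from
tenfold cross-validation on the out-of-fold binomial deviance, taking
the largest λ within one standard error of the minimum (the 1SE rule).
Folds are stratified on the outcome: with ~5% outcome prevalence and
n ≈ 335, unstratified tenfold CV frequently produces folds without a
single event, leaving the deviance criterion undefined, so
stratification is required for the procedure to run at this scale at
all (an outcome with fewer minority-class cases than folds is refused
with guidance). Fold assignment is seed-reproducible. No post-selection
refitting is done; the reported coefficients carry the 1SE-rule
shrinkage, which is deliberate (the near-unpenalized end of the path,
not the 1SE point, is what converges to the generating coefficients as
n grows — both behaviors are tested).

## Bootstrap diagnostics

Edge-weight accuracy: B person-resamples with replacement, percentile
(2.5/97.5) intervals — percentile rather than BCa, matching the
methodology this procedure follows. Difference tests: the bootstrap
distribution of θ_a − θ_b per parameter pair; "significant" means the
central 95% interval excludes zero. Stability: the case-dropping subset
bootstrap — for drop proportions 10%…75% in 5% steps, B subsamples
without replacement, correlating subset centralities (Pearson on raw
values; Spearman behind a flag) with full-sample centralities. The CS
coefficient is the largest drop proportion at which ≥95% of subsets
retain r ≥ 0.70; 0 if none qualifies. Resamples that make a node
degenerate are kept and flagged rather than redrawn (redrawing would
bias the bootstrap distribution); subsets with constant centralities
have undefined correlations and count as below threshold.

## Synthetic data generator

Wave 1 is drawn from an Ising model; wave-2 symptom k is Bernoulli with
log-odds α_k + Σ_j B[j,k] x_j^{w1}, independently across symptoms given
wave 1 — exactly the first-order process the CLPN estimator assumes.
Sampling is exact (from the enumerated 2^p table) for p ≤ 12 and by
Gibbs otherwise (default 1000 burn-in sweeps, thinning 10); enumeration
is guarded at p ≤ 20. The exact enumeration doubles as the oracle
against which the samplers and, via parameter recovery, the estimators
are validated.

Three named scenarios fix the ground truth:

- `paper_like` (n = 335): nine symptoms; thresholds calibrated by a
  root finder on the enumerated distribution so the exact marginal
  endorsement rates sit at 5–6.9% — low-prevalence screening items,
  inside the 2–8% band typical of community gambling samples, with the
  floor placed high enough that a 335-person sample virtually never
  yields an empty symptom column; eight positive couplings of 2.0–3.0
  on the log-odds scale (strongest between "criticized by others" and
  "financial problems"); cross-lagged effects of 1.5 from the two
  driver symptoms, tolerance (2) and health problems (6), onto the
  wave-2 symptoms they are meant to predict.
- `null` (n = 335): W = 0, B = 0, 5% marginals — independent symptoms,
  for calibration and type-I-error checks.
- `strong_recovery` (n = 2000): a chain graph with couplings of 2 at
  30% marginals plus strong (2.0) cross-lagged driver effects — a
  regime where a consistent estimator should recover the exact
  structure, used for recovery and stability checks.

What the generator does **not** emulate: ordinal response generation
beyond dichotomized binaries, covariate-driven heterogeneity (sex/age
effects), panel attrition and missingness, and any misfit between the
Ising/logistic forms and real response processes. Passing recovery
tests therefore demonstrates correctness of the estimators under their
own assumptions, not robustness to violations of them.

## Problem sizes used by the test suite

The validation suite runs simulations at sizes chosen to finish on one
CPU in a few minutes per check while keeping the assertions meaningful;
all seeds are fixed:

- estimator calibration under the null: 100 seeds (Ising) and 50 seeds
  (CLPN) at n = 2000;
- recovery: 50 seeds each (chain couplings; driver out-strength ranks)
  at n = 2000;
- permutation-test validity: 150 null replications with 39 permutations
  each at n = 335 per group (39 is the smallest permutation count at
  which, with smoothed p-values, the attained level is exactly the
  nominal 5%: rejection needs at most 1 of 39 permuted statistics at or
  above the observed one, P = 2/40);
- stability behavior: B = 200 subsamples on reduced drop-proportion
  grids bracketing the asserted CS values;
- sampler checks: 20 000 draws against exact enumerated moments.

`scripts/acceptance.py` re-runs the full pipeline at the study scale
(n = 335) with 200 permutations, 200 bootstrap resamples and 50
case-dropping subsamples per drop proportion.

## Known limitations

- The CLPN conditions only on wave-1 symptoms; it does not separate
  within- from between-person variance and supports no causal reading.
- EBIC-LASSO + AND-rule is conservative at n = 335 with 5% prevalence:
  many true couplings are missed, and estimated networks are sparser
  than the generating ones (visible in the worked example).
- Permutation invariance testing of two waves of the same people by
  independent re-splitting ignores the pairing; the paired mode exists
  for that reason.
- Exact replication of third-party edge weights can differ in late
  decimals through λ-grid and solver-tolerance choices, which are not
  standardized across implementations.
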