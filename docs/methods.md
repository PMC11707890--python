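# Methods

## Model

The package models a perturbation condition by the linear structural
equation model (SEM)

    X = A X + g(D) + ε,      g(D) = B D,

with responses X ∈ ℝ^p, drug concentrations D ∈ ℝ^q, direct causal
effects A ∈ ℝ^{p×p} among the responses (`A[j,k]` = effect of a
one-unit change of response k on response j), known drug-target map
B ∈ ℝ^{p×q}, and exogenous error ε with E[ε] = 0 and ε ⟂ D. Since the
drug vector has no unobserved common cause with the responses, the
interventional and conditional means coincide and the prediction target
is

    f(D) = E[X | do(D)] = (I − A)^{-1} B D.

Elements of ε may be correlated; `CausalSEM` accepts an optional full
noise covariance to model hidden confounding among responses (cell
cycle, batch conditions). Estimation of A does not require
non-Gaussianity, equal variances, or the absence of that confounding —
identification comes from the interventions themselves.

### Estimators

**LR.** `min_R Σ_i ‖X_i − R D_i‖² + λ Σ|R_jk|`. The λ=0 solution is
per-response ordinary least squares; it requires the drug matrix of the
training rows to have full column rank over the non-zeroed columns and
otherwise raises (a rank-deficient LODO design is exactly the situation
in which LR is inconsistent, so the failure is surfaced, not papered
over; `allow_minimum_norm=True` opts into the minimum-norm solution for
exploration). For the LODO convention the held-out drug's coefficients
are forced to zero before fitting on the remaining columns.

**CSR.** With G the matrix of intervention covariates g(D_i) = B D_i,
the λ=0 estimator is the least-squares fit of X on G, giving T̂ and
Â = I − T̂^{-1}; it requires G to have full column rank, i.e. that the
training drugs jointly target every response — a condition that can
hold even when individual drugs are absent from training, which is what
licenses LODO extrapolation. The estimated structure's `I − Â` is
checked for positive definiteness after fitting (`pd_report_`) rather
than constrained during optimization.

**Linear Cellbox.** The ODE `dx/dt = W x + u` with decay on the
diagonal of W has, for W with all eigenvalue real parts negative, the
steady state `x* = −W^{-1} u` from x(0) = 0. Matching u = B D to the
SEM shows the steady-state least-squares problem over W is the CSR
problem reparameterized by `W = A − I`, so `CellboxLinear` fits CSR and
maps back. Predictions of the two are identical up to floating-point
solve error (≤1e−12 in practice); the numerical integrator exists to
witness the equivalence and to detect instability, not to fit.

### Positive definiteness of non-symmetric matrices

`I − A` and fitted T are generally non-symmetric, and "positive
definite" has two common readings. Both are implemented:
`"real-eigenvalue"` (all eigenvalues have positive real part) is the
default because it is exactly the stability condition of the Cellbox
steady state (`W = A − I` stable ⟺ eigenvalues of `I − A` in the right
half-plane); `"symmetric-part"` (eigenvalues of `(M + Mᵀ)/2` positive)
is the stricter quadratic-form reading. Every report records which mode
produced it. For any A whose nonzero pattern is a DAG,
`det(I − A) = 1` and all eigenvalues of `I − A` equal 1, so DAG
structures pass the default check.

## Synthetic data generator

`benchmark_sem()` builds the 5-response / 15-drug system used
throughout: B's first five columns are the identity (single-target
drugs, strength 1) and its ten remaining columns enumerate all C(5,2)
response pairs at strength 0.5 in lexicographic order — the pair order
for the middle columns is this module's explicit assumption, and
structure recovery is invariant to it as long as the design is full
rank. A has entries 1.6 (X1→X2), 1.2 (X1→X3) and 2.0 (X3→X4); the noise
is i.i.d. N(0, 0.1²). `all_pairs_design(q)` applies every unordered
drug pair once at unit concentration (n = q(q−1)/2 = 105 for q = 15),
pairs in lexicographic order, condition ids `"drugA+drugB"`.

Simulation draws ε at the structural level and solves
`(I − A) X_i = B D_i + ε_i`, so noise propagates through the network:
the residual covariance is `(I−A)^{-1} Σ_ε (I−A)^{-T}`, which the test
suite verifies empirically at 10⁴ replicates.

What the generator emulates: the two-drug combination structure, known
direct targets, steady-state readout, network-propagated noise. What it
does not: dose–response nonlinearity, off-target drug effects,
measurement error that does not propagate (e.g. assay noise added after
equilibrium), time-course dynamics, and >2-drug combinations. Passing
tests on this generator therefore demonstrate correctness of the
estimators under their own assumptions, not robustness on real screens
— the misspecified-B setting (every 0.5 target strength inflated to 1)
probes the single assumption the comparison turns on.

`random_dag_sem` / `random_mixed_design` produce arbitrary-shape
instances (used for property tests and for dry-running the repeated
random-fold protocol at a realistic 89-condition × 12-drug × 87-response
screen shape; at that shape p exceeds the training size, so the
unpenalized CSR rank condition cannot hold and the protocol dry-run
uses LR).

## Validation protocols

- `random_fold_split`: train size is `round(train_frac · n)` with
  half-away-from-zero rounding, pinned by the convention that 70% of 89
  conditions is 62.
- `lodo_split_by_drug`: partition by zero/nonzero concentration of one
  drug.
- `lodo_per_condition`: for each test condition of a base random-fold
  split of a two-drug design, one of its two drugs is chosen uniformly
  (seeded) and the training set is subset to conditions not using it;
  each test condition gets its own refit.
- `evaluate`: Pearson r and MAE pooled over all flattened
  (condition, response) cells — the scatter-plot convention; per-response
  correlations are available separately since pooled and per-response
  summaries can differ.
- `repeated_random_fold`: repeats the split, averages each
  (condition, response) prediction across the runs where the condition
  was in test, then scores the averaged predictions.

Every driver takes one master seed; per-repetition seeds are the first
31 bits of `numpy.random.SeedSequence(master).generate_state(...)`, so
any repetition can be reproduced in isolation.

## Numerical choices

- Invertibility: reciprocal 2-norm condition number must exceed 1e−12
  (configurable on `CausalSEM`); λ=0 fits refuse rank-deficient designs
  instead of silently pseudo-inverting.
- LR lasso is solved by scikit-learn's coordinate descent on the
  equivalent rescaled objective (alpha = λ/2n, no intercept). No
  intercepts anywhere: responses are changes relative to the
  unperturbed state; optional column centering is available.
- The penalized structural objective
  `Σ‖X_i − (I−A)^{-1} B D_i‖² + λ‖A − diag(A)‖₁` is nonconvex through
  the matrix inverse, so coordinate descent has no closed-form updates;
  it is minimized by monotone proximal gradient — gradient of the
  smooth part via `∇_A = Tᵀ ∇_T Tᵀ`, `T = (I−A)^{-1}` — with
  backtracking line search, soft-thresholding of off-diagonals (the
  diagonal is unpenalized), a hard-zero mask applied exactly, and warm
  start from the closed-form unpenalized structure when the rank
  condition allows. Convergence: max coefficient change < 1e−8;
  iteration cap 1e5, exceeded ⇒ `ConvergenceError` carrying the
  objective trace. Masks that contradict a strong true edge on
  noise-free data can make the infimum unattainable (iterates diverge
  while the objective creeps down); the solver then raises rather than
  returning an arbitrary point.
- ODE steady states: adaptive RK45 from x(0) = 0, terminal event at
  `‖dx/dt‖∞ < tol` (default 1e−9), default horizon t_max = 200 time
  units; the integrator's rtol/atol default to two decades below the
  settling tolerance, since the residual cannot settle below the
  integration error itself. A divergence guard (state norm > 1e8)
  raises for unstable W. The random stable-W sampler shifts a Gaussian
  matrix's spectrum 0.5 left of the imaginary axis so settling occurs
  well before the horizon.
- Mask semantics: a mask entry marks a structure coefficient
  constrained to zero (e.g. phenotype→protein edges), applied
  identically in penalized CSR and Cellbox fits.

## Problem sizes

Default test and reproduction runs use the 105-condition benchmark,
50 replicates for structure-recovery summaries, 100 random systems
(p ≤ 8) for the ODE/closed-form comparison, and 1000 repetitions of the
repeated random-fold protocol at screen shape — sizes chosen so each
summary's Monte-Carlo error is far below its interpretation threshold
(e.g. the 50-replicate mean of an edge estimate has standard error
≈ 0.009 against a 0.05 reading tolerance).

## Known limitations

- Linearity end to end: nonlinear envelopes (sigmoid, clipped linear),
  learned saturation parameters, and nonlinear g are out of scope; the
  Cellbox equivalence is exact only for the linear variant.
- No tuning-parameter selection for λ and no standard errors or
  confidence statements on Â.
- Cyclic structures are admitted wherever `I − A` is invertible, but
  the acyclicity report is the only DAG diagnostic; equilibrium
  semantics of cyclic SEMs beyond invertibility are not modeled.
- The LODO-per-condition driver assumes exactly two active drugs per
  test condition, matching the combination-screen design it mirrors.
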