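# Methods

## Problem setting

We observe a multivariate time series x_{i,m} = x_i(t_0 + m Δt) from a
network dynamical system ẋ = F(x) + ξ with unknown smooth F and additive
noise ξ, and ask only *which* units j appear on the right-hand side of unit
i's equation — not what the coupling functions are. The object inferred is
the explicit dependency matrix Λ^i: a binary diagonal matrix with
Λ^i_jj = 1 exactly when ∂F_i/∂x_j ≢ 0. This covers pairwise links and
higher-order (e.g., three-point) interactions uniformly, because Λ^i simply
marks every unit whose state enters f_i at any order.

## Reconstruction model

Each unit's dynamics is decomposed first into interaction orders
(g^i_j(x_j), g^i_{jk}(x_j, x_k), …) and then each interaction into P basis
functions. The regression target is the estimated derivative; the regressors
come in *blocks*, one per candidate interaction, and a candidate either
enters with its whole block or not at all (a grouped-variable problem).

Selection is greedy block orthogonal least squares: starting from the
residual of the intercept-only fit, every unselected block is orthogonalized
against the span of the selected columns (modified Gram–Schmidt, each update
applied twice to control drift; rank decisions use a relative cutoff of
1e-10 in a rank-revealing QR), each candidate is scored by the squared norm
of the residual's projection onto its orthogonalized column space, and the
best block is selected. Ties break toward the smallest candidate key. After
each selection the fitting cost C_i(l) — the mean squared derivative
mismatch — is recorded on the training rows (from the recursion) and on the
validation rows (from a fresh ordinary-least-squares refit on the selected
raw blocks). C_i(0) is the zero-predictor cost, i.e., the mean squared
derivative.

An intercept column is always part of the fit. Constant drive terms —
natural frequencies ω_i of the oscillator models, constant influxes — lie in
no basis family's span; without the intercept they would leak into every
projection and bias the recovered coefficients. The intercept is not a
candidate and is not scored.

Stopping: at `l_max` (default min(#candidates, M_train/P)); when the best
candidate's gain falls below `tol` (default 1e-4) times the current residual
sum of squares; or when the training cost reaches a floor of 1e-14 times
C_i(0). For learning-curve diagnostics one sets `tol=0` and a fixed `l_max`
so the curve continues past the knee.

Units are processed independently (the per-unit problems share data but not
parameters), so results do not depend on processing order and the method
parallelizes trivially.

### Basis families

For a candidate unit j and target i (P functions per family index):

- **a** (x_j − x_i)^p — powers of differences
- **b** x_i^{p1} x_j^{p2}, 1 ≤ p1+p2 ≤ P — bivariate monomials
- **c** sin(p(x_j − x_i)), cos(p(x_j − x_i)) — Fourier modes of differences
- **d** 1/(1 + ‖(x_i, x_j) − center_p‖²) — rational radial basis functions,
  P centers drawn without replacement from the observed sample cloud
- **e** x_j^p — plain powers
- **f** sin(p x_j), cos(p x_j) — plain Fourier modes
- **ef** — the union of the e and f columns

The printed form of family d in some renderings omits the reciprocal; the
implemented 1/(1+r²) form is the member of the radial-basis class the
expansion centers imply. The self block (j = i) uses one-place semantics
(powers for a/b/d/e, Fourier for c/f, both for ef) so intrinsic terms like
−x_i are absorbable; it is excluded from AUC scoring. For multi-component
units a candidate's block stacks the basis columns of all its components,
and the self block additionally contains the degree-2 cross-component
monomials — the chaotic-oscillator model has an x¹x³ intrinsic product that
no single-component family spans. The **ef** union exists for the same
reason: those units combine linear intrinsic terms with sinusoidal coupling,
which neither a pure power nor a pure Fourier family captures alone. With
three-point candidates enabled, the candidate set is all unordered pairs
{j,k}; pairs containing the target are the degenerate (pairwise) candidates,
and two-place families evaluate on the difference x_a − x_b (canonical key
order; the sin/cos pairs span the same space regardless of order).

Every column is scaled to unit Euclidean norm before selection (recorded,
and undone when coefficients are reported), making the projection gains
scale-free. All-zero columns are dropped; blocks with no usable column are
flagged unselectable.

### Derivatives, splitting, scoring

Derivatives use a two-point forward stencil by default (state x_m paired
with (x_{m+1} − x_m)/Δt) or a three-point central stencil; estimates never
straddle segment boundaries. The train/validation split (default 60/40) is
by whole segments, never by samples, to avoid leakage between adjacent time
points; one seeded split is shared by all units of a fit.

Interaction scores for AUC are rank-based: the candidate selected at step l
scores (#candidates − l + 1), unselected candidates share the tied minimum
0. The AUC is the Mann–Whitney statistic with midrank ties, so a fully tied
score set gives exactly 1/2. Self pairs are never scored. For hidden-unit
runs only pairs among observed units are scored — the method makes no claim
about indirect paths through unobserved units. For hypernetwork runs the
candidate universe is all unordered pairs (degenerate pairwise keys
included) and the truth is the support of the second-order coupling
tensors. An alternative scoring by training-cost decrease is exposed
(`score_matrix_cost`); ranks are the default because the method's defined
output is the discovery order.

### Knee detection

The learning-curve knee l\* maximizes the distance of the log-cost points to
the chord joining the curve's endpoints, computed on the costs for
l = 1..L in normalized coordinates, ties toward smaller l. The zero-predictor
point l = 0 is excluded: its inclusion would place the maximum-curvature
point one step before the plateau onset that the in-degree corresponds to.
A knee is *confident* only when its normalized chord distance is ≥ 0.15 and
the curve drops by at least 10× overall; a flat curve reports l\* = 0 and a
strictly geometric decay (log-linear, no interior curvature maximum) is
low-confidence. In practice the separation is stark: correct-order bases
drop by ~10⁶ at the knee, wrong-order bases by well under 10×.

## Model systems and the synthetic-data generator

The generator defines the study conditions; all tests and the acceptance
script draw their inputs from it.

- **Michaelis–Menten gene regulation** — ẋ_i = −x_i + (1/n_i) Σ_j J_ij
  x_j/(1+x_j): transients toward steady state. Initial conditions uniform on
  [0.25, 2]; Δt = 0.25. The steady state is approached algebraically (the
  homogeneous mode of the linearization is marginal), which is why short
  *transients* from many initial conditions carry the information.
- **Phase oscillators** — ẋ_i = ω_i + (1/n_i) Σ_j J_ij [sin(x_j − x_i −
  1.05) + 0.33 sin(2(x_j − x_i))], and the hypernetwork extension with
  arguments x_j − x_k and second-order tensors E^i. ω_i i.i.d. standard
  normal (the source model states only that frequencies are constant);
  initial phases uniform on [−π, π]; phases recorded unwrapped (a wrap
  option exists; families a/c are shift-invariant either way); Δt = 0.05.
- **Rössler oscillators** — three components per unit, coupling
  (1/n_i) Σ_j J_ij sin(x_j¹) into the first component; chaotic. Initial
  conditions uniform on [−10, 10]² × [0, 1]; Δt = 0.05; divergence guard at
  |x| > 1e6.
- **Glycolytic oscillator** (7 species) and **circadian clock** (10
  variables) — fixed biological systems with built-in three-point
  interactions (e.g., k₂S₂(N−S₅), k₃P₂T₂ association). Parameter defaults
  follow the cited source models (Wolf & Heinrich 2000; Leloup & Goldbeter
  1998) and are fully overridable via `SimConfig.params`. Glycolysis uses
  Δt = 0.01 min — its rate constants reach 100/min, so a coarser grid would
  corrupt two-point derivatives — and the clock Δt = 0.25 h. Both have
  negative-concentration guards.

Networks draw each unit's n_in in-neighbors uniformly without replacement;
link weights default to 1 (the 1/n_i normalisation of the couplings reads
naturally with homogeneous weights), with a uniform [0.5, 1] option for
heterogeneity studies. Hypernetworks make each of the n_in interactions a
genuine pair {j,k} (j≠k≠i) with probability p_h, else a pairwise link
stored as the degenerate pair (j, i) inside E^i — with this encoding the
double-sum coupling reduces exactly to the pairwise form at p_h = 0. Unit
generation is per-unit seeded (counter-based), so it is order-independent.

Noise enters as additive white noise in the SDE sense: Euler–Maruyama steps
x ← x + h f(x) + η √h N(0,1) with internal step h = Δt/10 by default; η is
the noise's diffusion amplitude (its standard deviation scale). With η = 0
the integrator switches to Heun's second-order method. Nonnegative systems
are clipped at 0 under noise; with η = 0 a negative excursion beyond 1e-8
raises instead of being masked.

What the generator does **not** emulate: measurement noise distinct from
dynamical noise, irregular sampling, missing samples within a segment,
delays, and non-stationary parameters. Passing tests therefore demonstrate
correctness of the method under the stated generative conditions, not
robustness to every artifact of real recordings.

## Study conditions used by the tests and acceptance script

Problem sizes are the package's reference conditions: phase networks N = 20,
n_in = 10, M = 2000 (200 segments × 10 samples) for the threshold check;
N = 20, n_in = 5, l_max = 12, tol = 0 for learning curves; gene-regulation
transients N = 100, n_in = 10, m = 5, M = 2000 for baseline comparisons,
also with 40% of units observed and η = 0.02 for the hidden-unit regime;
chaotic oscillators N = 20, n_in = 5, M = 2000 with the ef family;
hypernetworks N = 20, n_in = 5, M = 1000 across p_h ∈ {0, 0.5, 1}.
Replicate counts are 5–10 per condition with means compared against
two-standard-error bands of the difference where "within replicate error"
is asserted.

## Numerical choices and degenerate inputs

- Rank tolerance 1e-10 (relative) throughout; candidate gains use an
  eigendecomposition-based pseudo-inverse of the block Gram matrix with the
  matching cutoff, the selected block a rank-revealing pivoted QR.
- Candidate blocks of equal width are evaluated as one batched tensor per
  greedy step (BLAS matmuls), which is what makes 100-unit fits take
  seconds.
- Final coefficients come from one OLS refit of the training rows on the
  selected raw (unnormalized) blocks plus intercept; rank-deficient refits
  fall back to least-norm solutions (LAPACK gelsy).
- y ≡ 0 targets return an empty ranking with stop reason `residual_tol`;
  fully degenerate candidate sets return `degenerate`; per-unit failures in
  a network fit are caught and reported without aborting other units.
- Partial correlations invert the covariance directly and demand an explicit
  ridge when it is singular or has condition number above 1e12.
- Transfer entropy uses equal-frequency binning (default 4 bins, lag 1
  sample), the plug-in convention 0·log 0 = 0, clipping at 0, and only
  within-segment (past, future) pairs.

## Known limitations

- AUC pools ranks across target units; per-unit candidate counts are equal
  within a run, but score scales across units are comparable only through
  ranks, which is the intended semantics.
- For multi-component units, unit-level scores pool component-level
  selections by earliest discovery; a noisy component can therefore inject a
  false candidate ahead of a slowly-discovered true one (visible as the
  chaotic-oscillator regime's AUC sitting below the scalar-unit regimes').
- The three-point expansion stops at order 2; higher orders are
  representable by the same key mechanism but are not exercised.
- Weighted inference is out of scope: only existence/absence of interactions
  is scored, and coupling strengths are reported only as fitted
  coefficients.
- Synchronized or otherwise low-dimensional trajectories do not sample the
  dynamics space and cannot identify interactions — distributed sampling
  from many initial conditions is the recommended regime.
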