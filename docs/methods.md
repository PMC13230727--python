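# Methods

## Forward model

The lower-level programme optimises a convex basis function of the
candidate flux subvector over the steady-state polytope:

    min/max  F(C, v_O)   s.t.   S v = 0,   v_min ≤ v ≤ v_max.

The objective sees only the candidate coordinates `O`; all other fluxes
enter through the constraints, so the full FBA system is always solved
whatever the candidate set.  The strict mass balance can be relaxed to
a two-sided band `−ε ≤ S v ≤ ε` (`LowerConfig.eps_ss`).  The default is
ε = 0: on small and mid-size networks the strict equality is solvable
to machine precision, and a positive ε measurably changes the optimum
(the solver exploits the band whenever that lowers the objective, so
‖S v*‖ sits exactly at ε).  For compact and genome-scale models where
the equality stalls convergence, ε = 1e−2 and 1e−1 respectively are the
recommended settings.  `delta` (default 1e−6) guards the logarithm of
the one concave basis (`inverse_log`); `logsumexp` instead uses the
standard max-shift stabilisation and needs no guard.

### Solver

All smooth modes are solved by a feasibility-preserving active-set
method: a phase-1 LP (HiGHS) produces a feasible point, the active
constraints at the current point define an affine subspace, and a
reduced-space Newton iteration with Armijo backtracking minimises the
objective inside it.  Steps that hit an inactive bound (or an inactive
side of the ±ε band) add that constraint; multipliers of the wrong sign
drop one; the pivoting repeats until the KKT system holds, typically to
1e−13 or better.  Duals are recovered from the stationarity system by
least squares.  `inverse_log` reduces to a linear programme (the log is
monotone), solved by HiGHS and then polished the same way.  A
trust-region SQP fallback (scipy `trust-constr`) handles the rare case
where pivoting stalls.

The `norm` mode shares its argmin with `sum_squares` (squaring is
monotone on nonnegatives), so the smooth squared problem is solved
first and the polish restores the norm-mode duals from the true
gradient.  At a zero-norm optimum the objective is non-differentiable
and the only stable certificate is the zero subgradient with all
multipliers zero; the solver detects this within a 1e−9 relative
neighbourhood and flags the result degenerate.

### Differentiation

The sensitivity `dv*/dC` comes from implicit differentiation of the
polished KKT system: with Lagrangian Hessian `H` and active constraint
matrix `G` at the optimum,

    [ sgn·H  Gᵀ ] [ dv/dC ]   [ −sgn·∂(∇_v f)/∂C ]
    [   G     0 ] [ dy/dC ] = [          0        ]

Rows of fluxes pinned at active bounds are exactly zero.  A singular
KKT matrix — vertex optima of linear-forward modes, degenerate active
sets — is solved in the least-squares sense and flagged; at a strict
vertex the true derivative is zero and the flag tells the caller the
point is locally non-smooth in C.  The mixed derivative ∂(∇f)/∂C is
obtained by central differences of the analytic gradient (step 1e−6,
error ~1e−10); the Hessians are analytic.

## Training

Coefficients live on the probability simplex via `C = softmax(θ)`,
which both enforces positivity/unit-sum and removes the scale
degeneracy of the objective.  The loss is the mean squared residual
over an explicit evaluation set `E` (default: all measured reactions;
the mean, not the sum, so the scale is comparable across observability
levels), optionally plus `λ‖C‖₂²`.  Training runs L-BFGS-B on θ —
limited memory 100, strong-Wolfe-style line search with at most 20
evaluations per step — for a fixed budget of 50 recorded quasi-Newton
steps (25 is enough at genome scale).  The `initial_step` field is kept
for configuration fidelity with momentum-style optimisers but the line
search chooses the actual steps.  No early stopping beyond the
optimiser's own convergence test; converged runs return a shorter loss
history with a flag.

Measurement-derived bound overrides tighten the network before
training: the solver sees the bounds, the loss sees the medians.  The
override rule (the package's own choice, since no canonical mapping
from replicate error to bounds exists) is `median ± k·MAD` with k = 3,
or `value ± 5 %` for single values — tighter measurements give tighter
bounds.  Overrides only ever shrink the model's intervals; a disjoint
override is ignored with a logged warning.

λ is selected from the grid {1e−6, 1e−5, 1e−4} by short runs (10
epochs; 5 at genome scale) from fresh random starts, smallest final
regularised loss winning, ties toward smaller λ.  Multi-start trains
five independent initial points (coefficients uniform on [0,1], mapped
to θ = log C) and keeps the record with the lowest final loss, ties
broken by start id.  Starts share no mutable state, so a parallel
executor would select identically; exact ties between distinct optima
are resolved by position, which is the one deliberately
order-dependent rule.

Vertex optima deserve a note: for some coefficient vectors (frequently
under `logsumexp`) the forward optimum sits at a polytope vertex, where
`dv*/dC = 0` and a gradient start cannot move.  This is a property of
the problem, not the implementation — roughly half of random starts on
the toy problem land there — and it is exactly why the method
prescribes multi-start: the probability that all five starts stall is a
few percent, and stalled starts cost one epoch each.

## Initialisation by Bayesian optimisation

Under partial observability the loss surface has large flat regions and
good starts matter.  The initialiser models the short-run loss (the
loss after 10 training epochs from a candidate point; 5 at genome
scale) as a black box on [0,1]^d: 5 scrambled Sobol points seed a
Gaussian process (constant mean via target centring, RBF kernel,
fitted white noise; hyperparameters by marginal-likelihood maximisation
with restarts), and 10 acquisition rounds minimise the lower confidence
bound μ − β·σ (β = 2.0, the package's default since no canonical value
exists) with quasi-Newton restarts from the box centre plus a
derivative-free polish (the surrogate's dynamic range can drop below
finite-difference resolution).  Points stay in the unit box and are
renormalised onto the simplex only when a training run consumes them.
Failed evaluations enter the surrogate at a capped sentinel; if every
evaluation fails the loop falls back to uniform random points with a
warning.

## KKT verification

`compute_residuals` is a pure function of a solution and its
multipliers — no optimisation.  Primal feasibility and stationarity use
the ∞-norm (the most conservative certificate); bounds feasibility is
reported as the fraction of fluxes inside their bounds (1 = all), with
the maximum violation logged separately; complementary slackness is the
per-block maximum of |multiplier × slack|, the lower-bound block
reported as "Comp. Slack Min" and the upper-bound block as "Comp. Slack
Max".  When ε > 0 the relaxed violation max(|S v|−ε, 0) is reported
alongside the classical ‖S v‖∞.  Certification thresholds (primal 1e−8,
stationarity 1e−4, complementarity 1e−5) are configuration; the
solver's own solutions typically sit at 1e−13 or below.

## Single-level benchmark

The benchmark optimises (v, C, duals) jointly: squared error over the
measured set, the forward problem's stationarity `C + Sᵀy⁺ − Sᵀy⁻ −
μ_lb + μ_ub = 0` as a hard constraint, simplex-restricted C, and a
penalty ρ·R_KKT on dual magnitudes and constraint slacks in place of
complementarity.  Inside the feasible set every absolute value in
R_KKT resolves to a linear form, so the whole problem is one convex QP
(solved with trust-region SQP).  ρ defaults to 1e−2 and is the
formulation's only free knob — the benchmark CLI sweeps {1e−4, 1e−2,
1}.  Infinite bounds would make the slack terms undefined; they are
clipped to a ±1e4 box and the affected reactions flagged.

## Synthetic scenarios

`random_network` builds sparse integer stoichiometries with one
exchange-like column per metabolite and guarantees feasibility by
construction: a null-space flux vector is sampled first and bounds are
widened around it.  One reaction's bounds exclude zero (a forced
substrate uptake/secretion, mirroring the toy network's forced flux);
without it the zero flux vector is feasible and every norm-like
objective trivially returns v = 0, so observations would carry no
signal.  Observations are the forward solution at a known `C_true`,
optionally corrupted with relative Gaussian noise and subsampled
exchange-reactions-first (extracellular fluxes are what real
experiments measure).  What passing recovery tests show is that the
estimator inverts its own forward model under exact model match; they
say nothing about model misspecification, measurement bias, or
thermodynamic infeasibility in real data — see limitations.

Test and acceptance problem sizes (toy 2×5; synthetic 8×20, ten seeded
replicates; five starts, fifty epochs) were chosen so the full suite
exercises every code path at desk scale.

## Known limitations

* No thermodynamic (Gibbs-energy) constraints; irreversibility only
  through bounds.
* Coefficients are not identifiable: many C produce the same optimal
  fluxes.  All guarantees are on predicted-flux error.
* Vertex optima give zero gradients; multi-start mitigates but does not
  eliminate the failure mode.
* The benchmark's stationarity convention assumes a maximisation-style
  forward objective with +C, as in its standard formulation; it is not
  a reimplementation of the original bilevel NLP it is inspired by.
* Genome-scale models are supported through the same code paths
  (dense linear algebra) but not performance-tuned for them.
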