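# celltarget

Inverse flux balance analysis: inferring the cellular objective from
flux measurements by differentiating through the forward FBA programme.

## The problem

Constraint-based metabolic models predict flux distributions by
assuming the cell optimises some objective — biomass yield, ATP
production, enzymatic parsimony — over the steady-state flux polytope

```
v*(C) = argmin_v  F(C, v_O)    s.t.   S v = 0,   v_min ≤ v ≤ v_max
```

where `S` is the m×n stoichiometric matrix, `v` the flux vector and
`F` a convex surrogate objective over a candidate reaction set `O`,
weighted by coefficients `C`.  For well-studied microbes the objective
is conventional; for mammalian production cells (CHO and friends) it is
not known, and the *inverse* problem arises: given measured fluxes
`v_exp`, which objective coefficients `C` make the forward optimum
reproduce them?

`celltarget` solves this bilevel problem with gradients.  The upper
level minimises the mean squared error

```
L(C) = (1/|E|) Σ_{i∈E} ( v_i*(C) − v_i_exp )²     (+ λ‖C‖₂²)
```

over coefficients constrained to the probability simplex through a
softmax reparameterisation `C = softmax(θ)` (preventing trivial
rescaling), training θ with limited-memory quasi-Newton steps.  The
gradient of the loss flows *through the solution of the lower convex
programme* by implicit differentiation of its polished KKT system — the
package's own differentiable convex layer.

Supported convex basis functions for `F`:

| mode        | type    | objective                          |
|-------------|---------|------------------------------------|
| norm        | convex  | minimise ‖C ⊙ v‖₂                  |
| sum_squares | convex  | minimise Σ (Cᵢ vᵢ)²                |
| logsumexp   | convex  | minimise log Σ exp(Cᵢ vᵢ)          |
| inverse_log | concave | maximise log(Σ Cᵢ vᵢ + δ)          |

Around the core sit:

* **KKT verification** (`celltarget.kkt`) — residuals of all four
  first-order condition blocks certify every solution; for convex
  programmes with affine constraints these conditions are necessary and
  sufficient.
* **Bayesian-optimisation initialisation** (`celltarget.bo_init`) —
  Sobol design + Gaussian-process surrogate of the short-run loss +
  lower-confidence-bound acquisition, feeding a five-start multi-start.
* **A single-level convex benchmark** (`celltarget.objfind`) — fluxes,
  coefficients and forward-problem duals optimised jointly with
  stationarity as a hard constraint and slack/dual magnitudes penalised
  (complementarity is not imposed), solvable in one convex shot.
* **Synthetic scenarios** (`celltarget.datasets`) — random feasible-by-
  construction networks with known generating objectives, for recovery
  tests.

## Worked example

Infer an objective for the packaged 5-reaction, 2-metabolite toy
network, whose reference fluxes are its minimum-norm feasible point:

```
$ celltarget infer --basis norm --epochs 50 --starts 5 --seed 1 --out run/
final loss 0.0000e+00 (start 1); outputs in run/
```

`run/predictions.tsv` shows the forward solve at the inferred
coefficients reproducing the data exactly (v1 and v5 are zero up to
solver precision):

```
reaction_id  v_pred         v_exp
v1           4.74e-17       4.74e-17
v2           -2             -2
v3           1              1
v4           1              1
v5           0              0
```

Many different coefficient vectors achieve this — the inverse problem
is degenerate, and the package reports predicted-flux error, never
closeness to any "true" C.  The KKT report certifies the solutions of
all three convex bases:

```
$ celltarget kkt --out run/
       Mode  Primal Feas.  Bounds Feas.  Stationarity Resid.  Comp. Slack Min  Comp. Slack Max
  logsumexp  0.000000e+00           1.0         3.816392e-17     0.000000e+00              0.0
       norm  0.000000e+00           1.0         4.163336e-17     0.000000e+00              0.0
sum_squares  4.320733e-17           1.0         5.551115e-17     3.456586e-18              0.0
```

Primal feasibility is ‖S v*‖∞, Bounds Feas. the fraction of fluxes
inside their bounds (1 = all), and the remaining columns the
stationarity and complementary-slackness residuals.  `celltarget
benchmark` runs the gradient-based method and the single-level
benchmark side by side; `celltarget forward` replays the forward solve
at stored coefficients (the backwards–forwards compatibility check).

Library use mirrors the CLI:

```python
import numpy as np
from celltarget import ObjectiveSpec, TrainConfig, multi_start, solve_forward
from celltarget.datasets import toy_network, toy_dataset

net, data = toy_network(), toy_dataset()
spec = ObjectiveSpec(tuple(range(5)), "norm", np.zeros(5))
best = multi_start(net, data, spec, TrainConfig(epochs=50, n_starts=5, seed=1))
v = solve_forward(net, spec.with_theta(best.final_theta)).v_opt
```

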