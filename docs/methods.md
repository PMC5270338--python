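# Methods

## Model

`taskdilemma` simulates a community of `n` individuals who may contribute
*participation load* `p_i >= 0` toward a shared task, subject to the community
budget `sum_i p_i <= P`. Three coupled processes evolve in discrete time.

**Task completion.** The task level `z` grows from `z0` toward a ceiling
`z_bar` under

    z(t+1) = z(t) + phi * h(p(t)) * (z_bar - z(t)),    phi in (0, 1],

where the production function

    h(p) = sum_i beta_i * p_i**alpha_i,    alpha_i > 0, beta_i >= 0,

is decelerating for `alpha_i < 1`, linear at 1, accelerating above 1. The
update requires `h < 1` on the feasible set; `ProductionFunction.validate_range`
certifies this by exact maximization over the budget simplex (see *Numerics*).
With constant `h` the trajectory is the geometric closed form
`z(t) = z_bar - (1 - phi h)**t (z_bar - z0)`, and the first step at which the
residual fraction falls to `sigma` is `t* = ceil(log sigma / log(1 - phi h))`.
The numerator is the residual-fraction convention: the residual after `t`
steps is exactly `(1 - phi h)**t`, and the formula is tested against
brute-force iteration of the update, which is the authoritative oracle for it.

**Reputation and reciprocity.** Individuals communicate over an undirected
network. Each ordered edge carries a relative reputation updated by
exponential smoothing with forgetting,

    r_ij(t+1) = (1 - tau_ij) r_ij(t) + tau_ij * (p_j(t)/P) * r_bar,

so `r_ij` tracks `r_bar * p_j / P` at rate `tau_ij` (saturating in one step at
`tau = 1`, frozen at `tau = 0`, decaying to zero for idle neighbours).
Reciprocity is `r_i = sum_{j in N_i} delta_ij r_ij` and adds to the constant
motivation: `b_i = gamma_i + r_i`.

**Marginal gain and load passing.** With linear costs `c_i p_i`, the gated
marginal gain is `g_i(p_i) = b_i - c_i p_i` when `b_i >= c_i P`, else
identically 0. The gate is *non-strict* at the boundary so that an individual
with `b_i = c_i P` participates (its gain reaches zero only at full load).
Community satisfaction is the separable concave utility
`U(p) = sum_i (b_i p_i - c_i p_i^2 / 2)`; its constrained maximum is the
water-filling point where all active individuals share one marginal gain
`mu*` (module `equilibrium`, with a simplex-grid brute-force oracle).

Load moves each round toward that optimum by a local rule: individual `i`
passes to the strictly-better neighbours tied for the largest gain in its
neighbourhood, splitting its budget equally among ties, with each transfer

    L = min( p_i/|S_i|,  (g_j - g_i)/(c_i + c_j),  theta * (g_j - g_i)/c_j ).

The middle cap is the pairwise equal-gain point (no overshoot); the right cap
lowers the receiver's gain by exactly the fraction `theta` of the gap, which
is what produces gradual trajectories and geometric equalization. Taking the
maximum feasible transfer instead would equalize pairs in one step and
destroy the gradual dynamics the rate analysis assumes. For non-linear gain
functions the same two caps are found by bisection to 1e-12. All plans in a
round are computed from the same state and applied synchronously, so the
total load is conserved exactly. Ineligible individuals (gain gated to 0,
slope 0) still donate — load drains away from them at the theta rate — but
are never selected as targets.

**Reservoir.** Scenarios start from `p = 0`, while the passing rule assumes
the full budget circulates. The gap is reconciled by a reservoir: a virtual
participant holding `P - sum_i p_i` with constant gain 0 and slope 0,
adjacent to everyone. Each individual with positive gain draws
`min(reservoir/k, theta * g_i / c_i)` per round (`k` = number of drawers);
the reservoir never pulls load back. `sum_i p_i + reservoir = P` is an exact
invariant, asserted to 1e-12 along every tested trajectory.

**Step order.** One global step computes, all from time-t values:
(1) reciprocity and gains, (2) the task update, (3) the reputation update,
(4) one reservoir exchange followed by one passing round. Effective
motivations `b_i` are frozen within a step; gains change during the round
only through the loads. The serialization is this package's choice — the
three update rules are defined independently and any fully synchronous order
is consistent with them; this one has no within-step feedback and is
reproducible bit-for-bit from a seed.

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `P` | total participation budget | 1 | printed experiment setting |
| `phi` | task-update scaling | 0.1 | printed experiment setting |
| `z_bar`, `z0` | task ceiling / start | 1, 0 | task starts unstarted |
| `beta_i` | production weights | `1/n` | keeps `h < 1` on the simplex for any `alpha` |
| `theta` | passing rate | 0.005 | printed for the 3-individual balancing example |
| `delta_ij` | reciprocity weights | `1/|N_i|` | bounds `r_i` by `r_bar` regardless of degree; `"unit"` (`delta = 1`) is also supported |
| `sigma` | convergence residual | 0.05 | convergence time = first step with 95% completed |
| `max_steps` | horizon | 5000 | covers the slowest (accelerating-production) conditions |
| `stop_tol` | movement threshold | 1e-10 | see *Termination* |

Monte Carlo defaults (`mc_complete` / `mc_line` fixtures, n = 5): exactly one
uniformly chosen individual is motivated with `gamma = c_i P` (eligible under
the non-strict gate), `c_i ~ U(0.5, 1.5)`, `tau_ij ~ U(0, 1)` per ordered
pair, `r_bar = 10`, `theta = 0.05`. The uniform supports, the motivation
magnitude, and `r_bar` are declared assumptions: the boundary-eligible
motivation is the weakest one that starts participation, the cost support
brackets 1 symmetrically, and `r_bar = 10` makes reciprocity able to lift a
neighbour over the eligibility threshold (`r_i` at equal sharing is
`r_bar/n = 2`, above the largest cost slope) so that cooperation can cascade
on the complete network. All are plain config fields, so sweeps can probe
sensitivity.

## Termination

A run stops at `max_steps`, or once the task is complete to within `sigma`
*and* the load state has stopped moving: the total movement (reservoir draws
plus transfers) in the last round is at most `stop_tol`. Because the theta
cap ties transfers to gain gaps, a movement below `stop_tol` bounds the
residual pairwise gain gap by `stop_tol * max(c)/theta`, i.e. gains are
equalized to well below 1e-6 at the defaults. A scenario in which nobody is
eligible, no load is held and no reputation can develop is detected as a
*deficient equilibrium* and stopped early (the state is provably frozen).
Monte Carlo runs stop at the convergence time itself — the first step with
`z >= (1 - sigma) z_bar` — since their summaries (convergence times,
last-100-step load totals, terminal reciprocity) are defined on the task
completion process.

## Numerics

- **Range certification.** The supremum of `h` over the budget simplex is
  found by exact case analysis for the power family: all vertices `P e_i`;
  the interior marginal-equalization point of the strictly concave
  coordinates (Lagrange condition solved by bisection on the log-multiplier);
  and, because at most one coordinate with `alpha >= 1` can be positive at a
  maximizer (the restriction between two such coordinates is convex), a 1-D
  scan-plus-refine over the split between each such coordinate and the
  concave pool. A dense simplex grid search is the independent oracle in the
  tests, never the implementation.
- **Minimum iterations.** `ceil` is applied to the log ratio minus 1e-12 so
  exact-integer ratios are not rounded up by float noise; the brute-force
  iteration oracle fixes the convention.
- **Conservation.** Transfers are computed then applied in one vectorized
  pass; equal-split rounding can leave a donor a few ulp below zero, which is
  clipped (bounded by ~1e-16 per event, far inside the 1e-12 invariant).
  Transfers below 1e-15 are zeroed to avoid denormal churn. Reputation
  updates clip at most one ulp to keep `r_ij in [0, r_bar]` exact.
- **Water-filling.** The active-set iteration is exact for this quadratic
  family; KKT residuals are asserted to 1e-10. Ties in `(b, c)` need no
  tie-break: the utility is strictly concave for `c > 0`, so the maximizer is
  unique.
- **Seeding.** Monte Carlo child seeds are spawned from the master seed with
  the `(condition, run)` counter pair via `numpy.random.SeedSequence`,
  reduced below 2^31 and recorded, so any single run can be reproduced in
  isolation.

## Problem sizes

The test suite and the built-in sweep run at desk scale by design: 200 runs
per condition over `alpha in {0.25, 0.5, 1, 1.25, 3}` on the complete and
line topologies with n = 5 (2000 runs total). The topology/production
ordinal effects — completion slows as `alpha` grows; full connectivity wins
for decelerating production and the line wins for accelerating production;
complete networks spread load more equally — are stable at this scale; the
full 8-value `alpha` sweep is available through the `montecarlo` CLI.

## What the generator emulates — and does not

The synthetic scenarios reproduce the study conditions: constant motivations,
linear costs, a single motivated individual per Monte Carlo run, shared
production parameters, and equal reciprocity weights. They do not model
time-varying motivation (social loafing, Köhler or sucker effects), directed
or weighted interaction, multi-task allocation, or measurement noise —
passing tests therefore certify the model's internal consistency and its
qualitative topology/production effects, not behavioural realism of any real
community.

## Known limitations

- **Boundary stalls.** Equalization through local passing is guaranteed only
  when the constrained optimum has strictly positive entries. An individual
  whose optimal load is zero can empty out; on sparse topologies (a line)
  this can disconnect the flow of load between its neighbours and freeze a
  non-equalized but stationary state. This is a property of the local rule,
  not a numerical artifact; randomized equivalence tests therefore condition
  on an interior optimum.
- The sufficient-condition check for guaranteed completion certifies only
  the linear certificate `psi(x) = eps * x` from an observed trajectory; it
  does not synthesize general comparison functions.
- The brute-force utility oracle is limited to `n <= 4` (combinatorial
  growth of the simplex grid).
- Monte Carlo censoring: runs not converged by `max_steps` enter the
  summaries as `+inf` convergence times; condition summaries carry a flag
  when more than 25% of runs are censored (medians remain meaningful below
  50%).
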