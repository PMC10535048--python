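# Methods

## Problem

Multi-contact neurostimulation systems (spinal cord stimulation,
deep brain stimulation) fractionate the stimulus current across `n`
electrode contacts. A configuration is a vector of current fractions
`alpha` in which the anodic fractions sum to +1 and the cathodic
fractions to -1, with every `|alpha_i| <= 1`. The package selects
`alpha` so that a neural-excitation field is as large as possible in a
region of interest (ROI) and/or capped in regions of avoidance (ROA).

Two field quantities drive excitation, both directional derivatives of
the extracellular potential `V` along the unit fiber direction `r`:

* E-field objective `-dV/dr` (V/m) — predictive of excitation at axon
  terminals of local cells;
* activating function `d2V/dr2` (V/m^2) — predictive of excitation of
  axons of passage.

Quasi-static linearity lets every field be written as a superposition
`F(X, alpha) = sum_i alpha_i f_i(X)` of unit-current basis fields
`f_i`, either generated analytically or imported from an external
volume-conductor solver as a CSV table.

## Field model

Basis fields come from the potential of a monopole point source in an
unbounded homogeneous anisotropic medium,

    V = I / (4 pi sqrt(sxx syy szz))
        / sqrt(dx^2/sxx + dy^2/syy + dz^2/szz),

with closed-form first and second directional derivatives (no stencils;
finite differences appear only as test oracles). Default conductivities
are white matter: 0.6 S/m along the fiber (z) axis and 0.083 S/m
transversely. Coordinates are SI meters, right-handed, z rostrocaudal.
Imported basis tables must already contain differentiated values; the
package never differentiates sampled data, which avoids any dependence
on the exporter's grid spacing.

Idealizing contacts as point sources at contact centers is the model's
main fidelity limit relative to finite-size cylindrical contacts in a
layered anatomy; the built-in fixtures are therefore qualitative
stand-ins, not reproductions of any specific clinical geometry.

## Smoothing surrogates

The objective `max over X of F(X, alpha)` and the balance constraint
`sum |alpha_i| = 2` are non-smooth. Two differentiable surrogates make
the problem amenable to Lagrange-multiplier machinery:

* Boltzmann soft max `sum v_i e^(beta v_i) / sum e^(beta v_i)`.
  Positive `beta` tracks the largest value, negative `beta` the most
  negative value. Computed with max-shifted exponents, so arbitrarily
  large `beta * v` is safe.
* smooth absolute value `alpha * tanh(gamma * alpha)`, even,
  differentiable at 0, and below `|alpha|` everywhere.

The constraints become `h1 = 2 - sum alpha_i tanh(gamma alpha_i) = 0`
and `h2 = sum alpha_i = 0`.

**Choice of beta.** `beta` is set so that `beta * F ~ 10` at the field
magnitude that matters: for an unconstrained solve, the best attainable
two-contact (bipole) field of the region; for a capped region, the cap
itself (floored at 1% of the bipole scale so `beta` stays finite as the
cap goes to 0). Pushing `beta` a further 4x or 16x was found to move
the located optimum by well under 0.1% — the soft-max error is not the
accuracy bottleneck — so no continuation in `beta` is performed.

**Choice of gamma (default 100).** The `tanh` surrogate under-counts
intermediate fractions, which lets the optimizer park small parasitic
currents on nominally inactive contacts. At `gamma = 50` roughly 10% of
the anodic current leaks this way (top anode fraction 0.89 instead of
~1); at `gamma = 100` the leak is ~5% and the smooth-abs error is below
0.01 for every `|alpha| >= 0.1`, i.e. below what 3-significant-digit
reporting can express. 100 is therefore the default.

## Single-objective solver

The Lagrangian `L = max_S - lam1 h1 - lam2 h2` gives a square system of
`n + 2` stationarity equations with a closed-form Jacobian (the
soft-max Hessian is assembled analytically). Solutions are found by
multistart:

1. Latin-hypercube draws of `(alpha, lam)` with `alpha` in [-1, 1] and
   multipliers in [-10, 10];
2. per draw, three candidate solves: a direct root solve from the draw,
   and two SLSQP locator passes (maximize and minimize the smoothed
   objective subject to the equality constraints) whose endpoints seed
   the root solve with least-squares multipliers;
3. each root solve is Powell-hybrid followed, if needed, by damped
   Newton with backtracking line search, to residual norm 1e-10 (the
   basis is internally rescaled to O(1) so this tolerance is
   meaningful); non-converged candidates are discarded.

The locator passes exist because the stationary set contains a large
almost-flat manifold of antisymmetric "field cancellation"
configurations that captures nearly every naive root solve; seeding
from constrained extrema recovers the maximizing roots reliably
(0/40 -> 60/60 convergence on the 16-contact fixture).

Converged points are deduplicated (L-inf distance 1e-4 on corrected
fractions) and classified by the bordered Hessian minor sign test, with
a projected-eigenvalue fallback whenever a tested minor falls below
1e-10 in magnitude. Exact symmetries of the fixtures make equivalent
optima form continua; a negative-semidefinite tangent Hessian with at
least one strictly negative direction is therefore reported as a (weak)
maximum, and a fully flat one — which arises only when the objective is
locally constant on the feasible set — likewise.

**Post-processing.** A converged `alpha*` satisfies the smoothed
constraints, not the exact ones, so it is corrected to
`2 alpha* / sum |alpha*_i|`, after which the exact balance rules hold
to machine precision. For device programmability the corrected
fractions are then rounded to 3 significant digits, and the rounding
residuals folded into the largest-magnitude anode and cathode so the
rounded fractions still balance exactly; the adjustment is bounded by
`n` half-units in the last place or an error is raised.

## Multi-objective solver

With `Q` regions, one objective is kept as primary and each other
region's soft max is capped: `g_i = max_S,i - eps_i <= 0`
(epsilon-constraint method — robust to nonconvex fronts, unlike
weighted sums). The generalized Lagrangian adds multipliers `mu_i >= 0`
and the Karush-Kuhn-Tucker conditions apply: stationarity, primal
feasibility, dual feasibility, complementary slackness.

Complementary slackness is resolved exactly by enumerating all
`2^(Q-1)` active sets. Each active set gives a square root-finding
problem (active constraints pinned to equality) solved by the same
multistart two-phase machinery; candidates failing any KKT condition
(feasibility tolerance 1e-8 x field scale, dual tolerance -1e-10,
slackness 1e-8 x scale) are discarded, and survivors are classified
with the active constraint gradients included in the bordered Hessian.

Pareto fronts are traced by sweeping the caps over a grid — by default
25 points spanning the capped region's achievable range, whose
endpoints come from the two single-objective solves (its maximum and
its minimum). Front points report the *exact* pointwise maximum of each
region's field at the corrected fractions: the solve-time soft
objectives are on cap-dependent scales (because `beta` adapts to the
cap) and would not be comparable across the front. Dominance flags use
each region's sense (ROI maximize, ROA minimize) with an O(n^2) scan.

## Baselines

Two reference families quantify what the optimizer buys:

* random balanced configurations: a random sign pattern (at least one
  anode and one cathode) with uniform spacings normalized per polarity,
  seed-deterministic. The sampler is a documented choice; deficit
  statistics depend on it, and a sampler biased toward near-bipolar
  patterns would show a smaller gap.
* all `n (n - 1)` ordered bipoles (cathode/anode pairs).

Baseline objectives use the exact pointwise maximum (nothing is
differentiated), which keeps `beta` out of the comparison. On the
two-lead fixture the mean random configuration falls ~69% short of the
optimized maximum, and the optimized maximum lands within ~0.3% of the
best ideal bipole — slightly below it, as expected from the smoothing
bias of the surrogate constraints.

## Fixtures

* `cube8` — eight point sources at the corners of a 10 mm cube in white
  matter, with nested regions (point, z-line, plane, box) used to show
  the region-dimensionality rule: enlarging a region can only raise the
  attainable objective when the smaller region is a subset. The point
  region is deliberately off-center; at the exact center all eight
  sources produce identical fields and the balanced-current objective
  vanishes identically.
* `two_lead_16` — two parallel 8-contact leads, 4 mm apart, 4 mm
  contact pitch, centered on z = 0. Axon-line regions (161 points,
  0.5 mm spacing, 80 mm span, 2 mm dorsal offset) run parallel to the
  leads at the midline and under each lead; two lateral boxes carry the
  E-field kind. The dorsal offset is a documented arbitrary choice — no
  CSF layer exists in the homogeneous analytic medium.

The midline axon sees *identical* fields from mirror-image contacts, so
its optima form an exactly flat continuum (any split of a fraction
between a contact and its mirror partner is equivalent); tests that
need a unique two-contact optimum use the off-midline axon lines.

## Problem sizes and numerical choices

Test and acceptance runs use 25-60 multistart draws for 16-contact
problems (empirically ~15x more than needed to hit the global optimum
on these fixtures), 10 draws per epsilon point in sweeps, a 25-point
epsilon grid, 10 000 random baseline draws, and exhaustive 0.05-step
grid oracles for 4-contact cross-checks (4002 balanced grid points).
Root-solver tolerance is 1e-10 on the normalized residual, iteration
cap 200. All randomness flows from explicit seeds; rerunning any
command or script with the same seed reproduces outputs byte-for-byte.

## Known limitations

* Point-source contacts and a homogeneous medium: field magnitudes are
  not comparable to a layered anatomical model, only the optimization
  structure is.
* Activation thresholds of actual neuron models are out of scope; all
  objectives are field quantities, and threshold-based conclusions
  (e.g. which structure fires first) cannot be drawn from them.
* A threshold/volume-of-activation objective (sigmoid-smoothed integral
  of supra-threshold field) would fit the framework but is not
  implemented.
* The grid of 2^(Q-1) active sets is exhaustive and exact but scales
  poorly in the number of regions; it is intended for Q <= 3.
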