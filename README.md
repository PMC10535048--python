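# steeropt

Analytic current-steering optimization for multi-contact
neurostimulation electrode arrays.

Modern spinal cord and deep brain stimulation systems can fractionate
the stimulus current across many contacts, which makes the space of
possible settings far too large to explore by trial and error. Given a
volume-conductor field model, `steeropt` computes the current fractions
`alpha` (anodes summing to +1, cathodes to -1) that maximize a
neural-excitation field — the activating function `d2V/dr2` for axons,
or the directional E-field `-dV/dr` for terminal excitation — over a
region of interest, and can simultaneously cap the field in regions of
avoidance, tracing the activation/avoidance trade-off as a Pareto
front. It is intended for neural-engineering researchers who have
per-contact unit-current field solutions (from an FEM model, or from
the built-in analytic point-source model) and want optimal, clinically
representable contact fractionations.

## Method

The non-smooth pieces of the problem are replaced by differentiable
surrogates: the maximum over region points by the Boltzmann operator
`max_S(F, beta) = sum F_i e^(beta F_i) / sum e^(beta F_i)`, and
`|alpha|` in the balance constraint by `alpha tanh(gamma alpha)`. The
single-objective problem

    maximize  max_S(F(X, alpha), beta)
    s.t.      h1 = 2 - sum alpha_i tanh(gamma alpha_i) = 0
              h2 = sum alpha_i = 0

is solved through the stationarity system of its Lagrangian (n + 2
equations with analytic Jacobian) from many Latin-hypercube starts;
critical points are classified as maxima/minima/saddles by the bordered
Hessian. Multi-region problems use the epsilon-constraint method — the
secondary objectives become inequality constraints
`max_S,i - eps_i <= 0` — solved via the generalized Lagrangian with
exact active-set enumeration and full Karush-Kuhn-Tucker validation;
sweeping `eps` traces the Pareto front. Solutions are rescaled to
satisfy the exact balance rules and rounded to 3 significant digits
without breaking them. See `docs/methods.md` for the details and the
numerical choices.

## Worked example

Optimize the activating function along an axon running beside one lead
of a two-lead, 16-contact percutaneous array (built-in fixture):

```python
import numpy as np
from steeropt import SolverSettings, make_two_lead_16, multistart_solve, round_fractions

fx = make_two_lead_16()                       # 2 leads x 8 contacts, 4 mm pitch
basis = fx.basis("left_axon")                 # 161-point axon, d2V/dz2 per 1 A
points = multistart_solve(basis, settings=SolverSettings(seed=1, n_starts=60))

best = points[0]                              # sorted by objective, descending
print(best.classification)                    # -> maximum
print(f"{best.primary_objective:.4g}")        # -> 6.973e+06   (V/m^2 per A, soft max)
rounded = round_fractions(best.alpha)
for lab, a in zip(fx.contacts.labels, rounded.alpha):
    if abs(a) > 0.05:
        print(lab, a)                         # -> C4 -1.0
                                              # -> C6 0.9432
```

The optimizer rediscovers, from random starts, that a single
cathode/anode pair spaced one contact apart is optimal for a single
axon target: C4 carries the full cathodic current, C6 ~94% of the
anodic current, and the remaining 14 contacts are below 0.05. The
objective value is the smoothed maximum of the activating function
along the axon for a 1 A stimulus — within 0.3% of the best of all 240
ideal bipoles, which brute-force enumeration
(`steeropt.enumerate_bipolar`) confirms.

The same fixture supports the multi-objective workflow:

```python
from steeropt import SolverSettings
from steeropt.multi_objective import default_epsilon_schedule, pareto_sweep

basis = fx.basis_for("left_axon", "right_axon")   # target vs avoidance axon
settings = SolverSettings(seed=1, n_starts=10)
schedule = default_epsilon_schedule("right_axon", basis["right_axon"],
                                    settings=settings, n_points=25)
front = pareto_sweep("left_axon", ("right_axon",), schedule, basis,
                     settings=settings)
for p in front.points[:3]:
    print(f"eps={p.epsilon['right_axon']:.3g}  "
          f"ROI={p.objectives['left_axon']:.4g}  "
          f"ROA={p.objectives['right_axon']:.4g}")
# eps=2.88e+05  ROI=7.187e+06  ROA=2.971e+05
# eps=5.79e+05  ROI=7.257e+06  ROA=5.522e+05
# eps=8.7e+05   ROI=7.257e+06  ROA=5.522e+05
```

At loose caps the constraint never binds and the unconstrained optimum
(ROI 7.257e6, ROA 5.52e5) repeats; at the tightest cap the avoidance
field drops to ~4% of the target field for a ~1% loss of target
objective — the trade-off a programmer would choose from. Reported
front objectives are exact pointwise field maxima at the corrected
fractions (the cap itself binds on the smoothed objective).

A CLI wraps the same pipeline: `steeropt gen-fixture`, `optimize`,
`pareto`, `baseline`, and `evaluate` (see `steeropt --help`); every run
writes a JSON manifest sufficient to reproduce it bit-identically.

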