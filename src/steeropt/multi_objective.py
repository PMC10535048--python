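"""Multi-objective current steering via the epsilon-constraint method.

With several regions (multiple ROIs, or an ROI plus regions of
avoidance) the trade-off between objectives is explored by keeping one
region's smoothed-max objective as the primary objective and turning
every other region's objective into an inequality constraint

    g_i(alpha) = max_S(F_i(X, alpha), beta_i) - eps_i <= 0,

then sweeping the caps eps_i to trace the Pareto front.  Each solve
uses the generalized Lagrangian

    L = max_S1 - sum_j lambda_j h_j - sum_i mu_i g_i

whose critical points must satisfy the Karush-Kuhn-Tucker conditions:
stationarity, primal feasibility (g <= 0, h = 0), dual feasibility
(mu >= 0), and complementary slackness (mu_i g_i = 0).  Complementary
slackness is resolved exactly by enumerating active sets: for each of
the 2^(Q-1) subsets of constraints assumed active, the corresponding
square root-finding problem is solved by the same multistart Newton
machinery as the single-objective case, and candidate solutions are
kept only if they pass the full KKT validation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .field_model import BasisFieldSet, RegionRole
from .smooth_ops import (
    Configuration,
    SmoothingParams,
    auto_beta,
    balance_constraints,
    balance_gradients,
    balance_h1_hessian_diag,
    smooth_max,
    smooth_max_grad,
    smooth_max_hessian,
)
from .single_objective import (
    CriticalPoint,
    SolverSettings,
    _dedup,
    classify_constrained,
    correct_fractions,
    multistart_solve,
    newton_solve,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EpsilonSchedule",
    "ParetoPoint",
    "ParetoFront",
    "residual_multi",
    "jacobian_multi",
    "validate_kkt",
    "solve_epsilon",
    "default_epsilon_schedule",
    "pareto_sweep",
    "dominance_filter",
]


@dataclass(frozen=True)
class EpsilonSchedule:
    """Ordered epsilon caps per constrained region (field units)."""

    bounds: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("schedule must cover at least one region")
        clean = {}
        for name, eps in self.bounds.items():
            eps = tuple(float(e) for e in eps)
            if len(eps) == 0:
                raise ValueError(f"empty epsilon list for region {name!r}")
            diffs = np.diff(eps)
            if len(eps) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError(
                    f"epsilon list for region {name!r} must be strictly monotone"
                )
            clean[name] = eps
        object.__setattr__(self, "bounds", clean)


@dataclass
class ParetoPoint:
    epsilon: dict[str, float]
    objectives: dict[str, float]      # true smooth-max value per region
    config: Configuration
    point: CriticalPoint
    nondominated: bool = False


@dataclass
class ParetoFront:
    """Sweep result: one candidate per epsilon combination that was feasible."""

    points: list[ParetoPoint]
    senses: dict[str, str]            # region name -> {"maximize", "minimize"}

    @property
    def nondominated(self) -> list[ParetoPoint]:
        return [p for p in self.points if p.nondominated]


def _region_order(basis_per_region: dict[str, BasisFieldSet],
                  primary: str) -> list[str]:
    if primary not in basis_per_region:
        raise KeyError(f"unknown primary region {primary!r}")
    return [primary] + [k for k in basis_per_region if k != primary]


def residual_multi(alpha, lam, mu, basis_per_region: dict[str, BasisFieldSet],
                   params: dict[str, SmoothingParams],
                   epsilon: dict[str, float], active_set: tuple[str, ...],
                   primary: str) -> np.ndarray:
    """KKT stationarity system for a fixed active set.

    Length n + 2 + |active_set|: stationarity in alpha, the two equality
    constraints, and g_i = 0 for each active inequality.  Inactive
    constraints do not appear (their multipliers are identically zero).
    """
    a = np.asarray(alpha, dtype=float).reshape(-1)
    l = np.asarray(lam, dtype=float).reshape(-1)
    m = np.asarray(mu, dtype=float).reshape(-1)
    for name in active_set:
        if name not in basis_per_region or name == primary:
            raise KeyError(f"active set names unknown region {name!r}")
    n = basis_per_region[primary].n
    if a.shape[0] != n or l.shape[0] != 2 or m.shape[0] != len(active_set):
        raise ValueError("dimension mismatch in residual_multi")
    p0 = params[primary]
    stat = smooth_max_grad(basis_per_region[primary], a, p0.beta)
    g1, g2 = balance_gradients(a, p0.gamma)
    h1, h2 = balance_constraints(a, p0.gamma)
    stat = stat - l[0] * g1 - l[1] * g2
    g_rows = []
    for mu_i, name in zip(m, active_set):
        b = basis_per_region[name]
        p = params[name]
        stat = stat - mu_i * smooth_max_grad(b, a, p.beta)
        g_rows.append(smooth_max(b.values @ a, p.beta) - epsilon[name])
    return np.concatenate([stat, [h1, h2], g_rows])


def jacobian_multi(alpha, lam, mu, basis_per_region, params, epsilon,
                   active_set, primary) -> np.ndarray:
    """Closed-form Jacobian of ``residual_multi``."""
    a = np.asarray(alpha, dtype=float).reshape(-1)
    l = np.asarray(lam, dtype=float).reshape(-1)
    m = np.asarray(mu, dtype=float).reshape(-1)
    n = a.shape[0]
    k = len(active_set)
    p0 = params[primary]
    H = smooth_max_hessian(basis_per_region[primary], a, p0.beta)
    H = H - l[0] * np.diag(balance_h1_hessian_diag(a, p0.gamma))
    g1, g2 = balance_gradients(a, p0.gamma)
    grads = []
    for mu_i, name in zip(m, active_set):
        b = basis_per_region[name]
        p = params[name]
        H = H - mu_i * smooth_max_hessian(b, a, p.beta)
        grads.append(smooth_max_grad(b, a, p.beta))
    J = np.zeros((n + 2 + k, n + 2 + k))
    J[:n, :n] = H
    J[:n, n] = -g1
    J[:n, n + 1] = -g2
    J[n, :n] = g1
    J[n + 1, :n] = g2
    for i, g in enumerate(grads):
        J[:n, n + 2 + i] = -g
        J[n + 2 + i, :n] = g
    return J


def validate_kkt(alpha, lam, mu_full: dict[str, float],
                 basis_per_region, params, epsilon, primary,
                 feas_tol: float = 1e-8, dual_tol: float = 1e-10,
                 slack_tol: float = 1e-8) -> tuple[bool, dict[str, bool]]:
    """Check the four KKT conditions for a candidate point.

    Returns overall validity plus a per-condition report:
    ``primal_inequality`` (g_i <= tol for all constrained regions),
    ``primal_equality`` (|h1|, |h2| <= tol), ``dual`` (mu_i >= -tol),
    and ``slackness`` (|mu_i * g_i| <= tol).  Tolerances on g scale
    with the region's field magnitude.
    """
    a = np.asarray(alpha, dtype=float).reshape(-1)
    p0 = params[primary]
    h1, h2 = balance_constraints(a, p0.gamma)
    report = {}
    report["primal_equality"] = abs(h1) <= 1e-6 and abs(h2) <= 1e-6
    ok_feas, ok_dual, ok_slack = True, True, True
    for name, mu_i in mu_full.items():
        b = basis_per_region[name]
        p = params[name]
        scale = max(1.0, float(np.max(np.abs(b.values))))
        g = smooth_max(b.values @ a, p.beta) - epsilon[name]
        if g > feas_tol * scale:
            ok_feas = False
        if mu_i < -dual_tol:
            ok_dual = False
        if abs(mu_i * g) > slack_tol * scale:
            ok_slack = False
    report["primal_inequality"] = ok_feas
    report["dual"] = ok_dual
    report["slackness"] = ok_slack
    return all(report.values()), report


def _common_scale(basis_per_region: dict[str, BasisFieldSet]) -> float:
    return max(float(np.max(np.abs(b.values))) for b in basis_per_region.values())


def _scaled_problem(basis_per_region, params, epsilon):
    """Divide every basis by a common scale so residuals are O(1).

    Objectives, epsilon caps, and multipliers all rescale by the same
    factor; beta rescales inversely, so the stationary alphas are
    unchanged.
    """
    scale = _common_scale(basis_per_region)
    scaled_b = {
        k: BasisFieldSet(region=b.region, values=b.values / scale,
                         contact_labels=b.contact_labels,
                         provenance=b.provenance)
        for k, b in basis_per_region.items()
    }
    scaled_p = {
        k: SmoothingParams(beta=p.beta * scale, gamma=p.gamma)
        for k, p in params.items()
    }
    scaled_eps = {k: e / scale for k, e in epsilon.items()}
    return scaled_b, scaled_p, scaled_eps, scale


def _bipole_scale(b: BasisFieldSet) -> float:
    col_max = np.max(b.values, axis=1)
    col_min = np.min(b.values, axis=1)
    return float(np.max(col_max - col_min))


def default_params(basis_per_region: dict[str, BasisFieldSet],
                   gamma: float = 100.0,
                   epsilon: dict[str, float] | None = None,
                   ) -> dict[str, SmoothingParams]:
    """Per-region smoothing scales.

    beta follows the rule beta * (relevant field magnitude) ~ 10.  For
    the primary region the relevant magnitude is the best attainable
    bipole field.  For a constrained region with a cap eps the relevant
    magnitude is the cap itself (the constraint pins the region's soft
    max at eps), floored at 1% of the region's bipole scale so beta
    stays finite as eps -> 0.
    """
    params = {}
    for name, b in basis_per_region.items():
        scale = _bipole_scale(b)
        if epsilon is not None and name in epsilon:
            scale = max(abs(epsilon[name]), 0.01 * scale)
        params[name] = SmoothingParams(beta=10.0 / scale, gamma=gamma)
    return params


def solve_epsilon(primary: str, constraint_regions: tuple[str, ...],
                  epsilon: dict[str, float],
                  basis_per_region: dict[str, BasisFieldSet],
                  params: dict[str, SmoothingParams] | None = None,
                  settings: SolverSettings | None = None,
                  ) -> list[CriticalPoint]:
    """Solve one epsilon-constrained problem by active-set enumeration.

    All 2^(Q-1) subsets of the inequality constraints are tried as the
    active set; each yields a square KKT root-finding problem solved by
    multistart Newton.  Solutions failing any KKT condition are
    discarded; survivors are classified with the active constraints
    included in the bordered Hessian, deduplicated, and the maxima of
    the primary objective returned sorted descending.
    """
    settings = settings or SolverSettings()
    if params is None:
        params = default_params(basis_per_region, epsilon=epsilon)
    sb, sp, se, scale = _scaled_problem(basis_per_region, params, epsilon)
    n = sb[primary].n
    points: list[CriticalPoint] = []
    for r in range(len(constraint_regions) + 1):
        for active in itertools.combinations(constraint_regions, r):
            points.extend(
                _solve_active_set(primary, constraint_regions, active,
                                  se, sb, sp, settings)
            )
    # report objectives in true field units
    for pt in points:
        pt.objective = {k: v * scale for k, v in pt.objective.items()}
    points = _dedup(points, settings.dedup_tol)
    maxima = [p for p in points if p.classification == "maximum"]
    maxima.sort(key=lambda p: -p.primary_objective)
    if not maxima:
        logger.warning("no valid KKT maximum found for epsilon=%s", epsilon)
    return maxima


def _locate_constrained(a0, active, epsilon, basis_per_region, params,
                        primary, max_iter: int = 300):
    """SLSQP locator: maximize the primary objective with the active
    inequality constraints pinned to equality and the rest enforced as
    inequalities.  Only used to land inside the KKT root's basin."""
    from scipy.optimize import minimize

    p0 = params[primary]
    b0 = basis_per_region[primary]
    n = b0.n
    cons = [
        {"type": "eq",
         "fun": lambda a: balance_constraints(a, p0.gamma)[0],
         "jac": lambda a: balance_gradients(a, p0.gamma)[0]},
        {"type": "eq",
         "fun": lambda a: balance_constraints(a, p0.gamma)[1],
         "jac": lambda a: balance_gradients(a, p0.gamma)[1]},
    ]
    for name in basis_per_region:
        if name == primary:
            continue
        b, p, eps = basis_per_region[name], params[name], epsilon[name]
        kind = "eq" if name in active else "ineq"
        sign = -1.0 if kind == "eq" else 1.0  # ineq means eps - g >= 0

        def g_fun(a, b=b, p=p, eps=eps, sign=sign):
            val = smooth_max(b.values @ a, p.beta) - eps
            return -val if sign > 0 else val

        def g_jac(a, b=b, p=p, sign=sign):
            g = smooth_max_grad(b, a, p.beta)
            return -g if sign > 0 else g

        cons.append({"type": kind, "fun": g_fun, "jac": g_jac})
    res = minimize(
        lambda a: -smooth_max(b0.values @ a, p0.beta),
        a0,
        jac=lambda a: -smooth_max_grad(b0, a, p0.beta),
        constraints=cons,
        bounds=[(-1.0, 1.0)] * n,
        method="SLSQP",
        options={"maxiter": max_iter, "ftol": 1e-14},
    )
    return res.x if np.all(np.isfinite(res.x)) else None


def _solve_active_set(primary, constraint_regions, active, epsilon,
                      basis_per_region, params, settings):
    from scipy.optimize import root

    from .single_objective import lstsq_multipliers, project_balanced

    n = basis_per_region[primary].n
    k = len(active)
    dim = n + 2 + k
    sampler = qmc.LatinHypercube(d=dim, seed=settings.seed + 7919 * (k + 1))
    draws = sampler.random(settings.n_starts)
    lo = np.array([settings.alpha_bounds[0]] * n
                  + [settings.multiplier_bounds[0]] * (2 + k))
    hi = np.array([settings.alpha_bounds[1]] * n
                  + [settings.multiplier_bounds[1]] * (2 + k))
    starts = qmc.scale(draws, lo, hi)

    def fun(z):
        return residual_multi(z[:n], z[n:n + 2], z[n + 2:],
                              basis_per_region, params, epsilon,
                              active, primary)

    def jac(z):
        return jacobian_multi(z[:n], z[n:n + 2], z[n + 2:],
                              basis_per_region, params, epsilon,
                              active, primary)

    def certify(x0):
        sol = root(fun, x0, jac=jac, method="hybr")
        x, rn = sol.x, float(np.linalg.norm(sol.fun))
        if rn > settings.residual_tol:
            x, rn, _ = newton_solve(fun, jac, x, tol=settings.residual_tol,
                                    max_iter=settings.max_iter)
        return x, rn

    p0 = params[primary]
    out: list[CriticalPoint] = []
    for i, x0 in enumerate(starts):
        candidates = [x0]
        a1 = _locate_constrained(project_balanced(x0[:n]), active, epsilon,
                                 basis_per_region, params, primary)
        if a1 is not None:
            g1, g2 = balance_gradients(a1, p0.gamma)
            rows = [g1, g2] + [
                smooth_max_grad(basis_per_region[name], a1,
                                params[name].beta)
                for name in active
            ]
            lam_mu = lstsq_multipliers(
                smooth_max_grad(basis_per_region[primary], a1, p0.beta),
                np.vstack(rows),
            )
            candidates.append(np.concatenate([a1, lam_mu]))
        for cand in candidates:
            x, rn = certify(cand)
            if rn > settings.residual_tol:
                continue
            out.append((x, rn, i))
            break

    solved, out = out, []
    for x, rn, i in solved:
        a_raw, lam, mu_act = x[:n], x[n:n + 2], x[n + 2:]
        if float(np.sum(np.abs(a_raw))) < 1e-8:
            continue
        mu_full = {name: 0.0 for name in constraint_regions}
        for name, mu_i in zip(active, mu_act):
            mu_full[name] = float(mu_i)
        valid, _report = validate_kkt(
            a_raw, lam, mu_full, basis_per_region, params, epsilon, primary
        )
        if not valid:
            continue
        try:
            corrected = correct_fractions(a_raw)
        except ValueError:
            continue
        classification = _classify_multi(
            a_raw, lam, mu_act, active, basis_per_region, params, primary
        )
        obj = {
            name: smooth_max(b.values @ a_raw, params[name].beta)
            for name, b in basis_per_region.items()
        }
        out.append(CriticalPoint(
            alpha=corrected, alpha_raw=a_raw, lam=lam,
            mu=np.array([mu_full[name] for name in constraint_regions]),
            residual_norm=rn, classification=classification,
            objective={primary: obj[primary],
                       **{k: v for k, v in obj.items() if k != primary}},
            start_index=i,
        ))
    return out


def _classify_multi(alpha, lam, mu_act, active, basis_per_region, params,
                    primary):
    p0 = params[primary]
    H = smooth_max_hessian(basis_per_region[primary], alpha, p0.beta)
    H = H - lam[0] * np.diag(balance_h1_hessian_diag(alpha, p0.gamma))
    g1, g2 = balance_gradients(alpha, p0.gamma)
    borders = [g1, g2]
    for mu_i, name in zip(mu_act, active):
        b = basis_per_region[name]
        p = params[name]
        H = H - mu_i * smooth_max_hessian(b, alpha, p.beta)
        borders.append(smooth_max_grad(b, alpha, p.beta))
    return classify_constrained(H, np.vstack(borders))


def default_epsilon_schedule(region_name: str, basis: BasisFieldSet,
                             params: SmoothingParams | None = None,
                             settings: SolverSettings | None = None,
                             n_points: int = 25) -> EpsilonSchedule:
    """Epsilon grid spanning the achievable range of one region's objective.

    The endpoints come from the two single-objective solves on that
    region: its unconstrained maximum and its minimum (the near-zero
    field configurations).
    """
    pts = multistart_solve(basis, params=params, settings=settings)
    if not pts:
        raise RuntimeError(
            f"could not bracket the objective range for region {region_name!r}"
        )
    objs = [p.primary_objective for p in pts]
    hi, lo = max(objs), min(objs)
    if hi <= lo:
        hi = lo + abs(lo) * 0.1 + 1e-12
    eps = np.linspace(lo, hi, n_points)
    return EpsilonSchedule(bounds={region_name: tuple(eps)})


def pareto_sweep(primary: str, constraint_regions: tuple[str, ...],
                 schedule: EpsilonSchedule,
                 basis_per_region: dict[str, BasisFieldSet],
                 params: dict[str, SmoothingParams] | None = None,
                 settings: SolverSettings | None = None) -> ParetoFront:
    """Trace the Pareto front by sweeping the epsilon caps.

    For every epsilon combination in the schedule the constrained
    problem is solved (with the constrained regions' beta adapted to the
    cap when ``params`` is None) and the best valid maximum kept; the
    reported objectives are the exact pointwise maxima of each region's
    field at the corrected fractions, so that points solved at
    different caps are compared on a common scale.  Dominance flags are
    assigned under each region's sense (ROI: maximize, ROA: minimize).
    """
    settings = settings or SolverSettings()
    for name in constraint_regions:
        if name not in schedule.bounds:
            raise KeyError(f"schedule missing epsilon list for {name!r}")
    senses = {}
    for name, b in basis_per_region.items():
        senses[name] = ("minimize" if b.region.role is RegionRole.ROA
                        else "maximize")
    names = list(constraint_regions)
    grids = [schedule.bounds[name] for name in names]
    points: list[ParetoPoint] = []
    for combo in itertools.product(*grids):
        epsilon = dict(zip(names, combo))
        p_eps = params
        if p_eps is None:
            p_eps = default_params(basis_per_region, epsilon=epsilon)
        sols = solve_epsilon(primary, constraint_regions, epsilon,
                             basis_per_region, p_eps, settings)
        if not sols:
            continue
        best = sols[0]
        objectives = {
            name: float(np.max(b.values @ best.alpha.alpha))
            for name, b in basis_per_region.items()
        }
        points.append(ParetoPoint(
            epsilon=epsilon, objectives=objectives,
            config=best.alpha, point=best,
        ))
    if not points:
        logger.warning("no feasible epsilon in the schedule; empty front")
        return ParetoFront(points=[], senses=senses)
    order = [primary] + names
    vecs = [np.array([p.objectives[name] for name in order]) for p in points]
    flags = _nondominated_flags(vecs, [senses[name] for name in order])
    for p, f in zip(points, flags):
        p.nondominated = bool(f)
    return ParetoFront(points=points, senses=senses)


def _nondominated_flags(vectors, senses) -> np.ndarray:
    """O(n^2) dominance scan; sense 'minimize' flips the comparison."""
    sign = np.array([1.0 if s == "maximize" else -1.0 for s in senses])
    V = np.array([np.asarray(v, dtype=float) * sign for v in vectors])
    n = V.shape[0]
    flags = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.all(V[j] >= V[i]) and np.any(V[j] > V[i]):
                flags[i] = False
                break
    return flags


def dominance_filter(points, senses):
    """Return the nondominated subset of objective vectors, order-stable.

    ``points`` is a sequence of equal-length objective vectors and
    ``senses`` the per-objective sense ("maximize" or "minimize").
    """
    vecs = [np.asarray(p, dtype=float).reshape(-1) for p in points]
    if not vecs:
        return []
    dims = {v.shape[0] for v in vecs}
    if len(dims) != 1:
        raise ValueError("all points must share the same dimensionality")
    if len(senses) != dims.pop():
        raise ValueError("one sense per objective dimension is required")
    flags = _nondominated_flags(vecs, list(senses))
    return [p for p, f in zip(points, flags) if f]
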