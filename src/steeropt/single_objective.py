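"""Single-objective current-fraction optimization via Lagrange multipliers.

The problem is: maximize the smoothed maximum of the excitation field
over a region of interest, subject to the two smoothed balance
constraints h1 (sum of |alpha| equals 2) and h2 (net current zero).
The Lagrangian

    L(alpha, lambda) = max_S(F(X, alpha), beta)
                       - lambda_1 h1(alpha) - lambda_2 h2(alpha)

is stationary where its gradient vanishes, which gives a square system
of n + 2 nonlinear equations (n fractions plus 2 multipliers).  The
system is solved by damped Newton iteration with the analytic Jacobian
from many Latin-hypercube initial guesses; converged solutions are
deduplicated and classified as maxima, minima, or saddle points via the
bordered Hessian minor test (with a projected-eigenvalue fallback for
near-singular minors).

Solutions of the smoothed problem satisfy the exact balance rules only
approximately, so a converged solution alpha* is rescaled to
2*alpha*/sum|alpha*| ("corrected"), and finally rounded to three
significant digits with the rounding residual folded back into the
largest entries so the rounded fractions still balance exactly
("rounded"), matching what a clinical device can actually be programmed
with.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import null_space
from scipy.stats import qmc

from .field_model import BasisFieldSet
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

logger = logging.getLogger(__name__)

__all__ = [
    "SolverSettings",
    "CriticalPoint",
    "residual_single",
    "jacobian_single",
    "newton_solve",
    "multistart_solve",
    "classify",
    "classify_constrained",
    "correct_fractions",
    "round_fractions",
]


@dataclass(frozen=True)
class SolverSettings:
    """Multistart root-solver configuration.

    Initial current-fraction guesses are drawn in ``alpha_bounds`` and
    multiplier guesses in ``multiplier_bounds`` by Latin hypercube
    sampling; runs are deterministic for a fixed ``seed``.
    """

    n_starts: int = 200
    alpha_bounds: tuple[float, float] = (-1.0, 1.0)
    multiplier_bounds: tuple[float, float] = (-10.0, 10.0)
    seed: int = 0
    residual_tol: float = 1e-10
    max_iter: int = 200
    dedup_tol: float = 1e-4
    rounding_digits: int = 3

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        for name in ("residual_tol", "dedup_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CriticalPoint:
    """A converged stationary point of the (generalized) Lagrangian."""

    alpha: Configuration          # corrected fractions (sum|alpha| = 2)
    alpha_raw: np.ndarray         # solver output before correction
    lam: np.ndarray               # 2 equality multipliers (scaled problem)
    mu: np.ndarray                # inequality multipliers (may be empty)
    residual_norm: float
    classification: str           # {maximum, minimum, saddle, invalid}
    objective: dict[str, float]   # region name -> smooth-max value
    start_index: int = -1
    reason: str = ""

    @property
    def primary_objective(self) -> float:
        return next(iter(self.objective.values()))


def residual_single(alpha, lam, basis: BasisFieldSet,
                    params: SmoothingParams) -> np.ndarray:
    """Stationarity system of the single-objective Lagrangian (length n+2).

    Entries 0..n-1: grad_alpha max_S - lam1*grad h1 - lam2*grad h2;
    entries n, n+1: the constraint residuals h1 and h2.
    """
    a = np.asarray(alpha, dtype=float).reshape(-1)
    l = np.asarray(lam, dtype=float).reshape(-1)
    if a.shape[0] != basis.n or l.shape[0] != 2:
        raise ValueError("dimension mismatch in residual_single")
    g_obj = smooth_max_grad(basis, a, params.beta)
    g1, g2 = balance_gradients(a, params.gamma)
    h1, h2 = balance_constraints(a, params.gamma)
    r = np.empty(a.shape[0] + 2)
    r[:-2] = g_obj - l[0] * g1 - l[1] * g2
    r[-2] = h1
    r[-1] = h2
    return r


def jacobian_single(alpha, lam, basis: BasisFieldSet,
                    params: SmoothingParams) -> np.ndarray:
    """Closed-form Jacobian of ``residual_single`` ((n+2) x (n+2))."""
    a = np.asarray(alpha, dtype=float).reshape(-1)
    l = np.asarray(lam, dtype=float).reshape(-1)
    if a.shape[0] != basis.n or l.shape[0] != 2:
        raise ValueError("dimension mismatch in jacobian_single")
    n = a.shape[0]
    H = smooth_max_hessian(basis, a, params.beta)
    H = H - l[0] * np.diag(balance_h1_hessian_diag(a, params.gamma))
    g1, g2 = balance_gradients(a, params.gamma)
    J = np.zeros((n + 2, n + 2))
    J[:n, :n] = H
    J[:n, n] = -g1
    J[:n, n + 1] = -g2
    J[n, :n] = g1
    J[n + 1, :n] = g2
    return J


def newton_solve(fun, jac, x0, tol: float = 1e-10, max_iter: int = 200):
    """Damped Newton iteration with backtracking on the residual norm.

    Returns ``(x, residual_norm, converged)``.  Singular Jacobians fall
    back to a least-squares step; steps that cannot reduce the residual
    terminate the iteration.
    """
    x = np.asarray(x0, dtype=float).copy()
    r = fun(x)
    rn = float(np.linalg.norm(r))
    for _ in range(max_iter):
        if not np.all(np.isfinite(r)):
            return x, np.inf, False
        if rn <= tol:
            return x, rn, True
        J = jac(x)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            return x, rn, False
        t = 1.0
        while t >= 1e-4:
            x_new = x + t * step
            r_new = fun(x_new)
            rn_new = float(np.linalg.norm(r_new))
            if np.isfinite(rn_new) and rn_new < (1.0 - 1e-4 * t) * rn:
                break
            t *= 0.5
        else:
            return x, rn, rn <= tol
        x, r, rn = x_new, r_new, rn_new
    return x, rn, rn <= tol


def _normalized(basis: BasisFieldSet) -> tuple[BasisFieldSet, float]:
    """Rescale basis values to O(1) so the Newton residual is well scaled.

    The objective is linear in the basis, so solving with B/scale and
    beta*scale yields the same stationary alpha; multipliers and
    objectives pick up a factor 1/scale and scale respectively.
    """
    scale = float(np.max(np.abs(basis.values)))
    if scale == 0.0:
        raise ValueError("basis fields are identically zero")
    scaled = BasisFieldSet(
        region=basis.region,
        values=basis.values / scale,
        contact_labels=basis.contact_labels,
        provenance=basis.provenance,
    )
    return scaled, scale


def classify_constrained(H_L: np.ndarray, Jg: np.ndarray,
                         minor_tol: float = 1e-10) -> str:
    """Classify a constrained stationary point from its curvature.

    ``H_L`` is the Hessian of the Lagrangian in the primal variables and
    ``Jg`` the (k x n) Jacobian of the active constraints.  The bordered
    Hessian [[0, Jg], [Jg^T, H_L]] is formed and the signs of its last
    n - k leading principal minors applied: all of sign (-1)^k means a
    minimum, alternating signs ending with (-1)^n means a maximum,
    anything else a saddle.  When any tested minor has magnitude below
    ``minor_tol`` the test is inconclusive and the eigenvalues of H_L
    projected onto the constraint tangent space decide instead.
    """
    Jg = np.atleast_2d(Jg)
    k, n = Jg.shape
    if np.linalg.matrix_rank(Jg) < k:
        return "invalid"
    if n - k <= 0:
        # no tangent directions: the point is the entire feasible set locally
        return "maximum"
    M = np.zeros((n + k, n + k))
    M[:k, k:] = Jg
    M[k:, :k] = Jg.T
    M[k:, k:] = H_L
    minors = []
    for order in range(2 * k + 1, n + k + 1):
        minors.append(float(np.linalg.det(M[:order, :order])))
    if all(abs(d) >= minor_tol for d in minors):
        signs = [math.copysign(1.0, d) for d in minors]
        min_pattern = [(-1.0) ** k] * len(minors)
        max_pattern = [(-1.0) ** (k + i + 1) for i in range(len(minors))]
        if signs == min_pattern:
            return "minimum"
        if signs == max_pattern:
            return "maximum"
        return "saddle"
    # fallback: eigenvalues of the Hessian restricted to the tangent space.
    # Semidefinite cases (exactly flat directions arise from symmetric
    # geometries where equivalent optima form a continuum) are resolved
    # by the strictly curved directions: a negative-semidefinite
    # projection with at least one strictly negative direction is a
    # (weak) maximum, and symmetrically for minima.
    Z = null_space(Jg)
    eig = np.linalg.eigvalsh(Z.T @ H_L @ Z)
    scale = max(1.0, float(np.max(np.abs(eig))) if eig.size else 1.0)
    tol = 1e-8 * scale
    has_neg, has_pos = np.any(eig < -tol), np.any(eig > tol)
    if has_neg and not has_pos:
        return "maximum"
    if has_pos and not has_neg:
        return "minimum"
    if not has_neg and not has_pos:
        # locally constant objective on the feasible set (e.g. a capped
        # objective identical to the primary): every point is a weak
        # extremum; label it a maximum so degenerate capped solves
        # remain reportable
        return "maximum"
    return "saddle"


def classify(point: CriticalPoint, basis: BasisFieldSet,
             params: SmoothingParams) -> str:
    """Bordered-Hessian classification of a single-objective critical point."""
    a = point.alpha_raw
    H = smooth_max_hessian(basis, a, params.beta)
    H = H - point.lam[0] * np.diag(balance_h1_hessian_diag(a, params.gamma))
    g1, g2 = balance_gradients(a, params.gamma)
    return classify_constrained(H, np.vstack([g1, g2]))


def correct_fractions(alpha_star, imbalance_tol: float = 1e-6) -> Configuration:
    """Rescale a balanced solver output so that sum|alpha| = 2 exactly."""
    a = np.asarray(alpha_star, dtype=float).reshape(-1)
    total = float(np.sum(np.abs(a)))
    if total == 0.0:
        raise ValueError("cannot correct an all-zero configuration")
    if abs(float(np.sum(a))) > imbalance_tol:
        raise ValueError(
            f"configuration is not balanced: sum alpha = {np.sum(a):.3e}"
        )
    corrected = 2.0 * a / total
    # guard against |alpha_i| = 1 + few ulp after the rescale
    corrected = np.clip(corrected, -1.0, 1.0)
    return Configuration(alpha=corrected, provenance="corrected")


def _round_sig(x: float, digits: int) -> float:
    if x == 0.0:
        return 0.0
    e = math.floor(math.log10(abs(x)))
    return round(x, -(e - digits + 1))


def round_fractions(config: Configuration, digits: int = 3) -> Configuration:
    """Round fractions to ``digits`` significant digits, re-balancing exactly.

    After per-entry rounding, the residuals of the positive and negative
    sums are folded into the largest-magnitude positive and negative
    entries so the exact balance rules hold at the reported precision.
    Raises if the required adjustment exceeds n half-units in the last
    place (which would mean the rounding cannot be reconciled).
    """
    if config.provenance not in ("corrected", "rounded"):
        raise ValueError("round_fractions expects a corrected configuration")
    a = np.array([_round_sig(x, digits) for x in config.alpha])
    n = a.shape[0]
    pos = a > 0
    neg = a < 0
    if not pos.any() or not neg.any():
        raise ValueError("configuration must contain both polarities")
    for mask, target in ((pos, 1.0), (neg, -1.0)):
        idx = np.flatnonzero(mask)
        j = idx[np.argmax(np.abs(a[idx]))]
        residual = target - float(np.sum(a[mask]))
        adjusted = a[j] + residual
        ulp = 10.0 ** (math.floor(math.log10(abs(adjusted))) - digits + 1)
        if abs(residual) > n * 0.5 * ulp + 1e-15:
            raise ValueError(
                f"rounding residual {residual:.3e} exceeds {n} half-ulp; "
                "cannot reconcile rounded fractions with the balance rules"
            )
        a[j] = adjusted
    if abs(float(np.sum(a[a > 0])) - 1.0) > 1e-12:
        raise ValueError("positive fractions failed to sum to 1 after rounding")
    if abs(float(np.sum(a[a < 0])) + 1.0) > 1e-12:
        raise ValueError("negative fractions failed to sum to -1 after rounding")
    return Configuration(alpha=a, provenance="rounded")


def _dedup(points: list[CriticalPoint], tol: float) -> list[CriticalPoint]:
    kept: list[CriticalPoint] = []
    for p in sorted(points, key=lambda p: p.residual_norm):
        if any(
            np.max(np.abs(p.alpha.alpha - q.alpha.alpha)) < tol for q in kept
        ):
            continue
        kept.append(p)
    return kept


def project_balanced(alpha: np.ndarray) -> np.ndarray:
    """Project onto the exact balance rules (anodes +1, cathodes -1).

    If a draw is all one sign, the smallest-magnitude entry's sign is
    flipped first so both polarities exist.
    """
    a = np.asarray(alpha, dtype=float).copy()
    if not np.any(a > 0) or not np.any(a < 0):
        a[np.argmin(np.abs(a))] *= -1.0
        if not np.any(a > 0) or not np.any(a < 0):  # a zero entry was flipped
            j = np.argmin(np.abs(a))
            a[j] = 0.5 if np.all(a <= 0) else -0.5
    pos, neg = a > 0, a < 0
    a[pos] /= np.sum(a[pos])
    a[neg] /= -np.sum(a[neg])
    return a


def lstsq_multipliers(grad_obj: np.ndarray,
                      constraint_grads: np.ndarray) -> np.ndarray:
    """Least-squares multipliers: argmin ||grad_obj - Jg^T lam||."""
    lam, *_ = np.linalg.lstsq(constraint_grads.T, grad_obj, rcond=None)
    return lam


def _locate_extremum(basis: BasisFieldSet, a0: np.ndarray,
                     params: SmoothingParams, sense: float,
                     max_iter: int = 300) -> np.ndarray | None:
    """SLSQP pass: drive a0 to a constrained extremum of the objective.

    ``sense`` +1 maximizes the smoothed objective, -1 minimizes it.
    Used only to land inside a Newton basin; the certified solution
    always comes from the stationarity system afterwards.
    """
    from scipy.optimize import minimize

    beta, gamma = params.beta, params.gamma
    n = basis.n
    cons = [
        {"type": "eq",
         "fun": lambda a: balance_constraints(a, gamma)[0],
         "jac": lambda a: balance_gradients(a, gamma)[0]},
        {"type": "eq",
         "fun": lambda a: balance_constraints(a, gamma)[1],
         "jac": lambda a: balance_gradients(a, gamma)[1]},
    ]
    res = minimize(
        lambda a: -sense * smooth_max(basis.values @ a, beta),
        a0,
        jac=lambda a: -sense * smooth_max_grad(basis, a, beta),
        constraints=cons,
        bounds=[(-1.0, 1.0)] * n,
        method="SLSQP",
        options={"maxiter": max_iter, "ftol": 1e-14},
    )
    return res.x if np.all(np.isfinite(res.x)) else None


def _certify_root(basis: BasisFieldSet, x0: np.ndarray,
                  params: SmoothingParams, settings: SolverSettings):
    """Solve the stationarity system from x0: Powell hybrid, Newton polish."""
    from scipy.optimize import root

    n = basis.n

    def fun(z):
        return residual_single(z[:n], z[n:], basis, params)

    def jac(z):
        return jacobian_single(z[:n], z[n:], basis, params)

    sol = root(fun, x0, jac=jac, method="hybr")
    x, rn = sol.x, float(np.linalg.norm(sol.fun))
    if rn > settings.residual_tol:
        x, rn, _ = newton_solve(fun, jac, x, tol=settings.residual_tol,
                                max_iter=settings.max_iter)
    return x, rn


def multistart_solve(basis: BasisFieldSet,
                     params: SmoothingParams | None = None,
                     settings: SolverSettings | None = None,
                     ) -> list[CriticalPoint]:
    """Find critical points of the single-objective Lagrangian.

    Latin-hypercube draws of (alpha, lambda) within the configured
    bounds seed the root solver.  Each draw is used three ways: a direct
    root solve of the stationarity system, and two SLSQP locator passes
    (maximizing and minimizing the smoothed objective under the balance
    constraints) whose endpoints are certified by re-solving the
    stationarity system to ``residual_tol``.  The locator passes are
    needed because the antisymmetric near-zero-field configurations form
    an almost-flat manifold that captures nearly every naive root solve.
    Non-converged starts are discarded, survivors deduplicated (L-inf
    distance on corrected alpha), classified via the bordered Hessian,
    and returned sorted by objective value, descending.  Deterministic
    for a fixed seed; returns an empty list (with a logged warning) when
    nothing converges.

    When ``params`` is None, beta is chosen so that beta times the best
    attainable bipole field is about 10, with gamma = 100.
    """
    settings = settings or SolverSettings()
    scaled, scale = _normalized(basis)
    if params is None:
        sparams = SmoothingParams(beta=auto_beta(scaled))
    else:
        sparams = SmoothingParams(beta=params.beta * scale,
                                  gamma=params.gamma)
    n = basis.n
    sampler = qmc.LatinHypercube(d=n + 2, seed=settings.seed)
    draws = sampler.random(settings.n_starts)
    lo = np.array([settings.alpha_bounds[0]] * n
                  + [settings.multiplier_bounds[0]] * 2)
    hi = np.array([settings.alpha_bounds[1]] * n
                  + [settings.multiplier_bounds[1]] * 2)
    starts = qmc.scale(draws, lo, hi)

    points: list[CriticalPoint] = []
    n_discarded = 0
    for i, x0 in enumerate(starts):
        candidates = [x0]
        a0 = project_balanced(x0[:n])
        for sense in (+1.0, -1.0):
            a1 = _locate_extremum(scaled, a0, sparams, sense)
            if a1 is None:
                continue
            g1, g2 = balance_gradients(a1, sparams.gamma)
            lam = lstsq_multipliers(
                smooth_max_grad(scaled, a1, sparams.beta),
                np.vstack([g1, g2]),
            )
            candidates.append(np.concatenate([a1, lam]))
        converged_any = False
        for cand in candidates:
            x, rn = _certify_root(scaled, cand, sparams, settings)
            if rn > settings.residual_tol:
                continue
            a_raw, lam = x[:n], x[n:]
            if float(np.sum(np.abs(a_raw))) < 1e-8:
                continue  # trivial all-zero point
            try:
                corrected = correct_fractions(a_raw)
            except ValueError:
                continue
            converged_any = True
            obj = scale * smooth_max(scaled.values @ a_raw, sparams.beta)
            pt = CriticalPoint(
                alpha=corrected,
                alpha_raw=a_raw,
                lam=lam,
                mu=np.empty(0),
                residual_norm=rn,
                classification="unclassified",
                objective={basis.region.name: obj},
                start_index=i,
            )
            pt.classification = classify(pt, scaled, sparams)
            points.append(pt)
        if not converged_any:
            n_discarded += 1

    if n_discarded:
        logger.info("discarded %d/%d starts with no converged candidate",
                    n_discarded, settings.n_starts)
    if not points:
        logger.warning("no multistart run converged; returning empty list")
        return []
    points = _dedup(points, settings.dedup_tol)
    points.sort(key=lambda p: -p.primary_objective)
    return points
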