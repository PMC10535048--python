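"""Differentiable surrogates for max and |.|, and the current-balance constraints.

Current fractions ``alpha`` across ``n`` contacts must satisfy the
balance rules: positive fractions (anodes) sum to +1 and negative
fractions (cathodes) sum to -1.  These conditional statements are not
differentiable as written, so they are replaced by the equivalent pair

    h1(alpha) = 2 - sum_i alpha_i * tanh(gamma * alpha_i) = 0
    h2(alpha) = sum_i alpha_i = 0

where ``alpha*tanh(gamma*alpha)`` is a smooth, even approximation of
``|alpha|`` controlled by ``gamma > 0``.  Likewise the non-smooth max of
the field over region points is replaced by the Boltzmann operator

    max_S(v, beta) = sum_i v_i e^{beta v_i} / sum_i e^{beta v_i},

which tends to ``max(v)`` as ``beta -> +inf`` and to ``min(v)`` as
``beta -> -inf`` (so a negative ``beta`` selects the largest negative
field value).  In practice ``beta * max|v| ~ 10`` already gives an
excellent approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .field_model import BasisFieldSet

__all__ = [
    "SmoothingParams",
    "Configuration",
    "smooth_max",
    "smooth_max_weights",
    "smooth_max_grad",
    "smooth_max_hessian",
    "smooth_abs",
    "balance_constraints",
    "balance_gradients",
    "balance_h1_hessian_diag",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Scales of the two smoothing surrogates.

    beta : smooth-max scale, reciprocal field units.  Its sign selects
        whether the largest positive (beta > 0) or largest negative
        (beta < 0) field value is tracked.
    gamma : smooth-abs scale, dimensionless; larger is sharper.
    """

    beta: float
    gamma: float = 100.0

    def __post_init__(self) -> None:
        if self.beta == 0.0 or not np.isfinite(self.beta):
            raise ValueError("beta must be nonzero and finite")
        if self.gamma <= 0.0 or not np.isfinite(self.gamma):
            raise ValueError("gamma must be positive and finite")


@dataclass(frozen=True)
class Configuration:
    """A vector of contact current fractions with a provenance tag.

    ``raw`` solutions come straight from the root solver and satisfy the
    smoothed constraints only approximately; ``corrected`` and
    ``rounded`` configurations satisfy the exact balance rules.
    """

    alpha: np.ndarray
    provenance: str = "raw"  # {"raw", "corrected", "rounded"}

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float).reshape(-1)
        if not np.all(np.isfinite(a)):
            raise ValueError("current fractions must be finite")
        if self.provenance not in ("raw", "corrected", "rounded"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance in ("corrected", "rounded"):
            if abs(np.sum(np.abs(a)) - 2.0) > 1e-9:
                raise ValueError("corrected fractions must satisfy sum|alpha| = 2")
            if abs(np.sum(a)) > 1e-9:
                raise ValueError("corrected fractions must satisfy sum alpha = 0")
            if np.any(np.abs(a) > 1.0 + 1e-9):
                raise ValueError("each |alpha_i| must be at most 1")
        object.__setattr__(self, "alpha", a)

    @property
    def n(self) -> int:
        return self.alpha.shape[0]


def smooth_max(values, beta: float) -> float:
    """Boltzmann-weighted soft maximum of ``values``.

    Overflow-safe: the exponent is shifted by its maximum before
    exponentiation.  For ``beta > 0`` the result lies between the mean
    and the maximum of ``values``.
    """
    v = np.asarray(values, dtype=float).reshape(-1)
    if v.size == 0:
        raise ValueError("smooth_max of an empty vector is undefined")
    if beta == 0.0:
        raise ValueError("beta must be nonzero")
    e = beta * v
    w = np.exp(e - np.max(e))
    return float(np.sum(v * w) / np.sum(w))


def smooth_max_weights(values, beta: float) -> np.ndarray:
    """Softmax weights w_i = e^{beta v_i} / sum_j e^{beta v_j}."""
    v = np.asarray(values, dtype=float).reshape(-1)
    e = beta * v
    w = np.exp(e - np.max(e))
    return w / np.sum(w)


def _soft_sensitivity(values: np.ndarray, beta: float):
    """d smooth_max / d v_j = w_j * (1 + beta*(v_j - S))."""
    v = np.asarray(values, dtype=float).reshape(-1)
    w = smooth_max_weights(v, beta)
    s = float(np.sum(w * v))
    d = w * (1.0 + beta * (v - s))
    return w, s, d


def smooth_max_grad(basis: BasisFieldSet, alpha, beta: float) -> np.ndarray:
    """Gradient of ``smooth_max(superpose(basis, alpha), beta)`` w.r.t. alpha."""
    a = np.asarray(alpha, dtype=float).reshape(-1)
    if a.shape[0] != basis.n:
        raise ValueError("alpha length does not match the basis contact count")
    f = basis.values @ a
    _, _, d = _soft_sensitivity(f, beta)
    return basis.values.T @ d


def smooth_max_hessian(basis: BasisFieldSet, alpha, beta: float) -> np.ndarray:
    """Hessian of the smoothed objective w.r.t. alpha (n x n, symmetric).

    With w the softmax weights, S the smooth max and d the per-point
    sensitivities, the field-space Hessian is

        H_jk = beta*w_j*(delta_jk - w_k) * (1 + beta*(v_j - S))
               + beta*w_j*delta_jk - beta*w_j*d_k

    and the alpha-space Hessian is B^T H B.
    """
    a = np.asarray(alpha, dtype=float).reshape(-1)
    if a.shape[0] != basis.n:
        raise ValueError("alpha length does not match the basis contact count")
    B = basis.values
    v = B @ a
    w, s, d = _soft_sensitivity(v, beta)
    m = v.shape[0]
    coef = 1.0 + beta * (v - s)  # d_j = w_j * coef_j
    H = beta * (w * coef)[:, None] * (np.eye(m) - w[None, :])
    H += beta * np.diag(w)
    H -= beta * np.outer(w, d)
    return B.T @ H @ B


def smooth_abs(alpha, gamma: float) -> np.ndarray:
    """Elementwise alpha*tanh(gamma*alpha): smooth, even, and <= |alpha|."""
    if gamma <= 0.0:
        raise ValueError("gamma must be positive")
    a = np.asarray(alpha, dtype=float)
    return a * np.tanh(gamma * a)


def balance_constraints(alpha, gamma: float) -> tuple[float, float]:
    """Residuals of the two smoothed balance constraints.

    h1 = 2 - sum alpha_i*tanh(gamma*alpha_i) and h2 = sum alpha_i; both
    vanish at an exactly balanced configuration (for large gamma).
    """
    a = np.asarray(alpha, dtype=float).reshape(-1)
    h1 = 2.0 - float(np.sum(smooth_abs(a, gamma)))
    h2 = float(np.sum(a))
    return h1, h2


def balance_gradients(alpha, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of (h1, h2) w.r.t. alpha.

    d h1/d alpha_j = -[tanh(g a_j) + g a_j sech^2(g a_j)];
    d h2/d alpha_j = 1.
    """
    a = np.asarray(alpha, dtype=float).reshape(-1)
    t = np.tanh(gamma * a)
    sech2 = 1.0 - t * t
    g1 = -(t + gamma * a * sech2)
    g2 = np.ones_like(a)
    return g1, g2


def balance_h1_hessian_diag(alpha, gamma: float) -> np.ndarray:
    """Diagonal of the (diagonal) Hessian of h1.

    d^2 h1/d alpha_j^2 = -2*gamma*sech^2(g a_j)*(1 - g a_j tanh(g a_j)).
    """
    a = np.asarray(alpha, dtype=float).reshape(-1)
    t = np.tanh(gamma * a)
    sech2 = 1.0 - t * t
    return -2.0 * gamma * sech2 * (1.0 - gamma * a * t)


def auto_beta(basis: BasisFieldSet, target_product: float = 10.0,
              sign: float = 1.0) -> float:
    """Pick beta so that |beta| * (attainable field scale) ~ target_product.

    The scale is the largest field magnitude reachable by any two-contact
    bipole, a cheap proxy for the magnitude at the optimum; the sign of
    ``sign`` selects soft-max (+) vs soft-min (-) behavior.
    """
    B = basis.values
    # max over points of |f_j - f_k| over all contact pairs = bipole fields
    col_max = np.max(B, axis=1)
    col_min = np.min(B, axis=1)
    scale = float(np.max(col_max - col_min))
    if scale <= 0.0:
        scale = float(np.max(np.abs(B)))
    if scale == 0.0:
        raise ValueError("basis fields are identically zero; beta undefined")
    return float(np.sign(sign)) * target_product / scale
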