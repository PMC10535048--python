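"""Reference configurations: seeded random draws and exhaustive bipoles.

Optimized current fractions are only convincing relative to what naive
strategies achieve.  Two references are provided: (a) random balanced
configurations — a random sign pattern with uniform spacings normalized
so anodes sum to +1 and cathodes to -1 — and (b) the complete set of
bipolar configurations (one cathode at -1, one anode at +1, all other
contacts off), which is what an experienced programmer would sweep by
hand.  Baseline objectives use the exact pointwise maximum of the field
over the region (no smoothing is needed since nothing is differentiated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_model import BasisFieldSet, superpose
from .smooth_ops import Configuration

__all__ = [
    "BaselineReport",
    "sample_random_configuration",
    "enumerate_bipolar",
    "exact_objective",
    "baseline_report",
]


@dataclass
class BaselineReport:
    random_objectives: np.ndarray
    bipolar_objectives: np.ndarray
    bipolar_pairs: list[tuple[str, str]]      # (cathode, anode) labels
    summary: dict[str, float]                 # mean / percentiles of randoms
    deficit: float | None                     # 1 - mean(random)/optimum
    best_bipolar: tuple[str, str] | None


def sample_random_configuration(n: int, rng: np.random.Generator) -> Configuration:
    """Draw a balanced random configuration on n contacts.

    A random nonempty sign pattern (at least one anode and one cathode)
    is drawn, then independent uniform spacings are normalized so the
    positive fractions sum to +1 and the negative to -1 exactly.
    """
    if n < 2:
        raise ValueError("need at least 2 contacts")
    while True:
        signs = rng.integers(0, 2, size=n) * 2 - 1
        if np.any(signs > 0) and np.any(signs < 0):
            break
    u = rng.random(n)
    alpha = np.zeros(n)
    pos = signs > 0
    neg = ~pos
    alpha[pos] = u[pos] / np.sum(u[pos])
    alpha[neg] = -u[neg] / np.sum(u[neg])
    return Configuration(alpha=alpha, provenance="corrected")


def enumerate_bipolar(n: int) -> list[tuple[int, int, Configuration]]:
    """All n*(n-1) ordered (cathode, anode) bipoles.

    Returns (cathode index, anode index, configuration) triples with
    -1 at the cathode and +1 at the anode.
    """
    if n < 2:
        raise ValueError("need at least 2 contacts")
    out = []
    for c in range(n):
        for a in range(n):
            if a == c:
                continue
            alpha = np.zeros(n)
            alpha[c] = -1.0
            alpha[a] = 1.0
            out.append((c, a, Configuration(alpha=alpha, provenance="corrected")))
    return out


def exact_objective(basis: BasisFieldSet, config: Configuration) -> float:
    """Exact maximum of the superposed field over the region points."""
    return float(np.max(superpose(basis, config.alpha)))


def baseline_report(basis: BasisFieldSet, optimum_objective: float,
                    n_random: int = 10_000,
                    rng: np.random.Generator | None = None) -> BaselineReport:
    """Compare random and bipolar configurations against an optimum.

    The deficit is 1 - mean(random objectives)/optimum; it is omitted
    (None) when the optimum is not positive.
    """
    rng = rng or np.random.default_rng(0)
    rand_obj = np.array([
        exact_objective(basis, sample_random_configuration(basis.n, rng))
        for _ in range(n_random)
    ])
    bip = enumerate_bipolar(basis.n)
    bip_obj = np.array([exact_objective(basis, cfg) for _, _, cfg in bip])
    pairs = [(basis.contact_labels[c], basis.contact_labels[a])
             for c, a, _ in bip]
    summary = {
        "mean": float(np.mean(rand_obj)),
        "p05": float(np.percentile(rand_obj, 5)),
        "p50": float(np.percentile(rand_obj, 50)),
        "p95": float(np.percentile(rand_obj, 95)),
    }
    deficit = None
    if optimum_objective > 0:
        deficit = 1.0 - summary["mean"] / optimum_objective
    best = pairs[int(np.argmax(bip_obj))] if pairs else None
    return BaselineReport(
        random_objectives=rand_obj,
        bipolar_objectives=bip_obj,
        bipolar_pairs=pairs,
        summary=summary,
        deficit=deficit,
        best_bipolar=best,
    )
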