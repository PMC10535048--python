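"""Unit-current basis fields in an anisotropic volume conductor.

The electric potential of a monopole point source carrying current ``I``
(amperes) in an unbounded homogeneous medium with a diagonal conductivity
tensor ``diag(sigma_xx, sigma_yy, sigma_zz)`` is

    V(p) = I / (4*pi*sqrt(sxx*syy*szz))
           * 1 / sqrt(dx^2/sxx + dy^2/syy + dz^2/szz)

where ``(dx, dy, dz)`` is the displacement from the source.  Two field
quantities derived from ``V`` predict neural excitation:

* the *E-field* objective ``-dV/dr`` (V/m), relevant for excitation at
  axon terminals of local cells, and
* the *activating function* ``d^2 V / dr^2`` (V/m^2), relevant for
  excitation of axons of passage,

with ``r`` a unit direction parallel to the target neural structure.
Because the governing equations are linear, the field produced by an
arbitrary set of contact currents is the superposition of per-contact
basis fields sampled with a unit current of +1 A on one contact at a
time; this module generates those basis fields analytically or imports
them from a delimited table (e.g. exported from a finite-element
solver).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnisotropicMedium",
    "ContactArray",
    "FieldKind",
    "RegionRole",
    "RegionSpec",
    "BasisFieldSet",
    "monopole_potential",
    "analytic_basis_fields",
    "import_basis_fields",
    "export_basis_fields",
    "superpose",
]


class FieldKind(str, Enum):
    """Which directional derivative of the potential drives excitation."""

    E_FIELD = "E_FIELD"  # -dV/dr, V/m per ampere
    ACTIVATING_FUNCTION = "ACTIVATING_FUNCTION"  # d2V/dr2, V/m^2 per ampere


class RegionRole(str, Enum):
    ROI = "ROI"  # region of interest: activation desired
    ROA = "ROA"  # region of avoidance: activation undesired


@dataclass(frozen=True)
class AnisotropicMedium:
    """Homogeneous medium with a diagonal conductivity tensor (S/m)."""

    sigma_xx: float
    sigma_yy: float
    sigma_zz: float

    def __post_init__(self) -> None:
        for name in ("sigma_xx", "sigma_yy", "sigma_zz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_xx, self.sigma_yy, self.sigma_zz])


# White matter: higher conductivity along the fiber (z) axis than across it.
WHITE_MATTER = AnisotropicMedium(sigma_xx=0.083, sigma_yy=0.083, sigma_zz=0.6)


@dataclass(frozen=True)
class ContactArray:
    """Stimulating contacts idealized as point sources.

    Parameters
    ----------
    positions : (n, 3) array, meters
    labels : n unique identifiers, e.g. ``C1..C16``.
    """

    positions: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if pos.shape[0] < 2:
            raise ValueError("need at least 2 contacts")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d == 0.0):
            raise ValueError("contact positions must be pairwise distinct")
        labels = tuple(self.labels)
        if len(labels) != pos.shape[0]:
            raise ValueError("one label per contact required")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class RegionSpec:
    """A sampled region (ROI or ROA) with its excitation field kind.

    ``points`` is an (m, 3) array of sample locations in meters,
    ``direction`` the unit fiber direction along which derivatives are
    taken.
    """

    name: str
    points: np.ndarray
    direction: np.ndarray
    field_kind: FieldKind = FieldKind.ACTIVATING_FUNCTION
    role: RegionRole = RegionRole.ROI

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError("points must be an (m, 3) array with m >= 1")
        if not np.all(np.isfinite(pts)):
            raise ValueError("region points must be finite")
        r = np.asarray(self.direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(r) - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector (|r| = 1)")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "direction", r)
        object.__setattr__(self, "field_kind", FieldKind(self.field_kind))
        object.__setattr__(self, "role", RegionRole(self.role))

    @property
    def m(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class BasisFieldSet:
    """Per-contact unit-current field samples over one region.

    ``values[i, j]`` is the field (per the region's ``field_kind``) at
    region point ``i`` produced by +1 A on contact ``j`` with every
    other contact at 0 A.
    """

    region: RegionSpec
    values: np.ndarray
    contact_labels: tuple[str, ...]
    provenance: str = "analytic"  # {"analytic", "imported"}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (m, n) matrix")
        if v.shape[0] != self.region.m:
            raise ValueError("row count must equal the region's point count")
        labels = tuple(self.contact_labels)
        if v.shape[1] != len(labels):
            raise ValueError("column count must equal the contact count")
        if not np.all(np.isfinite(v)):
            raise ValueError("basis field values must all be finite")
        if self.provenance not in ("analytic", "imported"):
            raise ValueError("provenance must be 'analytic' or 'imported'")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "contact_labels", labels)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def _displacement_terms(point: np.ndarray, source: np.ndarray,
                        medium: AnisotropicMedium):
    delta = np.asarray(point, dtype=float) - np.asarray(source, dtype=float)
    sig = medium.sigmas
    q = float(np.sum(delta * delta / sig))
    if q == 0.0:
        raise ZeroDivisionError(
            "evaluation point coincides with the source position"
        )
    k = 1.0 / (4.0 * np.pi * np.sqrt(np.prod(sig)))
    return delta, sig, q, k


def monopole_potential(point, source, current: float,
                       medium: AnisotropicMedium) -> float:
    """Potential (V) of a point source in an anisotropic medium.

    Linear in ``current``; reduces to ``I / (4*pi*sigma*r)`` when the
    medium is isotropic.
    """
    _, _, q, k = _displacement_terms(point, source, medium)
    return current * k / np.sqrt(q)


def _directional_derivatives(points: np.ndarray, source: np.ndarray,
                             direction: np.ndarray,
                             medium: AnisotropicMedium):
    """First and second derivatives of the unit-current potential along r.

    With Q(s) = sum_i (delta_i + s*r_i)^2 / sigma_i and V = k * Q^{-1/2},
    Q' = 2a with a = sum r_i*delta_i/sigma_i, Q'' = 2b with
    b = sum r_i^2/sigma_i, so

        dV/ds   = -k * a * Q^{-3/2}
        d2V/ds2 =  k * (3*a^2 * Q^{-5/2} - b * Q^{-3/2}).
    """
    delta = np.atleast_2d(points) - np.asarray(source, dtype=float)
    sig = medium.sigmas
    q = np.sum(delta * delta / sig, axis=1)
    if np.any(q == 0.0):
        raise ZeroDivisionError(
            "a region point coincides with a contact position"
        )
    k = 1.0 / (4.0 * np.pi * np.sqrt(np.prod(sig)))
    a = delta @ (direction / sig)
    b = float(np.sum(direction * direction / sig))
    first = -k * a * q ** -1.5
    second = k * (3.0 * a * a * q ** -2.5 - b * q ** -1.5)
    return first, second


def analytic_basis_fields(contacts: ContactArray, region: RegionSpec,
                          medium: AnisotropicMedium) -> BasisFieldSet:
    """Closed-form basis fields for point-source contacts.

    Column ``j`` holds the region's field kind evaluated for a +1 A
    source at contact ``j``.
    """
    cols = []
    for j in range(contacts.n):
        first, second = _directional_derivatives(
            region.points, contacts.positions[j], region.direction, medium
        )
        if region.field_kind is FieldKind.E_FIELD:
            cols.append(-first)
        else:
            cols.append(second)
    return BasisFieldSet(
        region=region,
        values=np.column_stack(cols),
        contact_labels=contacts.labels,
        provenance="analytic",
    )


def import_basis_fields(table, region_meta: RegionSpec) -> BasisFieldSet:
    """Read a basis-field table: columns ``x, y, z`` then one per contact.

    ``table`` may be a path or an open text buffer.  Coordinates in the
    table override ``region_meta.points``; row order is preserved.
    Raises ``ValueError`` naming the offending row/column on missing
    columns, non-numeric cells, or non-finite entries.
    """
    df = pd.read_csv(table, float_precision="round_trip")
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    contact_cols = [c for c in df.columns if c not in ("x", "y", "z")]
    if not contact_cols:
        raise ValueError("table has no contact columns after x, y, z")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(numeric.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric or non-finite value in column {col!r} at row {row}"
            )
    points = df[["x", "y", "z"]].to_numpy(dtype=float)
    region = RegionSpec(
        name=region_meta.name,
        points=points,
        direction=region_meta.direction,
        field_kind=region_meta.field_kind,
        role=region_meta.role,
    )
    values = df[contact_cols].to_numpy(dtype=float)
    return BasisFieldSet(
        region=region,
        values=values,
        contact_labels=tuple(contact_cols),
        provenance="imported",
    )


def export_basis_fields(basis: BasisFieldSet, path_or_buf) -> None:
    """Write a basis-field CSV (17 significant digits, round-trip safe)."""
    df = pd.DataFrame(basis.region.points, columns=["x", "y", "z"])
    for j, label in enumerate(basis.contact_labels):
        df[label] = basis.values[:, j]
    df.to_csv(path_or_buf, index=False, float_format="%.17g")


def superpose(basis: BasisFieldSet, alpha: Sequence[float]) -> np.ndarray:
    """Field at every region point for contact current fractions ``alpha``."""
    a = np.asarray(alpha, dtype=float).reshape(-1)
    if a.shape[0] != basis.n:
        raise ValueError(
            f"alpha has length {a.shape[0]} but basis has {basis.n} contacts"
        )
    return basis.values @ a
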