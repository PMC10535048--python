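"""Built-in geometries so every solver is testable without external data.

Two fixtures are provided.  ``cube8`` is an idealized arrangement of
eight monopole sources at the corners of a cube in anisotropic white
matter, with nested regions of 0 to 3 dimensions used to illustrate how
the region's dimensionality shapes the optimum.  ``two_lead_16``
emulates a pair of parallel percutaneous leads (8 contacts each,
4 mm center-to-center contact pitch, 4 mm lead separation), with axon
lines and lateral boxes as regions.  Contacts are idealized as point
sources at the contact centers — a deliberate fidelity limit of the
analytic model relative to finite-size cylindrical contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_model import (
    WHITE_MATTER,
    AnisotropicMedium,
    BasisFieldSet,
    ContactArray,
    FieldKind,
    RegionRole,
    RegionSpec,
    analytic_basis_fields,
)

__all__ = ["FixtureSpec", "make_cube8", "make_two_lead_16"]

MM = 1e-3


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    contacts: ContactArray
    medium: AnisotropicMedium
    regions: dict[str, RegionSpec]

    def basis(self, region_name: str) -> BasisFieldSet:
        """Analytic basis fields for one named region."""
        return analytic_basis_fields(
            self.contacts, self.regions[region_name], self.medium
        )

    def basis_for(self, *region_names: str) -> dict[str, BasisFieldSet]:
        return {name: self.basis(name) for name in region_names}


def _grid(xs, ys, zs) -> np.ndarray:
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def make_cube8(edge_length: float = 10 * MM) -> FixtureSpec:
    """Eight point sources at the corners of a cube, regions nested inside.

    Regions (all direction z, activating-function kind, strictly inside
    the cube): a single off-center point, a z-line through it, the plane
    z = edge/8, and a centered box whose grid contains all three.  The
    point is deliberately asymmetric: a region placed at the exact
    center sees identical fields from all eight sources and the
    objective vanishes identically on the balanced-current manifold.
    """
    h = edge_length / 2.0
    corners = _grid([-h, h], [-h, h], [-h, h])
    contacts = ContactArray(
        positions=corners,
        labels=tuple(f"S{i + 1}" for i in range(8)),
    )
    q = edge_length / 4.0
    zdir = (0.0, 0.0, 1.0)
    x0, y0, z0 = q / 2.0, -q / 2.0, q / 2.0
    line_z = np.linspace(-q, q, 21)
    plane_xy = np.linspace(-q, q, 9)
    box_ax = np.linspace(-q, q, 5)
    regions = {
        "point0d": RegionSpec(
            name="point0d", points=np.array([[x0, y0, z0]]),
            direction=zdir, field_kind=FieldKind.ACTIVATING_FUNCTION,
        ),
        "line1d": RegionSpec(
            name="line1d",
            points=np.column_stack([np.full(21, x0), np.full(21, y0), line_z]),
            direction=zdir, field_kind=FieldKind.ACTIVATING_FUNCTION,
        ),
        "plane2d": RegionSpec(
            name="plane2d",
            points=_grid(plane_xy, plane_xy, [z0]),
            direction=zdir, field_kind=FieldKind.ACTIVATING_FUNCTION,
        ),
        "box3d": RegionSpec(
            name="box3d",
            points=_grid(box_ax, box_ax, box_ax),
            direction=zdir, field_kind=FieldKind.ACTIVATING_FUNCTION,
        ),
    }
    return FixtureSpec(
        name="cube8", contacts=contacts, medium=WHITE_MATTER, regions=regions
    )


def make_two_lead_16(lead_separation: float = 4 * MM,
                     contact_pitch: float = 4 * MM,
                     n_per_lead: int = 8) -> FixtureSpec:
    """Two parallel z-aligned leads of point-source contacts.

    Lead 1 (labels C1..C8) sits at x = -separation/2, lead 2 (C9..C16)
    at x = +separation/2, both at y = 0, contact centers spaced by the
    pitch and centered on z = 0.  Axon-line regions run parallel to z at
    a 2 mm dorsal (y) offset, sampled every 0.5 mm over 80 mm (161
    points), which covers the array plus generous margins.  Two lateral
    boxes carry the E-field kind for targets where terminal excitation
    is the relevant mechanism.
    """
    half = lead_separation / 2.0
    z0 = -(n_per_lead - 1) / 2.0 * contact_pitch
    zc = z0 + contact_pitch * np.arange(n_per_lead)
    pos = np.vstack([
        np.column_stack([np.full(n_per_lead, -half), np.zeros(n_per_lead), zc]),
        np.column_stack([np.full(n_per_lead, +half), np.zeros(n_per_lead), zc]),
    ])
    contacts = ContactArray(
        positions=pos,
        labels=tuple(f"C{i + 1}" for i in range(2 * n_per_lead)),
    )
    zdir = (0.0, 0.0, 1.0)
    y_axon = 2 * MM
    z_axon = np.arange(-40.0, 40.0 + 1e-9, 0.5) * MM  # 161 samples
    m = z_axon.shape[0]

    def axon_line(name, x, role):
        return RegionSpec(
            name=name,
            points=np.column_stack([np.full(m, x), np.full(m, y_axon), z_axon]),
            direction=zdir,
            field_kind=FieldKind.ACTIVATING_FUNCTION,
            role=role,
        )

    box_y = np.linspace(1 * MM, 3 * MM, 3)
    box_z = np.linspace(-8 * MM, 8 * MM, 9)
    left_x = np.linspace(-7 * MM, -4 * MM, 4)
    right_x = np.linspace(4 * MM, 7 * MM, 4)
    regions = {
        "midline_axon": axon_line("midline_axon", 0.0, RegionRole.ROI),
        "left_axon": axon_line("left_axon", -half, RegionRole.ROI),
        "right_axon": axon_line("right_axon", +half, RegionRole.ROA),
        "left_box": RegionSpec(
            name="left_box", points=_grid(left_x, box_y, box_z),
            direction=zdir, field_kind=FieldKind.E_FIELD, role=RegionRole.ROI,
        ),
        "right_box": RegionSpec(
            name="right_box", points=_grid(right_x, box_y, box_z),
            direction=zdir, field_kind=FieldKind.E_FIELD, role=RegionRole.ROA,
        ),
    }
    return FixtureSpec(
        name="two_lead_16", contacts=contacts, medium=WHITE_MATTER,
        regions=regions,
    )


_FIXTURES = {"cube8": make_cube8, "two_lead_16": make_two_lead_16}


def get_fixture(name: str) -> FixtureSpec:
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
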