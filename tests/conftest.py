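"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from steeropt.field_model import (
    RegionRole,
    RegionSpec,
    analytic_basis_fields,
)
from steeropt.fixtures import make_two_lead_16

MM = 1e-3


@pytest.fixture(scope="session")
def two_lead():
    return make_two_lead_16()


@pytest.fixture(scope="session")
def four_contact():
    """Two leads with two contacts each: the smallest two-lead system."""
    return make_two_lead_16(n_per_lead=2)


@pytest.fixture(scope="session")
def four_contact_point_roi(four_contact):
    region = RegionSpec(
        name="pt_roi",
        points=np.array([[-1.5 * MM, 2 * MM, 1 * MM]]),
        direction=(0.0, 0.0, 1.0),
    )
    return analytic_basis_fields(four_contact.contacts, region,
                                 four_contact.medium)


@pytest.fixture(scope="session")
def four_contact_two_point_roi(four_contact):
    region = RegionSpec(
        name="pts2_roi",
        points=np.array([[-1.5 * MM, 2 * MM, 1 * MM],
                         [1.0 * MM, 2 * MM, -2 * MM]]),
        direction=(0.0, 0.0, 1.0),
    )
    return analytic_basis_fields(four_contact.contacts, region,
                                 four_contact.medium)


@pytest.fixture(scope="session")
def four_contact_point_roa(four_contact):
    """A point the optimal ROI bipole excites: makes an epsilon cap bind."""
    region = RegionSpec(
        name="pt_roa",
        points=np.array([[-0.5 * MM, 2 * MM, 2 * MM]]),
        direction=(0.0, 0.0, 1.0),
        role=RegionRole.ROA,
    )
    return analytic_basis_fields(four_contact.contacts, region,
                                 four_contact.medium)


def balanced_grid(n: int, step: float = 0.05) -> np.ndarray:
    """Every fraction vector on the given grid whose anodes sum to +1 and
    cathodes to -1 (exhaustive enumeration oracle)."""
    per = int(round(1.0 / step))
    k = np.arange(-per, per + 1, dtype=np.int32)
    G = np.array(np.meshgrid(*[k] * n, indexing="ij")).reshape(n, -1).T
    pos = np.where(G > 0, G, 0).sum(axis=1)
    neg = np.where(G < 0, G, 0).sum(axis=1)
    keep = (pos == per) & (neg == -per)
    return G[keep].astype(float) * step


@pytest.fixture(scope="session")
def grid4():
    return balanced_grid(4, step=0.05)


def central_derivative(f, x0, h):
    return (f(x0 + h) - f(x0 - h)) / (2.0 * h)


def richardson_derivative(f, x0, h):
    """Richardson-extrapolated central difference (h and h/2 stencils)."""
    d1 = central_derivative(f, x0, h)
    d2 = central_derivative(f, x0, h / 2.0)
    return (4.0 * d2 - d1) / 3.0


def fd_gradient(f, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def fd_jacobian(fun, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(fun(x))
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        J[:, i] = (np.asarray(fun(x + e)) - np.asarray(fun(x - e))) / (2.0 * h)
    return J
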