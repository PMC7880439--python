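"""Filament geometry, energy terms, and their analytic gradients.

This is the reference (vectorised numpy) implementation of the potential
energy surface.  The time-critical inner loop of the integrator re-implements
the same gradients in a scalar numba kernel; the test suite checks the two
against each other and against finite differences of the energy.

Geometry
--------
Monomer ``i`` is a sphere of radius R centred at ``(x_i, y_i)`` with an
orientation angle ``theta_i``.  Its longitudinal axis points along
``u(theta) = (-sin theta, cos theta)`` (straight chain built along +y has all
theta = 0).  The *plus* interaction site sits at ``center + R u`` and the
*minus* site at ``center - R u``.  Joint ``i`` bonds monomer ``i``'s plus
site to monomer ``i+1``'s minus site, so the bond penalises both stretching
and shear of the longitudinal interface, and couples to the orientation
angles of both monomers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import FilamentParams

__all__ = [
    "FilamentState",
    "EnergyBreakdown",
    "interaction_sites",
    "bend_energy",
    "bond_energy",
    "total_energy",
    "forces_and_torques",
    "straight_state",
    "relaxed_state",
    "wrap_angle",
]


@dataclass
class FilamentState:
    """Positions and orientations of all monomers at one time point."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not (self.x.shape == self.y.shape == self.theta.shape):
            raise ValueError("x, y, theta must have equal lengths")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def copy(self) -> "FilamentState":
        return FilamentState(self.x.copy(), self.y.copy(), self.theta.copy(),
                             self.time)

    def positions(self) -> np.ndarray:
        """(n, 2) array of monomer centres."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class EnergyBreakdown:
    """Total potential energy split into its two harmonic contributions (kT)."""

    bending: float
    stretching: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "total", self.bending + self.stretching)


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    return -np.remainder(-np.asarray(a) + np.pi, 2.0 * np.pi) + np.pi


def _axis(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return -np.sin(theta), np.cos(theta)


def interaction_sites(state: FilamentState, params: FilamentParams):
    """Plus- and minus-end interaction sites of every monomer.

    Returns ``(plus, minus)``, each of shape (n, 2), where
    ``plus = center + R u(theta)`` and ``minus = center - R u(theta)``.
    """
    ux, uy = _axis(state.theta)
    r = params.radius
    centers = state.positions()
    offset = r * np.column_stack([ux, uy])
    return centers + offset, centers - offset


def _bond_vectors(state: FilamentState, params: FilamentParams) -> np.ndarray:
    """(n-1, 2) vectors from each monomer's plus site to the next minus site."""
    plus, minus = interaction_sites(state, params)
    return plus[:-1] - minus[1:]


def bend_energy(theta_i: float, theta_below: float,
                params: FilamentParams) -> float:
    """Bending energy (kT) of one joint: (b/2)(wrap(theta_i - theta_below) - theta0)^2."""
    d = wrap_angle(theta_i - theta_below)
    return 0.5 * params.bend_stiffness_b * float(d - params.theta0) ** 2


def bond_energy(r: float, params: FilamentParams) -> float:
    """Longitudinal bond energy (kT) at inter-site distance ``r`` (nm)."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    return 0.5 * params.bond_stiffness_k * r * r


def total_energy(state: FilamentState, params: FilamentParams) -> EnergyBreakdown:
    """Total bending and stretching energy of the chain, in kT."""
    dth = wrap_angle(np.diff(state.theta)) - params.theta0
    bending = 0.5 * params.bend_stiffness_b * float(np.sum(dth * dth))
    bv = _bond_vectors(state, params)
    stretching = 0.5 * params.bond_stiffness_k * float(np.sum(bv * bv))
    return EnergyBreakdown(bending=bending, stretching=stretching)


def forces_and_torques(state: FilamentState, params: FilamentParams):
    """Analytic gradient of the total energy.

    Returns ``(dU_dx, dU_dy, dU_dtheta)``, each of length n.  These are raw
    gradients; the integrator decides which monomers are free to move.
    The angular gradient includes the chain-rule contribution of theta
    through the interaction-site positions.
    """
    n = state.n
    b, k, r = params.bend_stiffness_b, params.bond_stiffness_k, params.radius
    gx = np.zeros(n)
    gy = np.zeros(n)
    gt = np.zeros(n)

    # bending: per joint j, moment m = b * (wrap(dtheta_j) - theta0)
    m = b * (wrap_angle(np.diff(state.theta)) - params.theta0)
    gt[:-1] -= m
    gt[1:] += m

    # bonds: U = k/2 |rv|^2 with rv = c_j - c_{j+1} + R (u_j + u_{j+1})
    rv = _bond_vectors(state, params)
    krv = k * rv
    gx[:-1] += krv[:, 0]
    gx[1:] -= krv[:, 0]
    gy[:-1] += krv[:, 1]
    gy[1:] -= krv[:, 1]
    # d(rv)/d(theta_j) = d(rv)/d(theta_{j+1}) = R u'(theta) = R (-cos, -sin)
    dux = -np.cos(state.theta)
    duy = -np.sin(state.theta)
    proj = np.zeros(n)
    proj[:-1] += krv[:, 0] * dux[:-1] + krv[:, 1] * duy[:-1]
    proj[1:] += krv[:, 0] * dux[1:] + krv[:, 1] * duy[1:]
    gt += r * proj
    return gx, gy, gt


def straight_state(params: FilamentParams) -> FilamentState:
    """Perfectly straight chain along +y with touching interaction sites."""
    n = params.n_monomers
    y = np.arange(n) * params.spacing
    return FilamentState(np.zeros(n), y, np.zeros(n))


def relaxed_state(params: FilamentParams) -> FilamentState:
    """Zero-energy configuration with every joint at the equilibrium angle.

    For theta0 = 0 this is the straight chain; otherwise a uniformly curved
    arc, anchored like :func:`straight_state` at the minus end.
    """
    n = params.n_monomers
    theta = np.arange(n) * params.theta0
    x = np.zeros(n)
    y = np.zeros(n)
    r = params.radius
    for i in range(1, n):
        x[i] = x[i - 1] + r * (-np.sin(theta[i - 1]) - np.sin(theta[i]))
        y[i] = y[i - 1] + r * (np.cos(theta[i - 1]) + np.cos(theta[i]))
    return FilamentState(x, y, theta)
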