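"""Thermal protocol: cooling schedule and temperature-dependent water viscosity.

Supercooled water's viscosity follows a power law diverging at an apparent
solidification temperature Ts,

    eta(T) = eta0 * (T/Ts - 1)^(-gamma),

with parameter sets fitted to measurements at atmospheric pressure (plunge
freezing) and at 200 MPa (high-pressure freezing).  Cooling is linear,
T(t) = T0 - v t, clamped at a stop temperature slightly above Ts where the
model mobility is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DRAG_R, DRAG_T, kt_at

__all__ = [
    "ViscosityLaw",
    "CoolingSchedule",
    "ThermalProtocol",
    "temperature_at",
    "viscosity_at",
    "mobilities",
    "PLUNGE_LAW",
    "HIGH_PRESSURE_LAW",
    "VISCOSITY_PRESETS",
]


@dataclass(frozen=True)
class ViscosityLaw:
    """Power-law viscosity divergence of supercooled water."""

    eta0: float     # Pa s
    Ts: float       # K
    gamma: float    # dimensionless
    label: str = ""

    def __post_init__(self) -> None:
        if self.eta0 <= 0 or self.Ts <= 0 or self.gamma <= 0:
            raise ValueError("eta0, Ts and gamma must all be positive")

    def __call__(self, T):
        return viscosity_at(self, T)


#: Atmospheric-pressure fit (plunge freezing).
PLUNGE_LAW = ViscosityLaw(eta0=1.38e-4, Ts=225.6, gamma=1.64,
                          label="plunge-atmospheric")

#: 200 MPa fit (high-pressure freezing).
HIGH_PRESSURE_LAW = ViscosityLaw(eta0=2.2e-4, Ts=205.4, gamma=1.84,
                                 label="high-pressure-200MPa")

VISCOSITY_PRESETS = {
    "plunge-atmospheric": PLUNGE_LAW,
    "high-pressure-200MPa": HIGH_PRESSURE_LAW,
}


@dataclass(frozen=True)
class CoolingSchedule:
    """Linear cooling T(t) = max(T0 - v t, T_stop)."""

    T0: float
    rate_v: float
    T_stop: float

    def __post_init__(self) -> None:
        if self.rate_v < 0:
            raise ValueError("cooling rate must be >= 0")
        if self.rate_v > 0 and not self.T0 > self.T_stop:
            raise ValueError("T0 must exceed T_stop for a cooling run")

    @property
    def duration(self) -> float:
        """Time to reach T_stop, in µs (inf for isothermal schedules)."""
        if self.rate_v == 0:
            return np.inf
        return (self.T0 - self.T_stop) / self.rate_v * 1e6

    def __call__(self, t):
        return temperature_at(self, t)


def temperature_at(schedule: CoolingSchedule, t) -> float:
    """Temperature (K) at elapsed time ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    T = schedule.T0 - schedule.rate_v * t
    return np.maximum(T, schedule.T_stop)[()]


def viscosity_at(law: ViscosityLaw, T) -> float:
    """Viscosity (Pa s) at temperature ``T`` (K); error below Ts."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= law.Ts):
        raise ValueError(
            f"T={T} is at or below the solidification temperature Ts={law.Ts} K"
        )
    return (law.eta0 * (T / law.Ts - 1.0) ** (-law.gamma))[()]


def mobilities(law: ViscosityLaw, T: float, radius: float):
    """Stokes mobilities and diffusion coefficients of a sphere.

    Parameters are the viscosity law, temperature (K) and sphere radius (nm).
    Returns a dict with translational/rotational mobilities (1/(6 pi R eta),
    1/(8 pi R^3 eta)) and diffusion coefficients D_t = kB T mu_t,
    D_r = kB T mu_r, all in internal units (nm, µs, kT(295.15 K)).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    eta = viscosity_at(law, T)
    mu_t = 1.0 / (DRAG_T * radius * eta)
    mu_r = 1.0 / (DRAG_R * radius ** 3 * eta)
    kt = kt_at(T)
    return {"mu_t": mu_t, "mu_r": mu_r, "D_t": kt * mu_t, "D_r": kt * mu_r}


@dataclass(frozen=True)
class ThermalProtocol:
    """Cooling schedule plus viscosity law; maps elapsed time to (T, eta)."""

    schedule: CoolingSchedule
    viscosity: ViscosityLaw
    label: str = ""

    def __post_init__(self) -> None:
        if self.schedule.T_stop <= self.viscosity.Ts:
            raise ValueError(
                "T_stop must stay above the solidification temperature Ts"
            )

    def at(self, t: float) -> tuple[float, float]:
        """(temperature K, viscosity Pa s) at elapsed time t (seconds)."""
        T = temperature_at(self.schedule, t)
        return T, viscosity_at(self.viscosity, T)


def make_protocol(law: ViscosityLaw, rate_v: float, T0: float,
                  T_stop: float | None = None, label: str = "") -> ThermalProtocol:
    """Convenience constructor; T_stop defaults to Ts + 0.5 K."""
    if T_stop is None:
        T_stop = law.Ts + 0.5
    return ThermalProtocol(CoolingSchedule(T0=T0, rate_v=rate_v, T_stop=T_stop),
                           law, label=label)
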