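"""Overdamped Brownian dynamics propagation of a filament under a thermal protocol.

Each monomer obeys inertia-free Langevin dynamics: per time step dt the
planar coordinates advance by the Stokes drift ``-dt/(6 pi R eta) dU/dx``
plus thermal noise of variance ``2 kB T dt/(6 pi R eta)``, and the
orientation angle analogously with the rotational drag ``8 pi R^3 eta``.

Two propagation schemes share this drift and noise budget:

``"lm"`` (default)
    The Leimkuhler–Matthews splitting, whose noise increment is the average
    of the current and previous step's N(0,1) draws.  For harmonic forces it
    reproduces the exact Boltzmann configurational distribution at *any*
    stable time step, which is what allows the adaptive step to ride close
    to the stability bound without biasing equilibrium shape statistics.
``"euler"``
    Plain Euler–Maruyama, kept for validation; its stationary variance is
    biased by O(dt) on stiff modes.

Both draw exactly three independent normals per free monomer per step, in a
fixed documented order (triplets x, y, theta; monomers ascending), from a
counter-stable seeded generator — identical inputs give bit-identical
trajectories.

The adaptive step is ``dt = safety * min(gamma_t/k, gamma_r/(b + 2 k R^2))``,
the drag-to-curvature ratio of the stiffest potential; dt therefore grows
proportionally to the viscosity during cooling, which is what makes slow
protocols tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import KB, kt_at
from .environment import ThermalProtocol, temperature_at, viscosity_at
from .model import FilamentState, forces_and_torques, relaxed_state
from .params import FilamentParams

__all__ = [
    "BDConfig",
    "Trajectory",
    "bd_step",
    "run",
    "sample_equilibrium_init",
    "stability_dt",
]

_CHUNK = 1 << 15


@dataclass
class BDConfig:
    """Integrator settings for one replicate."""

    seed: int = 0
    dt_policy: str | float = "adaptive"   # "adaptive" or a fixed step in µs
    safety: float = 0.1                   # fraction of the stability bound
    scheme: str = "lm"                    # "lm" or "euler"
    record_every: int = 0                 # decimation interval, steps (0: none)
    max_steps: int = 20_000_000_000
    max_time: float = np.inf              # wall of simulated time, µs
    noise_scale: float = 1.0              # 0 for deterministic (zero-T) runs
    immob_window_K: float = 1.0           # observation window, kelvins of cooling
    immob_delta: float = 0.5              # tip displacement threshold, nm
    stop_on_immobilization: bool = False
    max_recorded_states: int = 4096

    def __post_init__(self) -> None:
        if isinstance(self.dt_policy, str):
            if self.dt_policy != "adaptive":
                raise ValueError("dt_policy must be 'adaptive' or a fixed step (µs)")
        elif self.dt_policy <= 0:
            raise ValueError("fixed dt must be positive")
        if not (0.0 < self.safety < 1.0):
            raise ValueError("safety factor must lie in (0, 1)")
        if self.scheme not in ("lm", "euler"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")


@dataclass
class Trajectory:
    """Decimated trajectory of one replicate plus bookkeeping."""

    states: list[FilamentState]
    schedule_log: np.ndarray          # columns: time_s, T_K, eta_Pas
    terminated_reason: str
    final_state: FilamentState = None
    n_steps: int = 0
    seed: int = 0
    immobilization_time: float | None = None   # µs
    immobilization_T: float | None = None      # K
    tip_record: np.ndarray = field(default=None, repr=False)


def stability_dt(params: FilamentParams, eta: float, safety: float) -> float:
    """Adaptive time step (µs) at viscosity ``eta`` (Pa s)."""
    from .constants import DRAG_R, DRAG_T
    gt = DRAG_T * params.radius * eta
    gr = DRAG_R * params.radius ** 3 * eta
    beff = params.bend_stiffness_b + 2.0 * params.bond_stiffness_k * params.radius ** 2
    return safety * min(gt / params.bond_stiffness_k, gr / beff)


def bd_step(state: FilamentState, params: FilamentParams, T: float, eta: float,
            dt: float, rng: np.random.Generator, *,
            noise_scale: float = 1.0) -> FilamentState:
    """One explicit Euler–Maruyama step (reference implementation).

    ``dt`` in µs, ``eta`` in Pa s, ``T`` in K.  Free monomers advance by
    drift plus noise; the first ``n_fixed`` monomers are clamped.  Three
    normals are drawn per free monomer (x, y, theta; monomers ascending).
    Raises if the update produces non-finite coordinates (dt too large).
    """
    from .constants import DRAG_R, DRAG_T
    gx, gy, gt_ = forces_and_torques(state, params)
    gamt = DRAG_T * params.radius * eta
    gamr = DRAG_R * params.radius ** 3 * eta
    kt = KB * T
    nf = params.n_fixed
    n_free = state.n - nf
    xi = rng.standard_normal((n_free, 3))
    new = state.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        new.x[nf:] += -dt / gamt * gx[nf:] + noise_scale * np.sqrt(2 * kt * dt / gamt) * xi[:, 0]
        new.y[nf:] += -dt / gamt * gy[nf:] + noise_scale * np.sqrt(2 * kt * dt / gamt) * xi[:, 1]
        new.theta[nf:] += -dt / gamr * gt_[nf:] + noise_scale * np.sqrt(2 * kt * dt / gamr) * xi[:, 2]
    new.time = state.time + dt
    if not (np.all(np.isfinite(new.x)) and np.all(np.isfinite(new.y))
            and np.all(np.isfinite(new.theta))):
        raise FloatingPointError(
            "non-finite coordinates after BD step -- time step too large "
            f"(dt={dt} µs, eta={eta} Pa s)"
        )
    return new


def _detect_immobilization(rec_t: np.ndarray, rec_xy: np.ndarray,
                           window: float, delta: float) -> float | None:
    """First time (µs) at which the tip stays within ``delta`` of its
    position over a trailing window of ``window`` µs; None if never."""
    n = rec_t.shape[0]
    j = 0
    for i in range(n):
        while rec_t[i] - rec_t[j] > window:
            j += 1
        if j == i or rec_t[i] - rec_t[j] < 0.95 * window:
            continue
        seg = rec_xy[j:i + 1]
        d2 = (seg[:, 0] - seg[0, 0]) ** 2 + (seg[:, 1] - seg[0, 1]) ** 2
        if np.max(d2) <= delta * delta:
            return float(rec_t[j])
    return None


def run(initial: FilamentState, params: FilamentParams,
        protocol: ThermalProtocol, config: BDConfig) -> Trajectory:
    """Propagate ``initial`` through the thermal protocol.

    Stops at the schedule's stop temperature, at ``config.max_time`` /
    ``max_steps``, or (optionally) at immobilisation.  Noise is generated in
    chunks by a seeded SFC64 generator and consumed row-per-step by the
    numba kernel.
    """
    n = params.n_monomers
    if initial.n != n:
        raise ValueError("initial state size does not match params.n_monomers")
    x = initial.x.copy()
    y = initial.y.copy()
    th = initial.theta.copy()
    clamp = (x[:params.n_fixed].copy(), y[:params.n_fixed].copy(),
             th[:params.n_fixed].copy())

    sched, law = protocol.schedule, protocol.viscosity
    v_us = sched.rate_v * 1e-6                     # K/µs
    rng = np.random.Generator(np.random.SFC64(config.seed))
    nf3 = 3 * (n - params.n_fixed)
    noise = np.empty((_CHUNK, nf3), dtype=np.float32)
    prev = rng.standard_normal(nf3)                # LM initial half-step noise
    dt_fixed = 0.0 if config.dt_policy == "adaptive" else float(config.dt_policy)

    # fixed-real-time tip recording for the immobilisation detector
    if v_us > 0:
        window = config.immob_window_K / v_us
        rec_interval = window / 64.0
        n_rec = int(np.ceil((sched.T0 - sched.T_stop) / config.immob_window_K * 64)) + 130
    else:
        window, rec_interval, n_rec = np.inf, 0.0, 1
    rec_t = np.zeros(n_rec)
    rec_xy = np.zeros((n_rec, 2))

    n_state = config.max_recorded_states if config.record_every > 0 else 1
    state_buf = np.zeros((n_state, 3 * n))
    state_t = np.zeros(n_state)

    t = 0.0
    steps = 0
    nrec = 0
    nstate = 0
    reason = None
    immob_t = None
    while True:
        budget = min(_CHUNK, config.max_steps - steps)
        if budget < _CHUNK:
            noise = np.empty((budget, nf3), dtype=np.float32)
        rng.standard_normal(out=noise, dtype=np.float32)
        used, t, code, nrec, nstate = _kernels.run_chunk(
            x, y, th, params.n_fixed, params.radius, params.bend_stiffness_b,
            params.theta0, params.bond_stiffness_k,
            sched.T0, v_us, sched.T_stop, law.eta0, law.Ts, law.gamma,
            config.safety, dt_fixed, config.noise_scale,
            config.scheme == "lm", t, config.max_time,
            noise[:budget], prev, steps,
            rec_t, rec_xy, rec_interval, nrec,
            config.record_every, state_buf, state_t, nstate)
        steps += used
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
                and np.all(np.isfinite(th))):
            raise FloatingPointError(
                f"non-finite coordinates after {steps} steps (seed {config.seed}) "
                "-- time step too large for this stiffness/viscosity"
            )
        if code == _kernels.REACHED_T_STOP:
            reason = "reached_T_stop"
            break
        if code == _kernels.REACHED_T_MAX:
            reason = "reached_max_time"
            break
        if steps >= config.max_steps:
            reason = "max_steps"
            break
        if config.stop_on_immobilization and nrec > 2:
            immob_t = _detect_immobilization(rec_t[:nrec], rec_xy[:nrec],
                                             window, config.immob_delta)
            if immob_t is not None:
                reason = "immobilized"
                break

    if immob_t is None and nrec > 2:
        immob_t = _detect_immobilization(rec_t[:nrec], rec_xy[:nrec],
                                         window, config.immob_delta)
    immob_T = None
    if immob_t is not None:
        immob_T = float(temperature_at(sched, immob_t * 1e-6))

    states = []
    for i in range(nstate):
        states.append(FilamentState(state_buf[i, :n].copy(),
                                    state_buf[i, n:2 * n].copy(),
                                    state_buf[i, 2 * n:].copy(),
                                    time=state_t[i]))
    final = FilamentState(x, y, th, time=t)
    # clamped monomers must be bit-identical to the initial state
    final.x[:params.n_fixed] = clamp[0]
    final.y[:params.n_fixed] = clamp[1]
    final.theta[:params.n_fixed] = clamp[2]

    log_t = np.array([s.time for s in states] + [t])
    T_log = np.asarray(temperature_at(sched, log_t * 1e-6), dtype=float).reshape(-1)
    eta_log = np.array([viscosity_at(law, max(Tk, sched.T_stop + 1e-9)) for Tk in T_log])
    schedule_log = np.column_stack([log_t * 1e-6, T_log, eta_log])

    return Trajectory(states=states, schedule_log=schedule_log,
                      terminated_reason=reason, final_state=final,
                      n_steps=steps, seed=config.seed,
                      immobilization_time=immob_t, immobilization_T=immob_T,
                      tip_record=np.column_stack([rec_t[:nrec], rec_xy[:nrec]]))


def sample_equilibrium_init(params: FilamentParams, T: float,
                            rng: np.random.Generator) -> FilamentState:
    """Draw an exact equilibrium configuration of the bending degrees of freedom.

    Joint angles are independent Normal(theta0, kB T / b) variates (the
    Boltzmann marginal of the harmonic bending potential when the
    longitudinal bonds are stiff) and the bonds are built with zero
    extension, anchored at the clamped minus end.  The clamped monomers
    reproduce the straight-anchor geometry of :func:`cryofil.model.straight_state`.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    n = params.n_monomers
    sigma2 = kt_at(T) / params.bend_stiffness_b
    theta = np.zeros(n)
    # clamped monomers stay at the anchor orientation; free joints fluctuate
    for i in range(1, n):
        if i < params.n_fixed:
            theta[i] = theta[i - 1]
        else:
            theta[i] = theta[i - 1] + params.theta0 + np.sqrt(sigma2) * rng.standard_normal()
    x = np.zeros(n)
    y = np.zeros(n)
    r = params.radius
    sn = np.sin(theta)
    cs = np.cos(theta)
    for i in range(1, n):
        x[i] = x[i - 1] - r * (sn[i - 1] + sn[i])
        y[i] = y[i - 1] + r * (cs[i - 1] + cs[i])
    return FilamentState(x, y, theta)
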