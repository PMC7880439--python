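"""The simulated cryofixation experiments, wired end to end.

Each experiment runs an ensemble of independent Brownian dynamics
replicates of one filament species through a thermal protocol and reduces
the final (immobilised) shapes to the headline statistics: the curvature
profile and its gradient, the apparent persistence length, and the emergent
immobilisation temperature.

Slow protocols and the quasi-static cold start
----------------------------------------------
At 10^4 K/s the filament relaxation time stays far below the remaining
cooling time until ~1–2 K above the viscosity singularity, so the shape
ensemble tracks thermal equilibrium during essentially the whole descent;
only the last couple of kelvins are dynamically interesting.  The ``*_1e4``
protocol presets therefore start from a directly sampled equilibrium
ensemble at ``T_start = 210 K`` and integrate the dynamics from there —
simulating the quasi-static portion explicitly would cost ~10^10 steps per
replicate without changing the frozen shapes.  Fast protocols (10^6 K/s and
up) are integrated from their nominal start temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import (PersistenceFit, TraceEnsemble, curvature_gradient,
                       curvature_profile, fit_persistence_length,
                       mean_cos_deflection)
from .environment import (HIGH_PRESSURE_LAW, PLUNGE_LAW, CoolingSchedule,
                          ThermalProtocol, ViscosityLaw)
from .integrator import BDConfig, run, sample_equilibrium_init
from .model import straight_state
from .params import FilamentParams, params_from_persistence, species as species_preset

__all__ = [
    "ExperimentSpec",
    "FreezeResult",
    "PersistenceShiftResult",
    "protocol_preset",
    "PROTOCOL_PRESETS",
    "freeze_experiment",
    "persistence_shift_experiment",
    "required_rate_scan",
    "length_independence_check",
]

_AMBIENT = 295.15  # 22 degC


def _make(law: ViscosityLaw, v: float, T0: float, label: str) -> ThermalProtocol:
    return ThermalProtocol(
        CoolingSchedule(T0=T0, rate_v=v, T_stop=law.Ts + 0.5), law, label=label)


#: (protocol, default quasi-static start temperature or None)
PROTOCOL_PRESETS: dict[str, tuple[ThermalProtocol, float | None]] = {
    "HPF_1e4": (_make(HIGH_PRESSURE_LAW, 1e4, _AMBIENT, "HPF_1e4"), 210.0),
    "plunge_1e6": (_make(PLUNGE_LAW, 1e6, _AMBIENT, "plunge_1e6"), None),
    "plunge_1e7": (_make(PLUNGE_LAW, 1e7, _AMBIENT, "plunge_1e7"), None),
    "isothermal_310K": (
        ThermalProtocol(CoolingSchedule(T0=310.0, rate_v=0.0, T_stop=226.1),
                        PLUNGE_LAW, label="isothermal_310K"), None),
}


def protocol_preset(name: str) -> ThermalProtocol:
    try:
        return PROTOCOL_PRESETS[name][0]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOL_PRESETS)}"
        ) from None


@dataclass
class ExperimentSpec:
    """A replicated freezing experiment."""

    species: str | FilamentParams = "floppy_pf"
    protocol: str | ThermalProtocol = "plunge_1e6"
    n_replicates: int = 40
    init_mode: str = "straight"       # straight | equilibrium | relax_then_freeze
    relax_duration: float = 1e3       # µs, for relax_then_freeze warm-up
    base_seed: int = 0
    T_start: float | None = None      # quasi-static cold start (K); None = preset
    segment_len: float | None = None  # curvature chord length, nm (default 2 spacings)
    bd: BDConfig = field(default_factory=BDConfig)
    isothermal_duration: float = 1e4  # µs cap for rate 0 protocols

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.init_mode not in ("straight", "equilibrium", "relax_then_freeze"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    def resolve(self) -> tuple[FilamentParams, ThermalProtocol, float | None]:
        p = self.species if isinstance(self.species, FilamentParams) \
            else species_preset(self.species)
        if isinstance(self.protocol, ThermalProtocol):
            proto, t_start = self.protocol, None
        else:
            proto, t_start = PROTOCOL_PRESETS[self.protocol] \
                if self.protocol in PROTOCOL_PRESETS \
                else (_missing_protocol(self.protocol), None)
        if self.T_start is not None:
            t_start = self.T_start
        return p, proto, t_start


def _missing_protocol(name):
    raise KeyError(f"unknown protocol {name!r}; available: {sorted(PROTOCOL_PRESETS)}")


@dataclass
class FreezeResult:
    """Outputs of one freezing experiment."""

    ensemble: TraceEnsemble
    profile: object
    gradient: float              # deg/nm^2, signed WLS slope
    gradient_se: float
    immobilization_T: float      # ensemble mean, K (nan if never triggered)
    immobilization_T_sd: float
    seeds: list[int]
    total_steps: int
    terminated: list[str]


def _init_state(params, proto, t_start, mode, seed, relax_duration, bd):
    rng = np.random.Generator(np.random.SFC64([seed, 0xC0F11]))
    if t_start is not None:
        return sample_equilibrium_init(params, t_start, rng)
    T0 = proto.schedule.T0
    if mode == "straight":
        return straight_state(params)
    if mode == "equilibrium":
        return sample_equilibrium_init(params, T0, rng)
    # relax_then_freeze: dynamical warm-up at T0 from straight
    warm = ThermalProtocol(
        CoolingSchedule(T0=T0, rate_v=0.0, T_stop=proto.viscosity.Ts + 0.5),
        proto.viscosity)
    cfg = replace(bd, seed=seed + 0x5EED, max_time=relax_duration)
    return run(straight_state(params), params, warm, cfg).final_state


def _cooled_protocol(proto: ThermalProtocol, t_start: float | None) -> ThermalProtocol:
    if t_start is None:
        return proto
    return ThermalProtocol(
        CoolingSchedule(T0=t_start, rate_v=proto.schedule.rate_v,
                        T_stop=proto.schedule.T_stop),
        proto.viscosity, label=proto.label + f"@{t_start:g}K")


def _run_ensemble(spec: ExperimentSpec):
    """Shared replicate loop; returns (params, protocol, final states, trajs)."""
    params, proto, t_start = spec.resolve()
    run_proto = _cooled_protocol(proto, t_start)
    if run_proto.schedule.rate_v == 0:
        cap = {"max_time": spec.isothermal_duration}
    else:
        cap = {}
    finals, trajs = [], []
    for i in range(spec.n_replicates):
        seed = spec.base_seed + i
        state = _init_state(params, run_proto, t_start, spec.init_mode, seed,
                            spec.relax_duration, spec.bd)
        cfg = replace(spec.bd, seed=seed, **cap)
        try:
            traj = run(state, params, run_proto, cfg)
        except FloatingPointError as err:
            raise RuntimeError(
                f"replicate {i} (seed {seed}) aborted: {err}") from err
        finals.append(traj.final_state)
        trajs.append(traj)
    return params, run_proto, finals, trajs


def freeze_experiment(spec: ExperimentSpec) -> FreezeResult:
    """Freeze an ensemble and reduce it to curvature statistics.

    Runs ``n_replicates`` independent trajectories (replicate i seeded with
    ``base_seed + i``) through the cooling protocol, collects the final
    shapes (clamped monomers trimmed from the traces), and computes the
    curvature profile, its weighted-least-squares gradient, and the mean
    emergent immobilisation temperature.
    """
    params, proto, finals, trajs = _run_ensemble(spec)
    ensemble = TraceEnsemble.from_states(
        finals, params.spacing,
        meta={"species": spec.species if isinstance(spec.species, str) else "custom",
              "protocol": proto.label, "seeds": [t.seed for t in trajs]},
        n_trim=params.n_fixed)
    seg = spec.segment_len if spec.segment_len is not None else 2 * params.spacing
    profile = curvature_profile(ensemble, segment_len=seg)
    slope, slope_se = curvature_gradient(profile)
    immo = np.array([t.immobilization_T for t in trajs if t.immobilization_T is not None],
                    dtype=float)
    return FreezeResult(
        ensemble=ensemble, profile=profile, gradient=slope, gradient_se=slope_se,
        immobilization_T=float(np.mean(immo)) if immo.size else float("nan"),
        immobilization_T_sd=float(np.std(immo)) if immo.size else float("nan"),
        seeds=[t.seed for t in trajs],
        total_steps=int(sum(t.n_steps for t in trajs)),
        terminated=[t.terminated_reason for t in trajs])


@dataclass
class PersistenceShiftResult:
    """Equilibrium persistence length and its apparent value after freezing."""

    P_equilibrium: PersistenceFit        # at reference_T, before freezing
    P_apparent: dict[str, PersistenceFit]
    immobilization_T: dict[str, float]
    reference_T: float
    seeds: dict[str, list[int]]


def persistence_shift_experiment(
        species: str | FilamentParams = "soft_polymer",
        protocols: tuple[str, ...] = ("HPF_1e4", "plunge_1e6", "plunge_1e7"),
        n_replicates: int = 100,
        base_seed: int = 0,
        reference_T: float = 310.0,
        init_mode: str = "equilibrium",
        relax_duration: float = 1e3,
        bd: BDConfig | None = None,
        convention: str = "decay") -> PersistenceShiftResult:
    """Two-stage experiment: equilibrate at ``reference_T``, then freeze.

    Stage 1 measures the true persistence length of the ensemble at the
    reference temperature (by direct Boltzmann sampling, or a dynamical
    warm-up when ``init_mode='relax_then_freeze'``).  Stage 2 freezes the
    same species under each protocol, with cooling starting at
    ``reference_T`` (fast rates) or from the quasi-static cold start (slow
    rates), and refits the persistence length of the immobilised shapes.
    """
    params = species if isinstance(species, FilamentParams) \
        else species_preset(species)
    if params.theta0 != 0.0:
        raise ValueError("persistence-shift experiments require theta0 = 0")
    bd = bd or BDConfig()

    # stage 1: equilibrium ensemble at the reference temperature
    rng = np.random.Generator(np.random.SFC64([base_seed, 0xE0]))
    chains = [sample_equilibrium_init(params, reference_T, rng)
              for _ in range(n_replicates)]
    ens0 = TraceEnsemble.from_states(chains, params.spacing,
                                     meta={"stage": "equilibrium",
                                           "T": reference_T})
    fit0 = fit_persistence_length(mean_cos_deflection(ens0), reference_T,
                                  convention=convention)

    apparent: dict[str, PersistenceFit] = {}
    immob: dict[str, float] = {}
    seeds: dict[str, list[int]] = {}
    for j, name in enumerate(protocols):
        proto, t_start = PROTOCOL_PRESETS[name] if isinstance(name, str) \
            else (name, None)
        proto = ThermalProtocol(
            CoolingSchedule(T0=reference_T, rate_v=proto.schedule.rate_v,
                            T_stop=proto.schedule.T_stop),
            proto.viscosity, label=proto.label)
        spec = ExperimentSpec(
            species=params, protocol=proto,
            n_replicates=n_replicates, init_mode=init_mode,
            relax_duration=relax_duration,
            base_seed=base_seed + 1000 * (j + 1), T_start=t_start, bd=bd)
        p2, rproto, finals, trajs = _run_ensemble(spec)
        ens = TraceEnsemble.from_states(finals, params.spacing,
                                        meta={"protocol": name})
        apparent[name] = fit_persistence_length(
            mean_cos_deflection(ens), reference_T, convention=convention)
        ts = [t.immobilization_T for t in trajs if t.immobilization_T is not None]
        immob[name] = float(np.mean(ts)) if ts else float("nan")
        seeds[name] = [t.seed for t in trajs]
    return PersistenceShiftResult(P_equilibrium=fit0, P_apparent=apparent,
                                  immobilization_T=immob,
                                  reference_T=reference_T, seeds=seeds)


def required_rate_scan(rigidities: list[float],
                       target_gradient: float = 0.03,
                       rates: np.ndarray | None = None,
                       n_replicates: int = 20,
                       base_seed: int = 0,
                       spacing: float = 4.0,
                       n_monomers: int = 16,
                       theta0: float = 0.2,
                       bd: BDConfig | None = None) -> list[dict]:
    """Minimal cooling rate producing a curvature gradient of the target size.

    ``rigidities`` are persistence lengths in nm (decay convention).  For
    each, cooling rates from the log-spaced grid are evaluated from the
    fastest downward until the ensemble gradient magnitude drops below
    ``target_gradient``; the crossing is bracketed by the last two rates.
    Unreachable targets are reported as censored, never extrapolated.
    """
    if rates is None:
        rates = np.logspace(5, 7.5, 6)
    rates = np.sort(np.asarray(rates, dtype=float))
    bd = bd or BDConfig()
    out = []
    for pi, P in enumerate(rigidities):
        params = params_from_persistence(P, spacing=spacing,
                                         n_monomers=n_monomers, theta0=theta0)
        grads = {}
        crossing = None
        below = None
        for ri in range(len(rates) - 1, -1, -1):
            v = rates[ri]
            proto = _make(PLUNGE_LAW, v, _AMBIENT, f"scan_{v:.3g}")
            spec = ExperimentSpec(species=params, protocol=proto,
                                  n_replicates=n_replicates,
                                  init_mode="straight",
                                  base_seed=base_seed + 10_000 * (pi + 1) + 100 * ri,
                                  bd=bd)
            res = freeze_experiment(spec)
            grads[v] = (res.gradient, res.gradient_se)
            if abs(res.gradient) >= target_gradient:
                crossing = v
            else:
                below = v
                break
        if crossing is None:
            entry = {"persistence": P, "required_rate": float("inf"),
                     "bracket": (rates[-1], float("inf")), "censored": True}
        elif below is None:
            entry = {"persistence": P, "required_rate": crossing,
                     "bracket": (0.0, crossing),
                     "censored": crossing == rates[0]}
        else:
            entry = {"persistence": P,
                     "required_rate": float(np.sqrt(below * crossing)),
                     "bracket": (below, crossing), "censored": False}
        entry["gradients"] = grads
        out.append(entry)
    return out


def length_independence_check(lengths_nm: tuple[float, ...] = (56.0, 88.0, 120.0),
                              rate: float = 1.28e7,
                              persistence: float = 2100.0,
                              n_replicates: int = 20,
                              base_seed: int = 0,
                              spacing: float = 4.0,
                              theta0: float = 0.2,
                              common_fit_range: bool = True,
                              bd: BDConfig | None = None) -> dict:
    """Curvature gradients for several filament lengths at one cooling rate.

    Length L counts ``L / spacing`` monomers (the clamped dimer included).
    By default the gradient of every length is fitted over the same
    near-tip window (the usable range of the shortest filament), so the
    comparison is not confounded by the fit span.  Returns per-length
    gradients and the maximum pairwise difference in units of the pooled
    standard error.
    """
    bd = bd or BDConfig()
    proto = _make(PLUNGE_LAW, rate, _AMBIENT, f"length_check_{rate:.3g}")
    fit_range = None
    if common_fit_range:
        n_min = int(round(min(lengths_nm) / spacing))
        fit_range = (0.0, (n_min - 2 - 1) * spacing - 2 * spacing)
    results = {}
    for li, L in enumerate(lengths_nm):
        n = int(round(L / spacing))
        params = params_from_persistence(persistence, spacing=spacing,
                                         n_monomers=n, theta0=theta0)
        spec = ExperimentSpec(species=params, protocol=proto,
                              n_replicates=n_replicates, init_mode="straight",
                              base_seed=base_seed + 1000 * (li + 1), bd=bd)
        res = freeze_experiment(spec)
        g, se = curvature_gradient(res.profile, fit_range=fit_range)
        results[L] = {"n_monomers": n, "gradient": g, "gradient_se": se}
    grads = [r["gradient"] for r in results.values()]
    ses = [r["gradient_se"] for r in results.values()]
    pooled = float(np.sqrt(np.mean(np.square(ses)) * 2))
    max_diff = float(np.max(np.abs(np.subtract.outer(grads, grads))))
    return {"per_length": results, "max_pairwise_diff": max_diff,
            "pooled_se": pooled, "max_diff_over_se": max_diff / pooled}
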