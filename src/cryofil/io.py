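"""Configuration files, output writers, and provenance stamping.

Configs are YAML with three sections (``species``, ``protocol``,
``experiment``); every physical key carries its unit in its name.  Unknown
keys are rejected with their full path — silent typos in stiffnesses are
how simulation studies die.  All outputs embed the config hash and the seed
list, so any table can be regenerated bit-exactly from its own header.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import CurvatureProfile, PersistenceFit, TraceEnsemble
from .environment import (VISCOSITY_PRESETS, CoolingSchedule, ThermalProtocol,
                          ViscosityLaw)
from .integrator import BDConfig, Trajectory
from .params import SPECIES_PRESETS, FilamentParams
from .protocols import PROTOCOL_PRESETS, ExperimentSpec

__all__ = [
    "RunConfig", "load_config", "dump_config", "config_hash",
    "write_traces", "read_traces", "write_profile", "write_trajectory",
]

_SPECIES_KEYS = {
    "preset": str,
    "n_monomers": int,
    "radius_nm": float,
    "bend_stiffness_kT_per_rad2": float,
    "theta0_rad": float,
    "bond_stiffness_kT_per_nm2": float,
    "n_fixed": int,
}
_PROTOCOL_KEYS = {
    "preset": str,
    "viscosity_preset": str,
    "eta0_Pa_s": float,
    "Ts_K": float,
    "gamma": float,
    "T0_K": float,
    "cooling_rate_K_per_s": float,
    "T_stop_K": float,
}
_EXPERIMENT_KEYS = {
    "n_replicates": int,
    "init_mode": str,
    "base_seed": int,
    "T_start_K": float,
    "segment_len_nm": float,
    "persistence_convention": str,
    "dt_policy": object,
    "safety": float,
    "scheme": str,
    "isothermal_duration_us": float,
}


@dataclass
class RunConfig:
    """Validated, fully resolved configuration of one experiment."""

    spec: ExperimentSpec
    persistence_convention: str = "decay"
    raw: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def _check_keys(section: dict, allowed: dict, path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ValueError(f"unknown config key {path}.{key!r} "
                             f"(allowed: {sorted(allowed)})")


def _species_from(section: dict) -> FilamentParams | str:
    _check_keys(section, _SPECIES_KEYS, "species")
    if "preset" in section:
        base = SPECIES_PRESETS.get(section["preset"])
        if base is None:
            raise ValueError(f"species.preset: unknown preset {section['preset']!r}")
        over = {k: v for k, v in section.items() if k != "preset"}
        if not over:
            return section["preset"]
        mapping = {"n_monomers": "n_monomers", "radius_nm": "radius",
                   "bend_stiffness_kT_per_rad2": "bend_stiffness_b",
                   "theta0_rad": "theta0",
                   "bond_stiffness_kT_per_nm2": "bond_stiffness_k",
                   "n_fixed": "n_fixed"}
        return base.with_(**{mapping[k]: v for k, v in over.items()})
    try:
        return FilamentParams(
            n_monomers=int(section["n_monomers"]),
            radius=float(section["radius_nm"]),
            bend_stiffness_b=float(section["bend_stiffness_kT_per_rad2"]),
            theta0=float(section.get("theta0_rad", 0.0)),
            bond_stiffness_k=float(section.get("bond_stiffness_kT_per_nm2", 100.0)),
            n_fixed=int(section.get("n_fixed", 1)),
        )
    except KeyError as err:
        raise ValueError(f"species: missing required key {err}") from None
    except ValueError as err:
        raise ValueError(f"species: {err}") from None


def _protocol_from(section: dict) -> ThermalProtocol | str:
    _check_keys(section, _PROTOCOL_KEYS, "protocol")
    if "preset" in section and len(section) == 1:
        if section["preset"] not in PROTOCOL_PRESETS:
            raise ValueError(f"protocol.preset: unknown preset {section['preset']!r}")
        return section["preset"]
    if "viscosity_preset" in section:
        law = VISCOSITY_PRESETS.get(section["viscosity_preset"])
        if law is None:
            raise ValueError(
                f"protocol.viscosity_preset: unknown {section['viscosity_preset']!r}")
    else:
        try:
            law = ViscosityLaw(eta0=float(section["eta0_Pa_s"]),
                               Ts=float(section["Ts_K"]),
                               gamma=float(section["gamma"]), label="custom")
        except KeyError as err:
            raise ValueError(f"protocol: missing required key {err}") from None
    try:
        T0 = float(section["T0_K"])
        v = float(section["cooling_rate_K_per_s"])
    except KeyError as err:
        raise ValueError(f"protocol: missing required key {err}") from None
    T_stop = float(section.get("T_stop_K", law.Ts + 0.5))
    try:
        return ThermalProtocol(CoolingSchedule(T0=T0, rate_v=v, T_stop=T_stop),
                               law, label=section.get("preset", "custom"))
    except ValueError as err:
        raise ValueError(f"protocol: {err}") from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML experiment config.

    Unknown keys anywhere raise with the full key path.  Presets expand to
    their printed parameter values; explicit keys override preset fields.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    for key in raw:
        if key not in ("species", "protocol", "experiment"):
            raise ValueError(f"unknown config section {key!r}")
    sp = _species_from(raw.get("species", {"preset": "floppy_pf"}))
    proto = _protocol_from(raw.get("protocol", {"preset": "plunge_1e6"}))
    exp = dict(raw.get("experiment", {}))
    _check_keys(exp, _EXPERIMENT_KEYS, "experiment")
    bd = BDConfig(
        seed=int(exp.get("base_seed", 0)),
        dt_policy=exp.get("dt_policy", "adaptive"),
        safety=float(exp.get("safety", 0.1)),
        scheme=exp.get("scheme", "lm"),
    )
    spec = ExperimentSpec(
        species=sp, protocol=proto,
        n_replicates=int(exp.get("n_replicates", 40)),
        init_mode=exp.get("init_mode", "straight"),
        base_seed=int(exp.get("base_seed", 0)),
        T_start=exp.get("T_start_K"),
        segment_len=exp.get("segment_len_nm"),
        isothermal_duration=float(exp.get("isothermal_duration_us", 1e4)),
        bd=bd,
    )
    return RunConfig(spec=spec,
                     persistence_convention=exp.get("persistence_convention", "decay"),
                     raw=raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.raw, sort_keys=True))


def config_hash(raw: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _header(meta: dict) -> str:
    lines = ["# cryofil output"]
    for k, v in meta.items():
        lines.append(f"# {k}: {json.dumps(v, default=str)}")
    return "\n".join(lines) + "\n"


def write_traces(ensemble: TraceEnsemble, path: str | Path,
                 meta: dict | None = None) -> None:
    """Write a trace ensemble as commented-header CSV.

    Columns: replicate, monomer_index (0 = free tip), x_nm, y_nm.
    """
    rows = []
    for r, t in enumerate(ensemble.traces):
        for i, (x, y) in enumerate(t):
            rows.append((r, i, x, y))
    df = pd.DataFrame(rows, columns=["replicate", "monomer_index", "x_nm", "y_nm"])
    m = {"spacing_nm": ensemble.spacing, **ensemble.meta, **(meta or {})}
    buf = _io.StringIO()
    buf.write(_header(m))
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_traces(path: str | Path) -> TraceEnsemble:
    """Read a trace-ensemble CSV written by :func:`write_traces` (or any
    table with replicate, monomer_index, x_nm, y_nm columns; tip first)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for ln in lines:
        if ln.startswith("#"):
            body_start += 1
            if ":" in ln:
                k, _, v = ln[1:].partition(":")
                try:
                    meta[k.strip()] = json.loads(v.strip())
                except json.JSONDecodeError:
                    meta[k.strip()] = v.strip()
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    traces = []
    for _, grp in df.groupby("replicate"):
        grp = grp.sort_values("monomer_index")
        traces.append(np.column_stack([grp["x_nm"], grp["y_nm"]]))
    spacing = meta.pop("spacing_nm", None)
    if spacing is None:
        spacing = float(np.median(np.linalg.norm(np.diff(traces[0], axis=0), axis=1)))
    return TraceEnsemble(traces, float(spacing), meta)


def write_profile(profile: CurvatureProfile, path: str | Path,
                  meta: dict | None = None) -> None:
    df = pd.DataFrame({
        "distance_from_tip_nm": profile.distance_from_tip,
        "mean_curvature_deg_per_nm": profile.mean_curvature,
        "sem_curvature_deg_per_nm": profile.sem_curvature,
        "n_per_bin": profile.n_per_bin,
    })
    m = {"segment_len_nm": profile.segment_len,
         "n_excluded": profile.n_excluded, **(meta or {})}
    buf = _io.StringIO()
    buf.write(_header(m))
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_trajectory(traj: Trajectory, path: str | Path,
                     meta: dict | None = None) -> None:
    """Columnar text trajectory: one row per recorded monomer-state."""
    rows = []
    for si, state in enumerate(list(traj.states) + [traj.final_state]):
        t_s, T_K, eta = traj.schedule_log[min(si, traj.schedule_log.shape[0] - 1)]
        for i in range(state.n):
            rows.append((traj.seed, si, t_s, T_K, eta, i,
                         state.x[i], state.y[i], state.theta[i]))
    df = pd.DataFrame(rows, columns=["replicate", "snapshot", "time_s", "T_K",
                                     "eta_Pas", "monomer_index", "x_nm",
                                     "y_nm", "theta_rad"])
    m = {"terminated": traj.terminated_reason, "n_steps": traj.n_steps,
         "seed": traj.seed, **(meta or {})}
    buf = _io.StringIO()
    buf.write(_header(m))
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def persistence_fit_dict(fit: PersistenceFit) -> dict:
    return {"P_hat_nm": fit.P_hat, "P_se_nm": fit.P_se,
            "temperature_ref_K": fit.temperature_ref,
            "convention": fit.convention, "lower_bound": fit.lower_bound}
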