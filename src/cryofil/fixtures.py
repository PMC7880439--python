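"""Synthetic trace generators with exactly known shape statistics.

These are the oracles for the estimator layer: an arc of radius R has
curvature 180/(pi R) deg/nm everywhere; a trace built with a prescribed
curvature ramp has that ramp; a chain of independent Gaussian joint angles
with per-joint variance sigma^2 has mean tangent cosine exp(-n sigma^2 / 2)
at a separation of n joints.
"""

from __future__ import annotations

import numpy as np

from .analysis import TraceEnsemble

__all__ = ["make_fixture_traces"]


def _polyline_from_headings(headings: np.ndarray, spacing: float) -> np.ndarray:
    """Points of a unit-speed polyline whose segment j has angle headings[j]."""
    steps = spacing * np.column_stack([np.cos(headings), np.sin(headings)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts


def make_fixture_traces(kind: str, *, n_points: int = 16, spacing: float = 4.0,
                        n_traces: int = 1, radius: float = 28.65,
                        kappa0: float = 0.5, kappa_slope: float = 0.03,
                        sigma2: float = 0.02,
                        rng: np.random.Generator | None = None) -> TraceEnsemble:
    """Build an ensemble of analytically constructed traces.

    kind:
        ``"straight"`` — zero curvature everywhere (P formally infinite).
        ``"arc"`` — circle of ``radius`` nm: uniform curvature
        180/(pi*radius) deg/nm.
        ``"linear-curvature"`` — curvature kappa(s) = kappa0 + kappa_slope*s
        (deg/nm, s from the tip at the first point).
        ``"gaussian-chain"`` — independent Normal(0, sigma2) joint angles:
        mean cosine decay exp(-n*sigma2/2) at separation n joints.
    """
    rng = rng or np.random.default_rng(0)
    nseg = n_points - 1
    traces = []
    for _ in range(n_traces):
        if kind == "straight":
            headings = np.zeros(nseg)
        elif kind == "arc":
            # turning per segment = spacing / radius (radians)
            headings = np.arange(nseg) * (spacing / radius)
        elif kind == "linear-curvature":
            # heading increment between segments j and j+1 equals the
            # curvature at the shared point s = (j+1)*spacing
            s_joint = np.arange(1, nseg) * spacing
            turn = np.radians((kappa0 + kappa_slope * s_joint) * spacing)
            headings = np.concatenate([[0.0], np.cumsum(turn)])
        elif kind == "gaussian-chain":
            joints = rng.normal(0.0, np.sqrt(sigma2), size=nseg - 1)
            headings = np.concatenate([[0.0], np.cumsum(joints)])
        else:
            raise ValueError(f"unknown fixture kind {kind!r}")
        traces.append(_polyline_from_headings(headings, spacing))
    meta = {"kind": kind, "spacing": spacing}
    if kind == "straight":
        meta["persistence"] = np.inf
    elif kind == "arc":
        meta["curvature_deg_per_nm"] = float(np.degrees(1.0 / radius))
    elif kind == "linear-curvature":
        meta["kappa0"] = kappa0
        meta["kappa_slope"] = kappa_slope
    elif kind == "gaussian-chain":
        meta["sigma2"] = sigma2
        meta["decay_length"] = 2.0 * spacing / sigma2
    return TraceEnsemble(traces, spacing, meta)
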