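"""Shape statistics of filament traces: curvature profiles, curvature
gradients, and persistence-length estimation.

A *trace* is the ordered sequence of monomer centres of one filament, tip
(free end) first.  Curvature is estimated from the turning angle between
successive chords of a fixed segment length — the same estimator applied to
experimental filament traces — and reported in deg/nm as an unsigned
magnitude.  The curvature *gradient* is the weighted least-squares slope of
mean curvature versus arc distance from the tip, in deg/nm^2; a filament
whose tip is more strongly curved than its base has a negative slope, and
the magnitude is the headline artifact statistic.

Persistence length is estimated from the decay of the mean cosine of the
tangent deflection with arc distance.  Two conventions are supported (see
:meth:`cryofil.params.FilamentParams.persistence_length`): the default
``"decay"`` fits ``<cos> = exp(-s/P)`` so P is the bare decay length
(= 2B/kBT for planar equilibrium chains); ``"planar"`` fits
``exp(-s/(2P))`` so P = B/kBT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .model import FilamentState

__all__ = [
    "TraceEnsemble",
    "CurvatureProfile",
    "PersistenceFit",
    "curvature_profile",
    "curvature_gradient",
    "mean_cos_deflection",
    "fit_persistence_length",
]


@dataclass
class TraceEnsemble:
    """A set of filament traces (tip-first 2D point chains) plus provenance.

    ``traces`` is a list of (n_i, 2) arrays in nm.  ``spacing`` is the
    nominal monomer spacing; consecutive points should sit within 20% of it.
    """

    traces: list[np.ndarray]
    spacing: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = [np.asarray(t, dtype=float) for t in self.traces]
        for i, t in enumerate(self.traces):
            if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 3:
                raise ValueError(f"trace {i} must be an (n>=3, 2) array")
            d = np.linalg.norm(np.diff(t, axis=0), axis=1)
            # spacing sanity: the typical spacing must match the nominal one
            # (catches wrong metadata/units); individual spacings may deviate
            # more because sharp thermal bends geometrically contract the
            # centre-to-centre distance
            dev = np.abs(d - self.spacing) / self.spacing
            if abs(np.median(d) - self.spacing) > 0.2 * self.spacing \
                    or np.any(dev > 0.6):
                raise ValueError(
                    f"trace {i}: point spacing inconsistent with nominal "
                    f"({self.spacing} nm)"
                )

    @classmethod
    def from_states(cls, states: list[FilamentState], spacing: float,
                    meta: dict | None = None, n_trim: int = 0) -> "TraceEnsemble":
        """Build from simulation states; monomer order is reversed so the
        free tip comes first.  ``n_trim`` drops that many monomers at the
        clamped end (e.g. the anchored dimer)."""
        traces = []
        for s in states:
            p = s.positions()[::-1]
            traces.append(p[:p.shape[0] - n_trim])
        return cls(traces, spacing, meta or {})

    def __len__(self) -> int:
        return len(self.traces)


@dataclass
class CurvatureProfile:
    """Mean curvature versus arc distance from the free tip."""

    distance_from_tip: np.ndarray   # bin centres, nm
    mean_curvature: np.ndarray      # deg/nm
    sem_curvature: np.ndarray       # deg/nm
    n_per_bin: np.ndarray
    segment_len: float = np.nan
    n_excluded: int = 0
    #: (n_traces, n_bins) per-replicate curvature, NaN where a trace is too
    #: short for a bin; carries the replicate structure that the gradient's
    #: jackknife error needs (bins of one trace are strongly correlated).
    per_replicate: np.ndarray | None = None


@dataclass
class PersistenceFit:
    """Fitted persistence length with uncertainty."""

    P_hat: float                    # nm
    P_se: float                     # nm
    decay_curve: np.ndarray         # columns: distance s (nm), mean cosine
    temperature_ref: float          # K, for interpretation via P = B/kBT
    convention: str = "decay"
    lower_bound: bool = False       # True when the data do not decay


def _tangent_angles(trace: np.ndarray) -> np.ndarray:
    seg = np.diff(trace, axis=0)
    return np.arctan2(seg[:, 1], seg[:, 0])


def curvature_profile(ensemble: TraceEnsemble,
                      segment_len: float = 8.0) -> CurvatureProfile:
    """Chord-based curvature profile binned by distance from the tip.

    For each trace, the local curvature attributed to arc position
    ``s = (j+m) * spacing`` (the point shared by two chords of length
    ``segment_len = m * spacing``) is the unsigned turning angle between
    those chords divided by ``segment_len``, in deg/nm.  Traces shorter than
    two segments are excluded (counted in ``n_excluded``).
    """
    d = ensemble.spacing
    m = int(round(segment_len / d))
    if m < 2:
        raise ValueError("segment_len must be at least 2 monomer spacings")
    rows = []
    n_excluded = 0
    max_bin = 0
    for trace in ensemble.traces:
        n = trace.shape[0]
        if n < 2 * m + 1:
            n_excluded += 1
            continue
        max_bin = max(max_bin, n - m - 1)
        row = {}
        for j in range(n - 2 * m):
            v1 = trace[j + m] - trace[j]
            v2 = trace[j + 2 * m] - trace[j + m]
            ang = np.arctan2(v1[0] * v2[1] - v1[1] * v2[0],
                             v1[0] * v2[0] + v1[1] * v2[1])
            row[j + m] = np.degrees(abs(ang)) / (m * d)
        rows.append(row)
    if n_excluded:
        warnings.warn(f"{n_excluded} trace(s) shorter than two segments excluded")
    if not rows:
        raise ValueError("no trace is long enough for this segment length")
    idx = np.arange(m, max_bin + 1)
    per_rep = np.full((len(rows), idx.size), np.nan)
    for r, row in enumerate(rows):
        for k, v in row.items():
            per_rep[r, k - m] = v
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_rep, axis=0)
        cnt = np.sum(np.isfinite(per_rep), axis=0)
        sem = np.nanstd(per_rep, axis=0, ddof=1) / np.sqrt(np.maximum(cnt, 1))
    sem[cnt < 2] = np.nan
    return CurvatureProfile(idx * d, mean, sem, cnt, segment_len=m * d,
                            n_excluded=n_excluded, per_replicate=per_rep)


def curvature_gradient(profile: CurvatureProfile,
                       fit_range: tuple[float, float] | None = None
                       ) -> tuple[float, float]:
    """Weighted least-squares slope of curvature vs distance from tip.

    Returns ``(slope, slope_se)`` in deg/nm^2.  The point estimate is the
    WLS slope of the mean profile with weights 1/sem^2.  Because every
    replicate contributes to all bins (and neighbouring bins share chord
    segments), bin means are correlated; the error is therefore estimated
    by a leave-one-replicate-out jackknife rather than from the naive WLS
    covariance.  A negative slope means the tip is more curved than the
    base; report the magnitude when quoting "the" curvature gradient.
    """
    x = profile.distance_from_tip
    per = profile.per_replicate
    if fit_range is not None:
        mask = (x >= fit_range[0]) & (x <= fit_range[1])
        x = x[mask]
        per = per[:, mask] if per is not None else None
    if per is None:
        raise ValueError("profile lacks per-replicate data")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x-range for gradient fit")

    def wls_slope(mat: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cnt = np.sum(np.isfinite(mat), axis=0)
            ym = np.nanmean(mat, axis=0)
            sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(cnt, 1))
        ok = (cnt >= 2) & np.isfinite(sem) & (sem > 0)
        if np.sum(ok) < 3:
            raise ValueError(
                "need at least 3 bins with valid errors inside fit_range")
        w = 1.0 / sem[ok] ** 2
        xv, yv = x[ok], ym[ok]
        xbar = np.sum(w * xv) / np.sum(w)
        ybar = np.sum(w * yv) / np.sum(w)
        sxx = np.sum(w * (xv - xbar) ** 2)
        return float(np.sum(w * (xv - xbar) * (yv - ybar)) / sxx)

    slope = wls_slope(per)
    n_rep = per.shape[0]
    if n_rep < 3:
        raise ValueError("need at least 3 replicates for the jackknife error")
    jack = np.array([wls_slope(np.delete(per, i, axis=0)) for i in range(n_rep)])
    slope_se = float(np.sqrt((n_rep - 1) / n_rep * np.sum((jack - jack.mean()) ** 2)))
    return slope, slope_se


def mean_cos_deflection(ensemble: TraceEnsemble) -> np.ndarray:
    """Mean cosine of the tangent deflection versus arc distance from the tip.

    For each trace the tangent angle of segment ``j`` (tip-first ordering)
    is compared against the tangent of the first segment at the free tip;
    the cosine is averaged across traces at each arc separation
    ``s = j * spacing``.  Intended for intrinsically straight species
    (theta0 = 0).

    Returns an array with columns (s, mean cos); the first row is (0, 1).
    """
    d = ensemble.spacing
    nseg = min(t.shape[0] for t in ensemble.traces) - 1
    acc = np.zeros(nseg)
    for trace in ensemble.traces:
        phi = _tangent_angles(trace[:nseg + 1])
        acc += np.cos(phi - phi[0])
    mean = acc / len(ensemble.traces)
    s = np.arange(nseg) * d
    return np.column_stack([s, mean])


def fit_persistence_length(decay: np.ndarray, temperature: float,
                           convention: str = "decay") -> PersistenceFit:
    """Fit the exponential tangent-correlation decay.

    ``decay`` holds (arc distance nm, mean cosine) pairs starting at (0, 1).
    Under ``convention="decay"`` the model is ``exp(-s/P)``; under
    ``"planar"`` it is ``exp(-s/(2P))``.  Non-decaying data yield
    ``lower_bound=True`` with P set to the resolvable lower bound.
    """
    decay = np.asarray(decay, dtype=float)
    if decay.ndim != 2 or decay.shape[1] != 2 or decay.shape[0] < 4:
        raise ValueError("decay must be an (n>=4, 2) array of (s, mean cos)")
    if abs(decay[0, 1] - 1.0) > 1e-9 or decay[0, 0] != 0.0:
        raise ValueError("first decay point must be (0, 1)")
    if convention not in ("decay", "planar"):
        raise ValueError(f"unknown persistence convention: {convention!r}")
    s, c = decay[:, 0], decay[:, 1]
    factor = 1.0 if convention == "decay" else 2.0
    if np.min(c) > 1.0 - 1e-6:
        # no measurable decay over the trace length
        return PersistenceFit(P_hat=np.inf, P_se=np.inf, decay_curve=decay,
                              temperature_ref=temperature,
                              convention=convention, lower_bound=True)
    ell0 = max(s[-1] / max(-np.log(max(c[-1], 1e-12)), 1e-9), s[1])
    popt, pcov = curve_fit(lambda ss, ell: np.exp(-ss / ell), s, c,
                           p0=[ell0], maxfev=10000)
    ell, ell_var = float(popt[0]), float(pcov[0, 0])
    return PersistenceFit(P_hat=ell / factor,
                          P_se=np.sqrt(max(ell_var, 0.0)) / factor,
                          decay_curve=decay, temperature_ref=temperature,
                          convention=convention)
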