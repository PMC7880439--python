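"""Mechanical parameters of a bead-chain filament and the named species presets.

A filament is a planar chain of identical spheres.  Adjacent spheres are
joined by a harmonic bending potential acting on the difference of their
orientation angles,

    W(theta) = b/2 (dtheta - theta0)^2,

and a harmonic longitudinal bond acting on the distance r between the two
interaction sites at the facing poles of the spheres,

    U(r) = k/2 r^2.

``b`` and ``k`` are stored in internal energy units (kT at 295.15 K); see
:mod:`cryofil.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .constants import T_REF, kcal_per_mol_to_kt, kt_at


@dataclass(frozen=True)
class FilamentParams:
    """Mechanical and geometric constants of one filament species.

    Parameters
    ----------
    n_monomers:
        Number of spheres in the chain (>= 2).
    radius:
        Sphere radius in nm.  The nominal monomer spacing is ``2 * radius``.
    bend_stiffness_b:
        Flexural rigidity of each inter-monomer joint, kT/rad^2 (kT at
        295.15 K).
    theta0:
        Equilibrium bend angle per joint, rad.  0 for intrinsically straight
        polymers.
    bond_stiffness_k:
        Harmonic stiffness of the longitudinal bond, kT/nm^2.
    n_fixed:
        Number of monomers at the minus end whose coordinates (and
        orientations) are clamped.  A microtubule protofilament keeps one
        whole dimer (2 monomers) in the lattice.
    """

    n_monomers: int
    radius: float
    bend_stiffness_b: float
    theta0: float = 0.0
    bond_stiffness_k: float = 100.0
    n_fixed: int = 2

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError(f"n_monomers must be >= 2, got {self.n_monomers}")
        if not (1 <= self.n_fixed < self.n_monomers):
            raise ValueError(
                f"n_fixed must satisfy 1 <= n_fixed < n_monomers, got {self.n_fixed}"
            )
        for name in ("radius", "bend_stiffness_b", "bond_stiffness_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def spacing(self) -> float:
        """Nominal center-to-center monomer spacing, nm."""
        return 2.0 * self.radius

    @property
    def contour_length(self) -> float:
        """Nominal contour length of the whole chain, nm."""
        return (self.n_monomers - 1) * self.spacing

    @property
    def bending_modulus(self) -> float:
        """Continuum bending modulus B = b * spacing, in kT(295.15 K) * nm."""
        return self.bend_stiffness_b * self.spacing

    def persistence_length(self, temperature: float = T_REF,
                           convention: str = "decay") -> float:
        """Equilibrium persistence length at ``temperature`` (K), nm.

        ``convention="decay"`` returns the bare e-folding length of the mean
        tangent cosine of a planar chain, 2 B / kB T -- the number obtained
        when the textbook 3D formula <cos> = exp(-s/P) is applied to 2D
        traces, and the convention under which the tubulin presets map to
        their published persistence lengths.  ``convention="planar"`` returns
        the strict planar worm-like-chain value B / kB T (the decay is then
        exp(-s/2P)).
        """
        base = self.bending_modulus / kt_at(temperature)
        if convention == "decay":
            return 2.0 * base
        if convention == "planar":
            return base
        raise ValueError(f"unknown persistence convention: {convention!r}")

    def with_(self, **changes) -> "FilamentParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _soft_b_kt() -> float:
    # 3.3 kcal/mol/rad^2 converted at the 310 K simulation temperature,
    # then expressed in the internal kT(295.15 K) unit.
    b_kt310 = kcal_per_mol_to_kt(3.3, 310.0)
    return b_kt310 * 310.0 / T_REF


#: 'Floppy' tubulin protofilament: b = 58 kT/rad^2 (P ~ 0.5 um).
FLOPPY_PF = FilamentParams(n_monomers=16, radius=2.0, bend_stiffness_b=58.0,
                           theta0=0.2, bond_stiffness_k=100.0, n_fixed=2)

#: 'Rigid' tubulin protofilament: b = 300 kT/rad^2 (P ~ 2.5 um).
RIGID_PF = FLOPPY_PF.with_(bend_stiffness_b=300.0)

#: Generic soft polymer: 16 spheres of 2.4 nm diameter, b = 3.3 kcal/mol/rad^2,
#: no intrinsic curvature, one anchored sphere.  The weaker bond stiffness
#: (25 kT/nm^2; rms site separation ~0.3 nm, still small against the 2.4 nm
#: spacing) keeps the stability-limited time step practical for this species.
SOFT_POLYMER = FilamentParams(n_monomers=16, radius=1.2,
                              bend_stiffness_b=_soft_b_kt(), theta0=0.0,
                              bond_stiffness_k=25.0, n_fixed=1)

SPECIES_PRESETS: dict[str, FilamentParams] = {
    "floppy_pf": FLOPPY_PF,
    "rigid_pf": RIGID_PF,
    "soft_polymer": SOFT_POLYMER,
}


def species(name: str) -> FilamentParams:
    """Look up a species preset by name."""
    try:
        return SPECIES_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown species {name!r}; available: {sorted(SPECIES_PRESETS)}"
        ) from None


def params_from_persistence(persistence_nm: float, *, spacing: float = 4.0,
                            n_monomers: int = 16, theta0: float = 0.2,
                            temperature: float = T_REF,
                            convention: str = "decay",
                            **kwargs) -> FilamentParams:
    """Build a species whose equilibrium persistence length is ``persistence_nm``.

    Inverts :meth:`FilamentParams.persistence_length` under the given
    convention; used for rigidity scans specified in persistence-length terms.
    """
    factor = 2.0 if convention == "decay" else 1.0
    if convention not in ("decay", "planar"):
        raise ValueError(f"unknown persistence convention: {convention!r}")
    b = persistence_nm * kt_at(temperature) / (factor * spacing)
    return FilamentParams(n_monomers=n_monomers, radius=spacing / 2.0,
                          bend_stiffness_b=b, theta0=theta0, **kwargs)
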