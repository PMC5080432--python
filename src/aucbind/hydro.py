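"""Closed-form hydrodynamics of sedimenting nanoparticle–protein complexes.

This module collects the analytic relations that connect a particle's size
and density to its sedimentation coefficient ``s`` and translational
diffusion coefficient ``D`` in a sedimentation-velocity (SV) experiment,
and builds from them the binding model for protein adsorption on a
nanoparticle (NP):

* the Svedberg/Stokes relation for a sphere,
  ``s = d_H² (ρ_p − ρ_s) / (18 η)``;
* the Stokes–Einstein relation ``D = k_B T / (3 π η d_H)``;
* its inversion ``(s, D) → (d_H, ρ_p)`` used to size particles from SV data;
* the volume-weighted density of an NP–protein complex carrying ``N_avg``
  proteins;
* the sphere-equivalent sedimentation coefficient of that complex;
* the Hill adsorption isotherm ``N_avg([P])`` with dissociation constant
  ``K_D``, saturation stoichiometry ``N_max`` and cooperativity ``n``;
* the full forward model ``s̄([P])`` obtained by composing the above, which
  is what gets fitted to measured binding isotherms;
* the frictional ratio ``f/f₀`` computed from an ``(s, D)`` pair, the
  standard shape indicator (1 for a sphere, >1 for elongated species).

All functions take and return SI quantities; see :mod:`aucbind.units` for
converters to Svedberg, g/cm³ etc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .units import K_B

__all__ = [
    "SolventModel",
    "ParticleSpec",
    "ProteinSpec",
    "InteractionParams",
    "WATER_20C",
    "BSA",
    "sedimentation_coefficient",
    "diffusion_coefficient",
    "particle_from_sD",
    "complex_density",
    "complex_s",
    "complex_volume",
    "complex_diameter",
    "hill_n_avg",
    "isotherm_s",
    "frictional_ratio",
    "diffusion_from_s_fr",
]


@dataclass(frozen=True)
class SolventModel:
    """Solvent properties entering the hydrodynamic relations.

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity η in Pa·s.
    density : float
        Mass density ρ_s in kg/m³.
    temperature : float
        Absolute temperature in K.
    """

    viscosity: float = 1.002e-3
    density: float = 998.23
    temperature: float = 293.15

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if not 250.0 < self.temperature < 373.0:
            raise ValueError(
                f"temperature {self.temperature} K outside plausible "
                "liquid-water range (250, 373)"
            )


#: Water at 20 °C, the default SV measurement condition.
WATER_20C = SolventModel()


@dataclass(frozen=True)
class ParticleSpec:
    """A sedimenting particle modelled as an equivalent sphere.

    Parameters
    ----------
    hydrodynamic_diameter : float
        Stokes-equivalent diameter d_H in m.
    density : float
        Particle density ρ_p in kg/m³ (hydrodynamic, i.e. including the
        ligand shell for a coated NP).
    label : str
        Free-text identifier.
    """

    hydrodynamic_diameter: float
    density: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.hydrodynamic_diameter <= 0:
            raise ValueError("hydrodynamic_diameter must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")

    @property
    def volume(self) -> float:
        """Total hydrodynamic volume V = (π/6) d³ in m³."""
        return math.pi / 6.0 * self.hydrodynamic_diameter**3


# BSA modelled as an equilateral triangular prism (8.4 nm edge, 3.2 nm
# thick): V = (√3/4)·edge²·thickness ≈ 97.8 nm³.
_BSA_VOLUME_M3 = math.sqrt(3.0) / 4.0 * (8.4e-9) ** 2 * 3.2e-9


@dataclass(frozen=True)
class ProteinSpec:
    """A protein characterized by hydrodynamic volume and density.

    Parameters
    ----------
    hydrodynamic_volume : float
        V_P in m³.
    density : float
        ρ_P in kg/m³.  Globular proteins fall in 1200–1300 kg/m³; a warning
        is emitted outside 1000–2000.
    label : str
        Free-text identifier.
    """

    hydrodynamic_volume: float = _BSA_VOLUME_M3
    density: float = 1300.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.hydrodynamic_volume <= 0:
            raise ValueError("hydrodynamic_volume must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if not 1000.0 < self.density < 2000.0:
            warnings.warn(
                f"protein density {self.density} kg/m³ outside the typical "
                "1000-2000 kg/m³ range",
                stacklevel=2,
            )

    @property
    def equivalent_diameter(self) -> float:
        """Diameter of the sphere with the same hydrodynamic volume (m)."""
        return (6.0 * self.hydrodynamic_volume / math.pi) ** (1.0 / 3.0)


#: Bovine serum albumin with the triangular-prism volume and ρ = 1.3 g/cm³.
BSA = ProteinSpec(label="BSA")


@dataclass(frozen=True)
class InteractionParams:
    """Hill-model parameters of NP–protein association.

    Parameters
    ----------
    k_d : float
        Dissociation constant K_D in mol/L: the free-protein concentration
        at half-maximal coverage.
    n_max : float
        Maximum (saturation) number of proteins per particle; real-valued
        because it is an ensemble average.
    hill_n : float
        Hill coefficient; <1 anti-cooperative, >1 cooperative.
    """

    k_d: float
    n_max: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValueError("k_d must be > 0")
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")


def sedimentation_coefficient(
    particle: ParticleSpec, solvent: SolventModel = WATER_20C
) -> float:
    """Sedimentation coefficient of a sphere, in seconds.

    ``s = d_H² (ρ_p − ρ_s) / (18 η)``.  Negative values (floating species,
    ρ_p < ρ_s) are returned as-is.
    """
    d = particle.hydrodynamic_diameter
    return d * d * (particle.density - solvent.density) / (18.0 * solvent.viscosity)


def diffusion_coefficient(
    particle: ParticleSpec, solvent: SolventModel = WATER_20C
) -> float:
    """Translational diffusion coefficient from Stokes–Einstein, m²/s.

    ``D = k_B T / (3 π η d_H)``.
    """
    return K_B * solvent.temperature / (
        3.0 * math.pi * solvent.viscosity * particle.hydrodynamic_diameter
    )


def particle_from_sD(
    s: float, d_coeff: float, solvent: SolventModel = WATER_20C, label: str = ""
) -> ParticleSpec:
    """Invert an ``(s, D)`` pair into a sphere-equivalent particle.

    ``d_H = k_B T / (3 π η D)`` from Stokes–Einstein, then
    ``ρ_p = ρ_s + 18 η s / d_H²`` from the Svedberg/Stokes relation.  This is
    the standard sizing route for SV data on dense colloids, where both the
    diameter and the (unknown) particle density are wanted.

    Parameters
    ----------
    s : float
        Sedimentation coefficient in seconds (> 0).
    d_coeff : float
        Diffusion coefficient in m²/s (> 0).
    """
    if s <= 0:
        raise ValueError(f"s must be > 0 for a sedimenting species, got {s}")
    if d_coeff <= 0:
        raise ValueError(f"D must be > 0, got {d_coeff}")
    d_h = K_B * solvent.temperature / (3.0 * math.pi * solvent.viscosity * d_coeff)
    rho = solvent.density + 18.0 * solvent.viscosity * s / (d_h * d_h)
    return ParticleSpec(hydrodynamic_diameter=d_h, density=rho, label=label)


def complex_density(
    np_spec: ParticleSpec, protein: ProteinSpec, n_avg: float
) -> float:
    """Volume-weighted density of an NP carrying ``n_avg`` proteins, kg/m³.

    ``ρ_cx = (ρ_NP V_NP + N_avg ρ_P V_P) / (V_NP + N_avg V_P)`` — the
    homogeneous-aggregate approximation.
    """
    if n_avg < 0:
        raise ValueError(f"n_avg must be >= 0, got {n_avg}")
    v_np = np_spec.volume
    v_p = protein.hydrodynamic_volume
    return (np_spec.density * v_np + n_avg * protein.density * v_p) / (
        v_np + n_avg * v_p
    )


def complex_volume(np_spec: ParticleSpec, protein: ProteinSpec, n_avg: float) -> float:
    """Total hydrodynamic volume of the complex, m³."""
    if n_avg < 0:
        raise ValueError(f"n_avg must be >= 0, got {n_avg}")
    return np_spec.volume + n_avg * protein.hydrodynamic_volume


def complex_diameter(np_spec: ParticleSpec, protein: ProteinSpec, n_avg: float) -> float:
    """Sphere-equivalent diameter of the complex, m."""
    return (6.0 * complex_volume(np_spec, protein, n_avg) / math.pi) ** (1.0 / 3.0)


def complex_s(
    np_spec: ParticleSpec,
    protein: ProteinSpec,
    n_avg: float,
    solvent: SolventModel = WATER_20C,
) -> float:
    """Sedimentation coefficient of the sphere-equivalent complex, seconds.

    The complex is treated as a sphere of volume ``V_NP + N_avg V_P`` with
    the volume-weighted density of :func:`complex_density`.  Adsorbing light
    protein onto a dense NP usually *lowers* s: the buoyant-mass gain is
    outweighed by the friction gain from the larger diameter.
    """
    rho_cx = complex_density(np_spec, protein, n_avg)
    d_cx = complex_diameter(np_spec, protein, n_avg)
    cx = ParticleSpec(hydrodynamic_diameter=d_cx, density=max(rho_cx, 1e-300))
    return sedimentation_coefficient(cx, solvent) if rho_cx > 0 else 0.0


def hill_n_avg(params: InteractionParams, conc) -> float:
    """Average proteins per particle at free protein concentration ``conc``.

    ``N_avg = N_max [P]ⁿ / (K_Dⁿ + [P]ⁿ)``.  Accepts scalars or numpy
    arrays for ``conc`` (mol/L, ≥ 0).
    """
    import numpy as _np

    c = _np.asarray(conc, dtype=float)
    if _np.any(c < 0):
        raise ValueError("conc must be >= 0")
    # work with (c/K_D)^n to avoid overflow at extreme concentrations
    with _np.errstate(divide="ignore"):
        x = _np.where(c > 0, (c / params.k_d) ** params.hill_n, 0.0)
    out = params.n_max * x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def isotherm_s(
    np_spec: ParticleSpec,
    protein: ProteinSpec,
    params: InteractionParams,
    conc: float,
    solvent: SolventModel = WATER_20C,
) -> float:
    """Model sedimentation coefficient at protein concentration ``conc``.

    The complete forward model fitted to SV binding isotherms: the Hill
    coverage at ``conc`` plugged into the sphere-equivalent complex ``s``.
    Protein is assumed in large excess over NP binding sites, so ``conc``
    is the total protein concentration.
    """
    n_avg = hill_n_avg(params, conc)
    return complex_s(np_spec, protein, n_avg, solvent)


def frictional_ratio(
    s: float, d_coeff: float, rho_p: float, solvent: SolventModel = WATER_20C
) -> float:
    """Frictional ratio f/f₀ from a measured ``(s, D)`` pair.

    ``f/f₀ = [ k_B T/(3 π η D) · √((ρ_p − ρ_s)/(18 η s)) ]^{2/3}``

    The first factor is the Stokes–Einstein diameter from D; the second is
    the reciprocal Stokes diameter from s at the assumed analyte density
    ``rho_p``.  For a sphere the two diameters coincide and f/f₀ = 1;
    elongation raises friction, depressing D more than s, giving f/f₀ > 1.

    Raises
    ------
    ValueError
        If s ≤ 0, D ≤ 0, or ρ_p ≤ ρ_s (no real equivalent sphere).
    """
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    if d_coeff <= 0:
        raise ValueError(f"D must be > 0, got {d_coeff}")
    if rho_p <= solvent.density:
        raise ValueError(
            f"analyte density {rho_p} kg/m³ must exceed solvent density "
            f"{solvent.density} kg/m³"
        )
    d_from_diff = K_B * solvent.temperature / (
        3.0 * math.pi * solvent.viscosity * d_coeff
    )
    inv_d_from_s = math.sqrt(
        (rho_p - solvent.density) / (18.0 * solvent.viscosity * s)
    )
    return (d_from_diff * inv_d_from_s) ** (2.0 / 3.0)


def diffusion_from_s_fr(
    s: float, fr: float, rho_p: float, solvent: SolventModel = WATER_20C
) -> float:
    """Diffusion coefficient implied by ``s`` at frictional ratio ``fr``.

    Inverts the f/f₀ scaling law: with ``d_s = √(18 η s / (ρ_p − ρ_s))``
    the Stokes diameter from s, ``D = k_B T / (3 π η fr^{3/2} d_s)``.
    Used to pin the (s, D) coupling when fitting scan sets with an assumed
    shape factor.
    """
    if s <= 0 or fr <= 0:
        raise ValueError("s and fr must be > 0")
    if rho_p <= solvent.density:
        raise ValueError("rho_p must exceed solvent density")
    d_s = math.sqrt(18.0 * solvent.viscosity * s / (rho_p - solvent.density))
    return K_B * solvent.temperature / (
        3.0 * math.pi * solvent.viscosity * fr**1.5 * d_s
    )
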