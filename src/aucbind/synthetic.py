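"""Synthetic data generation and packaged reference parameter sets.

Every pipeline stage — forward simulation, inversion, isotherm fitting,
shape analysis — is testable without any experimental download: this
module generates noisy binding isotherms from the Hill/hydrodynamic
forward model (emulating triplicate SV experiments) and complete synthetic
scan-set experiments (emulating one SV run per protein concentration).

:data:`FIXTURES` packages the published reference characterizations of
four DGU-fractionated gold nanoparticle preparations (citrate-, MUA- and
MUS-coated, 2.2–12.6 nm cores) binding serum albumin, as measured by
SV-AUC: hydrodynamic diameter, particle density, s, D and the fitted
(K_D, N_max, n).  These serve as realistic ground-truth parameter sets
for closed-loop recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hydro import (
    BSA,
    InteractionParams,
    ParticleSpec,
    ProteinSpec,
    SolventModel,
    WATER_20C,
    complex_density,
    complex_diameter,
    diffusion_from_s_fr,
    hill_n_avg,
    isotherm_s,
)
from .isotherm import IsothermDataset
from .lamm import (
    CellGeometry,
    RotorProgram,
    ScanSet,
    SpeciesState,
    add_noise,
    default_scan_times,
    simulate_sv,
)
from .units import K_B, from_svedberg, gcm3_to_si, nm_to_m

__all__ = ["Fixture", "FIXTURES", "generate_isotherm", "generate_scan_experiment"]


@dataclass(frozen=True)
class Fixture:
    """A packaged NP/protein system with its published parameter set."""

    label: str
    particle: ParticleSpec
    protein: ProteinSpec | None
    params: InteractionParams | None
    s: float                    # reported sedimentation coefficient, seconds
    d: float                    # reported diffusion coefficient, m²/s
    core_diameter: float        # m
    source: str


def _fx(label, d_core_nm, d_h_nm, rho_gcm3, s_sved, d_m2s, kd_um, n_max, n,
        protein, source):
    return Fixture(
        label=label,
        particle=ParticleSpec(
            hydrodynamic_diameter=nm_to_m(d_h_nm),
            density=gcm3_to_si(rho_gcm3),
            label=label.split("_")[0],
        ),
        protein=protein,
        params=InteractionParams(k_d=kd_um * 1e-6, n_max=n_max, hill_n=n),
        s=from_svedberg(s_sved),
        d=d_m2s,
        core_diameter=nm_to_m(d_core_nm),
        source=source,
    )


_HSA = ProteinSpec(label="HSA")   # same prism volume/density model as BSA

#: Published SV-AUC characterizations of AuNP–albumin systems: hydrodynamic
#: diameter, particle density, (s, D) of the bare particle, and the fitted
#: Hill parameters (K_D in M, N_max, n).
FIXTURES: dict[str, Fixture] = {
    "citrate_BSA": _fx(
        "citrate_BSA", 12.6, 13.6, 17.7, 1080.0, 3.38e-11,
        13.6, 36.0, 0.9, BSA,
        "citrate-coated AuNPs + BSA, published SV-AUC characterization",
    ),
    "MUA_BSA": _fx(
        "MUA_BSA", 6.1, 9.4, 5.9, 234.0, 4.13e-11,
        5.4, 18.0, 0.8, BSA,
        "11-mercaptoundecanoic-acid-coated AuNPs + BSA, published SV-AUC "
        "characterization",
    ),
    "MUS_s_BSA": _fx(
        "MUS_s_BSA", 2.2, 5.6, 2.4, 22.0, 6.16e-11,
        9.2, 2.0, 1.6, BSA,
        "small 11-mercaptoundecane-sulfonate-coated AuNPs + BSA, published "
        "SV-AUC characterization",
    ),
    "MUS_m_BSA": _fx(
        "MUS_m_BSA", 4.4, 7.0, 5.5, 119.0, 5.78e-11,
        1.1, 10.0, 1.3, BSA,
        "medium 11-mercaptoundecane-sulfonate-coated AuNPs + BSA, published "
        "SV-AUC characterization",
    ),
    "MUS_m_HSA": _fx(
        "MUS_m_HSA", 4.4, 7.0, 5.5, 119.0, 5.78e-11,
        0.57, 5.0, 1.6, _HSA,
        "medium 11-mercaptoundecane-sulfonate-coated AuNPs + HSA, published "
        "SV-AUC characterization",
    ),
}


def default_conc_grid(params: InteractionParams, n_points: int = 12) -> np.ndarray:
    """Log-spaced concentrations over [K_D/30, 100 K_D] plus a zero point."""
    grid = np.geomspace(params.k_d / 30.0, 100.0 * params.k_d, n_points)
    return np.concatenate([[0.0], grid])


def generate_isotherm(
    particle: ParticleSpec,
    protein: ProteinSpec,
    params: InteractionParams,
    conc_grid=None,
    rel_noise: float = 0.02,
    n_reps: int = 3,
    seed: int | None = None,
    solvent: SolventModel = WATER_20C,
) -> IsothermDataset:
    """Generate a noisy synthetic binding isotherm.

    Emulates triplicate SV experiments: at each concentration, ``n_reps``
    draws of the model s̄ with multiplicative Gaussian noise of relative
    SD ``rel_noise`` (the visual magnitude of typical triplicate error
    bars is ~2%); the dataset stores the replicate mean and sample SD.

    All randomness flows through ``seed``.
    """
    if rel_noise < 0:
        raise ValueError("rel_noise must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if conc_grid is None:
        conc_grid = default_conc_grid(params)
    conc_grid = np.asarray(conc_grid, dtype=float)

    rng = np.random.default_rng(seed)
    s_true = np.array(
        [isotherm_s(particle, protein, params, float(c), solvent)
         for c in conc_grid]
    )
    if rel_noise == 0:
        return IsothermDataset(
            conc=conc_grid,
            s_mean=s_true,
            s_sd=np.zeros_like(s_true),
            n_reps=np.full(conc_grid.size, n_reps),
        )
    draws = s_true[:, None] * (
        1.0 + rng.normal(0.0, rel_noise, size=(conc_grid.size, n_reps))
    )
    ddof = 1 if n_reps > 1 else 0
    return IsothermDataset(
        conc=conc_grid,
        s_mean=draws.mean(axis=1),
        s_sd=draws.std(axis=1, ddof=ddof),
        n_reps=np.full(conc_grid.size, n_reps),
    )


def generate_scan_experiment(
    particle: ParticleSpec,
    protein: ProteinSpec,
    params: InteractionParams,
    conc: float,
    cell: CellGeometry | None = None,
    rotor: RotorProgram | None = None,
    solvent: SolventModel = WATER_20C,
    noise: float = 0.005,
    seed: int | None = 0,
    loading_signal: float = 0.8,
    imposed_fr: float = 1.0,
    grid_points: int = 400,
) -> ScanSet:
    """Simulate one SV run of the NP–protein mixture at ``conc``.

    The sedimenting species is the sphere-equivalent complex at the Hill
    coverage for ``conc``: s from the full forward model and D from
    Stokes–Einstein at the complex diameter, optionally depressed by an
    imposed frictional ratio (D is divided by ``imposed_fr``^{3/2}) to
    emulate shape anisotropy.  Free protein carries no signal, matching
    detection at the plasmon wavelength where only the gold absorbs.
    """
    if conc < 0:
        raise ValueError("conc must be >= 0")
    if cell is None:
        cell = CellGeometry()
    n_avg = hill_n_avg(params, conc)
    s = isotherm_s(particle, protein, params, conc, solvent)
    d_cx = complex_diameter(particle, protein, n_avg)
    d_sphere = K_B * solvent.temperature / (
        3.0 * np.pi * solvent.viscosity * d_cx
    )
    d_coeff = d_sphere / imposed_fr**1.5
    if rotor is None:
        rotor = RotorProgram(
            10000.0, default_scan_times(max(s, 1e-13), 10000.0, cell, 45)
        )
    scans = simulate_sv(
        cell, rotor,
        [SpeciesState(s=s, d=d_coeff, signal=loading_signal)],
        solvent, grid_points=grid_points,
    )
    scans.metadata["conc_molar"] = conc
    scans.metadata["n_avg_true"] = float(n_avg)
    scans.metadata["rho_cx_true"] = complex_density(particle, protein, n_avg)
    scans.metadata["imposed_fr"] = imposed_fr
    if noise > 0:
        scans = add_noise(scans, noise, seed if seed is not None else 0)
    return scans
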