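"""Sedimentation-coefficient distributions from SV scan sets.

A simplified c(s)-style analysis: the measured scans are fitted as a
nonnegative superposition of noise-free Lamm solutions, one per point of a
sedimentation-coefficient grid.  The diffusion coefficient attached to
each basis function follows the frictional-ratio scaling law
``D(s, f/f₀)`` at a single assumed f/f₀, so a one-dimensional line search
over f/f₀ candidates stands in for the full two-dimensional c(s, f/f₀)
optimization of dedicated AUC packages.  Downstream, only the
signal-weighted average ``s̄`` (and the effective D at the best f/f₀) are
consumed by the binding-isotherm analysis.

The least-squares problem is solved by nonnegative least squares with
Tikhonov regularization on the second difference of the distribution
(smoothness prior), the standard stabilization for this ill-posed
inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .hydro import SolventModel, WATER_20C, diffusion_from_s_fr
from .lamm import CellGeometry, RotorProgram, ScanSet, SpeciesState, simulate_sv

__all__ = [
    "SedDistribution",
    "AverageCoefficients",
    "fit_distribution",
    "weighted_average_s",
    "scan_fr_grid",
    "clear_basis_cache",
]


@dataclass
class SedDistribution:
    """A discrete sedimentation-coefficient distribution.

    ``weights[i]`` is the loading signal (OD) carried by a species of
    sedimentation coefficient ``s_grid[i]``; the sum over the grid
    approximates the total loading signal.
    """

    s_grid: np.ndarray          # seconds
    weights: np.ndarray         # OD per grid point, >= 0
    regularization: float
    fit_rmsd: float             # OD
    method: str = "nnls-tikhonov2"
    warnings: list = field(default_factory=list)

    def total_signal(self) -> float:
        return float(self.weights.sum())


@dataclass
class AverageCoefficients:
    """Weighted-average coefficients from a scan-set inversion."""

    s_w: float                  # seconds
    d_eff: float                # m²/s
    fr_grid_value: float        # selected f/f₀
    rmsd_profile: dict = field(default_factory=dict)   # fr -> refit RMSD
    warnings: list = field(default_factory=list)


# Lamm-solution bases are expensive relative to the NNLS solve and are
# identical across f/f0 candidates and repeated inversions of the same
# experiment layout, so keep a small keyed cache.
_BASIS_CACHE: dict = {}
_BASIS_CACHE_MAX = 12


def clear_basis_cache() -> None:
    _BASIS_CACHE.clear()


def _cell_rotor_from_metadata(scans: ScanSet) -> tuple[CellGeometry, RotorProgram]:
    meta = scans.metadata
    try:
        cell = CellGeometry(
            meniscus_radius=meta["meniscus_m"], base_radius=meta["base_m"]
        )
        rotor = RotorProgram(meta["rpm"], tuple(scans.times))
    except KeyError as exc:
        raise ValueError(
            "scan metadata must carry meniscus_m, base_m and rpm to build "
            "the Lamm basis"
        ) from exc
    return cell, rotor


def _lamm_basis(
    scans: ScanSet,
    s_grid: np.ndarray,
    fr: float,
    rho_p: float,
    solvent: SolventModel,
    grid_points: int = 300,
) -> np.ndarray:
    """Matrix of flattened unit-signal Lamm solutions, shape (npix, ns)."""
    cell, rotor = _cell_rotor_from_metadata(scans)
    key = (
        round(cell.meniscus_radius, 12),
        round(cell.base_radius, 12),
        rotor.rotor_speed,
        tuple(np.round(scans.times, 6)),
        tuple(np.round(s_grid / 1e-13, 6)),
        round(fr, 6),
        round(rho_p, 6),
        round(solvent.viscosity, 12),
        round(solvent.density, 6),
        round(solvent.temperature, 6),
        grid_points,
        scans.radii.size,
    )
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]

    cols = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pellet-truncation warnings expected
        for s in s_grid:
            d = diffusion_from_s_fr(float(s), fr, rho_p, solvent)
            sim = simulate_sv(
                cell,
                rotor,
                [SpeciesState(s=float(s), d=d, signal=1.0)],
                solvent,
                grid_points=grid_points,
            )
            # project onto the recorded radii
            prof = np.vstack(
                [
                    np.interp(scans.radii, sim.radii, sim.signal[i])
                    for i in range(sim.times.size)
                ]
            )
            cols.append(prof.ravel())
    basis = np.column_stack(cols)
    if len(_BASIS_CACHE) >= _BASIS_CACHE_MAX:
        _BASIS_CACHE.pop(next(iter(_BASIS_CACHE)))
    _BASIS_CACHE[key] = basis
    return basis


def _second_difference(n: int) -> np.ndarray:
    if n < 3:
        return np.zeros((0, n))
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


def fit_distribution(
    scans: ScanSet,
    s_grid,
    fr: float = 1.0,
    rho_p: float | None = None,
    solvent: SolventModel = WATER_20C,
    reg_strength: float = 0.0,
    grid_points: int | None = None,
    fit_window: tuple | None = None,
) -> SedDistribution:
    """Fit a nonnegative sedimentation-coefficient distribution to scans.

    Parameters
    ----------
    scans : ScanSet
        ≥ 10 scans; metadata must carry the cell geometry and rotor speed.
    s_grid : array-like
        30–200 sedimentation coefficients (seconds) bracketing the signal.
    fr : float
        Assumed frictional ratio; sets D for every basis function through
        the scaling law.
    rho_p : float
        Assumed analyte density (kg/m³), needed by the scaling law.
    solvent : SolventModel
    reg_strength : float
        Tikhonov weight α on the second difference of the distribution;
        the augmented system ``[B; √α L] w ≈ [data; 0]`` is solved by NNLS.
        α is scaled by the mean basis column norm so its magnitude is
        comparable across problems.
    fit_window : (float, float), optional
        Radial analysis window in m.  By default the inner 2% and outer 4%
        of the solution column are excluded: the back-diffusion pellet
        layer at the base is optically and numerically unreliable (in real
        data) / grid-limited (in simulation), exactly as dedicated c(s)
        software excludes it.

    Returns
    -------
    SedDistribution
        With the refit RMSD (OD) of the regularized solution over the
        analysis window.
    """
    s_grid = np.sort(np.asarray(s_grid, dtype=float))
    if s_grid.size < 2:
        raise ValueError("s_grid needs at least 2 points")
    if scans.times.size < 10:
        raise ValueError(f"need >= 10 scans, got {scans.times.size}")
    if rho_p is None:
        raise ValueError("rho_p (assumed analyte density) is required")
    if reg_strength < 0:
        raise ValueError("reg_strength must be >= 0")
    if grid_points is None:
        # match the basis discretization to the data sampling so numerical
        # diffusion is comparable between basis and (simulated) data
        grid_points = int(np.clip(scans.radii.size, 200, 600))

    if np.allclose(scans.signal, 0.0):
        raise ValueError("all-zero scans: no signal to invert")

    meta = scans.metadata
    if fit_window is None:
        men = meta.get("meniscus_m", scans.radii[0])
        base = meta.get("base_m", scans.radii[-1])
        col = base - men
        fit_window = (men + 0.02 * col, base - 0.04 * col)
    rmask = (scans.radii >= fit_window[0]) & (scans.radii <= fit_window[1])
    if rmask.sum() < 10:
        raise ValueError("fit_window leaves fewer than 10 radial points")
    pixmask = np.tile(rmask, scans.times.size)

    data = scans.signal[:, rmask].ravel()
    basis = _lamm_basis(scans, s_grid, fr, rho_p, solvent, grid_points)[pixmask]
    wlist: list[str] = []

    if reg_strength > 0:
        scale = np.sqrt(reg_strength) * np.linalg.norm(basis, axis=0).mean()
        L = scale * _second_difference(s_grid.size)
        A = np.vstack([basis, L])
        b = np.concatenate([data, np.zeros(L.shape[0])])
    else:
        A, b = basis, data
    w, _ = nnls(A, b)

    resid = basis @ w - data
    rmsd = float(np.sqrt(np.mean(resid**2)))

    # boundary pile-up: significant weight in the edge grid points signals
    # that the grid does not bracket the species
    total = w.sum()
    if total > 0 and (w[0] + w[-1]) > 0.05 * total:
        wlist.append("boundary-pile-up: s_grid may not bracket the signal")
        warnings.warn(wlist[-1], stacklevel=2)

    return SedDistribution(
        s_grid=s_grid,
        weights=w,
        regularization=reg_strength,
        fit_rmsd=rmsd,
        warnings=wlist,
    )


def weighted_average_s(dist: SedDistribution, window=None) -> float:
    """Signal-weighted average sedimentation coefficient over a window.

    ``s_w = Σ wᵢ sᵢ / Σ wᵢ`` over grid points inside ``window``
    (``(s_min, s_max)`` in seconds; default the full grid).
    """
    if window is None:
        lo, hi = -np.inf, np.inf
    else:
        lo, hi = window
    mask = (dist.s_grid >= lo) & (dist.s_grid <= hi)
    wsum = dist.weights[mask].sum()
    if not mask.any() or wsum <= 0:
        raise ValueError("window contains no distribution weight")
    return float((dist.weights[mask] * dist.s_grid[mask]).sum() / wsum)


def scan_fr_grid(
    scans: ScanSet,
    s_grid,
    fr_candidates,
    rho_p: float,
    solvent: SolventModel = WATER_20C,
    reg_strength: float = 0.0,
    grid_points: int | None = None,
    fit_window: tuple | None = None,
) -> AverageCoefficients:
    """Select the frictional ratio that best refits the scans.

    Runs :func:`fit_distribution` at every f/f₀ candidate, picks the one
    with the lowest refit RMSD, and reports the weighted-average s together
    with the effective diffusion coefficient implied by the scaling law at
    that (s̄, f/f₀).  A flat RMSD profile (< 2% relative spread) means the
    data do not constrain diffusion — typically too-fast sedimentation —
    and is flagged.
    """
    fr_candidates = sorted(float(f) for f in fr_candidates)
    if not fr_candidates:
        raise ValueError("need at least one fr candidate")

    rmsd_profile: dict = {}
    best = None
    for fr in fr_candidates:
        dist = fit_distribution(
            scans, s_grid, fr, rho_p, solvent, reg_strength, grid_points,
            fit_window,
        )
        rmsd_profile[fr] = dist.fit_rmsd
        if best is None or dist.fit_rmsd < best[1].fit_rmsd:
            best = (fr, dist)

    fr_best, dist_best = best
    wlist: list[str] = []
    if len(fr_candidates) > 1:
        vals = np.array(list(rmsd_profile.values()))
        if vals.min() > 0 and (vals.max() - vals.min()) / vals.min() < 0.02:
            wlist.append(
                "flat RMSD profile over f/f0 candidates: diffusion is not "
                "resolved by these scans; fr is unreliable"
            )
            warnings.warn(wlist[-1], stacklevel=2)

    s_w = weighted_average_s(dist_best)
    d_eff = diffusion_from_s_fr(s_w, fr_best, rho_p, solvent)
    return AverageCoefficients(
        s_w=s_w,
        d_eff=d_eff,
        fr_grid_value=fr_best,
        rmsd_profile=rmsd_profile,
        warnings=wlist,
    )
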