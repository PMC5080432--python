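"""Fitting the sedimentation-coefficient binding isotherm.

The measured quantity is the weighted-average sedimentation coefficient
``s̄`` of the NP–protein mixture at a series of protein concentrations.
The forward model (:func:`aucbind.hydro.isotherm_s`) composes the Hill
adsorption isotherm with the sphere-equivalent hydrodynamics of the
complex; fitting it to the (concentration, s̄) data yields the
dissociation constant K_D, the saturation stoichiometry N_max and the
Hill coefficient n, with the particle, protein and solvent parameters
held fixed at their independently measured values.

The fit is a bounded trust-region nonlinear least squares in
(log₁₀ K_D, N_max, n), weighted by the replicate standard deviations,
multi-started over log-spaced K_D because Hill fits are multi-modal in
(K_D, n).  Parameter standard errors come from the Jacobian at the
optimum; a seeded parametric bootstrap is available as a cross-check.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .hydro import (
    BSA,
    InteractionParams,
    ParticleSpec,
    ProteinSpec,
    SolventModel,
    WATER_20C,
    complex_s,
    hill_n_avg,
    isotherm_s,
    sedimentation_coefficient,
)

__all__ = [
    "IsothermDataset",
    "IsothermFit",
    "fit_isotherm",
    "predict_isotherm",
    "dilution_shift",
]

# lower limit of measurable K_D for absorbance-detected AuNPs: below this
# the protein is no longer in large excess over NP binding sites
KD_LOWER_WARN = 0.01e-6   # mol/L
# practical upper limit on protein concentration (solution viscosity)
CONC_UPPER_WARN = 10e-3   # mol/L


@dataclass
class IsothermDataset:
    """(concentration, mean s, replicate SD, replicate count) points."""

    conc: np.ndarray        # mol/L
    s_mean: np.ndarray      # seconds
    s_sd: np.ndarray        # seconds
    n_reps: np.ndarray      # ints

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.s_mean = np.asarray(self.s_mean, dtype=float)
        self.s_sd = np.asarray(self.s_sd, dtype=float)
        self.n_reps = np.asarray(self.n_reps, dtype=int)
        n = self.conc.size
        if not (self.s_mean.size == self.s_sd.size == self.n_reps.size == n):
            raise ValueError("isotherm columns must have equal length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.conc).size != n:
            raise ValueError("concentrations must be distinct")
        if np.any(self.s_sd < 0):
            raise ValueError("s_sd must be >= 0")
        if n < 5:
            _warnings.warn(
                f"only {n} isotherm points; at least 5 are recommended",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.conc.size

    def sorted(self) -> "IsothermDataset":
        order = np.argsort(self.conc)
        return IsothermDataset(
            self.conc[order], self.s_mean[order],
            self.s_sd[order], self.n_reps[order],
        )


@dataclass
class IsothermFit:
    """Result of fitting the binding isotherm."""

    params: InteractionParams
    param_sd: dict                      # {"k_d": ..., "n_max": ..., "hill_n": ...}
    residuals: np.ndarray               # data − model, seconds, data order
    rmsd: float                         # weighted residual norm (unitless if weighted)
    warnings: list
    particle: ParticleSpec
    protein: ProteinSpec
    solvent: SolventModel
    data: IsothermDataset
    converged: bool = True
    n_starts_used: int = 0
    bootstrap_sd: dict | None = None


def _default_bounds(
    particle: ParticleSpec, protein: ProteinSpec
) -> tuple[tuple, tuple, tuple]:
    """(K_D, N_max, n) box.  N_max is capped at 10× a geometric packing
    estimate (spherical shell of protein-sized spheres around the NP)."""
    d_np = particle.hydrodynamic_diameter
    d_p = protein.equivalent_diameter
    geom_max = max(2.0, 4.0 * ((d_np + d_p) / d_p) ** 2)
    return (1e-9, 1e-1), (0.0, 10.0 * geom_max), (0.2, 5.0)


def _model_s(theta: np.ndarray, conc, particle, protein, solvent) -> np.ndarray:
    log_kd, n_max, n = theta
    p = InteractionParams(k_d=10.0**log_kd, n_max=max(n_max, 0.0), hill_n=n)
    return np.array(
        [isotherm_s(particle, protein, p, float(c), solvent) for c in conc]
    )


def _initial_nmax(
    data: IsothermDataset, particle, protein, solvent, nmax_hi: float
) -> float:
    """Coverage that reproduces the most extreme observed s shift."""
    from scipy.optimize import brentq

    s0 = sedimentation_coefficient(particle, solvent)
    target = data.s_mean[np.argmax(np.abs(data.s_mean - s0))]

    def f(n):
        return complex_s(particle, protein, n, solvent) - target

    try:
        if f(0.0) * f(nmax_hi) < 0:
            return max(1.0, brentq(f, 0.0, nmax_hi, xtol=1e-3))
    except ValueError:
        pass
    return max(1.0, 0.1 * nmax_hi)


def fit_isotherm(
    data: IsothermDataset,
    particle: ParticleSpec,
    protein: ProteinSpec = BSA,
    solvent: SolventModel = WATER_20C,
    bounds: tuple | None = None,
    n_starts: int = 8,
    seed: int | None = None,
    bootstrap: int = 0,
) -> IsothermFit:
    """Estimate (K_D, N_max, n) from a binding isotherm.

    Parameters
    ----------
    data : IsothermDataset
        ≥ 5 points; should include conc = 0 or conc ≪ K_D to anchor the
        bare-particle s (warned otherwise).
    particle, protein, solvent
        Fixed physical inputs from independent SV experiments.
    bounds : ((kd_lo, kd_hi), (nmax_lo, nmax_hi), (n_lo, n_hi)), optional
        Defaults: K_D ∈ [1e-9, 1e-1] M, N_max ∈ [0, 10 × geometric max],
        n ∈ [0.2, 5].
    n_starts : int
        Multi-starts over log-spaced K_D in [1e-8, 1e-3] M.
    seed : int, optional
        Seeds the bootstrap only; the fit itself is deterministic.
    bootstrap : int
        If > 0, number of parametric-bootstrap replicates for the
        uncertainty cross-check.

    Returns
    -------
    IsothermFit
        Weighted least-squares estimate (weights 1/s_sd², unit weights
        when SDs are absent) with Jacobian-based standard errors.
    """
    data = data.sorted()
    if len(data) < 5:
        raise ValueError(f"need at least 5 isotherm points, got {len(data)}")
    wlist: list[str] = []

    if bounds is None:
        bounds = _default_bounds(particle, protein)
    (kd_lo, kd_hi), (nm_lo, nm_hi), (n_lo, n_hi) = bounds

    # flat data: no concentration dependence to fit
    span = np.ptp(data.s_mean)
    scale = max(abs(data.s_mean).max(), 1e-300)
    noise_scale = np.median(data.s_sd[data.s_sd > 0]) if np.any(data.s_sd > 0) else 0.0
    if span <= max(1e-6 * scale, 0.2 * noise_scale):
        wlist.append("no binding detected: s is constant across concentrations")
        _warnings.warn(wlist[-1], stacklevel=2)
        p = InteractionParams(k_d=math.sqrt(kd_lo * kd_hi), n_max=nm_lo,
                              hill_n=1.0)
        model = _model_s(
            np.array([math.log10(p.k_d), p.n_max, p.hill_n]),
            data.conc, particle, protein, solvent,
        )
        return IsothermFit(
            params=p,
            param_sd={"k_d": float("nan"), "n_max": float("nan"),
                      "hill_n": float("nan")},
            residuals=data.s_mean - model,
            rmsd=float(np.sqrt(np.mean((data.s_mean - model) ** 2))),
            warnings=wlist,
            particle=particle, protein=protein, solvent=solvent, data=data,
            converged=False,
        )

    if not (np.any(data.conc == 0)):
        # a low-concentration anchor pins the bare-particle s
        wlist.append(
            "no conc=0 (or conc << K_D) anchor point; bare-particle s is "
            "extrapolated"
        )

    # weights: 1/sd² with a small floor against near-zero triplicate SDs
    if np.all(data.s_sd > 0):
        floor = 1e-3 * np.median(data.s_sd)
        sig = np.maximum(data.s_sd, floor)
    else:
        sig = np.full(len(data), max(span, scale) * 0.01)
        if np.any(data.s_sd > 0):
            wlist.append("some SDs are zero; using unit weights")

    lo = np.array([math.log10(kd_lo), nm_lo, n_lo])
    hi = np.array([math.log10(kd_hi), nm_hi, n_hi])
    nmax0 = min(
        _initial_nmax(data, particle, protein, solvent, nm_hi), 0.99 * nm_hi
    )

    def resid(theta):
        return (_model_s(theta, data.conc, particle, protein, solvent)
                - data.s_mean) / sig

    # Hill fits are multi-modal along a (K_D, n, N_max) ridge: start from a
    # log-spaced K_D grid crossed with anti-/non-/cooperative n guesses
    kd_starts = np.geomspace(1e-8, 1e-3, max(1, n_starts))
    n_starts_grid = (0.6, 1.0, 1.6)
    best = None
    n_used = 0
    for kd0 in kd_starts:
        for n0 in n_starts_grid:
            x0 = np.clip(
                np.array([math.log10(kd0), nmax0, n0]), lo + 1e-9, hi - 1e-9
            )
            try:
                res = least_squares(
                    resid, x0, bounds=(lo, hi), method="trf",
                    x_scale=[1.0, max(nmax0, 1.0), 1.0],
                    ftol=1e-12, xtol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            n_used += 1
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise RuntimeError("isotherm fit failed to converge from any start")
    # polish the winner
    res = least_squares(
        resid, best.x, bounds=(lo, hi), method="trf",
        x_scale=[1.0, max(nmax0, 1.0), 1.0],
        ftol=1e-12, xtol=1e-12, gtol=1e-12,
    )
    if res.success and res.cost <= best.cost:
        best = res

    theta = best.x
    kd_fit = 10.0 ** theta[0]
    params = InteractionParams(k_d=kd_fit, n_max=theta[1], hill_n=theta[2])

    # Jacobian-based standard errors; delta method back from log10 K_D
    m, npar = len(data), 3
    dof = max(m - npar, 1)
    s2 = 2.0 * best.cost / dof
    J = best.jac
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
        sd_log_kd, sd_nmax, sd_n = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        sd_log_kd = sd_nmax = sd_n = float("nan")
    param_sd = {
        "k_d": kd_fit * math.log(10.0) * sd_log_kd,
        "n_max": sd_nmax,
        "hill_n": sd_n,
    }

    model = _model_s(theta, data.conc, particle, protein, solvent)
    residuals = data.s_mean - model
    rmsd = float(np.sqrt(2.0 * best.cost / m))

    if kd_fit < KD_LOWER_WARN:
        wlist.append(
            f"fitted K_D = {kd_fit:.2e} M is below the ~0.01 uM measurable "
            "limit: protein is no longer in large excess over NP binding "
            "sites"
        )
    if 10.0 * kd_fit > CONC_UPPER_WARN:
        wlist.append(
            f"fitted K_D = {kd_fit:.2e} M implies saturating protein "
            "concentrations above ~10 mM; solution viscosity would "
            "invalidate the sedimentation analysis"
        )
    for w in wlist:
        _warnings.warn(w, stacklevel=2)

    fit = IsothermFit(
        params=params,
        param_sd=param_sd,
        residuals=residuals,
        rmsd=rmsd,
        warnings=wlist,
        particle=particle,
        protein=protein,
        solvent=solvent,
        data=data,
        converged=True,
        n_starts_used=n_used,
    )

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(bootstrap):
            fake = model + rng.normal(0.0, sig)
            try:
                res = least_squares(
                    lambda th: (_model_s(th, data.conc, particle, protein,
                                         solvent) - fake) / sig,
                    theta, bounds=(lo, hi), method="trf",
                    x_scale=[1.0, max(nmax0, 1.0), 1.0],
                )
            except Exception:
                continue
            if res.success:
                boots.append(res.x)
        if len(boots) >= 10:
            b = np.array(boots)
            fit.bootstrap_sd = {
                "k_d": float(np.std(10.0 ** b[:, 0], ddof=1)),
                "n_max": float(np.std(b[:, 1], ddof=1)),
                "hill_n": float(np.std(b[:, 2], ddof=1)),
            }
    return fit


def predict_isotherm(fit: IsothermFit, conc_grid) -> np.ndarray:
    """Model s̄ on a concentration grid, shape (n, 2): (conc, s_model)."""
    if not fit.converged:
        raise ValueError("fit did not converge; no model curve available")
    conc_grid = np.asarray(conc_grid, dtype=float)
    s = np.array(
        [
            isotherm_s(fit.particle, fit.protein, fit.params, float(c),
                       fit.solvent)
            for c in conc_grid
        ]
    )
    return np.column_stack([conc_grid, s])


def dilution_shift(
    fit: IsothermFit, conc_before: float, dilution_factor: float
) -> tuple[float, float, float]:
    """Predicted s̄ shift of the reversibility (dilution) experiment.

    A mixture equilibrated at ``conc_before`` is diluted by
    ``dilution_factor`` and re-equilibrated; reversible adsorption implies
    partial desorption, and — in the usual regime where protein coating
    slows sedimentation — a shift towards *higher* s.

    Returns ``(s_before, s_after, delta_s)`` in seconds, with
    ``delta_s = s_after − s_before``.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    s_before = isotherm_s(
        fit.particle, fit.protein, fit.params, conc_before, fit.solvent
    )
    s_after = isotherm_s(
        fit.particle, fit.protein, fit.params, conc_before / dilution_factor,
        fit.solvent,
    )
    return s_before, s_after, s_after - s_before
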