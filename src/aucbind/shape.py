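"""Frictional-ratio evolution of NP–protein complexes with coverage.

Once the Hill parameters are fitted, the average coverage N_avg at each
experimental protein concentration follows by direct back-calculation, and
with it the model density of the complex.  Feeding that density together
with the *measured* (s, D) pair at the same concentration into the
frictional-ratio relation yields f/f₀ as a function of concentration (and
coverage) — a qualitative probe of how the complex's shape evolves as
proteins accumulate: spheres stay at f/f₀ ≈ 1, transiently elongated
complexes (e.g. two proteins on opposite poles of a small particle) rise
above it.

The thermodynamic parameters entering this series were themselves fitted
under a near-spherical assumption, so the f/f₀ series is a post-hoc
diagnostic, not an analytically rigorous shape determination; the output
records this caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hydro import (
    SolventModel,
    complex_density,
    frictional_ratio,
    hill_n_avg,
)
from .isotherm import IsothermFit

__all__ = ["ShapeSeries", "shape_series", "n_avg_series"]

CAVEAT = (
    "thermodynamic parameters were fitted assuming near-spherical "
    "sedimentation; f/f0 deviations are a post-hoc diagnostic and not "
    "analytically rigorous"
)


@dataclass
class ShapeSeries:
    """Per-concentration coverage, complex density and frictional ratio."""

    conc: np.ndarray        # mol/L
    n_avg: np.ndarray
    rho_cx: np.ndarray      # kg/m³
    s_meas: np.ndarray      # seconds
    d_meas: np.ndarray      # m²/s
    fr: np.ndarray          # f/f₀; NaN where density is flagged
    fr_sd: np.ndarray       # propagated SD; NaN where unavailable
    flagged: np.ndarray     # True where rho_cx <= solvent density
    metadata: dict = field(default_factory=dict)


def shape_series(
    fit: IsothermFit,
    measured,
    solvent: SolventModel | None = None,
    d_meas_source: str = "unspecified",
) -> ShapeSeries:
    """Back-calculate the f/f₀ series from a fit and measured (s, D) pairs.

    Parameters
    ----------
    fit : IsothermFit
        Converged isotherm fit supplying (K_D, N_max, n) and the fixed
        particle/protein specs.
    measured : iterable of tuples
        ``(conc, s_meas, d_meas)`` or ``(conc, s_meas, d_meas, s_sd, d_sd)``
        rows; conc in mol/L, s in seconds, D in m²/s.  When replicate SDs
        are given, the f/f₀ error bar follows by first-order propagation
        (∂ln fr/∂ln D = −2/3, ∂ln fr/∂ln s = −1/3).
    d_meas_source : str
        Provenance tag for the D values (e.g. "cs_invert", "user"),
        recorded in the output metadata.

    Rows where the model complex density does not exceed the solvent
    density are flagged and carry no f/f₀ value.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if solvent is None:
        solvent = fit.solvent

    rows = [tuple(map(float, row)) for row in measured]
    n = len(rows)
    conc = np.array([r[0] for r in rows])
    s_meas = np.array([r[1] for r in rows])
    d_meas = np.array([r[2] for r in rows])
    s_sd = np.array([r[3] if len(r) > 3 else np.nan for r in rows])
    d_sd = np.array([r[4] if len(r) > 4 else np.nan for r in rows])

    n_avg = np.array([hill_n_avg(fit.params, c) for c in conc])
    rho_cx = np.array(
        [complex_density(fit.particle, fit.protein, na) for na in n_avg]
    )
    fr = np.full(n, np.nan)
    fr_sd = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        if rho_cx[i] <= solvent.density or s_meas[i] <= 0 or d_meas[i] <= 0:
            flagged[i] = True
            continue
        fr[i] = frictional_ratio(s_meas[i], d_meas[i], rho_cx[i], solvent)
        if np.isfinite(s_sd[i]) or np.isfinite(d_sd[i]):
            rel_d = (d_sd[i] / d_meas[i]) if np.isfinite(d_sd[i]) else 0.0
            rel_s = (s_sd[i] / s_meas[i]) if np.isfinite(s_sd[i]) else 0.0
            fr_sd[i] = fr[i] * math.sqrt(
                (2.0 / 3.0 * rel_d) ** 2 + (1.0 / 3.0 * rel_s) ** 2
            )

    return ShapeSeries(
        conc=conc, n_avg=n_avg, rho_cx=rho_cx,
        s_meas=s_meas, d_meas=d_meas, fr=fr, fr_sd=fr_sd, flagged=flagged,
        metadata={"caveat": CAVEAT, "d_meas_source": d_meas_source},
    )


def n_avg_series(fit: IsothermFit, conc_grid) -> np.ndarray:
    """Model coverage N_avg on a concentration grid, shape (n, 2)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    conc_grid = np.asarray(conc_grid, dtype=float)
    n_avg = np.array([hill_n_avg(fit.params, float(c)) for c in conc_grid])
    return np.column_stack([conc_grid, n_avg])
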