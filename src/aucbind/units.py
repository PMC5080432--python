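"""Physical constants and unit conversions.

All internal computation is in SI (m, kg, s, Pa·s, mol/L for molar
concentrations).  Conventional AUC units (Svedberg, g/cm³, nm, µM) appear
only at the I/O boundary through the converters below.
"""

from __future__ import annotations

#: Boltzmann constant, J/K (CODATA exact value).
K_B = 1.380649e-23

#: One Svedberg in seconds.
SVEDBERG = 1e-13


def to_svedberg(s_si: float) -> float:
    """Convert a sedimentation coefficient from seconds to Svedberg."""
    return s_si / SVEDBERG


def from_svedberg(s_sved: float) -> float:
    """Convert a sedimentation coefficient from Svedberg to seconds."""
    return s_sved * SVEDBERG


def gcm3_to_si(rho: float) -> float:
    """g/cm³ → kg/m³."""
    return rho * 1e3


def si_to_gcm3(rho: float) -> float:
    """kg/m³ → g/cm³ (division, so conventional values round-trip exactly)."""
    return rho / 1e3


def nm_to_m(x: float) -> float:
    return x * 1e-9


def m_to_nm(x: float) -> float:
    return x / 1e-9


def nm3_to_m3(v: float) -> float:
    return v * 1e-27


def m3_to_nm3(v: float) -> float:
    return v / 1e-27


def um_to_molar(c: float) -> float:
    """µM → mol/L."""
    return c * 1e-6


def molar_to_um(c: float) -> float:
    """mol/L → µM."""
    return c * 1e6


def mpas_to_pas(eta: float) -> float:
    """mPa·s → Pa·s."""
    return eta * 1e-3


def celsius_to_kelvin(t: float) -> float:
    return t + 273.15
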