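"""File formats: scan CSVs, spec configs, isotherm tables, fit results.

Scan dialect
------------
One CSV file per radial scan with ``#``-prefixed header lines::

    # time_s=120.0
    # rpm=10000
    # temp_c=20.0
    # wavelength_nm=520
    radius_cm,signal_od
    6.0015,0.7991
    ...

A plain-text manifest in the same directory lists the scan filenames in
time order, one per line.  The reader tolerates CRLF line endings and
extra comment lines.

Config dialect
--------------
Particle / protein / solvent specs are flat TOML tables with conventional
units: ``d_h_nm``, ``density_g_cm3`` (particle); ``v_p_nm3``,
``density_g_cm3`` (protein); ``eta_mpa_s``, ``rho_s_g_cm3``, ``temp_c``
(solvent).
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .hydro import InteractionParams, ParticleSpec, ProteinSpec, SolventModel
from .isotherm import IsothermDataset, IsothermFit
from .lamm import ScanSet
from .units import (
    celsius_to_kelvin,
    from_svedberg,
    gcm3_to_si,
    m3_to_nm3,
    m_to_nm,
    mpas_to_pas,
    nm3_to_m3,
    nm_to_m,
    si_to_gcm3,
    to_svedberg,
)

__all__ = [
    "write_scanset",
    "read_scanset",
    "read_particle_config",
    "read_protein_config",
    "read_solvent_config",
    "write_particle_config",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "write_fit_json",
    "read_fit_json",
    "write_distribution_csv",
]

MANIFEST = "manifest.txt"


def write_scanset(scans: ScanSet, outdir) -> Path:
    """Write one CSV per scan plus a manifest; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = scans.metadata
    names = []
    for i, t in enumerate(scans.times):
        name = f"scan_{i:04d}.csv"
        names.append(name)
        with open(outdir / name, "w") as fh:
            fh.write(f"# time_s={t}\n")
            fh.write(f"# rpm={meta.get('rpm', '')}\n")
            fh.write(f"# temp_c={meta.get('temperature', 293.15) - 273.15}\n")
            fh.write(f"# wavelength_nm={meta.get('wavelength_nm', 520.0)}\n")
            fh.write(f"# meniscus_cm={meta.get('meniscus_m', scans.radii[0]) * 100}\n")
            fh.write(f"# base_cm={meta.get('base_m', scans.radii[-1]) * 100}\n")
            fh.write(f"# noise_sigma={meta.get('noise_sigma', 0.0)}\n")
            seed = meta.get("seed")
            fh.write(f"# seed={seed if seed is not None else ''}\n")
            fh.write("radius_cm,signal_od\n")
            for r, c in zip(scans.radii, scans.signal[i]):
                fh.write(f"{r * 100:.6f},{c:.6e}\n")
    (outdir / MANIFEST).write_text("\n".join(names) + "\n")
    return outdir


def _parse_scan_file(path: Path) -> tuple[dict, np.ndarray, np.ndarray]:
    header: dict = {}
    radii, signal = [], []
    with open(path, "r", newline="") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
                continue
            if line.lower().startswith("radius"):
                continue
            parts = line.split(",")
            radii.append(float(parts[0]))
            signal.append(float(parts[1]))
    return header, np.asarray(radii), np.asarray(signal)


def read_scanset(scandir) -> ScanSet:
    """Read a scan directory (manifest + per-scan CSVs) into a ScanSet."""
    scandir = Path(scandir)
    manifest = scandir / MANIFEST
    if manifest.exists():
        names = [ln.strip() for ln in manifest.read_text().splitlines()
                 if ln.strip()]
    else:
        names = sorted(p.name for p in scandir.glob("scan_*.csv"))
    if not names:
        raise FileNotFoundError(f"no scans found in {scandir}")

    times, profiles = [], []
    radii = None
    meta: dict = {}
    for name in names:
        header, r_cm, sig = _parse_scan_file(scandir / name)
        times.append(float(header["time_s"]))
        if radii is None:
            radii = r_cm / 100.0
            meta = {
                "rpm": float(header.get("rpm", 0) or 0),
                "temperature": celsius_to_kelvin(
                    float(header.get("temp_c", 20.0))
                ),
                "wavelength_nm": float(header.get("wavelength_nm", 520.0)),
                "noise_sigma": float(header.get("noise_sigma", 0.0) or 0.0),
            }
            if header.get("meniscus_cm"):
                meta["meniscus_m"] = float(header["meniscus_cm"]) / 100.0
            if header.get("base_cm"):
                meta["base_m"] = float(header["base_cm"]) / 100.0
            seed_txt = header.get("seed", "")
            if seed_txt and seed_txt != "None":
                meta["seed"] = int(float(seed_txt))
        profiles.append(sig)
    order = np.argsort(times)
    return ScanSet(
        radii=radii,
        times=np.asarray(times)[order],
        signal=np.vstack(profiles)[order],
        metadata=meta,
    )


def _load_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def read_particle_config(path) -> ParticleSpec:
    cfg = _load_toml(path)
    return ParticleSpec(
        hydrodynamic_diameter=nm_to_m(float(cfg["d_h_nm"])),
        density=gcm3_to_si(float(cfg["density_g_cm3"])),
        label=str(cfg.get("label", Path(path).stem)),
    )


def read_protein_config(path) -> ProteinSpec:
    cfg = _load_toml(path)
    return ProteinSpec(
        hydrodynamic_volume=nm3_to_m3(float(cfg["v_p_nm3"])),
        density=gcm3_to_si(float(cfg["density_g_cm3"])),
        label=str(cfg.get("label", Path(path).stem)),
    )


def read_solvent_config(path) -> SolventModel:
    cfg = _load_toml(path)
    return SolventModel(
        viscosity=mpas_to_pas(float(cfg.get("eta_mpa_s", 1.002))),
        density=gcm3_to_si(float(cfg.get("rho_s_g_cm3", 0.99823))),
        temperature=celsius_to_kelvin(float(cfg.get("temp_c", 20.0))),
    )


def write_particle_config(spec: ParticleSpec, path) -> None:
    """Write a particle spec as flat TOML (keys documented in the module)."""
    lines = [
        f'label = "{spec.label}"',
        f"d_h_nm = {m_to_nm(spec.hydrodynamic_diameter)!r}",
        f"density_g_cm3 = {si_to_gcm3(spec.density)!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_isotherm_csv(path) -> IsothermDataset:
    """Read an isotherm table: conc_molar, s_svedberg, sd_svedberg, n_reps."""
    df = pd.read_csv(path, comment="#")
    return IsothermDataset(
        conc=df["conc_molar"].to_numpy(float),
        s_mean=from_svedberg(df["s_svedberg"].to_numpy(float)),
        s_sd=from_svedberg(df["sd_svedberg"].to_numpy(float)),
        n_reps=df["n_reps"].to_numpy(int)
        if "n_reps" in df else np.ones(len(df), dtype=int),
    )


def write_isotherm_csv(data: IsothermDataset, path) -> None:
    pd.DataFrame(
        {
            "conc_molar": data.conc,
            "s_svedberg": to_svedberg(data.s_mean),
            "sd_svedberg": to_svedberg(data.s_sd),
            "n_reps": data.n_reps,
        }
    ).to_csv(path, index=False)


def write_fit_json(fit: IsothermFit, path, seed=None) -> None:
    """Serialize a fit result (parameters in conventional units)."""
    out = {
        "params": {
            "k_d_molar": fit.params.k_d,
            "n_max": fit.params.n_max,
            "hill_n": fit.params.hill_n,
        },
        "param_sd": {
            "k_d_molar": fit.param_sd["k_d"],
            "n_max": fit.param_sd["n_max"],
            "hill_n": fit.param_sd["hill_n"],
        },
        "bootstrap_sd": fit.bootstrap_sd,
        "residuals_svedberg": [to_svedberg(r) for r in fit.residuals],
        "rmsd_weighted": fit.rmsd,
        "warnings": fit.warnings,
        "converged": fit.converged,
        "seed": seed,
        "inputs": {
            "particle": {
                "d_h_nm": m_to_nm(fit.particle.hydrodynamic_diameter),
                "density_g_cm3": si_to_gcm3(fit.particle.density),
                "label": fit.particle.label,
            },
            "protein": {
                "v_p_nm3": m3_to_nm3(fit.protein.hydrodynamic_volume),
                "density_g_cm3": si_to_gcm3(fit.protein.density),
                "label": fit.protein.label,
            },
            "solvent": {
                "eta_mpa_s": fit.solvent.viscosity * 1e3,
                "rho_s_g_cm3": si_to_gcm3(fit.solvent.density),
                "temp_c": fit.solvent.temperature - 273.15,
            },
        },
        "data": {
            "conc_molar": fit.data.conc.tolist(),
            "s_svedberg": to_svedberg(fit.data.s_mean).tolist(),
            "sd_svedberg": to_svedberg(fit.data.s_sd).tolist(),
            "n_reps": fit.data.n_reps.tolist(),
        },
    }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def read_fit_json(path) -> IsothermFit:
    raw = json.loads(Path(path).read_text())
    particle = ParticleSpec(
        hydrodynamic_diameter=nm_to_m(raw["inputs"]["particle"]["d_h_nm"]),
        density=gcm3_to_si(raw["inputs"]["particle"]["density_g_cm3"]),
        label=raw["inputs"]["particle"].get("label", ""),
    )
    protein = ProteinSpec(
        hydrodynamic_volume=nm3_to_m3(raw["inputs"]["protein"]["v_p_nm3"]),
        density=gcm3_to_si(raw["inputs"]["protein"]["density_g_cm3"]),
        label=raw["inputs"]["protein"].get("label", ""),
    )
    solvent = SolventModel(
        viscosity=mpas_to_pas(raw["inputs"]["solvent"]["eta_mpa_s"]),
        density=gcm3_to_si(raw["inputs"]["solvent"]["rho_s_g_cm3"]),
        temperature=celsius_to_kelvin(raw["inputs"]["solvent"]["temp_c"]),
    )
    data = IsothermDataset(
        conc=np.asarray(raw["data"]["conc_molar"]),
        s_mean=from_svedberg(np.asarray(raw["data"]["s_svedberg"])),
        s_sd=from_svedberg(np.asarray(raw["data"]["sd_svedberg"])),
        n_reps=np.asarray(raw["data"]["n_reps"], dtype=int),
    )
    return IsothermFit(
        params=InteractionParams(
            k_d=raw["params"]["k_d_molar"],
            n_max=raw["params"]["n_max"],
            hill_n=raw["params"]["hill_n"],
        ),
        param_sd={
            "k_d": raw["param_sd"]["k_d_molar"],
            "n_max": raw["param_sd"]["n_max"],
            "hill_n": raw["param_sd"]["hill_n"],
        },
        residuals=from_svedberg(np.asarray(raw["residuals_svedberg"])),
        rmsd=raw["rmsd_weighted"],
        warnings=list(raw.get("warnings", [])),
        particle=particle,
        protein=protein,
        solvent=solvent,
        data=data,
        converged=raw.get("converged", True),
        bootstrap_sd=raw.get("bootstrap_sd"),
    )


def write_distribution_csv(dist, path) -> None:
    """Write a sedimentation-coefficient distribution: s_svedberg, weight."""
    pd.DataFrame(
        {"s_svedberg": to_svedberg(dist.s_grid), "weight": dist.weights}
    ).to_csv(path, index=False)
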