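"""Structured configuration: defaults, YAML loading, object construction.

One nested mapping holds every tunable of the framework, organised in
blocks (geometry, solution, particle, forces, simulation, analysis,
sweep).  Values at this boundary use the field's conventional units
(um, nm, mV, mol/L); the builders convert to SI on the way in.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .electrostatics import CONSTANTS, ParticleSpec, SolutionModel
from .forces import FluidModel, MembraneModel
from .dynamics import SimulationConfig

__all__ = [
    "default_config",
    "load_config",
    "solution_from_config",
    "particle_from_config",
    "membrane_from_config",
    "fluid_from_config",
    "simulation_from_config",
]

_DEFAULTS: dict = {
    "geometry": {
        "domain_size_um": 18.0,
        "mean_diameter_um": 1.0,
        "diameter_bounds_um": [0.2, 2.0],
        "min_gap_um": 0.1,
        "target_porosity": 0.3,
        "sigma_log": 0.6,
        "porosity_tol": 0.01,
        "mean_diameter_tol": 0.05,
        "clear_radius_um": 0.25,
        # recorded for completeness; a 2-D cross-section has no use for it
        "axon_length_um": 15.0,
    },
    "solution": {
        "ion_concentration_mol_L": 0.154,
        "temperature_K": 310.0,
        "permittivity_C_Vm": 6.55e-10,
        "viscosity_Pa_s": {"IF": 3.5e-3, "agarose": 6.9152e-4},
        "medium": "IF",
    },
    "particle": {
        "diameter_nm": 40.0,
        "zeta_mV": 0.0,
        "fixed_charge_e": None,
        "density_kg_m3": 1000.0,
    },
    "forces": {
        "coulomb": {"mode": "unscreened"},
        "membrane": {
            "zeta_mV": -20.0,
            "hamaker_J": 1e-20,
            "cutoff_nm": 10.0,
            "h_min_nm": 1.0,
        },
        "fluid": {"knudsen": 0.025, "flow_velocity_m_s": [0.0, 0.0]},
    },
    "simulation": {
        "dt_s": 1e-7,
        "n_steps": 20000,
        "n_particles": 900,
        "release_size_um": 0.2,
        "record_stride": 20,
        "dx_max_nm": 10.0,
        "seed": 0,
        "early_stop_alive_frac": 0.0,
        "medium": "WM",
    },
    "analysis": {
        "min_window": 0.20,
        "r2_threshold": 0.995,
        "slope_tolerance": 0.10,
        "min_alive_fraction": 0.80,
    },
    "sweep": {
        "sizes_nm": [20.0, 40.0, 60.0, 80.0, 90.0, 98.0],
        "zetas_mV": [0.0, -5.0, -10.0, -20.0, -30.0, -40.0, -50.0],
        "charge_mode": "fixed-zeta",
        "fixed_charge_e": -200.0,
        "medium": "WM",
        "replicates": 3,
        "base_seed": 1,
        "profile": "desk",
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file (deep merge)."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    return cfg


def solution_from_config(cfg: dict) -> SolutionModel:
    s = cfg["solution"]
    mu = s["viscosity_Pa_s"]
    if isinstance(mu, dict):
        mu = mu[s.get("medium", "IF")]
    return SolutionModel(
        ion_concentration=s["ion_concentration_mol_L"],
        eps=s["permittivity_C_Vm"],
        temperature=s["temperature_K"],
        mu=mu,
    )


def particle_from_config(cfg: dict) -> ParticleSpec:
    p = cfg["particle"]
    fc = p.get("fixed_charge_e")
    return ParticleSpec(
        diameter=p["diameter_nm"] * 1e-9,
        zeta=p["zeta_mV"] * 1e-3,
        fixed_charge=None if fc is None else fc * CONSTANTS.e,
        density=p.get("density_kg_m3", 1000.0),
    )


def membrane_from_config(cfg: dict) -> MembraneModel:
    m = cfg["forces"]["membrane"]
    return MembraneModel(
        zeta_membrane=m["zeta_mV"] * 1e-3,
        hamaker=m["hamaker_J"],
        cutoff=m["cutoff_nm"] * 1e-9,
        h_min=m["h_min_nm"] * 1e-9,
    )


def fluid_from_config(cfg: dict) -> FluidModel:
    f = cfg["forces"]["fluid"]
    return FluidModel(
        flow_velocity=tuple(f["flow_velocity_m_s"]), knudsen=f["knudsen"]
    )


def simulation_from_config(cfg: dict) -> SimulationConfig:
    s = cfg["simulation"]
    return SimulationConfig(
        dt=s["dt_s"],
        n_steps=s["n_steps"],
        n_particles=s["n_particles"],
        release_size=s["release_size_um"] * 1e-6,
        seed=s["seed"],
        record_stride=s["record_stride"],
        medium=s["medium"],
        dx_max=s["dx_max_nm"] * 1e-9,
        coulomb_mode=cfg["forces"]["coulomb"]["mode"],
        early_stop_alive_frac=s["early_stop_alive_frac"],
    )
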