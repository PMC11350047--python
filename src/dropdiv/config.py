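"""YAML configuration I/O.

One schema serves the well-mixed and spatial engines::

    species:
      enzyme: 0.25                # U/µL
      circuits:
        AB: {linker_total: 0.2, trigger_total: 1.0, c_tilde: 1.25}
        AC: {linker_total: 0.2, trigger_total: 1.0, c_tilde: 0.0}
    params:
      k_cat: 2.0e-3               # µM/s per U/µL
      K_m: 0.5                    # µM
      k_h_rna: 0.5                # 1/(µM·s)
      competition_mode: shared
      displacement_mode: two-step
      circuits:
        AB: {k_on: 0.005, k_d: 0.05}
        AC: {k_on: 0.05, k_d: 0.5}
    grid:    {nx: 64, ny: 64, spacing: 2.0, droplet_radius: 40.0}   # optional
    dmap:    {mobile_inside: 10.0, mobile_outside: 30.0,
              linker_inside: 0.1, linker_outside: 0.0}              # optional

All concentrations are µM except the enzyme (U/µL).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Dict, Tuple

import yaml

from .kinetics import CircuitParams, KineticParams, SpeciesSet, init_circuit
from .spatial import DiffusionMap, GridSpec

__all__ = ["load_config", "load_well_mixed", "load_grid", "load_dmap"]


def load_config(path: str | Path) -> Dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return cfg


def _params_from(cfg: Dict[str, Any]) -> KineticParams:
    p = dict(cfg.get("params", {}))
    circuit_rates = {
        name: CircuitParams(**rates)
        for name, rates in p.pop("circuits", {}).items()
    }
    species = cfg.get("species", {})
    for name in species.get("circuits", {}):
        circuit_rates.setdefault(name, CircuitParams())
    return KineticParams(circuits=circuit_rates, **p)


def _state_from(cfg: Dict[str, Any]) -> SpeciesSet:
    species = cfg.get("species", {})
    circuits = {}
    for name, doses in species.get("circuits", {}).items():
        circuits[name] = init_circuit(
            linker_total=doses.get("linker_total", 0.0),
            trigger_total=doses.get("trigger_total", 0.0),
            c_tilde=doses.get("c_tilde", 0.0),
            free_trigger_extra=doses.get("free_trigger_extra", 0.0),
        )
    if not circuits:
        raise ValueError("config defines no circuits")
    return SpeciesSet(circuits=circuits, enzyme=species.get("enzyme", 0.0))


def load_well_mixed(path: str | Path) -> Tuple[SpeciesSet, KineticParams]:
    """Initial state and kinetic parameters from a config file."""
    cfg = load_config(path)
    return _state_from(cfg), _params_from(cfg)


def load_grid(cfg: Dict[str, Any]) -> GridSpec:
    return GridSpec(**cfg.get("grid", {}))


def load_dmap(cfg: Dict[str, Any]) -> DiffusionMap:
    return DiffusionMap(**cfg.get("dmap", {}))
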