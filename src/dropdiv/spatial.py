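"""2-D reaction-diffusion engine for linker cleavage inside a DNA droplet.

The droplet is a static disk embedded in a square domain with no-flux walls.
Linker nanostructures are a condensed phase: their site fields live inside
the droplet and do not leave it (zero diffusivity outside, so the
harmonic-mean interface coefficient shuts off outward flux automatically).
Triggers, trigger–RNA hybrids and inhibitor RNAs are small and mobile
everywhere, with a position-dependent diffusion coefficient (slower inside
the crowded droplet than in the surrounding bulk).  The reaction part of the
dynamics in every cell is exactly the well-mixed circuit model of
:mod:`dropdiv.kinetics`.

Two time-stepping modes are provided:

* ``explicit`` — Euler operator splitting (reaction, then 5-point diffusion)
  with the usual ``dt <= h**2 / (4 D_max)`` stability bound enforced;
* ``imex`` — backward-Euler diffusion through a pre-factorized sparse
  operator plus subcycled explicit reaction.  Unconditionally stable in the
  diffusion step, which is what makes the multi-hour circuit horizons
  tractable; this is the production default of :func:`simulate_rd`.

Diffusive fluxes use harmonic-mean face coefficients, the standard
conservative treatment for piecewise-constant diffusivity, so total mass of
a non-reacting species is conserved to round-off under no-flux walls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .kinetics import (
    N_SITES,
    SPECIES,
    CircuitParams,
    KineticParams,
    SimulationError,
)

__all__ = [
    "GridSpec",
    "DiffusionMap",
    "FieldState",
    "RDConfig",
    "RDResult",
    "StabilityError",
    "laplacian",
    "step_rd",
    "simulate_rd",
    "radial_profile",
]

#: species transported with the mobile (small-molecule) diffusivity profile
MOBILE_SPECIES = ("T", "iT", "R")
#: species tied to the linker nanostructure (confined to the droplet)
LINKER_SPECIES = ("S", "C", "P")


class StabilityError(ValueError):
    """Explicit diffusion step requested with an unstable dt."""


@dataclass(frozen=True)
class GridSpec:
    """Square lattice with an embedded disk-shaped droplet.

    nx, ny          : number of cells
    spacing         : cell size, µm
    droplet_center  : (x, y) in µm; defaults to the domain center
    droplet_radius  : µm
    """

    nx: int = 64
    ny: int = 64
    spacing: float = 2.0
    droplet_center: Optional[Tuple[float, float]] = None
    droplet_radius: float = 40.0
    boundary_condition: str = "no-flux"

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3")
        if self.spacing <= 0 or self.droplet_radius <= 0:
            raise ValueError("spacing and droplet_radius must be positive")
        if self.boundary_condition != "no-flux":
            raise ValueError("only no-flux boundaries are supported")
        cx, cy = self.center
        lx, ly = self.nx * self.spacing, self.ny * self.spacing
        if (
            cx - self.droplet_radius < 0
            or cy - self.droplet_radius < 0
            or cx + self.droplet_radius > lx
            or cy + self.droplet_radius > ly
        ):
            raise ValueError("droplet must lie strictly inside the domain")
        if not self.mask.any():
            raise ValueError("droplet mask is empty")

    @property
    def center(self) -> Tuple[float, float]:
        if self.droplet_center is not None:
            return self.droplet_center
        return (self.nx * self.spacing / 2.0, self.ny * self.spacing / 2.0)

    @property
    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) + 0.5) * self.spacing
        y = (np.arange(self.ny) + 0.5) * self.spacing
        return np.meshgrid(x, y)  # shapes (ny, nx)

    @property
    def radius_map(self) -> np.ndarray:
        xx, yy = self.cell_centers
        cx, cy = self.center
        return np.hypot(xx - cx, yy - cy)

    @property
    def mask(self) -> np.ndarray:
        """Boolean (ny, nx) array: True inside the droplet."""
        return self.radius_map <= self.droplet_radius


@dataclass(frozen=True)
class DiffusionMap:
    """Inside/outside diffusivities (µm²/s) for the two transport classes."""

    mobile_inside: float = 10.0
    mobile_outside: float = 30.0
    linker_inside: float = 0.1
    linker_outside: float = 0.0

    def __post_init__(self) -> None:
        for v in (
            self.mobile_inside,
            self.mobile_outside,
            self.linker_inside,
            self.linker_outside,
        ):
            if v < 0:
                raise ValueError("diffusivities must be non-negative")

    def field_for(self, species: str, grid: GridSpec) -> np.ndarray:
        mask = grid.mask
        if species in MOBILE_SPECIES:
            inside, outside = self.mobile_inside, self.mobile_outside
        elif species in LINKER_SPECIES:
            inside, outside = self.linker_inside, self.linker_outside
        else:
            raise KeyError(f"unknown species {species!r}")
        return np.where(mask, inside, outside).astype(float)

    @property
    def d_max(self) -> float:
        return max(
            self.mobile_inside,
            self.mobile_outside,
            self.linker_inside,
            self.linker_outside,
        )


@dataclass
class FieldState:
    """Per-species concentration fields; each circuit maps species name to
    an array of shape ``(2, ny, nx)`` (one layer per trigger site)."""

    circuits: Dict[str, Dict[str, np.ndarray]]
    enzyme: float
    grid: GridSpec
    clamp_count: int = 0  # cells clamped to zero across the run so far

    def copy(self) -> "FieldState":
        return FieldState(
            {
                c: {sp: a.copy() for sp, a in d.items()}
                for c, d in self.circuits.items()
            },
            self.enzyme,
            self.grid,
            self.clamp_count,
        )

    def linker_total(self, circuit: str) -> np.ndarray:
        d = self.circuits[circuit]
        return d["S"][0] + d["C"][0] + d["P"][0]

    def uncleaved_field(self, circuit: str) -> np.ndarray:
        """Concentration field of not-fully-cleaved linker (µM); zero where
        no linker is present."""
        d = self.circuits[circuit]
        ltot = self.linker_total(circuit)
        out = np.zeros_like(ltot)
        nz = ltot > 0
        out[nz] = ltot[nz] * (
            1.0 - (d["P"][0][nz] / ltot[nz]) * (d["P"][1][nz] / ltot[nz])
        )
        return out

    def droplet_mean_w(self, circuit: str) -> float:
        """Droplet-averaged uncleaved fraction w of this circuit's linker."""
        mask = self.grid.mask
        ltot = self.linker_total(circuit)[mask]
        unc = self.uncleaved_field(circuit)[mask]
        tot = ltot.sum()
        if tot <= 0:
            raise ValueError(f"no linker inside droplet for circuit {circuit!r}")
        return float(unc.sum() / tot)


def uniform_fields(
    grid: GridSpec,
    linker_doses: Mapping[str, float],
    trigger_doses: Mapping[str, Tuple[float, float, float]],
    enzyme: float,
    triggers_outside: bool = True,
) -> FieldState:
    """Build an initial field state from bulk doses.

    ``linker_doses[circuit]`` is the intact-linker concentration inside the
    droplet; ``trigger_doses[circuit] = (trigger_total, c_tilde,
    free_trigger_extra)`` describes the trigger mixture, placed in the bulk
    outside the droplet when ``triggers_outside`` (the experimental protocol:
    the mixture is added to the droplet suspension) or everywhere otherwise.
    """
    mask = grid.mask.astype(float)
    region = (1.0 - mask) if triggers_outside else np.ones_like(mask)
    circuits: Dict[str, Dict[str, np.ndarray]] = {}
    for name, ltot in linker_doses.items():
        t_tot, c_tilde, extra = trigger_doses[name]
        hybrid = min(c_tilde * t_tot, t_tot)
        t_free = t_tot - hybrid + extra
        r_free = c_tilde * t_tot - hybrid
        shape = (N_SITES, grid.ny, grid.nx)
        fields = {
            "T": np.broadcast_to(t_free * region, shape).copy(),
            "iT": np.broadcast_to(hybrid * region, shape).copy(),
            "R": np.broadcast_to(r_free * region, shape).copy(),
            "S": np.broadcast_to(ltot * mask, shape).copy(),
            "C": np.zeros(shape),
            "P": np.zeros(shape),
        }
        circuits[name] = fields
    return FieldState(circuits=circuits, enzyme=enzyme, grid=grid)


# --------------------------------------------------------------------------
# diffusion operators


def laplacian(field: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Constant-coefficient 5-point Laplacian with reflecting (no-flux)
    boundaries, 1/µm² units.  The stencil is conservative: the sum over all
    cells of ``laplacian * spacing**2`` telescopes to zero."""
    f = np.asarray(field, dtype=float)
    if f.shape != (grid.ny, grid.nx):
        raise ValueError(
            f"field shape {f.shape} does not match grid ({grid.ny}, {grid.nx})"
        )
    p = np.pad(f, 1, mode="edge")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f
    ) / grid.spacing**2


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def diffusion_apply(field: np.ndarray, dmap_field: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Apply the conservative variable-coefficient operator ∇·(D∇u) with
    harmonic-mean face diffusivities and no-flux walls."""
    u = np.asarray(field, dtype=float)
    h2 = grid.spacing**2
    d = dmap_field
    # vertical faces (between columns)
    dx = _harmonic(d[:, :-1], d[:, 1:])
    fx = dx * (u[:, 1:] - u[:, :-1])  # flux * h
    # horizontal faces (between rows)
    dy = _harmonic(d[:-1, :], d[1:, :])
    fy = dy * (u[1:, :] - u[:-1, :])
    out = np.zeros_like(u)
    out[:, :-1] += fx
    out[:, 1:] -= fx
    out[:-1, :] += fy
    out[1:, :] -= fy
    return out / h2


def diffusion_matrix(dmap_field: np.ndarray, grid: GridSpec) -> sp.csc_matrix:
    """Sparse matrix of ∇·(D∇·) on the flattened (ny*nx) grid."""
    ny, nx = grid.ny, grid.nx
    h2 = grid.spacing**2
    d = dmap_field
    n = ny * nx

    def idx(iy: np.ndarray, ix: np.ndarray) -> np.ndarray:
        return iy * nx + ix

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    diag = np.zeros((ny, nx))

    # x-direction faces
    dx = _harmonic(d[:, :-1], d[:, 1:]) / h2
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx - 1), indexing="ij")
    left, right = idx(iy, ix), idx(iy, ix + 1)
    rows += [left.ravel(), right.ravel()]
    cols += [right.ravel(), left.ravel()]
    vals += [dx.ravel(), dx.ravel()]
    diag[:, :-1] -= dx
    diag[:, 1:] -= dx

    # y-direction faces
    dy = _harmonic(d[:-1, :], d[1:, :]) / h2
    iy, ix = np.meshgrid(np.arange(ny - 1), np.arange(nx), indexing="ij")
    lo, hi = idx(iy, ix), idx(iy + 1, ix)
    rows += [lo.ravel(), hi.ravel()]
    cols += [hi.ravel(), lo.ravel()]
    vals += [dy.ravel(), dy.ravel()]
    diag[:-1, :] -= dy
    diag[1:, :] -= dy

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag.ravel())
    return sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


# --------------------------------------------------------------------------
# reaction update (vectorized over the grid)


def _reaction_rates(
    state: FieldState, params: KineticParams
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-cell reaction fluxes, same scheme as the well-mixed model."""
    if params.competition_mode == "shared":
        total_sub = sum(
            d["iT"].sum(axis=0) for d in state.circuits.values()
        )  # (ny, nx)
    else:
        total_sub = None
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for name, d in state.circuits.items():
        cp = params.for_circuit(name)
        denom = params.K_m + (d["iT"] if total_sub is None else total_sub)
        rel = params.k_cat * state.enzyme * d["iT"] / denom
        inh = params.k_h_rna * d["T"] * d["R"]
        bind = cp.k_on * d["T"] * d["S"]
        if params.displacement_mode == "two-step":
            disp = cp.k_d * d["C"]
            dC = bind - disp
        else:
            disp = bind
            dC = np.zeros_like(bind)
        out[name] = {
            "T": rel - inh - bind,
            "iT": inh - rel,
            "R": -inh,
            "S": -bind,
            "C": dC,
            "P": disp,
        }
    return out


def _max_rate_coeff(state: FieldState, params: KineticParams) -> float:
    """Crude bound on the fastest linear relaxation rate (1/s) across the
    grid, used to pick the reaction subcycle step."""
    coeff = params.k_cat * state.enzyme / params.K_m
    for name, d in state.circuits.items():
        cp = params.for_circuit(name)
        t_max = float(d["T"].max(initial=0.0))
        r_max = float(d["R"].max(initial=0.0))
        s_max = float(d["S"].max(initial=0.0))
        coeff = max(
            coeff,
            params.k_h_rna * max(t_max, r_max),
            cp.k_on * max(t_max, s_max),
            cp.k_d if params.displacement_mode == "two-step" else 0.0,
        )
    return coeff


def _reaction_substep(state: FieldState, dt: float, params: KineticParams) -> None:
    rates = _reaction_rates(state, params)
    for name, d in state.circuits.items():
        for spn in SPECIES:
            arr = d[spn]
            arr += dt * rates[name][spn]
            neg = arr < 0
            if neg.any():
                state.clamp_count += int(neg.sum())
                arr[neg] = 0.0


def react(state: FieldState, dt: float, params: KineticParams, safety: float = 0.2) -> None:
    """Advance the local (reaction-only) dynamics by ``dt`` in place, using
    explicit Euler substeps sized to the fastest local rate."""
    coeff = _max_rate_coeff(state, params)
    n_sub = max(1, math.ceil(dt * coeff / safety))
    sub = dt / n_sub
    for _ in range(n_sub):
        _reaction_substep(state, sub, params)


# --------------------------------------------------------------------------
# stepping


def explicit_stability_dt(grid: GridSpec, dmap: DiffusionMap) -> float:
    """Largest explicit-Euler diffusion step, ``h**2 / (4 D_max)``."""
    if dmap.d_max == 0:
        return math.inf
    return grid.spacing**2 / (4.0 * dmap.d_max)


def step_rd(
    state: FieldState,
    dt: float,
    grid: GridSpec,
    dmap: DiffusionMap,
    params: KineticParams,
) -> FieldState:
    """One explicit operator-splitting step: reaction, then diffusion.

    Raises :class:`StabilityError` when ``dt`` exceeds the explicit
    diffusion stability bound.
    """
    bound = explicit_stability_dt(grid, dmap)
    if dt > bound:
        raise StabilityError(
            f"dt={dt:g} s exceeds the explicit diffusion stability bound "
            f"{bound:g} s; reduce dt or use the imex engine"
        )
    out = state.copy()
    react(out, dt, params)
    for name, d in out.circuits.items():
        for spn in SPECIES:
            dfield = dmap.field_for(spn, grid)
            if not dfield.any():
                continue
            for site in range(N_SITES):
                d[spn][site] += dt * diffusion_apply(d[spn][site], dfield, grid)
    return out


class _ImplicitDiffusion:
    """Backward-Euler diffusion solvers, one pre-factorized LU per
    transport class (the dt and D profiles are fixed over a run)."""

    def __init__(self, grid: GridSpec, dmap: DiffusionMap, dt: float):
        self.grid = grid
        self.solvers = {}
        n = grid.ny * grid.nx
        eye = sp.identity(n, format="csc")
        for cls, species in (("mobile", MOBILE_SPECIES), ("linker", LINKER_SPECIES)):
            dfield = dmap.field_for(species[0], grid)
            if not dfield.any():
                self.solvers[cls] = None
                continue
            a = diffusion_matrix(dfield, grid)
            self.solvers[cls] = splu((eye - dt * a).tocsc())

    def apply(self, field: np.ndarray, species: str) -> np.ndarray:
        cls = "mobile" if species in MOBILE_SPECIES else "linker"
        solver = self.solvers[cls]
        if solver is None:
            return field
        ny, nx = self.grid.ny, self.grid.nx
        return solver.solve(field.ravel()).reshape(ny, nx)


# --------------------------------------------------------------------------
# driver


@dataclass
class RDConfig:
    """Full configuration of a reaction-diffusion run."""

    grid: GridSpec
    dmap: DiffusionMap
    params: KineticParams
    linker_doses: Mapping[str, float]
    #: circuit -> (trigger_total, c_tilde, free_trigger_extra), µM
    trigger_doses: Mapping[str, Tuple[float, float, float]]
    enzyme: float
    t_end: float
    dt: float = 0.5
    snapshot_times: Sequence[float] = ()
    trace_interval: float = 20.0
    engine: str = "imex"  # or "explicit"
    triggers_outside: bool = True
    t_ref: float = 1.0  # normalization for reported times
    #: stop once every circuit's droplet-mean w falls below this level
    stop_w_floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt <= 0:
            raise ValueError("t_end and dt must be positive")
        if self.engine not in ("imex", "explicit"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class RDResult:
    """Snapshots plus droplet-averaged time courses of a run."""

    config: RDConfig
    snapshot_times: np.ndarray
    #: circuit -> list of uncleaved-linker fields, one per snapshot
    snapshots: Dict[str, List[np.ndarray]]
    #: droplet-mean traces: columns time, plus w_<circuit> per circuit
    traces: pd.DataFrame
    final_state: FieldState

    def w_trace(self, circuit: str) -> Tuple[np.ndarray, np.ndarray]:
        return (
            self.traces["time"].to_numpy(),
            self.traces[f"w_{circuit}"].to_numpy(),
        )


def simulate_rd(config: RDConfig) -> RDResult:
    """Run the reaction-diffusion model and collect snapshots and
    droplet-mean uncleaved-linker traces."""
    grid, dmap, params = config.grid, config.dmap, config.params
    state = uniform_fields(
        grid,
        config.linker_doses,
        config.trigger_doses,
        config.enzyme,
        config.triggers_outside,
    )
    dt = config.dt
    if config.engine == "explicit":
        bound = explicit_stability_dt(grid, dmap)
        if dt > bound:
            raise StabilityError(
                f"dt={dt:g} s exceeds the stability bound {bound:g} s"
            )
        implicit = None
    else:
        implicit = _ImplicitDiffusion(grid, dmap, dt)

    n_steps = int(math.ceil(config.t_end / dt))
    snap_times = np.asarray(sorted(config.snapshot_times), dtype=float)
    snap_idx = set(
        int(round(t / dt)) for t in snap_times if 0 <= t <= config.t_end
    )
    trace_every = max(1, int(round(config.trace_interval / dt)))

    circuits = list(state.circuits)
    snapshots: Dict[str, List[np.ndarray]] = {c: [] for c in circuits}
    taken_times: List[float] = []
    trace_rows: List[Dict[str, float]] = []

    def record_trace(t: float) -> bool:
        row = {"time": t}
        for c in circuits:
            row[f"w_{c}"] = state.droplet_mean_w(c)
        trace_rows.append(row)
        floor = config.stop_w_floor
        return floor is not None and all(
            row[f"w_{c}"] < floor for c in circuits
        )

    def record_snapshot(t: float) -> None:
        taken_times.append(t)
        for c in circuits:
            snapshots[c].append(state.uncleaved_field(c))

    record_trace(0.0)
    if 0 in snap_idx:
        record_snapshot(0.0)
    for step in range(1, n_steps + 1):
        t = step * dt
        react(state, dt, params)
        for d in state.circuits.values():
            for spn in SPECIES:
                for site in range(N_SITES):
                    if not d[spn][site].any():
                        continue  # nothing to transport
                    if implicit is not None:
                        d[spn][site] = implicit.apply(d[spn][site], spn)
                    else:
                        dfield = dmap.field_for(spn, grid)
                        if dfield.any():
                            d[spn][site] = d[spn][site] + dt * diffusion_apply(
                                d[spn][site], dfield, grid
                            )
        if not np.isfinite(state.circuits[circuits[0]]["T"]).all():
            raise SimulationError(f"non-finite fields at t={t:g} s")
        done = False
        if step % trace_every == 0 or step == n_steps:
            done = record_trace(t)
        if step in snap_idx:
            record_snapshot(t)
        if done:
            break

    traces = pd.DataFrame(trace_rows)
    traces["time_normalized"] = traces["time"] / config.t_ref
    return RDResult(
        config=config,
        snapshot_times=np.asarray(taken_times),
        snapshots=snapshots,
        traces=traces,
        final_state=state,
    )


# --------------------------------------------------------------------------
# diagnostics


def radial_profile(
    field: np.ndarray, grid: GridSpec, n_bins: int = 12
) -> pd.DataFrame:
    """Mean concentration in concentric annuli of the droplet.

    Returns columns ``r_mid`` (annulus midpoint radius, µm), ``mean``
    (NaN for annuli containing no cells) and ``n_cells``.  The
    cell-count-weighted average of the annulus means equals the droplet
    mean exactly.
    """
    f = np.asarray(field, dtype=float)
    if f.shape != (grid.ny, grid.nx):
        raise ValueError("field does not match grid")
    r = grid.radius_map
    edges = np.linspace(0.0, grid.droplet_radius, n_bins + 1)
    inside = grid.mask
    which = np.digitize(r, edges) - 1
    rows = []
    for b in range(n_bins):
        sel = inside & (which == b)
        n = int(sel.sum())
        rows.append(
            {
                "r_mid": 0.5 * (edges[b] + edges[b + 1]),
                "mean": float(f[sel].mean()) if n else np.nan,
                "n_cells": n,
            }
        )
    return pd.DataFrame(rows)
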