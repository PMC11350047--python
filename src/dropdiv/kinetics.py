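"""Well-mixed kinetics of the RNase H time-delay circuit and DNA-linker cleavage.

A *linker circuit* is one cross-linking DNA nanostructure (e.g. the linker
joining the A- and B-type branched motifs of a mixed droplet) together with
its two division-trigger sites.  Each site ``i`` (i = 1, 2) carries an
independent single-stranded DNA trigger that cleaves the linker at that site
by toehold-mediated strand displacement.  A linker molecule counts as cleaved
only once *both* of its sites have been displaced.

Per site the model tracks six species (all concentrations in µM):

========  ====================================================================
``T``     free division trigger
``iT``    inhibited trigger — trigger sequestered in a DNA:RNA hybrid with an
          inhibitor RNA (the miRNA input of the time-delay circuit)
``R``     free (excess) inhibitor RNA
``S``     intact linker sites (toehold accessible)
``C``     toehold-bound trigger–linker complex (two-step mode only)
``P``     displaced (cleaved) linker sites
========  ====================================================================

The time-delay circuit couples two reactions per site:

* RNase H degrades the RNA strand of the hybrid ``iT`` and releases the
  trigger at a Michaelis–Menten rate ``k_cat · c_E · iT / (K_m + iT)``.
  In shared-enzyme mode all hybrids compete for one enzyme pool and the
  denominator carries the *sum* of all hybrid substrates.
* Free inhibitor RNA re-sequesters free trigger by mass-action hybridization
  at rate ``k_h_rna · T · R``.

Linker cleavage consumes free trigger: bimolecular toehold binding
(``k_on · T · S``) followed by first-order strand displacement
(``k_d · C``); a single-step effective-bimolecular fallback collapses the
two steps into ``k_on · T · S`` directly producing ``P``.

Enzyme concentration is carried in U/µL; ``k_cat`` absorbs the unit
conversion (µM s⁻¹ per U/µL), so printed enzyme doses are usable verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Literal, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "CircuitParams",
    "KineticParams",
    "CircuitState",
    "SpeciesSet",
    "NormalizedDose",
    "Trajectory",
    "SimulationError",
    "init_circuit",
    "mm_release_rate",
    "inhibition_rate",
    "g_TD",
    "f_H_SD",
    "rhs_well_mixed",
    "simulate_well_mixed",
]

#: Per-site species, in canonical packing order.
SPECIES = ("T", "iT", "R", "S", "C", "P")
N_SITES = 2


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails to produce a valid trajectory."""


# --------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class CircuitParams:
    """Trigger–linker cleavage rates for one linker circuit.

    k_on : trigger–toehold hybridization rate, 1/(µM·s)
    k_d  : strand-displacement rate of the bound complex, 1/s
    """

    k_on: float = 0.05
    k_d: float = 0.5

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_d < 0:
            raise ValueError("rate constants must be non-negative")


@dataclass(frozen=True)
class KineticParams:
    """All rate constants of the time-delay circuit and linker cleavage.

    k_cat   : RNase H turnover, µM/s per (U/µL) of enzyme
    K_m     : RNase H Michaelis constant, µM
    k_h_rna : trigger–inhibitor-RNA hybridization rate, 1/(µM·s)
    circuits: cleavage rates per linker circuit, keyed by circuit name
    competition_mode : 'independent' (per-substrate MM denominator) or
                       'shared' (one enzyme pool; summed substrates)
    displacement_mode: 'two-step' (binding then displacement) or
                       'single-step' (effective bimolecular)
    """

    circuits: Mapping[str, CircuitParams] = field(
        default_factory=lambda: {"AB": CircuitParams()}
    )
    k_cat: float = 2e-3
    K_m: float = 0.5
    k_h_rna: float = 0.5
    competition_mode: Literal["independent", "shared"] = "independent"
    displacement_mode: Literal["two-step", "single-step"] = "two-step"

    def __post_init__(self) -> None:
        if self.k_cat < 0 or self.k_h_rna < 0:
            raise ValueError("rate constants must be non-negative")
        if self.K_m <= 0:
            raise ValueError("K_m must be positive")
        if self.competition_mode not in ("independent", "shared"):
            raise ValueError(f"unknown competition_mode {self.competition_mode!r}")
        if self.displacement_mode not in ("two-step", "single-step"):
            raise ValueError(f"unknown displacement_mode {self.displacement_mode!r}")

    def for_circuit(self, name: str) -> CircuitParams:
        try:
            return self.circuits[name]
        except KeyError:
            raise KeyError(
                f"no cleavage rates defined for linker circuit {name!r}; "
                f"known circuits: {sorted(self.circuits)}"
            ) from None


@dataclass(frozen=True)
class NormalizedDose:
    """Dimensionless inhibitor-RNA doses of the two-input comparator.

    c_tilde_ab / c_tilde_ac are the ratios of total inhibitor RNA to total
    trigger for the AB and AC circuits; delta is their difference (the
    comparator input) and total their sum (drives shared-enzyme competition).
    """

    c_tilde_ab: float
    c_tilde_ac: float

    def __post_init__(self) -> None:
        if self.c_tilde_ab < 0 or self.c_tilde_ac < 0:
            raise ValueError("normalized doses must be non-negative")

    @property
    def delta(self) -> float:
        return self.c_tilde_ab - self.c_tilde_ac

    @property
    def total(self) -> float:
        return self.c_tilde_ab + self.c_tilde_ac


# --------------------------------------------------------------------------
# state


@dataclass
class CircuitState:
    """Concentrations of one linker circuit; each field is shape ``(2,)``
    (one entry per trigger site)."""

    T: np.ndarray
    iT: np.ndarray
    R: np.ndarray
    S: np.ndarray
    C: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        for name in SPECIES:
            arr = np.asarray(getattr(self, name), dtype=float).reshape(N_SITES)
            setattr(self, name, arr)

    @property
    def linker_total(self) -> float:
        """Total linker concentration (µM), from site-1 bookkeeping."""
        return float(self.S[0] + self.C[0] + self.P[0])

    @property
    def uncleaved_fraction(self) -> float:
        """Fraction of linkers with at least one intact site.

        Site fates are independent across the linker population, so the
        fraction of molecules with *both* sites displaced is the product of
        the per-site displaced fractions.
        """
        ltot = self.linker_total
        if ltot <= 0:
            raise ValueError("circuit has no linker")
        return float(1.0 - (self.P[0] / ltot) * (self.P[1] / ltot))

    def trigger_totals(self) -> np.ndarray:
        """Per-site conserved trigger totals (free + inhibited + bound).

        A displaced site (``P``) retains its trigger hybridized to the
        cleaved strand, so it counts toward the conserved total.
        """
        return self.T + self.iT + self.C + self.P

    def copy(self) -> "CircuitState":
        return CircuitState(*(getattr(self, n).copy() for n in SPECIES))


@dataclass
class SpeciesSet:
    """Full well-mixed state: all linker circuits plus the enzyme level."""

    circuits: Dict[str, CircuitState]
    enzyme: float = 0.0  # U/µL

    def __post_init__(self) -> None:
        if self.enzyme < 0:
            raise ValueError("enzyme level must be non-negative")
        for st in self.circuits.values():
            for name in SPECIES:
                if np.any(getattr(st, name) < 0):
                    raise ValueError("concentrations must be non-negative")

    def copy(self) -> "SpeciesSet":
        return SpeciesSet(
            {k: v.copy() for k, v in self.circuits.items()}, self.enzyme
        )

    def total_hybrid(self) -> float:
        """Summed inhibited-trigger substrate across all circuits/sites."""
        return float(sum(st.iT.sum() for st in self.circuits.values()))


def init_circuit(
    linker_total: float,
    trigger_total: float,
    c_tilde: float = 0.0,
    free_trigger_extra: float = 0.0,
) -> CircuitState:
    """Initial state of one circuit from experimental-style doses.

    ``trigger_total`` is the total trigger per site (µM); ``c_tilde`` the
    normalized inhibitor-RNA dose (total RNA / total trigger).  Triggers and
    RNAs are pre-annealed: the hybrid takes ``min(RNA, trigger)``, the rest
    stays free.  ``free_trigger_extra`` adds uninhibited trigger on top
    (e.g. the plain triggers of a circuit without a time-delay stage).
    """
    if linker_total < 0 or trigger_total < 0 or c_tilde < 0:
        raise ValueError("doses must be non-negative")
    rna_total = c_tilde * trigger_total
    hybrid = min(rna_total, trigger_total)
    t_free = trigger_total - hybrid + free_trigger_extra
    r_free = rna_total - hybrid
    two = np.full(N_SITES, 1.0)
    return CircuitState(
        T=t_free * two,
        iT=hybrid * two,
        R=r_free * two,
        S=linker_total * two,
        C=0.0 * two,
        P=0.0 * two,
    )


# --------------------------------------------------------------------------
# rate laws


def mm_release_rate(
    u_iT: float | np.ndarray,
    params: KineticParams,
    c_E: float,
    total_substrate: float | None = None,
) -> float | np.ndarray:
    """Michaelis–Menten release of trigger from the DNA:RNA hybrid (µM/s).

    In shared-enzyme mode pass ``total_substrate`` = sum of all competing
    hybrids; the denominator then reads ``K_m + total_substrate``, which
    reduces enzyme throughput per substrate when many RNAs compete.
    """
    u = np.asarray(u_iT, dtype=float)
    if np.any(u < 0) or c_E < 0:
        raise ValueError("negative concentration")
    denom_sub = u if total_substrate is None else float(total_substrate)
    if total_substrate is not None and total_substrate < 0:
        raise ValueError("negative total substrate")
    return params.k_cat * c_E * u / (params.K_m + denom_sub)


def inhibition_rate(
    u_T: float | np.ndarray, u_R: float | np.ndarray, k_h_rna: float
) -> float | np.ndarray:
    """Mass-action sequestration of free trigger by inhibitor RNA (µM/s)."""
    t = np.asarray(u_T, dtype=float)
    r = np.asarray(u_R, dtype=float)
    if np.any(t < 0) or np.any(r < 0):
        raise ValueError("negative concentration")
    return k_h_rna * t * r


def _mm_denominator_substrate(state: SpeciesSet, params: KineticParams) -> float | None:
    if params.competition_mode == "shared":
        return state.total_hybrid()
    return None


def g_TD(state: SpeciesSet, params: KineticParams) -> Dict[str, np.ndarray]:
    """Net time-delay-circuit rate per trigger site: enzymatic release minus
    RNA sequestration.  Returns ``{circuit: (2,) array}`` in µM/s."""
    total = _mm_denominator_substrate(state, params)
    out: Dict[str, np.ndarray] = {}
    for name, st in state.circuits.items():
        rel = mm_release_rate(st.iT, params, state.enzyme, total)
        inh = inhibition_rate(st.T, st.R, params.k_h_rna)
        out[name] = np.asarray(rel - inh)
    return out


def f_H_SD(
    state: SpeciesSet, params: KineticParams
) -> Dict[str, Dict[str, np.ndarray]]:
    """Linker-cleavage fluxes per circuit: trigger consumption plus the
    site-state transition rates.

    Returns ``{circuit: {"bind": (2,), "displace": (2,), "consume": (2,)}}``
    where *bind* is toehold binding (T + S -> C), *displace* the displacement
    step (C -> P), and *consume* the total free-trigger consumption.
    In single-step mode binding displaces directly (T + S -> P).
    """
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for name, st in state.circuits.items():
        cp = params.for_circuit(name)
        bind = cp.k_on * st.T * st.S
        if params.displacement_mode == "two-step":
            displace = cp.k_d * st.C
        else:
            displace = bind
        out[name] = {"bind": bind, "displace": displace, "consume": bind}
    return out


def rhs_well_mixed(state: SpeciesSet, params: KineticParams) -> SpeciesSet:
    """Time derivative of the full state (same structure, values in µM/s)."""
    td = g_TD(state, params)
    sd = f_H_SD(state, params)
    total = _mm_denominator_substrate(state, params)
    d_circuits: Dict[str, CircuitState] = {}
    for name, st in state.circuits.items():
        rel = np.asarray(mm_release_rate(st.iT, params, state.enzyme, total))
        inh = np.asarray(inhibition_rate(st.T, st.R, params.k_h_rna))
        bind = sd[name]["bind"]
        if params.displacement_mode == "two-step":
            disp = sd[name]["displace"]
            dC = bind - disp
        else:
            disp = bind
            dC = np.zeros(N_SITES)
        d_circuits[name] = CircuitState(
            T=td[name] - bind,
            iT=inh - rel,
            R=-inh,
            S=-bind,
            C=dC,
            P=disp,
        )
    deriv = SpeciesSet.__new__(SpeciesSet)  # skip non-negativity validation
    deriv.circuits = d_circuits
    deriv.enzyme = 0.0
    return deriv


# --------------------------------------------------------------------------
# packing and integration


def _pack(state: SpeciesSet, order: Tuple[str, ...]) -> np.ndarray:
    return np.concatenate(
        [getattr(state.circuits[c], sp) for c in order for sp in SPECIES]
    )


def _unpack(y: np.ndarray, order: Tuple[str, ...], enzyme: float) -> SpeciesSet:
    circuits: Dict[str, CircuitState] = {}
    k = 0
    for c in order:
        vals = {}
        for sp in SPECIES:
            vals[sp] = y[k : k + N_SITES]
            k += N_SITES
        st = CircuitState.__new__(CircuitState)
        for sp in SPECIES:
            setattr(st, sp, np.asarray(vals[sp], dtype=float))
        circuits[c] = st
    out = SpeciesSet.__new__(SpeciesSet)
    out.circuits = circuits
    out.enzyme = enzyme
    return out


@dataclass
class Trajectory:
    """Well-mixed trajectory: concentrations of every species at each time."""

    times: np.ndarray
    #: {circuit: {species: array (n_times, 2)}}
    data: Dict[str, Dict[str, np.ndarray]]
    enzyme: float
    params: KineticParams

    @property
    def circuit_names(self) -> Tuple[str, ...]:
        return tuple(self.data)

    def species(self, circuit: str, name: str) -> np.ndarray:
        return self.data[circuit][name]

    def state_at(self, index: int) -> SpeciesSet:
        circuits = {
            c: CircuitState(*(self.data[c][sp][index] for sp in SPECIES))
            for c in self.data
        }
        return SpeciesSet(circuits, self.enzyme)

    def uncleaved_fraction(self, circuit: str) -> np.ndarray:
        """w(t): fraction of this circuit's linkers not yet fully cleaved,
        normalized so w(0) = 1 when all linkers start intact."""
        d = self.data[circuit]
        ltot = d["S"][0] + d["C"][0] + d["P"][0]
        ltot = ltot[0]
        if ltot <= 0:
            raise ValueError(f"circuit {circuit!r} has no linker")
        w = 1.0 - (d["P"][:, 0] / ltot) * (d["P"][:, 1] / ltot)
        return np.clip(w, 0.0, 1.0)  # guard integrator round-off overshoot

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (time, circuit, species, site)."""
        rows = []
        for c, spd in self.data.items():
            for sp, arr in spd.items():
                for site in range(N_SITES):
                    rows.append(
                        pd.DataFrame(
                            {
                                "time": self.times,
                                "circuit": c,
                                "species": f"{sp}{site + 1}",
                                "concentration": arr[:, site],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def simulate_well_mixed(
    init: SpeciesSet,
    params: KineticParams,
    t_grid: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the well-mixed circuit ODEs and sample at ``t_grid``.

    ``t_grid`` must be strictly increasing; the first entry is the initial
    time.  Raises :class:`SimulationError` if the integrator fails.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    order = tuple(init.circuits)
    y0 = _pack(init, order)
    enzyme = init.enzyme

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        st = _unpack(np.maximum(y, 0.0), order, enzyme)
        return _pack(rhs_well_mixed(st, params), order)

    sol = solve_ivp(
        fun,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integrator failed: {sol.message} (method={method}, rtol={rtol})"
        )
    if not np.isfinite(sol.y).all():
        raise SimulationError(
            f"integrator produced non-finite concentrations "
            f"(method={method}, rtol={rtol}); check parameter magnitudes"
        )
    ys = np.maximum(sol.y, 0.0)  # clamp integrator round-off undershoot
    data: Dict[str, Dict[str, np.ndarray]] = {}
    k = 0
    for c in order:
        data[c] = {}
        for sp in SPECIES:
            data[c][sp] = ys[k : k + N_SITES].T.copy()
            k += N_SITES
    return Trajectory(times=t_grid, data=data, enzyme=enzyme, params=params)
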