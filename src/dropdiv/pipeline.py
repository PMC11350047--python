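"""End-to-end drivers: timing-control runs, pathway-control runs, and the
miRNA-concentration comparator.

The comparator couples two time-delay circuits in one ternary droplet: the
AB circuit delays cleavage of the linker holding the B component, the AC
circuit that of the C component.  Both circuits draw on a single RNase H
pool (shared-enzyme Michaelis–Menten competition), so raising the *total*
RNA dose slows everything, while the *difference* of the two normalized
doses decides which component divides first.  Sweeping that difference and
locating the sign change of ``delta_tau`` measures the comparator's offset
concentration ``sigma``; asymmetric cleavage kinetics or division
thresholds shift ``sigma`` away from the ideal 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import division as dv
from .division import (
    DivisionTrace,
    HillParams,
    OffsetOutsideRange,
    PathwayResult,
    division_time,
    estimate_offset,
)
from .kinetics import (
    CircuitParams,
    KineticParams,
    SpeciesSet,
    Trajectory,
    init_circuit,
    simulate_well_mixed,
)
from .spatial import DiffusionMap, GridSpec, RDConfig, RDResult, simulate_rd

__all__ = [
    "ConditionSpec",
    "ConditionOutcome",
    "ComparatorResult",
    "COMPARATOR_DOSES",
    "comparator_conditions",
    "run_condition",
    "run_sweep",
    "total_dose_effect",
    "timing_run",
    "spatial_timing_run",
]

#: The five comparator dose pairs (c_tilde_ab, c_tilde_ac); their differences
#: span 1.25, 0.5, -0.5, -1.0, -1.25.
COMPARATOR_DOSES: Tuple[Tuple[float, float], ...] = (
    (1.25, 0.0),
    (1.25, 0.75),
    (0.75, 1.25),
    (0.25, 1.25),
    (0.0, 1.25),
)


@dataclass(frozen=True)
class ConditionSpec:
    """One comparator condition: doses, kinetics asymmetry and thresholds.

    ``ab_rate_factor`` scales the AB circuit's hybridization *and*
    strand-displacement rates relative to the AC circuit (0.1 = tenfold
    slower AB cleavage).  ``k_ab``/``k_ac`` are the per-component Hill
    thresholds on the normalized uncleaved-linker scale.
    """

    c_tilde_ab: float
    c_tilde_ac: float
    c_e_rh: float = 0.25  # U/µL
    ab_rate_factor: float = 0.1
    k_ab: float = 0.1
    k_ac: float = 0.9
    n: float = 16.0
    base_k_on: float = 0.05  # 1/(µM·s), AC-circuit toehold binding
    base_k_d: float = 0.5  # 1/s, AC-circuit strand displacement
    k_cat: float = 2e-3
    K_m: float = 0.5
    k_h_rna: float = 0.5
    trigger_total: float = 1.0  # µM per site
    linker_total: float = 0.2  # µM per linker type
    competition_mode: str = "shared"
    displacement_mode: str = "two-step"
    engine: str = "well-mixed"  # or "reaction-diffusion"
    t_end: float = 80000.0
    n_points: int = 2000
    seed: Optional[int] = None
    # reaction-diffusion engine settings
    grid: GridSpec = field(default_factory=GridSpec)
    dmap: DiffusionMap = field(default_factory=DiffusionMap)
    rd_dt: float = 1.0

    def __post_init__(self) -> None:
        if self.c_tilde_ab < 0 or self.c_tilde_ac < 0:
            raise ValueError("doses must be non-negative")
        if self.ab_rate_factor <= 0:
            raise ValueError("asymmetry factor must be positive")
        if self.engine not in ("well-mixed", "reaction-diffusion"):
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def delta_c_tilde(self) -> float:
        return self.c_tilde_ab - self.c_tilde_ac

    def kinetic_params(self) -> KineticParams:
        ac = CircuitParams(k_on=self.base_k_on, k_d=self.base_k_d)
        ab = CircuitParams(
            k_on=self.base_k_on * self.ab_rate_factor,
            k_d=self.base_k_d * self.ab_rate_factor,
        )
        return KineticParams(
            circuits={"AB": ab, "AC": ac},
            k_cat=self.k_cat,
            K_m=self.K_m,
            k_h_rna=self.k_h_rna,
            competition_mode=self.competition_mode,
            displacement_mode=self.displacement_mode,
        )

    def initial_state(self) -> SpeciesSet:
        return SpeciesSet(
            circuits={
                "AB": init_circuit(
                    self.linker_total, self.trigger_total, self.c_tilde_ab
                ),
                "AC": init_circuit(
                    self.linker_total, self.trigger_total, self.c_tilde_ac
                ),
            },
            enzyme=self.c_e_rh,
        )


def comparator_conditions(
    symmetric: bool = False, **overrides
) -> List[ConditionSpec]:
    """The five-condition comparator preset.

    ``symmetric=False``: tenfold-slower AB cleavage with thresholds
    K_AB = 0.1, K_AC = 0.9 (the non-ideal comparator); ``symmetric=True``:
    identical rates and K_AB = K_AC = 0.1 (the ideal comparator).
    Keyword overrides are forwarded to every :class:`ConditionSpec`.
    """
    kw = dict(overrides)
    if symmetric:
        kw.setdefault("ab_rate_factor", 1.0)
        kw.setdefault("k_ab", 0.1)
        kw.setdefault("k_ac", 0.1)
    return [
        ConditionSpec(c_tilde_ab=ab, c_tilde_ac=ac, **kw)
        for ab, ac in COMPARATOR_DOSES
    ]


@dataclass
class ConditionOutcome:
    """Result of one comparator condition."""

    spec: ConditionSpec
    trace_b: DivisionTrace
    trace_c: DivisionTrace
    tau_b: Optional[float]
    tau_c: Optional[float]

    @property
    def divided(self) -> bool:
        return self.tau_b is not None and self.tau_c is not None

    @property
    def result(self) -> Optional[PathwayResult]:
        if not self.divided:
            return None
        return PathwayResult(tau_div_b=self.tau_b, tau_div_c=self.tau_c)

    @property
    def pathway(self) -> str:
        res = self.result
        if res is None:
            undiv = [n for n, t in (("B", self.tau_b), ("C", self.tau_c)) if t is None]
            return f"undivided ({', '.join(undiv)})"
        return res.pathway


def _w_traces_well_mixed(spec: ConditionSpec) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    t_grid = np.linspace(0.0, spec.t_end, spec.n_points)
    traj = simulate_well_mixed(spec.initial_state(), spec.kinetic_params(), t_grid)
    return {c: (t_grid, traj.uncleaved_fraction(c)) for c in ("AB", "AC")}


def _w_traces_rd(spec: ConditionSpec) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    cfg = RDConfig(
        grid=spec.grid,
        dmap=spec.dmap,
        params=spec.kinetic_params(),
        linker_doses={"AB": spec.linker_total, "AC": spec.linker_total},
        trigger_doses={
            "AB": (spec.trigger_total, spec.c_tilde_ab, 0.0),
            "AC": (spec.trigger_total, spec.c_tilde_ac, 0.0),
        },
        enzyme=spec.c_e_rh,
        t_end=spec.t_end,
        dt=spec.rd_dt,
        trace_interval=max(spec.rd_dt, spec.t_end / spec.n_points),
        # both Hill thresholds sit at w >= 0.1; far below that the division
        # times are already fixed, so stop early
        stop_w_floor=0.02 * min(spec.k_ab, spec.k_ac) / 0.1,
    )
    res = simulate_rd(cfg)
    return {c: res.w_trace(c) for c in ("AB", "AC")}


def run_condition(spec: ConditionSpec) -> ConditionOutcome:
    """Simulate both circuits under one condition and extract the division
    times of the B and C components."""
    if spec.engine == "well-mixed":
        wtr = _w_traces_well_mixed(spec)
    else:
        wtr = _w_traces_rd(spec)
    t_ab, w_ab = wtr["AB"]
    t_ac, w_ac = wtr["AC"]
    trace_b = DivisionTrace.from_w(
        t_ab, w_ab, HillParams(K=spec.k_ab, n=spec.n), component="B"
    )
    trace_c = DivisionTrace.from_w(
        t_ac, w_ac, HillParams(K=spec.k_ac, n=spec.n), component="C"
    )
    return ConditionOutcome(
        spec=spec,
        trace_b=trace_b,
        trace_c=trace_c,
        tau_b=division_time(trace_b),
        tau_c=division_time(trace_c),
    )


@dataclass
class ComparatorResult:
    """Sweep outcome: per-condition table, traces, and offset estimate."""

    outcomes: List[ConditionOutcome]
    table: pd.DataFrame
    sigma: Optional[float]
    sigma_note: str = ""

    def __iter__(self):
        return iter(self.outcomes)


def run_sweep(conditions: Sequence[ConditionSpec]) -> ComparatorResult:
    """Run every condition and estimate the comparator offset ``sigma``
    from the sign change of ``delta_tau`` over ``delta_c_tilde``."""
    if len(conditions) < 2:
        raise ValueError("a sweep needs at least two conditions")
    outcomes = [run_condition(spec) for spec in conditions]
    rows = []
    for oc in outcomes:
        res = oc.result
        rows.append(
            {
                "c_tilde_ab": oc.spec.c_tilde_ab,
                "c_tilde_ac": oc.spec.c_tilde_ac,
                "delta_c_tilde": oc.spec.delta_c_tilde,
                "tau_b": oc.tau_b,
                "tau_c": oc.tau_c,
                "delta_tau": res.delta_tau if res else np.nan,
                "pathway": oc.pathway,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "delta_c_tilde", ascending=False, ignore_index=True
    )
    sigma: Optional[float] = None
    note = ""
    usable = table.dropna(subset=["delta_tau"])
    if len(usable) < 2:
        note = "fewer than two conditions divided; offset undefined"
    else:
        try:
            sigma = estimate_offset(
                list(zip(usable["delta_c_tilde"], usable["delta_tau"]))
            )
        except (OffsetOutsideRange, dv.AmbiguousOffset) as exc:
            note = str(exc)
    return ComparatorResult(outcomes=outcomes, table=table, sigma=sigma, sigma_note=note)


def total_dose_effect(
    base: ConditionSpec, scale_factors: Sequence[float]
) -> pd.DataFrame:
    """Effect of the total RNA dose on both division times at fixed dose
    difference.

    Scales both doses additively (``+s/2`` each, keeping ``delta_c_tilde``
    fixed) for each factor and reports the division times.  Requires
    shared-enzyme competition — with independent enzyme pools the total
    dose cannot couple the circuits and the check would be vacuous.
    """
    if base.competition_mode != "shared":
        raise ValueError(
            "total-dose effect requires shared-enzyme competition mode"
        )
    rows = []
    for s in scale_factors:
        spec = replace(
            base,
            c_tilde_ab=base.c_tilde_ab + s / 2.0,
            c_tilde_ac=base.c_tilde_ac + s / 2.0,
        )
        oc = run_condition(spec)
        rows.append(
            {
                "c_tilde_total": spec.c_tilde_ab + spec.c_tilde_ac,
                "delta_c_tilde": spec.delta_c_tilde,
                "tau_b": oc.tau_b,
                "tau_c": oc.tau_c,
            }
        )
    return pd.DataFrame(rows).sort_values("c_tilde_total", ignore_index=True)


# --------------------------------------------------------------------------
# timing-control runs (binary mixed droplet)


def timing_run(
    c_e_rh: float = 2.5e-2,
    c_tilde: float = 1.5,
    plain_fraction: float = 0.9,
    linker_total: float = 0.825,
    trigger_total: float = 1.0,
    plain_trigger: float = 2.5,
    hill: HillParams = HillParams(K=0.05, n=16.0),
    t_end: float = 150000.0,
    n_points: int = 3000,
    base_params: Optional[KineticParams] = None,
) -> Tuple[Trajectory, DivisionTrace]:
    """Timing-controlled division of a binary mixed droplet.

    The droplet carries two linker populations: a plain linker (fraction
    ``plain_fraction`` of the total, default 90%) cleaved immediately by
    free triggers, and a delayed linker (the remaining 10%) whose triggers
    are gated by the time-delay circuit at enzyme dose ``c_e_rh`` and
    normalized inhibitor-RNA dose ``c_tilde``.  The division ratio follows
    the Hill map of the *combined* uncleaved fraction
    ``w = plain_fraction * w_plain + (1 - plain_fraction) * w_delayed``.
    """
    if not 0 < plain_fraction < 1:
        raise ValueError("plain_fraction must lie in (0, 1)")
    cp = CircuitParams()
    params = base_params or KineticParams(
        circuits={"plain": cp, "delayed": cp},
        competition_mode="independent",
    )
    init = SpeciesSet(
        circuits={
            "plain": init_circuit(
                linker_total * plain_fraction, 0.0, 0.0, free_trigger_extra=plain_trigger
            ),
            "delayed": init_circuit(
                linker_total * (1 - plain_fraction), trigger_total, c_tilde
            ),
        },
        enzyme=c_e_rh,
    )
    t_grid = np.linspace(0.0, t_end, n_points)
    traj = simulate_well_mixed(init, params, t_grid)
    w = plain_fraction * traj.uncleaved_fraction("plain") + (
        1 - plain_fraction
    ) * traj.uncleaved_fraction("delayed")
    trace = DivisionTrace.from_w(t_grid, w, hill, component="AB")
    return traj, trace


def spatial_timing_run(
    c_e_rh: float = 0.25,
    c_tilde: float = 1.5,
    plain_fraction: float = 0.9,
    linker_total: float = 0.825,
    trigger_total: float = 1.0,
    plain_trigger: float = 2.5,
    grid: Optional[GridSpec] = None,
    dmap: Optional[DiffusionMap] = None,
    t_end: float = 3500.0,
    dt: float = 2.0,
    snapshot_times: Sequence[float] = (
        0, 25, 50, 75, 100, 150, 200, 400, 1000, 1600, 2200, 2800, 3500,
    ),
    engine: str = "imex",
) -> RDResult:
    """Reaction-diffusion version of the binary-droplet timing run.

    Linkers (90% plain, 10% circuit-gated) start inside the droplet; free
    triggers and the pre-annealed trigger/RNA hybrids start in the bulk
    outside, as in the experimental protocol of adding the trigger mixture
    to the droplet suspension.  With the default diffusivities the plain
    linker degrades outside-in (reaction outruns trigger transport) while
    the delayed linker degrades uniformly (the trickle of enzymatically
    released trigger homogenizes by diffusion before it reacts).
    """
    cp = CircuitParams()
    params = KineticParams(
        circuits={"plain": cp, "delayed": cp}, competition_mode="independent"
    )
    cfg = RDConfig(
        grid=grid or GridSpec(),
        dmap=dmap or DiffusionMap(),
        params=params,
        linker_doses={
            "plain": linker_total * plain_fraction,
            "delayed": linker_total * (1 - plain_fraction),
        },
        trigger_doses={
            "plain": (0.0, 0.0, plain_trigger),
            "delayed": (trigger_total, c_tilde, 0.0),
        },
        enzyme=c_e_rh,
        t_end=t_end,
        dt=dt,
        snapshot_times=snapshot_times,
        trace_interval=25.0,
        engine=engine,
    )
    return simulate_rd(cfg)
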