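"""Hill-type division model: from uncleaved-linker time courses to division
ratios, division times, pathway labels, and the comparator offset.

Droplet fission is switch-like in the amount of intact linker holding the two
phases together: essentially all linkers must be cleaved before the mixed
droplet separates.  That cooperativity is captured by a decreasing Hill
function of the uncleaved-linker fraction ``w``::

    H(w) = K**n / (K**n + w**n)

with threshold ``K`` and cooperativity ``n``.  The division ratio rescales
``H`` so that it runs from 0 (nothing cleaved, ``w = w0``) to 1 (everything
cleaved, ``w = 0``)::

    r_div = (H(w) - H_min) / (H_max - H_min),  H_max = H(0) = 1, H_min = H(w0)

The division time ``tau_div`` of a component is the first time its ``r_div``
crosses 0.5; for a ternary droplet the signed difference
``delta_tau = tau_B - tau_C`` selects the division pathway (positive:
C-droplet first, Pathway 1; negative: B-droplet first, Pathway 2).  Sweeping
the comparator input ``delta_c = c_ab - c_ac`` and locating the sign change
of ``delta_tau`` yields the comparator's offset concentration ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "HillParams",
    "DivisionTrace",
    "PathwayResult",
    "UndividedError",
    "OffsetOutsideRange",
    "AmbiguousOffset",
    "PATHWAY_1",
    "PATHWAY_2",
    "TIE",
    "hill_H",
    "division_ratio",
    "division_time",
    "delta_tau",
    "estimate_offset",
]

PATHWAY_1 = "Pathway 1"  # delta_tau > 0: C-droplet divides first
PATHWAY_2 = "Pathway 2"  # delta_tau < 0: B-droplet divides first
TIE = "tie"


class UndividedError(ValueError):
    """A component never reached the division level within the trace."""


class OffsetOutsideRange(ValueError):
    """delta_tau never changes sign over the tested conditions."""


class AmbiguousOffset(ValueError):
    """delta_tau changes sign more than once over the tested conditions."""


@dataclass(frozen=True)
class HillParams:
    """Threshold ``K`` (on the normalized uncleaved-linker scale) and
    cooperativity ``n`` of the division switch."""

    K: float = 0.05
    n: float = 16.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")


def hill_H(w: float | np.ndarray, params: HillParams) -> float | np.ndarray:
    """Decreasing Hill switch ``K^n / (K^n + w^n)``; H(0)=1, H(K)=0.5.

    Evaluated as ``1 / (1 + (w/K)**n)`` so that large ``w/K`` at high ``n``
    underflows gracefully to 0 instead of overflowing.
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any(w_arr < 0):
        raise ValueError("w must be non-negative")
    with np.errstate(over="ignore"):
        ratio_pow = (w_arr / params.K) ** params.n
    out = 1.0 / (1.0 + ratio_pow)
    return out if isinstance(w, np.ndarray) else float(out)


def division_ratio(
    w_trace: np.ndarray, params: HillParams
) -> np.ndarray:
    """Map an uncleaved-linker trace ``w(t)`` onto the division ratio.

    ``w_trace[0]`` must be the initial (maximal) uncleaved total ``w0 > 0``;
    r_div(w0) = 0 and r_div(0) = 1 by construction.
    """
    w = np.asarray(w_trace, dtype=float)
    if w.size == 0:
        raise ValueError("empty trace")
    w0 = w[0]
    if w0 <= 0:
        raise ValueError("initial uncleaved linker w0 must be positive")
    if np.any(w > w0 * (1 + 1e-9)):
        raise ValueError("w trace must start at its maximum")
    h = np.asarray(hill_H(w, params))
    h_max = 1.0  # H(0)
    h_min = float(hill_H(float(w0), params))
    if h_min >= h_max:
        raise ValueError(
            "division switch is saturated at the initial state "
            f"(H(w0) = 1 for w0 = {w0:g}, K = {params.K:g}); "
            "no dynamic range to normalize"
        )
    return np.clip((h - h_min) / (h_max - h_min), 0.0, 1.0)


@dataclass
class DivisionTrace:
    """Division-ratio time series for one droplet component."""

    time: np.ndarray
    r_div: np.ndarray
    component: str = ""
    w: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.r_div = np.asarray(self.r_div, dtype=float)
        if self.time.shape != self.r_div.shape:
            raise ValueError("time and r_div must have the same shape")
        if np.any((self.r_div < -1e-9) | (self.r_div > 1 + 1e-9)):
            raise ValueError("r_div must lie in [0, 1]")

    @classmethod
    def from_w(
        cls,
        time: np.ndarray,
        w: np.ndarray,
        params: HillParams,
        component: str = "",
    ) -> "DivisionTrace":
        return cls(
            time=np.asarray(time, dtype=float),
            r_div=division_ratio(np.asarray(w, dtype=float), params),
            component=component,
            w=np.asarray(w, dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time, "component": self.component, "r_div": self.r_div}
        if self.w is not None:
            data["w"] = self.w
        return pd.DataFrame(data)


def division_time(
    trace: DivisionTrace, level: float = 0.5
) -> Optional[float]:
    """Time of the first upward crossing of ``level``, linearly interpolated.

    Returns ``None`` when the trace never attains the level (the component
    remains undivided); later re-crossings (e.g. from noise) are ignored.
    """
    r = trace.r_div
    t = trace.time
    if r[0] >= level:
        return float(t[0])
    above = np.nonzero(r >= level)[0]
    if above.size == 0:
        return None
    j = int(above[0])
    i = j - 1
    if r[j] == level or r[j] == r[i]:
        return float(t[j])
    frac = (level - r[i]) / (r[j] - r[i])
    return float(t[i] + frac * (t[j] - t[i]))


@dataclass
class PathwayResult:
    """Division times of the B- and C-components and the resulting pathway."""

    tau_div_b: float
    tau_div_c: float

    @property
    def delta_tau(self) -> float:
        return self.tau_div_b - self.tau_div_c

    @property
    def pathway(self) -> str:
        if self.delta_tau > 0:
            return PATHWAY_1
        if self.delta_tau < 0:
            return PATHWAY_2
        return TIE


def delta_tau(
    tau_b: Optional[float], tau_c: Optional[float]
) -> Tuple[float, str]:
    """Signed division-time difference and pathway label.

    Raises :class:`UndividedError` when either component never divided.
    """
    missing = [
        name for name, tau in (("B", tau_b), ("C", tau_c)) if tau is None
    ]
    if missing:
        raise UndividedError(
            f"component(s) {', '.join(missing)} never reached the division level"
        )
    res = PathwayResult(tau_div_b=float(tau_b), tau_div_c=float(tau_c))
    return res.delta_tau, res.pathway


def estimate_offset(
    conditions: Sequence[Tuple[float, float]]
) -> float:
    """Comparator offset ``sigma`` from (delta_c, delta_tau) pairs.

    The offset is the midpoint of the two adjacent ``delta_c`` values that
    bracket the single sign change of ``delta_tau``; an exactly zero
    ``delta_tau`` marks the crossing at that condition directly.

    Raises :class:`OffsetOutsideRange` if the sign never changes and
    :class:`AmbiguousOffset` (listing all brackets) if it changes more than
    once.
    """
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    pairs = sorted(((float(dc), float(dt)) for dc, dt in conditions))
    dcs = [p[0] for p in pairs]
    signs = [np.sign(p[1]) for p in pairs]
    exact = [dc for dc, s in zip(dcs, signs) if s == 0]
    if len(exact) == 1 and sum(1 for s in signs if s != 0) == len(signs) - 1:
        return exact[0]
    brackets: List[Tuple[float, float]] = []
    for (dc0, s0), (dc1, s1) in zip(zip(dcs, signs), zip(dcs[1:], signs[1:])):
        if s0 != 0 and s1 != 0 and s0 != s1:
            brackets.append((dc0, dc1))
    if not brackets:
        raise OffsetOutsideRange(
            "delta_tau has the same sign over all tested conditions; "
            "the offset lies outside the tested range"
        )
    if len(brackets) > 1:
        raise AmbiguousOffset(
            f"delta_tau changes sign more than once; brackets: {brackets}"
        )
    lo, hi = brackets[0]
    return 0.5 * (lo + hi)
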