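"""Isothermal titration calorimetry: thermogram integration and the
per-virion ejection-enthalpy series.

Titrating concentrated phage into a LamB receptor solution triggers DNA
ejection in vitro; the instrument records the differential power between the
reference and sample cells in ucal/s.  Integrating each injection pulse over
time gives the reaction heat, which still contains phage-dilution,
receptor-dilution and pressure-volume contributions.  Those are measured by
three control titrations (phage into buffer, buffer into LamB, buffer into
buffer) and removed by the standard bookkeeping

    H_ej = H_sample - H_phage_into_buffer - H_buffer_into_lamb + H_buffer_into_buffer

(each dilution control contains the buffer-into-buffer pressure-volume term,
so subtracting both removes it twice and it is added back once).

Sign convention: released heat (exothermic) is negative; figures and the
transition-enthalpy discussion use |dH_ej|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .presets import BOLTZMANN_J_PER_K

__all__ = [
    "CAL_PER_JOULE",
    "EnthalpySeries",
    "Thermogram",
    "enthalpy_series",
    "integrate_injections",
    "joules_to_kT",
    "kT_to_joules",
    "per_virion",
    "read_thermogram_csv",
    "subtract_controls",
    "write_enthalpy_csv",
]

#: J per ucal.
UCAL_TO_J = 4.184e-6
CAL_PER_JOULE = 1.0 / 4.184

ROLES = ("sample", "phage_into_buffer", "buffer_into_lamb", "buffer_into_buffer")

_QUIET_S = 5.0  # width of the pre-injection quiet window used for the baseline


@dataclass
class Thermogram:
    """One ITC trace: differential power vs time plus the injection schedule."""

    t: np.ndarray                 # [s], strictly increasing
    P: np.ndarray                 # [ucal/s]
    injections: Sequence[float]   # injection start times [s]
    role: str = "sample"
    T_C: float = 25.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.t.shape != self.P.shape or self.t.ndim != 1:
            raise ValueError("t and P must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        inj = np.asarray(self.injections, dtype=float)
        if inj.size < 1:
            raise ValueError("at least one injection is required")
        if np.any(inj < self.t[0]) or np.any(inj > self.t[-1]):
            raise ValueError("injection times must lie within the trace")
        self.injections = inj


@dataclass
class EnthalpySeries:
    """Temperature series of per-virion ejection enthalpies."""

    T: np.ndarray        # [C], strictly increasing
    dH: np.ndarray       # [J/virion], exothermic negative
    dH_se: np.ndarray    # standard error per temperature
    n_rep: np.ndarray    # replicates per temperature
    condition: str = ""

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.dH = np.asarray(self.dH, dtype=float)
        self.dH_se = np.asarray(self.dH_se, dtype=float)
        self.n_rep = np.asarray(self.n_rep, dtype=int)
        if not (len(self.T) == len(self.dH) == len(self.dH_se) == len(self.n_rep)):
            raise ValueError("all fields must have equal length")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.n_rep < 1):
            raise ValueError("each temperature needs at least one replicate")

    @property
    def values(self) -> np.ndarray:
        return self.dH

    @property
    def se(self) -> np.ndarray:
        return self.dH_se


def _median_quiet(trace: Thermogram, t_end: float) -> float | None:
    """Median power over the quiet window [t_end - 5 s, t_end)."""
    mask = (trace.t >= t_end - _QUIET_S) & (trace.t < t_end)
    if mask.sum() < 2:
        return None
    return float(np.median(trace.P[mask]))


def integrate_injections(trace: Thermogram) -> np.ndarray:
    """Per-injection heats [ucal] from trapezoidal baseline-subtracted integration.

    For each injection the baseline is the linear interpolation between the
    median power in the 5 s quiet window before the injection and the one
    before the next injection (or trace end).  If a quiet window is not
    available the routine warns and falls back to a global median baseline.
    """
    inj = np.sort(np.asarray(trace.injections, dtype=float))
    if inj.size >= 2 and np.min(np.diff(inj)) < _QUIET_S:
        raise ValueError("inter-injection gaps must be at least 5 s")
    # integration window ends: next injection, last one closed by same spacing
    if inj.size >= 2:
        last_gap = float(np.min(np.diff(inj)))
    else:
        last_gap = float(trace.t[-1] - inj[-1])
    ends = np.append(inj[1:], min(inj[-1] + last_gap, trace.t[-1]))

    heats = np.empty(inj.size)
    global_base = float(np.median(trace.P))
    for i, (t0, t1) in enumerate(zip(inj, ends)):
        m0 = _median_quiet(trace, t0)
        m1 = _median_quiet(trace, t1)
        # half-open window: the sample at the next injection time already
        # carries that injection's pulse onset
        if i < inj.size - 1:
            mask = (trace.t >= t0) & (trace.t < t1)
        else:
            mask = (trace.t >= t0) & (trace.t <= t1)
        tt, pp = trace.t[mask], trace.P[mask]
        if m0 is None or m1 is None:
            warnings.warn(
                "quiet window unavailable; falling back to global baseline",
                stacklevel=2,
            )
            base = np.full_like(tt, global_base)
        else:
            base = m0 + (m1 - m0) * (tt - t0) / (t1 - t0)
        heats[i] = np.trapezoid(pp - base, tt)
    return heats


def subtract_controls(
    sample: Iterable[float],
    phage_into_buffer: Iterable[float],
    buffer_into_lamb: Iterable[float],
    buffer_into_buffer: Iterable[float],
    temperatures_C: Mapping[str, float] | None = None,
) -> float:
    """Net per-injection ejection heat [ucal] after control subtraction.

    ``net = <H_sample> - <H_phage_into_buffer> - <H_buffer_into_lamb>
    + <H_buffer_into_buffer>`` (means over injections).  When per-role cell
    temperatures are given, a spread above 0.5 C is rejected — controls must
    be measured at the series temperature.
    """
    if temperatures_C is not None:
        temps = np.array([temperatures_C[r] for r in ROLES if r in temperatures_C])
        if temps.size and np.ptp(temps) > 0.5:
            raise ValueError(
                f"control temperatures spread {np.ptp(temps):.2f} C > 0.5 C"
            )
    mean = lambda h: float(np.mean(np.asarray(list(h), dtype=float)))
    return (
        mean(sample)
        - mean(phage_into_buffer)
        - mean(buffer_into_lamb)
        + mean(buffer_into_buffer)
    )


def per_virion(net_heat_ucal: float, phage_conc_per_ml: float,
               inj_volume_ml: float) -> float:
    """Convert a net injection heat [ucal] to J per virion.

    ``J/virion = net_ucal * 4.184e-6 / (phage_conc * inj_volume)`` with the
    plaque-forming-unit concentration treated as the virion concentration.
    """
    if phage_conc_per_ml <= 0 or inj_volume_ml <= 0:
        raise ValueError("concentration and injection volume must be positive")
    return net_heat_ucal * UCAL_TO_J / (phage_conc_per_ml * inj_volume_ml)


def joules_to_kT(H_J: float, T_C: float) -> float:
    """Express an energy [J] in units of kT at temperature ``T_C`` [C]."""
    if T_C <= -273.15:
        raise ValueError("temperature must be above absolute zero")
    return H_J / (BOLTZMANN_J_PER_K * (T_C + 273.15))


def kT_to_joules(H_kT: float, T_C: float) -> float:
    if T_C <= -273.15:
        raise ValueError("temperature must be above absolute zero")
    return H_kT * BOLTZMANN_J_PER_K * (T_C + 273.15)


def enthalpy_series(
    replicates: Mapping[float, Iterable[float]],
    condition: str = "",
) -> EnthalpySeries:
    """Build an :class:`EnthalpySeries` from per-temperature replicate values.

    Mean and standard error per temperature; a single replicate gets SE 0.
    """
    temps = sorted(replicates)
    dH, se, n = [], [], []
    for T in temps:
        vals = np.asarray(list(replicates[T]), dtype=float)
        if vals.size < 1:
            raise ValueError(f"no replicates at T={T}")
        dH.append(vals.mean())
        se.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
        n.append(vals.size)
    return EnthalpySeries(np.array(temps), np.array(dH), np.array(se),
                          np.array(n), condition=condition)


# -- CSV interfaces ---------------------------------------------------------

def read_thermogram_csv(trace_path, schedule_path, role="sample",
                        T_C=25.0) -> Thermogram:
    """Read a thermogram from a (t_s, P_ucal_per_s) CSV plus an injection
    schedule CSV with a ``t_inj_s`` column."""
    df = pd.read_csv(trace_path)
    sched = pd.read_csv(schedule_path)
    return Thermogram(
        df["t_s"].to_numpy(),
        df["P_ucal_per_s"].to_numpy(),
        sched["t_inj_s"].to_numpy(),
        role=role,
        T_C=T_C,
    )


def write_enthalpy_csv(series: EnthalpySeries, path) -> None:
    pd.DataFrame(
        {
            "T_C": series.T,
            "dH_J_per_virion": series.dH,
            "se": series.dH_se,
            "n": series.n_rep,
        }
    ).to_csv(path, index=False)
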