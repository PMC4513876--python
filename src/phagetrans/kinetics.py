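"""Ensemble kinetics of receptor-triggered DNA ejection.

Single-molecule fluorescence counts the cumulative number of virions that
have ejected their genome after LamB addition.  Treating initiation as a
one-step process, the cumulative count follows

    N(t) = a * (1 - exp(-k t)) + b

and the population half-time is t_1/2 = ln 2 / k.  The fit's observations
are the frame counts themselves (mirroring how the measurement is recorded);
a maximum-likelihood exponential fit on raw event times is provided only as
an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EjectionCounts",
    "KineticsFit",
    "KineticsFitError",
    "fit_event_times_mle",
    "fit_kinetics",
    "half_time",
    "half_time_ratio",
]

LN2 = math.log(2.0)


class KineticsFitError(RuntimeError):
    """The single-exponential fit failed (no dynamics, non-convergence,
    or rate pinned at a bound)."""


@dataclass
class EjectionCounts:
    """Cumulative ejection counts at frame times.

    The clock is re-zeroed at the first observed ejection (t[0] = 0), which
    absorbs the receptor delivery delay of the flow chamber.
    """

    t: np.ndarray          # frame times [s], t[0] == 0
    N: np.ndarray          # cumulative ejected count, non-decreasing
    n_total: int           # virions in the field of view
    T_C: float = 25.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.t.shape != self.N.shape or self.t.ndim != 1:
            raise ValueError("t and N must be 1-D arrays of equal length")
        if abs(self.t[0]) > 1e-12:
            raise ValueError("frame clock must be re-zeroed at first ejection")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(np.diff(self.N) < 0):
            raise ValueError("cumulative counts must be non-decreasing")
        if np.any(self.N > self.n_total):
            raise ValueError("counts cannot exceed the number of virions")


@dataclass
class KineticsFit:
    """Single-exponential fit of an ensemble ejection curve."""

    a: float               # amplitude [counts]
    k_rate: float          # rate constant [1/s]
    b: float               # offset [counts]
    cov: np.ndarray        # 3x3, order (a, k_rate, b)
    chi2_red: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.k_rate <= 0:
            raise ValueError("rate constant must be positive")

    @property
    def t_half(self) -> float:
        """Population half-time, ln 2 / k."""
        return LN2 / self.k_rate

    @property
    def k_se(self) -> float:
        v = self.cov[1, 1]
        return float(np.sqrt(v)) if np.isfinite(v) and v >= 0 else float("nan")


def _model(t, a, k, b):
    return a * (1.0 - np.exp(-k * t)) + b


def fit_kinetics(counts: EjectionCounts) -> KineticsFit:
    """Least-squares fit of ``N(t) = a (1 - exp(-k t)) + b``.

    Initialization: ``a`` at the final count, ``b`` at 0, ``k`` at the
    reciprocal of the time where the curve reaches half its final count.
    A series with no dynamics, a non-convergent fit, or a rate pinned at
    its bound raises :class:`KineticsFitError`.
    """
    t, N = counts.t, counts.N
    if len(t) < 10:
        raise ValueError("need at least 10 frames")
    if N[-1] < 20:
        raise ValueError("need a final count of at least 20 ejections")
    if np.ptp(N) == 0:
        raise KineticsFitError("constant counts: no ejection dynamics to fit")

    half_level = N[-1] / 2.0
    above = np.flatnonzero(N >= half_level)
    t_half0 = t[above[0]] if above.size and t[above[0]] > 0 else t[-1] / 10.0
    p0 = (float(N[-1]), 1.0 / t_half0, 0.0)
    k_floor = 1e-12
    try:
        popt, pcov = curve_fit(
            _model,
            t,
            N,
            p0=p0,
            bounds=([1e-9, k_floor, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            maxfev=20000,
            method="trf",
        )
    except RuntimeError as exc:
        raise KineticsFitError(f"kinetics fit did not converge: {exc}") from exc
    a, k, b = (float(v) for v in popt)
    if k <= 10 * k_floor:
        raise KineticsFitError("rate constant pinned at its lower bound")
    resid = N - _model(t, *popt)
    chi2_red = float(resid @ resid / max(len(t) - 3, 1))
    return KineticsFit(a=a, k_rate=k, b=b, cov=pcov, chi2_red=chi2_red,
                       n_frames=len(t))


def half_time(k_rate: float) -> float:
    """Half-time ``ln 2 / k`` [s] of a one-step process with rate ``k``."""
    if k_rate <= 0:
        raise ValueError("rate constant must be positive")
    return LN2 / k_rate


def half_time_ratio(slow: KineticsFit, fast: KineticsFit) -> float:
    """Ratio of half-times, slow over fast."""
    return slow.t_half / fast.t_half


def fit_event_times_mle(event_times_s: np.ndarray) -> float:
    """Maximum-likelihood rate constant from raw ejection waiting times.

    For exponential waiting times the MLE is ``k = 1 / mean(t)``.  Used as an
    independent cross-check of the frame-count fit, never as its replacement.
    """
    times = np.asarray(event_times_s, dtype=float)
    if times.size == 0 or np.any(times < 0):
        raise ValueError("need non-negative event times")
    mean = times.mean()
    if mean <= 0:
        raise ValueError("mean waiting time must be positive")
    return 1.0 / mean
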