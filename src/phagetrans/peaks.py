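"""Gaussian-plus-line modelling of the DNA diffraction peak.

The diffraction of hexagonally packed DNA inside the capsid produces a broad
peak near q ~ 0.25 1/A.  On the truncated window the peak is modelled as

    I(q) = (A0 / (w * sqrt(pi/2))) * exp(-2 ((q - q0) / w)^2) + k*q + c

where ``q0`` is the peak center, ``w`` the width, ``A0`` the peak area and
``k``, ``c`` the linear local background.  The area A0 is the order statistic
of the packaged genome (it carries the temperature/displacement factor), and
the center gives the interaxial spacing d = 4*pi / (sqrt(3) * q0) of the
hexagonal lattice.

The background slope is stored as ``k_bg`` throughout: the symbol ``k`` is
reserved for the ejection rate constant in :mod:`phagetrans.kinetics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

from .saxs import ScatteringProfile

__all__ = [
    "AreaSeries",
    "PeakFit",
    "PeakFitError",
    "fit_dna_peak",
    "interaxial_spacing",
    "peak_area_series",
    "peak_model",
]

#: Parameter order used for p0 / covariance rows: (q0, w, A0, k_bg, c_bg).
PARAM_NAMES = ("q0", "w", "A0", "k_bg", "c_bg")

_SQRT_PI_HALF = math.sqrt(math.pi / 2.0)
_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


class PeakFitError(RuntimeError):
    """Peak fit failed to converge; carries the initialization used."""

    def __init__(self, message: str, init: tuple | None = None):
        super().__init__(message)
        self.init = init


def peak_model(q, q0, w, A0, k_bg, c_bg):
    """Gaussian peak of area ``A0`` on a linear background."""
    return (A0 / (w * _SQRT_PI_HALF)) * np.exp(-2.0 * ((q - q0) / w) ** 2) \
        + k_bg * q + c_bg


@dataclass
class PeakFit:
    """Result of the Gaussian-plus-line fit on the DNA window."""

    q0: float
    w: float
    A0: float
    k_bg: float
    c_bg: float
    cov: np.ndarray            # 5x5, ordered as PARAM_NAMES
    chi2_red: float
    n_pts: int
    no_peak: bool = False      # A0 pinned at its zero bound

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("peak width must be positive")
        if self.A0 < 0:
            raise ValueError("peak area cannot be negative")

    def _se(self, i: int) -> float:
        v = self.cov[i, i]
        return float(np.sqrt(v)) if np.isfinite(v) and v >= 0 else float("nan")

    @property
    def q0_se(self) -> float:
        return self._se(0)

    @property
    def A0_se(self) -> float:
        return self._se(2)

    @property
    def fwhm(self) -> float:
        """Full width at half maximum, ``w * sqrt(2 ln 2)``."""
        return self.w * _SQRT_2LN2

    @property
    def height(self) -> float:
        """Peak maximum above the background, ``A0 / (w sqrt(pi/2))``."""
        return self.A0 / (self.w * _SQRT_PI_HALF)


@dataclass
class AreaSeries:
    """Temperature series of fitted peak areas for one condition.

    Failed fits appear as NaN gaps, never as zeros.
    """

    T: np.ndarray
    A: np.ndarray
    A_se: np.ndarray
    condition: str = ""
    fits: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.A_se = np.asarray(self.A_se, dtype=float)
        if not (len(self.T) == len(self.A) == len(self.A_se)):
            raise ValueError("T, A and A_se must have equal length")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    # uniform accessors shared with EnthalpySeries, used by the detector
    @property
    def values(self) -> np.ndarray:
        return self.A

    @property
    def se(self) -> np.ndarray:
        return self.A_se


def _initial_guess(q: np.ndarray, I: np.ndarray) -> tuple:
    # line through the window endpoints
    k0 = (I[-1] - I[0]) / (q[-1] - q[0])
    c0 = I[0] - k0 * q[0]
    resid = I - (k0 * q + c0)
    peak_idx = int(np.argmax(resid))
    q0 = float(q[peak_idx])
    height = float(resid[peak_idx])
    span = q[-1] - q[0]
    w0 = span / 5.0
    if height > 0:
        above = np.flatnonzero(resid >= height / 2.0)
        fwhm = float(q[above[-1]] - q[above[0]])
        if fwhm > 0:
            w0 = fwhm / _SQRT_2LN2
    A0 = max(float(np.trapezoid(resid, q)), 0.0)
    return (q0, w0, A0, k0, c0)


def fit_dna_peak(window: ScatteringProfile) -> PeakFit:
    """Fit the Gaussian-plus-line peak model on a truncated DNA window.

    Weighted least squares when per-point uncertainties are present (weights
    1/sigma^2), plain least squares otherwise.  Initialization: background
    from the line through the window endpoints, ``q0`` at the maximum of the
    line-subtracted signal, ``w`` from its FWHM, ``A0`` from its trapezoidal
    area.  ``A0`` landing on its zero bound is reported as an explicit
    "no peak" state rather than an error — a fully disordered genome has no
    diffraction peak.
    """
    q, I = window.q, window.I
    if len(q) < 8:
        raise ValueError("need at least 8 points to fit the 5-parameter model")
    p0 = _initial_guess(q, I)
    span = q[-1] - q[0]
    lower = [q[0], 1e-6 * span, 0.0, -np.inf, -np.inf]
    upper = [q[-1], np.inf, np.inf, np.inf, np.inf]
    p0 = (
        min(max(p0[0], lower[0]), upper[0]),
        max(p0[1], 2e-6 * span),
        p0[2],
        p0[3],
        p0[4],
    )
    sigma = window.sigma
    use_weights = sigma is not None and np.all(sigma > 0)
    try:
        popt, pcov = curve_fit(
            peak_model,
            q,
            I,
            p0=p0,
            sigma=sigma if use_weights else None,
            absolute_sigma=use_weights,
            bounds=(lower, upper),
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            maxfev=20000,
            method="trf",
        )
    except RuntimeError as exc:
        raise PeakFitError(f"peak fit did not converge: {exc}", init=p0) from exc

    resid = I - peak_model(q, *popt)
    if use_weights:
        resid = resid / sigma
    dof = max(len(q) - 5, 1)
    chi2_red = float(np.sum(resid**2) / dof)

    # "no peak": area negligible relative to the window's intensity scale
    scale = max(float(np.max(np.abs(I))), 1.0) * span
    no_peak = bool(popt[2] <= 1e-10 * scale)

    return PeakFit(
        q0=float(popt[0]),
        w=float(popt[1]),
        A0=float(popt[2]),
        k_bg=float(popt[3]),
        c_bg=float(popt[4]),
        cov=pcov,
        chi2_red=chi2_red,
        n_pts=len(q),
        no_peak=no_peak,
    )


def interaxial_spacing(q0: float, q0_se: float = 0.0) -> tuple[float, float]:
    """Hexagonal-lattice interaxial spacing from the peak center.

    ``d = 4 pi / (sqrt(3) q0)``; the uncertainty propagates as
    ``sigma_d = d * sigma_q0 / q0``.

    Returns
    -------
    (d, d_se) : tuple of float, in Angstrom.
    """
    if q0 <= 0:
        raise ValueError("peak center q0 must be positive")
    d = 4.0 * math.pi / (math.sqrt(3.0) * q0)
    return d, d * q0_se / q0


def peak_area_series(
    profiles: Mapping[float, ScatteringProfile],
    condition: str = "",
) -> AreaSeries:
    """Fit the DNA peak at every temperature and collect the area series.

    Parameters
    ----------
    profiles : mapping
        Temperature [C] -> truncated, background-subtracted window profile.

    Raises
    ------
    ValueError
        Fewer than 6 temperatures, or more than 30% failed fits.
    """
    if len(profiles) < 6:
        raise ValueError("need at least 6 temperatures for an area series")
    temps = np.array(sorted(profiles), dtype=float)
    A = np.full(temps.shape, np.nan)
    A_se = np.full(temps.shape, np.nan)
    fits: dict[float, PeakFit] = {}
    n_failed = 0
    for i, T in enumerate(temps):
        try:
            fit = fit_dna_peak(profiles[T])
        except PeakFitError:
            n_failed += 1
            continue
        fits[float(T)] = fit
        A[i] = fit.A0
        A_se[i] = fit.A0_se
    if n_failed > 0.3 * len(temps):
        raise ValueError(
            f"{n_failed}/{len(temps)} peak fits failed; series rejected"
        )
    return AreaSeries(temps, A, A_se, condition=condition, fits=fits)
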