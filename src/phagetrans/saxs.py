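"""Reduction of 1-D solution scattering profiles.

Scans are averaged pointwise, a buffer measurement is subtracted, and the
profile is truncated to the DNA diffraction window (default 0.18-0.33 1/A)
before the Gaussian-plus-line peak fit.  Grids must match exactly between
scans and between sample and buffer: resampling is a deliberate non-feature
so that reductions stay bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DNA_WINDOW",
    "ScatteringProfile",
    "average_scans",
    "read_dat",
    "subtract_background",
    "truncate_window",
    "write_dat",
]

#: Default DNA diffraction window [1/A].
DNA_WINDOW = (0.18, 0.33)

_GRID_TOL = 1e-9
_EDGE_TOL = 1e-12  # float-grid slack at closed window endpoints


@dataclass
class ScatteringProfile:
    """One reduced 1-D SAXS curve I(q).

    Parameters
    ----------
    q : array
        Scattering vector [1/A], strictly increasing.
    I : array
        Intensity [arbitrary units], same length as ``q``.
    sigma : array, optional
        Per-point 1-sigma uncertainty; must be positive where given.
    meta : dict
        Free-form provenance (sample label, temperature, scan count, ...).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.size < 2:
            raise ValueError("q must be a 1-D array with at least 2 points")
        if self.I.shape != self.q.shape:
            raise ValueError("q and I must have the same length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return self.q.size


def _require_common_grid(a: ScatteringProfile, b: ScatteringProfile) -> None:
    if len(a) != len(b) or np.any(np.abs(a.q - b.q) > _GRID_TOL):
        raise ValueError("q grids do not match; profiles are not resampled")


def average_scans(scans: list[ScatteringProfile]) -> ScatteringProfile:
    """Pointwise mean of repeated scans sharing one q grid.

    With two or more scans the returned ``sigma`` is the standard error of
    the mean over scans; a single scan passes its own ``sigma`` through.
    """
    if not scans:
        raise ValueError("no scans to average")
    first = scans[0]
    for scan in scans[1:]:
        _require_common_grid(first, scan)
    stack = np.vstack([s.I for s in scans])
    mean = stack.mean(axis=0)
    if len(scans) >= 2:
        sigma = stack.std(axis=0, ddof=1) / np.sqrt(len(scans))
    else:
        sigma = None if first.sigma is None else first.sigma.copy()
    meta = dict(first.meta)
    meta["n_scans"] = len(scans)
    return ScatteringProfile(first.q.copy(), mean, sigma, meta)


def subtract_background(
    sample: ScatteringProfile,
    buffer: ScatteringProfile,
    scale: float = 1.0,
) -> ScatteringProfile:
    """Subtract a buffer measurement: ``I_out = I_sample - scale * I_buffer``.

    Uncertainties combine in quadrature.  No automatic rescaling is applied;
    ``scale`` is exposed for sensitivity analysis only.
    """
    _require_common_grid(sample, buffer)
    I = sample.I - scale * buffer.I
    sigma = None
    if sample.sigma is not None or buffer.sigma is not None:
        s2 = np.zeros_like(sample.I)
        if sample.sigma is not None:
            s2 += sample.sigma**2
        if buffer.sigma is not None:
            s2 += (scale * buffer.sigma) ** 2
        sigma = np.sqrt(s2)
    meta = dict(sample.meta)
    meta["background_subtracted"] = True
    meta["background_scale"] = scale
    return ScatteringProfile(sample.q.copy(), I, sigma, meta)


def truncate_window(
    profile: ScatteringProfile,
    q_min: float = DNA_WINDOW[0],
    q_max: float = DNA_WINDOW[1],
) -> ScatteringProfile:
    """Restrict a profile to the closed interval [q_min, q_max].

    The DNA-window peak fit needs at least 8 points; fewer is rejected as an
    under-determined fit rather than silently returned.
    """
    mask = (profile.q >= q_min - _EDGE_TOL) & (profile.q <= q_max + _EDGE_TOL)
    n = int(mask.sum())
    if n < 8:
        raise ValueError(
            f"only {n} grid points in [{q_min}, {q_max}]; need at least 8"
        )
    sigma = None if profile.sigma is None else profile.sigma[mask]
    meta = dict(profile.meta)
    meta["q_window"] = (q_min, q_max)
    return ScatteringProfile(profile.q[mask], profile.I[mask], sigma, meta)


def write_dat(profile: ScatteringProfile, path: str | Path) -> None:
    """Write a 2/3-column ASCII ``.dat`` profile (q, I[, sigma])."""
    cols = [profile.q, profile.I]
    header = "q_A^-1 I"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), header=header)


def read_dat(path: str | Path) -> ScatteringProfile:
    """Read a 2/3-column ASCII ``.dat`` profile."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringProfile(data[:, 0], data[:, 1], sigma,
                             meta={"source": str(path)})
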