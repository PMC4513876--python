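"""Synthetic-experiment generators.

Every analysis stage in this package can be exercised without any downloaded
data: these generators produce SAXS scans, temperature series, ITC
thermograms and ejection-event streams with the statistical structure the
estimators assume, under named condition presets calibrated to the measured
values of the phage-lambda DNA-transition experiments
(:mod:`phagetrans.presets`).

All generators are seeded explicitly and are bit-reproducible: the same seed
and configuration give identical output.

What is emulated (and what is not) is documented in ``docs/methods.md``:
notably, the capsid envelope is a uniform-sphere form factor and the small
oscillating ripples on top of the measured DNA peak are treated as fit
residuals, not simulated.
"""

from __future__ import annotations

import warnings

import numpy as np

from .itc import UCAL_TO_J, EnthalpySeries, Thermogram, enthalpy_series
from .kinetics import EjectionCounts
from .peaks import AreaSeries, peak_model
from .presets import CapsidModel, ConditionPreset
from .saxs import ScatteringProfile

__all__ = [
    "hexagonal_q0",
    "make_ejection_events",
    "make_saxs_profile",
    "make_temperature_series",
    "make_thermogram",
    "sphere_form_factor",
]

_FULL_Q = (0.006, 0.850)


def sphere_form_factor(qR: np.ndarray) -> np.ndarray:
    """Normalized uniform-sphere form factor ``P(qR)``, with ``P(0) = 1``.

    ``P(x) = [3 (sin x - x cos x) / x^3]^2``.
    """
    x = np.asarray(qR, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-4
    xs = x[nz]
    out[nz] = (3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3) ** 2
    return out


def hexagonal_q0(spacing_A: float) -> float:
    """Diffraction-peak center [1/A] of a hexagonal lattice with interaxial
    spacing ``d``: ``q0 = 4 pi / (sqrt(3) d)`` (inverse of the spacing
    formula)."""
    if spacing_A <= 0:
        raise ValueError("spacing must be positive")
    return 4.0 * np.pi / (np.sqrt(3.0) * spacing_A)


def make_saxs_profile(
    preset: ConditionPreset,
    capsid: CapsidModel | None = None,
    T: float = 25.0,
    n_scans: int = 40,
    seed: int = 0,
    kind: str = "sample",
    q_min: float = _FULL_Q[0],
    q_max: float = _FULL_Q[1],
    dq: float = 0.002,
) -> list[ScatteringProfile]:
    """Generate raw SAXS scans for one condition at one temperature.

    A ``"sample"`` scan is capsid envelope + DNA diffraction peak + linear
    background; a ``"buffer"`` scan is the background alone, so that plain
    subtraction leaves capsid + peak.  Noise is multiplicative Gaussian with
    the preset's relative magnitude, independent per scan.

    Returns a list of ``n_scans`` profiles on a common grid.
    """
    if capsid is None:
        capsid = CapsidModel()
    if kind not in ("sample", "buffer"):
        raise ValueError("kind must be 'sample' or 'buffer'")
    if n_scans < 1:
        raise ValueError("n_scans must be at least 1")
    if q_min > _FULL_Q[0] + 1e-12 or q_max < _FULL_Q[1] - 1e-12:
        raise ValueError(
            f"q grid must cover at least {_FULL_Q[0]}-{_FULL_Q[1]} 1/A"
        )
    preset.check_temperature(T)

    n_q = int(round((q_max - q_min) / dq)) + 1
    q = np.linspace(q_min, q_max, n_q)
    background = capsid.bg_offset + capsid.bg_slope * q
    if kind == "buffer":
        clean = background
    else:
        q0 = hexagonal_q0(preset.spacing(T))
        area = preset.peak_area(T)
        clean = (
            capsid.scale * sphere_form_factor(q * capsid.radius_A)
            + peak_model(q, q0, preset.peak_width_A_inv, area, 0.0, 0.0)
            + background
        )

    rng = np.random.default_rng(seed)
    rel = preset.noise.saxs_rel
    scans = []
    for i in range(n_scans):
        noise = rng.normal(0.0, rel, size=q.shape) if rel > 0 else 0.0
        scans.append(
            ScatteringProfile(
                q.copy(),
                clean * (1.0 + noise),
                meta={
                    "preset": preset.name,
                    "T_C": T,
                    "kind": kind,
                    "seed": seed,
                    "scan": i,
                },
            )
        )
    return scans


def make_temperature_series(
    preset: ConditionPreset,
    modality: str,
    T_grid,
    n_rep: int = 6,
    seed: int = 0,
):
    """Generate a temperature series of peak areas or ejection enthalpies.

    Values follow the preset's piecewise-linear law with Gaussian replicate
    noise; per-temperature means and standard errors are attached.  Presets
    without a transition temperature produce a single straight line.

    Parameters
    ----------
    modality : {"saxs_area", "itc_enthalpy"}
    T_grid : array-like
        Strictly increasing temperatures [C], at least 6 points; for
        transition presets at least 2 points on each side of T*.

    Returns
    -------
    AreaSeries or EnthalpySeries
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size < 6 or np.any(np.diff(T_grid) <= 0):
        raise ValueError("T_grid must be strictly increasing with >= 6 points")
    for T in T_grid:
        preset.check_temperature(T)
    if preset.t_star_C is not None:
        n_pre = int(np.sum(T_grid < preset.t_star_C))
        n_post = T_grid.size - n_pre
        if n_pre < 2 or n_post < 2:
            raise ValueError(
                "need at least 2 grid points on each side of t_star_C"
            )
    if modality not in ("saxs_area", "itc_enthalpy"):
        raise ValueError("modality must be 'saxs_area' or 'itc_enthalpy'")
    if n_rep < 1:
        raise ValueError("n_rep must be at least 1")

    rng = np.random.default_rng(seed)
    if modality == "itc_enthalpy":
        law = preset.enthalpy
        sd = lambda _truth: preset.noise.dh_J
    else:
        law = preset.peak_area
        sd = lambda truth: preset.noise.area_rel * abs(truth)

    replicates = {}
    for T in T_grid:
        truth = law(T)
        sigma = sd(truth)
        vals = truth + (rng.normal(0.0, sigma, size=n_rep) if sigma > 0
                        else np.zeros(n_rep))
        replicates[float(T)] = vals

    if modality == "itc_enthalpy":
        return enthalpy_series(replicates, condition=preset.name)

    means = np.array([replicates[float(T)].mean() for T in T_grid])
    if n_rep > 1:
        ses = np.array(
            [replicates[float(T)].std(ddof=1) / np.sqrt(n_rep) for T in T_grid]
        )
    else:
        ses = np.array([sd(law(T)) for T in T_grid])
    return AreaSeries(T_grid.copy(), means, ses, condition=preset.name)


def make_thermogram(
    preset: ConditionPreset,
    T: float = 25.0,
    n_injections: int = 10,
    role: str = "sample",
    seed: int = 0,
    dt: float = 0.5,
    lead_s: float = 60.0,
    heats_ucal=None,
) -> Thermogram:
    """Generate an ITC trace: baseline + white noise + injection pulses.

    Each injection adds a single-exponential pulse
    ``h(t) = (H_i / tau) exp(-(t - t_i)/tau)`` for ``t >= t_i``, which
    integrates to ``H_i``.  For the ``"sample"`` role the per-injection heat
    is the preset's dH_ej(T) law scaled by the virions per injection plus the
    dilution/mixing control contributions; control roles carry only their own
    (smaller) heats.

    ``heats_ucal`` overrides the per-injection heats directly (scalar or
    sequence), which is how integration oracles with a known heat are built.
    """
    if n_injections < 1:
        raise ValueError("need at least one injection")
    preset.check_temperature(T)
    cfg = preset.itc
    ctrl = cfg.control_heats_ucal
    if heats_ucal is not None:
        heats = np.broadcast_to(
            np.asarray(heats_ucal, dtype=float), (n_injections,)
        ).copy()
    elif role == "sample":
        dH_ucal = preset.enthalpy(T) * cfg.virions_per_injection / UCAL_TO_J
        per_inj = (
            dH_ucal
            + ctrl["phage_into_buffer"]
            + ctrl["buffer_into_lamb"]
            - ctrl["buffer_into_buffer"]
        )
        heats = np.full(n_injections, per_inj)
    elif role in ctrl:
        heats = np.full(n_injections, ctrl[role])
    else:
        raise ValueError(f"unknown role {role!r}")

    spacing = cfg.injection_spacing_s
    tau = cfg.pulse_tau_s
    if spacing < 5.0 * tau:
        warnings.warn(
            "injection spacing shorter than 5 pulse decay constants; "
            "pulses overlap",
            stacklevel=2,
        )
    injections = lead_s + spacing * np.arange(n_injections)
    t_end = injections[-1] + spacing
    t = np.arange(0.0, t_end + dt / 2.0, dt)

    rng = np.random.default_rng(seed)
    noise_sd = preset.noise.baseline_ucal_per_s
    P = np.full_like(t, cfg.baseline_ucal_per_s)
    if noise_sd > 0:
        P = P + rng.normal(0.0, noise_sd, size=t.shape)
    for t_i, H in zip(injections, heats):
        after = t >= t_i - 1e-12
        P[after] += (H / tau) * np.exp(-(t[after] - t_i) / tau)

    return Thermogram(
        t,
        P,
        injections,
        role=role,
        T_C=T,
        meta={"preset": preset.name, "seed": seed, "true_heats_ucal": heats},
    )


def make_ejection_events(
    preset: ConditionPreset,
    T: float,
    n_phage: int = 1000,
    frame_dt: float = 5.0,
    duration: float = 2000.0,
    seed: int = 0,
    nonresponder_frac: float | None = None,
) -> EjectionCounts:
    """Simulate an ensemble DNA-ejection experiment at one temperature.

    Each responsive virion draws an exponential ejection time with the
    preset's rate constant at ``T``; a non-responder fraction never ejects.
    Cumulative counts are reported at frame times and the clock is re-zeroed
    at the first observed ejection, as in the fluorescence measurement.
    """
    if n_phage < 10:
        raise ValueError("need at least 10 virions")
    if duration < frame_dt:
        raise ValueError("duration must be at least one frame interval")
    k = preset.rate(T)
    if duration < 3.0 / k:
        raise ValueError(
            f"duration {duration} s too short to resolve rate {k:.3g}/s "
            f"(need >= {3.0 / k:.0f} s)"
        )
    frac = preset.nonresponder_frac if nonresponder_frac is None else nonresponder_frac
    if not 0.0 <= frac < 1.0:
        raise ValueError("nonresponder fraction must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    responder = rng.random(n_phage) >= frac
    times = np.sort(rng.exponential(1.0 / k, size=int(responder.sum())))

    frames = np.arange(0.0, duration + frame_dt / 2.0, frame_dt)
    counts = np.searchsorted(times, frames, side="right")
    first = np.flatnonzero(counts > 0)
    if first.size == 0:
        raise ValueError("no ejections observed within the duration")
    i0 = first[0]
    return EjectionCounts(
        t=frames[i0:] - frames[i0],
        N=counts[i0:].astype(float),
        n_total=n_phage,
        T_C=T,
        meta={
            "preset": preset.name,
            "seed": seed,
            "k_true": k,
            "event_times_s": times,
            "t_rezero_s": frames[i0],
        },
    )
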