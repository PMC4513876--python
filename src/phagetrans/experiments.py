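"""Named reproduction experiments.

Each experiment re-runs one headline quantity of the DNA-transition analysis
from scratch on synthetic data generated from the calibrated presets:
transition temperatures and the transition enthalpy from the changepoint
detector, ejection half-times from the kinetics fit, and interaxial spacings
from the full SAXS simulate/reduce/fit chain.  Experiments are seeded and
return ``{"value": float, "n": int}`` where ``n`` is the problem size
(number of seeded replicate runs, or scans per profile for the SAXS chain).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .itc import joules_to_kT
from .kinetics import KineticsFitError, fit_kinetics
from .peaks import fit_dna_peak, interaxial_spacing
from .presets import CapsidModel, get_preset
from .saxs import average_scans, subtract_background, truncate_window
from .synthetic import (
    make_ejection_events,
    make_saxs_profile,
    make_temperature_series,
)
from .transition import detect_transition, transition_enthalpy

__all__ = ["EXPERIMENTS", "run_experiment"]


def _seeds(seed: int, n: int, stream: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def _grid(lo: float, hi: float, step: float = 2.0) -> np.ndarray:
    return np.arange(lo, hi + step / 2.0, step)


def detected_break_temperatures(
    preset_name: str,
    T_grid,
    n_seeds: int,
    seed: int,
    modalities=("itc_enthalpy", "saxs_area"),
    n_rep: int = 6,
    alpha: float = 0.05,
) -> list[float]:
    """Detected break temperatures across seeded series (both modalities)."""
    preset = get_preset(preset_name)
    out: list[float] = []
    for m_idx, modality in enumerate(modalities):
        for s in _seeds(seed, n_seeds, stream=10 + m_idx):
            series = make_temperature_series(preset, modality, T_grid,
                                             n_rep=n_rep, seed=s)
            cp = detect_transition(series, alpha=alpha)
            if cp.detected:
                out.append(cp.t_star_C)
    return out


def _t_star_experiment(preset_name: str, lo: float, hi: float):
    def run(seed: int) -> dict:
        # 200 series total: 100 seeds per modality
        breaks = detected_break_temperatures(
            preset_name, _grid(lo, hi), n_seeds=100, seed=seed
        )
        return {"value": float(np.median(breaks)), "n": 200}

    return run


def transition_enthalpy_kT(seed: int) -> dict:
    """Mean transition enthalpy [kT/virion] over 50 seeded WT 10 mM ITC series."""
    preset = get_preset("WT_Mg10")
    vals = []
    for s in _seeds(seed, 50, stream=20):
        series = make_temperature_series(
            preset, "itc_enthalpy", _grid(18, 42), n_rep=6, seed=s
        )
        cp = detect_transition(series)
        if cp.detected:
            vals.append(transition_enthalpy(cp).kT_per_virion)
    return {"value": float(np.mean(vals)), "n": 50}


def _half_time_experiment(T: float, duration: float):
    def run(seed: int) -> dict:
        preset = get_preset("WT_Mg10")
        halves = []
        for s in _seeds(seed, 50, stream=30):
            counts = make_ejection_events(
                preset, T=T, n_phage=1000, frame_dt=5.0,
                duration=duration, seed=s,
            )
            try:
                halves.append(fit_kinetics(counts).t_half)
            except KineticsFitError:
                continue
        return {"value": float(np.median(halves)), "n": 50}

    return run


def spacing_chain(preset_name: str, temps, seed: int, n_scans: int = 40) -> float:
    """Mean interaxial spacing [A] over temperatures via the full SAXS chain:
    simulate scans -> average -> subtract buffer -> truncate -> peak fit ->
    hexagonal conversion."""
    preset = get_preset(preset_name)
    capsid = CapsidModel()
    seeds = _seeds(seed, 2 * len(temps), stream=40)
    ds = []
    for j, T in enumerate(temps):
        scans = make_saxs_profile(preset, capsid, T=T, n_scans=n_scans,
                                  seed=seeds[2 * j])
        buffers = make_saxs_profile(preset, capsid, T=T, n_scans=n_scans,
                                    seed=seeds[2 * j + 1], kind="buffer")
        reduced = subtract_background(average_scans(scans),
                                      average_scans(buffers))
        fit = fit_dna_peak(truncate_window(reduced))
        d, _ = interaxial_spacing(fit.q0, fit.q0_se)
        ds.append(d)
    return float(np.mean(ds))


def _spacing_experiment(preset_name: str, temps):
    def run(seed: int) -> dict:
        return {"value": spacing_chain(preset_name, temps, seed), "n": 40}

    return run


#: Registry of reproduction experiments, by descriptive name.
EXPERIMENTS: dict[str, Callable[[int], dict]] = {
    "transition_enthalpy_kT_per_virion": transition_enthalpy_kT,
    "t_star_wt_mg10_C": _t_star_experiment("WT_Mg10", 18, 42),
    "t_star_wt_mg20_C": _t_star_experiment("WT_Mg20", 18, 44),
    "t_star_wt_mg5_C": _t_star_experiment("WT_Mg5", 14, 40),
    "half_time_22C_s": _half_time_experiment(22.0, 2000.0),
    "half_time_37C_s": _half_time_experiment(37.0, 600.0),
    "spacing_l78_mg10_A": _spacing_experiment("L78_Mg10", (10.0, 25.0, 45.0)),
    "spacing_l78_edta_45C_A": _spacing_experiment("L78_Mg10_EDTA", (45.0,)),
}


def run_experiment(name: str, seed: int = 0) -> dict:
    """Run one registered reproduction experiment by name."""
    if name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {name!r}; available: "
            + ", ".join(sorted(EXPERIMENTS))
        )
    return EXPERIMENTS[name](seed)
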