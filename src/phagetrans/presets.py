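"""Named experimental condition presets.

A :class:`ConditionPreset` bundles everything the synthetic generators need to
emulate one experimental condition of the phage-lambda DNA-transition study:
the hexagonal DNA interaxial spacing law, the transition temperature ``T*``
(or ``None`` for conditions where the packaged genome never disorders in the
studied range), the piecewise-linear laws for the SAXS diffraction-peak area
and the per-virion ejection enthalpy ``dH_ej(T)``, ejection rate constants,
and declared noise magnitudes.  The calibration numbers live in one
declarative table, ``data/presets.yaml``, shipped with the package.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "BOLTZMANN_J_PER_K",
    "CapsidModel",
    "ConditionPreset",
    "ItcSettings",
    "NoiseModel",
    "available_presets",
    "get_preset",
    "load_preset_table",
]

#: Boltzmann constant [J/K] (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class NoiseModel:
    """Declared noise magnitudes for one condition preset."""

    saxs_rel: float = 0.01
    area_rel: float = 0.02
    dh_J: float = 4.0e-18
    baseline_ucal_per_s: float = 2.0e-5


@dataclass(frozen=True)
class ItcSettings:
    """Titration geometry and instrument settings used by the ITC generator."""

    phage_conc_per_ml: float = 5.0e13
    inj_volume_ml: float = 2.0e-6
    baseline_ucal_per_s: float = 0.2
    pulse_tau_s: float = 8.0
    injection_spacing_s: float = 120.0
    #: per-injection heats [ucal] of the three control titrations
    control_heats_ucal: Mapping[str, float] = field(
        default_factory=lambda: {
            "phage_into_buffer": -4.0e-4,
            "buffer_into_lamb": -2.5e-4,
            "buffer_into_buffer": -8.0e-5,
        }
    )

    @property
    def virions_per_injection(self) -> float:
        return self.phage_conc_per_ml * self.inj_volume_ml


@dataclass(frozen=True)
class CapsidModel:
    """Uniform-sphere model of the capsid scattering envelope.

    Only the local linear background under the DNA diffraction window matters
    for the Gaussian-plus-line peak fit; the sphere form factor provides the
    low-q capsid signal of a reduced profile.
    """

    radius_A: float = 290.0
    scale: float = 1.0e3
    bg_slope: float = -1.2
    bg_offset: float = 1.5

    def __post_init__(self) -> None:
        if self.radius_A <= 0:
            raise ValueError("capsid radius must be positive")
        if self.scale < 0:
            raise ValueError("capsid scale must be non-negative")


@dataclass(frozen=True)
class ConditionPreset:
    """One named experimental condition of the DNA-transition study.

    Temperature laws (all temperatures in deg C):

    * ``spacing(T) = spacing_A + spacing_slope_A_per_C*(T - spacing_T_ref_C)``
    * ``area(T) = area_ref*(1 - area_slope_per_C*(T - area_T_ref_C))
      * (1 - area_drop_frac*[T >= t_star_C])``
    * ``dH_ej(T)`` piecewise linear with discontinuity ``dH_jump_J`` at
      ``t_star_C`` (exothermic negative; positive jump = |dH| drop).
    """

    name: str
    spacing_A: float
    spacing_slope_A_per_C: float = 0.0
    spacing_T_ref_C: float = 20.0
    t_star_C: float | None = None
    T_min_C: float = 5.0
    T_max_C: float = 50.0
    peak_width_A_inv: float = 0.030
    area_ref: float = 1.0
    area_T_ref_C: float = 20.0
    area_slope_per_C: float = 0.004
    area_drop_frac: float = 0.0
    dH_T_ref_C: float = 18.0
    dH_intercept_J: float = -5.0e-18
    dH_slope_pre_J_per_C: float = -1.0e-17
    dH_slope_post_J_per_C: float = -1.0e-18
    dH_jump_J: float = 0.0
    k_rate_per_s: Mapping[float, float] | None = None
    nonresponder_frac: float = 0.10
    noise: NoiseModel = field(default_factory=NoiseModel)
    itc: ItcSettings = field(default_factory=ItcSettings)

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_drop_frac < 1.0:
            raise ValueError("area_drop_frac must lie in [0, 1)")
        if self.spacing_A <= 20.0:
            raise ValueError("interaxial spacing must exceed 20 A")
        if self.t_star_C is not None and not (
            self.T_min_C < self.t_star_C < self.T_max_C
        ):
            raise ValueError("t_star_C must lie strictly inside the T range")
        if self.k_rate_per_s is not None and any(
            k <= 0 for k in self.k_rate_per_s.values()
        ):
            raise ValueError("ejection rate constants must be positive")
        if not 0.0 <= self.nonresponder_frac < 1.0:
            raise ValueError("nonresponder_frac must lie in [0, 1)")

    # -- temperature laws ---------------------------------------------------

    def check_temperature(self, T_C: float) -> None:
        if not self.T_min_C <= T_C <= self.T_max_C:
            raise ValueError(
                f"T={T_C} C outside the defined range "
                f"[{self.T_min_C}, {self.T_max_C}] of preset {self.name!r}"
            )

    @property
    def has_transition(self) -> bool:
        return self.t_star_C is not None

    def spacing(self, T_C: float) -> float:
        """DNA interaxial spacing d(T) [Angstrom]."""
        self.check_temperature(T_C)
        return self.spacing_A + self.spacing_slope_A_per_C * (
            T_C - self.spacing_T_ref_C
        )

    def peak_area(self, T_C: float) -> float:
        """SAXS diffraction-peak area A(T) [arbitrary intensity * 1/A]."""
        self.check_temperature(T_C)
        a = self.area_ref * (1.0 - self.area_slope_per_C * (T_C - self.area_T_ref_C))
        if self.t_star_C is not None and T_C >= self.t_star_C:
            a *= 1.0 - self.area_drop_frac
        return a

    def enthalpy(self, T_C: float) -> float:
        """Per-virion ejection enthalpy dH_ej(T) [J], exothermic negative."""
        self.check_temperature(T_C)
        if self.t_star_C is None or T_C < self.t_star_C:
            return self.dH_intercept_J + self.dH_slope_pre_J_per_C * (
                T_C - self.dH_T_ref_C
            )
        pre_at_star = self.dH_intercept_J + self.dH_slope_pre_J_per_C * (
            self.t_star_C - self.dH_T_ref_C
        )
        return (
            pre_at_star
            + self.dH_jump_J
            + self.dH_slope_post_J_per_C * (T_C - self.t_star_C)
        )

    def rate(self, T_C: float) -> float:
        """Ejection rate constant k [1/s] at temperature ``T_C``.

        Rates are tabulated per temperature; lookup is exact to 0.01 C.
        """
        self.check_temperature(T_C)
        if self.k_rate_per_s is None:
            raise ValueError(f"preset {self.name!r} defines no ejection kinetics")
        for temp, k in self.k_rate_per_s.items():
            if abs(temp - T_C) < 1e-2:
                return k
        raise ValueError(
            f"no rate constant tabulated at T={T_C} C for preset {self.name!r}"
        )

    def with_noise(self, **levels: float) -> "ConditionPreset":
        """Copy of the preset with some noise magnitudes overridden.

        ``preset.with_noise(saxs_rel=0.0, dh_J=0.0)`` is the usual way to get
        a noiseless generator for round-trip checks.
        """
        return replace(self, noise=replace(self.noise, **levels))

    def noiseless(self) -> "ConditionPreset":
        """Copy with every noise magnitude set to zero."""
        return self.with_noise(saxs_rel=0.0, area_rel=0.0, dh_J=0.0,
                               baseline_ucal_per_s=0.0)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_preset_table() -> dict[str, ConditionPreset]:
    """Load the packaged preset calibration table."""
    text = (
        resources.files("phagetrans").joinpath("data/presets.yaml").read_text()
    )
    raw = yaml.safe_load(text)
    defaults = raw.get("defaults", {})
    table: dict[str, ConditionPreset] = {}
    for name, overrides in raw["presets"].items():
        cfg = _deep_merge(defaults, overrides or {})
        noise = NoiseModel(**cfg.pop("noise", {}))
        itc = ItcSettings(**cfg.pop("itc", {}))
        rates = cfg.pop("k_rate_per_s", None)
        if rates is not None:
            rates = {float(t): float(k) for t, k in rates.items()}
        table[name] = ConditionPreset(
            name=name, noise=noise, itc=itc, k_rate_per_s=rates, **cfg
        )
    return table


_TABLE: dict[str, ConditionPreset] | None = None


def _table() -> dict[str, ConditionPreset]:
    global _TABLE
    if _TABLE is None:
        _TABLE = load_preset_table()
    return _TABLE


def available_presets() -> list[str]:
    return sorted(_table())


def get_preset(name: str) -> ConditionPreset:
    """Look up a condition preset by name (e.g. ``"WT_Mg10"``)."""
    try:
        return _table()[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        ) from None
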