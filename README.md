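# phagetrans

Analysis of the temperature- and ion-controlled **disordering transition of
DNA packaged in bacteriophage capsids**, for biophysicists working with
solution SAXS, isothermal titration calorimetry (ITC) and single-molecule
ejection assays of pressurized dsDNA viruses (phage λ and its short-genome
mutants are the reference system).

The genome of phage λ is packed to near-crystalline density: hexagonally
ordered DNA at interaxial spacings *d* ≈ 27–30 Å, pressurized to tens of
atmospheres. When the stress on the confined genome reaches a critical value
— tuned by temperature, packaged DNA length and the ionic milieu (Mg²⁺,
spermine, EDTA) — the inner DNA layers disorder into a mobile, fluid-like
state that primes the virion for genome ejection. The package implements the
quantitative pipeline that maps this transition:

* **SAXS reduction & peak modelling** — scan averaging, buffer subtraction,
  truncation to the DNA diffraction window (0.18–0.33 Å⁻¹), and the
  Gaussian-plus-line fit

  *I(q) = (A₀ / (w·√(π/2))) · exp(−2((q−q₀)/w)²) + k·q + c*,

  where the area *A₀* measures the amount of ordered DNA and the center
  gives the hexagonal interaxial spacing *d = 4π/(√3·q₀)*.
* **ITC analysis** — baseline-corrected trapezoidal integration of injection
  pulses, the standard three-control subtraction
  (*H_ej = H_sample − H_phage→buffer − H_buffer→LamB + H_buffer→buffer*),
  per-virion normalization, and the ejection-enthalpy series ΔH_ej(T)
  (exothermic negative).
* **Transition detection** — the transition temperature *T\** appears as a
  discontinuity in an otherwise linear temperature series (ΔH_ej or peak
  area). The detector scans all interior breaks, fits two discontinuous
  lines, and tests them against a single line with an F-test (2, n−4),
  Bonferroni-adjusted over break positions. The detected jump gives the
  transition enthalpy (≈1.8×10⁴ kT/virion for wild-type λ in 10 mM Mg²⁺)
  and a per-bp lower bound ΔH / (0.06 × 48 000 bp).
* **Ejection kinetics** — the single-exponential ensemble model
  *N(t) = a(1 − e^{−kt}) + b* with half-time *t₁/₂ = ln 2 / k*.
* **Synthetic experiments** — seeded generators for SAXS scans (uniform-
  sphere capsid envelope + DNA peak + background), thermograms, temperature
  series and ejection-event streams, under named condition presets
  (`WT_Mg10`, `L78_Mg10`, `WT_Mg20`, `L78_Mg10_EDTA`, …) calibrated to the
  measured transition temperatures, spacings, enthalpies and half-times, so
  the whole pipeline is verifiable end to end without instrument data.

## Worked example

```python
import numpy as np
from phagetrans import (get_preset, make_temperature_series, detect_transition,
                        transition_enthalpy, per_bp_lower_bound)

wt = get_preset("WT_Mg10")                      # wild-type genome, 10 mM Mg
grid = np.arange(18.0, 43.0, 2.0)               # the measured ITC range [degC]
series = make_temperature_series(wt, "itc_enthalpy", grid, n_rep=6, seed=11)
cp = detect_transition(series)
te = transition_enthalpy(cp)
print(cp.t_star_C, te.kT_per_virion, per_bp_lower_bound(te.kT_per_virion))
```

prints

```
33.0 18515.756352579712 6.429082066867956
```

meaning: the changepoint detector places the transition at *T\** = 33 °C,
the enthalpy discontinuity corresponds to ≈1.85×10⁴ kT/virion for this seed
(the seed-averaged value is 1.8×10⁴), and attributing it to the
last-packaged 6% of the 48 000 bp genome bounds the transition enthalpy
below by ≈6 kT/bp. The scripts in `examples/` walk through each capability
the same way (SAXS spacing chain, ITC integration, detection, kinetics, full
pipeline); a thin CLI (`phagetrans reduce|fitpeak|itc|transition|kinetics|
reproduce|all`) exposes the same stages for `.dat`/CSV files.

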