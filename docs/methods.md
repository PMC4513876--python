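# Methods

This note documents the models, estimators and numerical choices behind
`phagetrans`, and what the synthetic experiments do and do not emulate.

## The physical picture

dsDNA packaged in a phage capsid is hexagonally ordered at interaxial
spacings of ~27–30 Å and under strong stress from DNA–DNA repulsion, bending
and packing defects. When temperature raises that stress to a critical
value, the innermost DNA layers disorder into a mobile state. Three
observables track the transition:

1. **Structure (SAXS).** The ordered lattice diffracts into a broad peak at
   q ≈ 0.2–0.3 Å⁻¹; the peak *area* measures the amount of coherently
   ordered DNA (it carries the thermal displacement factor), and the peak
   *center* gives the spacing d = 4π/(√3 q₀). At the transition temperature
   T\* the area drops abruptly; the spacing need not move.
2. **Energetics (ITC).** Titrating phage into LamB receptor solution ejects
   the genome; the released heat per virion, ΔH_ej(T), is approximately
   linear in T on each side of T\* with a discontinuity at T\* equal to the
   transition enthalpy.
3. **Kinetics (fluorescence).** Above T\* the mobile genome initiates
   ejection several-fold faster; cumulative ejection counts follow
   one-step kinetics N(t) = a(1 − e^(−kt)) + b, t₁/₂ = ln2/k.

## Estimators

### SAXS reduction and peak fit

Scans sharing one q grid are averaged pointwise (SE over scans becomes the
per-point σ); a buffer profile is subtracted 1:1 (σ in quadrature; a scale
factor is exposed for sensitivity analysis only, no automatic rescaling);
the profile is truncated to the **closed** interval [0.18, 0.33] Å⁻¹ (with
1e-12 slack for floating-point grids). Grids must match exactly —
resampling is a deliberate non-feature so reductions stay bit-reproducible.

The window is fitted with

    I(q) = (A0/(w√(π/2))) exp(−2((q−q0)/w)²) + k_bg·q + c_bg

by trust-region least squares (scipy `curve_fit`, tolerances 1e-10), with
weights 1/σ² when σ is present. Initialization: background from the line
through the window endpoints; q₀ at the maximum of the line-subtracted
signal; w from its FWHM (FWHM = w√(2 ln 2)); A₀ from its trapezoidal area.
Bounds: w > 0, A₀ ≥ 0, q₀ inside the window. A₀ landing on its zero bound
is an explicit **"no peak"** result (a fully disordered genome), not an
error; non-convergence raises an error carrying the initialization. The
background symbol is stored as `k_bg` because `k` names the kinetics rate
constant elsewhere.

Spacing errors use only the covariance diagonal: σ_d = d·σ_q0/q₀.
Area-series entries from failed fits are NaN gaps (a series with >30%
failures is rejected), and the changepoint detector omits gaps.

### ITC integration and bookkeeping

Each injection pulse is integrated trapezoidally over the half-open window
from its injection time up to (but excluding) the next injection time — the
sample at the next injection already carries that pulse's onset. The
baseline is interpolated linearly between the median power in the 5-s quiet
windows preceding the two window edges; if a quiet window is unavailable the
routine warns and uses the global median. Control subtraction follows the
standard convention

    H_ej = H_sample − H_phage→buffer − H_buffer→LamB + H_buffer→buffer,

adding the buffer-into-buffer (pressure–volume) term back once because both
dilution controls contain it. Per-virion normalization is
`net_µcal · 4.184e-6 / (conc · volume)`, with pfu/ml treated as virion
concentration. Exothermic heat is negative throughout; transition-enthalpy
magnitudes are reported as |ΔH|.

### Changepoint detection

The two-segment model is **discontinuous** (two independent lines, a jump at
the break) rather than a continuous broken stick: the transition signature
is a jump, not merely a slope change. The detector scans every interior
break with ≥3 points per side, keeps the break minimizing total RSS, and
compares against a single line with F = ((RSS₁−RSS₂)/2)/(RSS₂/(n−4)).

Two numerical/statistical choices matter:

* **Multiplicity.** Because the break is chosen by minimum RSS, the
  pointwise F-test over-detects on pure noise. The reported p-value is
  Bonferroni-adjusted over the number of candidate breaks; measured on pure
  lines with i.i.d. noise (500+ seeds) the false-detection rate is ≈4.3% at
  α = 0.05, i.e. at or below the nominal level, while detection power at
  the calibrated jump sizes remains 100%.
* **Weighting.** Segment fits are **unweighted by default** (pooled residual
  variance). Standard errors estimated from ~6 replicates are themselves
  noisy, and using them as hard 1/SE² weights makes the F-test
  anticonservative (measured ≈9% false detections at α = 0.05 on
  no-transition presets). `weighted=True` restores 1/SE² weighting for the
  case where per-point uncertainties are known exactly.

The break temperature is reported at the **midpoint of the bracketing grid
interval**: the data constrain T\* only between the last pre-break and first
post-break grid temperatures. On a 2 °C grid this reproduces a transition
at an inter-grid temperature exactly (e.g. 33 °C between 32 and 34) and is
at most one grid step off when the true break coincides with a grid point.
A perfect single line (RSS₁ ≈ 0 at 1e-18 of the series' scale) short-
circuits to "not detected"; a perfect two-segment fit short-circuits to
p = 0. The jump is the left-minus-right segment prediction at T\*, so for
enthalpy series (where ΔH rises toward zero at the transition) the detected
jump is negative while the area jump is positive.

The transition enthalpy is |jump| converted to kT at T\* (k_B exact SI,
T in K); the per-bp lower bound divides by fraction × genome length with
defaults 6% × 48 000 bp — the transition survives removal of 6% of the
genome but not more, so at most that fraction participates.

### Kinetics

The fit's observations are the cumulative frame counts (as recorded by the
measurement), initialized at a = N_final, b = 0, k = 1/t_half(observed),
with bounds a > 0, k > 0. The offset b is admitted even though the clock is
re-zeroed at the first observed ejection; b fitting near zero is a test
outcome, not an assumption. A constant series, non-convergence, or k pinned
at its bound raises a flagged error. An exponential MLE on raw waiting
times (k = 1/mean) is provided purely as a cross-check oracle.

## Synthetic experiments

The generators emulate the statistical structure the estimators assume,
under named condition presets whose numbers live in one declarative table
(`data/presets.yaml`) with provenance comments. Calibration anchors are the
measured values: T\* = 33 °C (WT, 10 mM Mg), 22/37/35 °C at 5/20/50 mM Mg,
36 °C for the 78%-genome + EDTA condition; d = 29.6 Å for the 78% mutant
(rising to 30.1 Å at 45 °C with EDTA); transition enthalpy 1.8×10⁴
kT/virion at 33 °C (7.6083e-17 J); half-times 331 s (22 °C) and 76 s
(37 °C), stored as rate constants ln2/t₁/₂.

Laws and defaults:

* **SAXS profile** = uniform-sphere capsid envelope (radius 290 Å, scale
  10³) + Gaussian DNA peak (width 0.03 Å⁻¹) + linear background, with
  multiplicative Gaussian noise (default 1% per scan; no counting
  statistics are modelled). The measured "small oscillating ripples" on the
  DNA peak are *not* simulated — the peak model treats them as residuals.
  The sphere envelope contributes ~10⁻³ relative intensity inside the DNA
  window, a deliberate, documented model violation of the Gaussian-plus-line
  fit; zero-noise round-trip identities at ≤1e-6 relative are therefore
  stated for the envelope-free generator, while the full chain recovers
  spacings well within 0.1 Å.
* **Peak area law** A(T) = A_ref(1 − 0.004(T−20))·(1 − 0.3·[T ≥ T*]): a
  weak linear decrease, with a single multiplicative 30% drop at T\* for
  transition presets ("sudden drop" vs "weak linear decrease" phrasing of
  the measurements; the drop fraction is a declared default).
* **Enthalpy law** is piecewise linear with the jump at T\*. For the WT
  10 mM preset the two quantitative anchors (jump = 1.8×10⁴ kT; jump ≈ half
  of |ΔH(T\*⁻)|) fix the calibration; the qualitative "|ΔH| grows ~4× from
  22 to 32 °C" cannot simultaneously hold with a strictly linear branch and
  comes out ≈3.2×. Replicate noise σ = 4e-18 J/virion is a declared
  default (measured error bars are published without magnitudes).
* **Thermograms**: flat baseline (0.2 µcal/s) + white noise (2e-5 µcal/s)
  + single-exponential pulses h(t) = (H/τ)e^(−(t−t_i)/τ), τ = 8 s,
  injections 120 s apart (> 5τ; closer spacing warns). Sample heats follow
  the preset enthalpy law scaled by virions per injection (5×10¹³ ml⁻¹ ×
  2 µl — the titration concentration is not published and is a declared
  config default, so absolute per-virion calibration comes from the
  presets); control roles carry only their own declared heats (~10% of the
  sample heat). At these magnitudes the per-injection integration error is
  dominated by quiet-window baseline estimation (~5–15%), averaging out
  over injections and replicates.
* **Ejection events**: exponential waiting times at the preset rate; a 10%
  non-responder fraction (declared default) never ejects and inflates
  neither a nor b; counts are reported at frame times (default 5 s) and the
  clock re-zeroes at the first frame with a nonzero count. Spacing laws are
  linear in T for all presets; for the EDTA condition a single line anchored
  at 29.6 Å @ 20 °C and 30.1 Å @ 45 °C stands in for the measured
  flat-then-rising curve (only the 45 °C value is quantitative).

Same seed + same configuration ⇒ bit-identical output everywhere (one
`numpy` Generator per call; pipeline/experiment drivers derive child seeds
via `SeedSequence`).

What passing tests show — and what they do not: the suite demonstrates that
the estimators recover the generating parameters under the assumed noise
structure (multiplicative/Gaussian, i.i.d. replicates, exponential waiting
times) at realistic magnitudes. Real profiles add capsid form-factor
ripples, detector artifacts, buffer mismatch and possible concentration
drifts that the generators deliberately omit; conclusions about instrument
data require the usual diagnostics (χ²_red, residual structure) that the
fit objects expose.

## Problem sizes

The reproduction experiments (`phagetrans.experiments`, driven by
`scripts/acceptance.py`) use: 200 seeded series (100 per modality) for each
transition-temperature estimate, 50 seeds for the transition enthalpy
(mean) and for each half-time (median, 1000 virions, 5-s frames, 2000 s at
22 °C / 600 s at 37 °C), and 40 scans per temperature for the spacing
chains — sizes chosen to match the scale of the emulated experiments while
keeping a full run in the seconds range.

## Known limitations

* Single changepoint only; the physics admits one transition in range.
* No Lorentzian/Voigt peak alternatives or multi-peak deconvolution.
* The ITC model has no binding isotherm (this is not a binding experiment)
  and no injection-volume corrections beyond the linear per-virion scaling.
* Changepoint inference assumes Gaussian noise; heavy-tailed outliers would
  need robust segment fits.
* T\* resolution is limited to the temperature grid; the reported value is
  an interval midpoint, not a sub-grid estimate.
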