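# Condition presets for the synthetic experiment generators.
#
# Each preset names one experimental condition (phage genome-length variant +
# ionic milieu) and carries the numbers the generators are calibrated to:
# hexagonal DNA interaxial spacing, transition temperature T* (null = no
# transition in range), the piecewise-linear laws for the SAXS peak area and
# the per-virion ejection enthalpy dH_ej(T), the ejection rate constants, and
# declared noise magnitudes.  Values marked "anchor" are printed measurement
# results for that condition; everything else is a declared default of this
# package (magnitudes not printed in any source).
#
# Conventions:
#   spacing(T)  = spacing_A + spacing_slope_A_per_C * (T - spacing_T_ref_C)   [Angstrom]
#   area(T)     = area_ref * (1 - area_slope_per_C*(T - area_T_ref_C))
#                          * (1 - area_drop_frac * [T >= t_star_C])
#   dH_ej(T)    = dH_intercept_J + dH_slope_pre_J_per_C*(T - dH_T_ref_C)          (T < T*)
#               = dH_ej(T*-) + dH_jump_J + dH_slope_post_J_per_C*(T - t_star_C)   (T >= T*)
#   (exothermic negative; dH_jump_J > 0 means |dH_ej| drops at T*)

defaults:
  T_min_C: 5.0
  T_max_C: 50.0
  spacing_slope_A_per_C: 0.0
  spacing_T_ref_C: 20.0
  peak_width_A_inv: 0.030        # declared; gives a well-contained peak in 0.18-0.33 1/A
  area_ref: 1.0                  # arbitrary intensity*q units
  area_T_ref_C: 20.0
  area_slope_per_C: 0.004        # "weak linear decrease" of peak area with T
  area_drop_frac: 0.0
  t_star_C: null
  dH_T_ref_C: 18.0
  dH_intercept_J: -5.0e-18
  dH_slope_pre_J_per_C: -1.0e-17
  dH_slope_post_J_per_C: -1.0e-18
  dH_jump_J: 0.0
  k_rate_per_s: null
  nonresponder_frac: 0.10        # declared: fraction of virions that never eject
  noise:
    saxs_rel: 0.01               # multiplicative, per scan (declared 1-2% class)
    area_rel: 0.02               # per replicate area value
    dh_J: 4.0e-18                # per replicate dH_ej value (declared)
    baseline_ucal_per_s: 2.0e-5  # ITC white noise on differential power
  itc:
    phage_conc_per_ml: 5.0e+13   # anchor for SAXS sample; ITC value unprinted, declared
    inj_volume_ml: 2.0e-6
    baseline_ucal_per_s: 0.2
    pulse_tau_s: 8.0             # declared single-exponential pulse decay
    injection_spacing_s: 120.0
    control_heats_ucal:          # declared control magnitudes (~10% of sample heat)
      phage_into_buffer: -4.0e-4
      buffer_into_lamb: -2.5e-4
      buffer_into_buffer: -8.0e-5

presets:
  WT_Mg10:                       # wild-type genome length, 10 mM MgCl2 Tris
    spacing_A: 27.5
    t_star_C: 33.0               # anchor: T* ~33 C
    area_drop_frac: 0.30
    dH_jump_J: 7.6083e-17        # anchor: 1.8e4 kT/virion at 33 C (kB*306.15 K)
    k_rate_per_s:                # anchor: t1/2 = 331 s at 22 C, 76 s at 37 C (ln2/t1/2)
      22.0: 2.09410e-3
      37.0: 9.12036e-3
  L94_Mg10:                      # 94% genome length, 10 mM Mg: no transition in range
    spacing_A: 28.5
    dH_intercept_J: -8.0e-18
    dH_slope_pre_J_per_C: -2.0e-18
    dH_slope_post_J_per_C: -2.0e-18
  L78_Mg10:                      # 78% genome length, 10 mM Mg: no transition in range
    spacing_A: 29.6              # anchor: d ~29.6 A, constant 10-45 C
    dH_intercept_J: -6.0e-18
    dH_slope_pre_J_per_C: -1.5e-18
    dH_slope_post_J_per_C: -1.5e-18
  WT_Mg5:                        # 5 mM MgCl2
    spacing_A: 27.3
    t_star_C: 22.0               # anchor: T* ~22 C at 5 mM
    area_drop_frac: 0.30
    dH_T_ref_C: 14.0
    dH_slope_pre_J_per_C: -1.2e-17
    dH_jump_J: 6.0e-17
  WT_Mg20:                       # 20 mM MgCl2
    spacing_A: 27.6
    t_star_C: 37.0               # anchor: T* ~37 C at 20 mM
    area_drop_frac: 0.30
    dH_slope_pre_J_per_C: -8.0e-18
    dH_jump_J: 8.0e-17
  WT_Mg50:                       # 50 mM MgCl2
    spacing_A: 27.8
    t_star_C: 35.0               # anchor: T* ~35 C at 50 mM
    area_drop_frac: 0.30
    dH_slope_pre_J_per_C: -9.0e-18
    dH_jump_J: 7.5e-17
  WT_Mg10_spermine:              # + 1 mM spermine(4+): transition switched off
    spacing_A: 27.4
    area_slope_per_C: 0.001      # "only slight variation" of area with T
    dH_slope_pre_J_per_C: -2.0e-18
    dH_slope_post_J_per_C: -2.0e-18
  L78_Mg10_EDTA:                 # 78% length + 20 mM EDTA: transition switched on
    spacing_A: 29.6              # anchor: 29.6 A at 20 C rising to 30.1 A at 45 C
    spacing_slope_A_per_C: 0.02
    t_star_C: 36.0               # anchor: T* ~36 C with EDTA
    area_drop_frac: 0.30
    dH_slope_pre_J_per_C: -6.0e-18
    dH_jump_J: 5.0e-17
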