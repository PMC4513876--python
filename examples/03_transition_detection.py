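"""Changepoint detection of T* and the transition-enthalpy estimates.

Enthalpy and peak-area temperature series are generated for the wild-type
genome in 10 mM Mg (transition at ~33 C) and for the 94%-length mutant (no
transition).  The detector fits two discontinuous lines against one line
(F-test, Bonferroni-adjusted over break positions).  The detected enthalpy
jump gives the transition enthalpy (~1.8e4 kT/virion) and, attributed to
the last-packaged 6% of the 48,000 bp genome, a lower bound of ~6 kT/bp.
"""

import numpy as np

from phagetrans import (
    compare_modalities,
    detect_transition,
    get_preset,
    make_temperature_series,
    per_bp_lower_bound,
    transition_enthalpy,
)

grid = np.arange(18.0, 43.0, 2.0)

wt = get_preset("WT_Mg10")
enth = make_temperature_series(wt, "itc_enthalpy", grid, n_rep=6, seed=11)
area = make_temperature_series(wt, "saxs_area", grid, n_rep=6, seed=12)
cp_itc = detect_transition(enth)
cp_area = detect_transition(area)
print(f"WT, ITC : detected={cp_itc.detected}  T*={cp_itc.t_star_C:.1f} C  "
      f"p={cp_itc.p_value:.2g}")
print(f"WT, SAXS: detected={cp_area.detected}  T*={cp_area.t_star_C:.1f} C  "
      f"p={cp_area.p_value:.2g}")
print(f"modality agreement: dT = {compare_modalities(cp_itc, cp_area):+.1f} C")

te = transition_enthalpy(cp_itc)
print(f"\ntransition enthalpy: {te.J_per_virion:.3e} J/virion "
      f"= {te.kT_per_virion:.3e} kT/virion at {te.t_star_C:.0f} C")
print(f"per-bp lower bound (6% of 48,000 bp): "
      f"{per_bp_lower_bound(te.kT_per_virion):.2f} kT/bp")

l94 = get_preset("L94_Mg10")
cp94 = detect_transition(
    make_temperature_series(l94, "itc_enthalpy", grid, n_rep=6, seed=11)
)
print(f"\n94% genome length: detected={cp94.detected} (p={cp94.p_value:.2g})"
      " - the shorter genome never reaches the critical stress.")
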