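"""ITC chain: thermograms -> injection heats -> per-virion enthalpy series.

For each cell temperature, a sample titration (phage into LamB receptor,
which triggers DNA ejection) and three control titrations are simulated;
pulses are integrated, controls subtracted, and the net heat normalized to
J per virion.  The resulting dH_ej(T) series shows the discontinuity at
T* ~ 33 C for the wild-type genome in 10 mM Mg.
"""

import numpy as np

from phagetrans import (
    enthalpy_series,
    get_preset,
    integrate_injections,
    joules_to_kT,
    make_thermogram,
    per_virion,
    subtract_controls,
)

preset = get_preset("WT_Mg10")
cfg = preset.itc
roles = ("sample", "phage_into_buffer", "buffer_into_lamb",
         "buffer_into_buffer")

replicates: dict[float, list[float]] = {}
for i, T in enumerate(np.arange(20.0, 41.0, 4.0)):
    heats = {
        role: integrate_injections(
            make_thermogram(preset, T=T, n_injections=8, role=role,
                            seed=100 * i + j)
        )
        for j, role in enumerate(roles)
    }
    net = subtract_controls(*(heats[r] for r in roles))
    replicates[float(T)] = [per_virion(net, cfg.phage_conc_per_ml,
                                       cfg.inj_volume_ml)]

series = enthalpy_series(replicates, condition=preset.name)
for T, dH in zip(series.T, series.dH):
    print(f"T = {T:4.1f} C   dH_ej = {dH:+.3e} J/virion "
          f"({joules_to_kT(dH, T):+.3e} kT)")

print("\n|dH_ej| grows steeply up to ~32 C, then collapses above the")
print("transition: the disordered genome stores much less internal stress.")
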