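"""Single-Boltzmann fit of a normalized activation (G-V) curve.

Generates tail-current data on the standard conditioning grid (-20 to
-110 mV in 10 mV steps) with 2% noise and recovers the half-activation
voltage and slope factor.
"""

import porekinetics as pk

curve = pk.generate_gv_data(v_half=-70.0, slope_k=8.0, noise_sd=0.02, seed=0)
fit = pk.fit_boltzmann(curve)
print("voltages (mV):", [int(v) for v in curve.voltages])
print("G/Gmax:", [round(float(g), 3) for g in curve.normalized_conductance])
print(f"fit: V1/2 = {fit.v_half:.1f} mV (true -70), "
      f"k = {fit.slope_k:.1f} mV (true 8)")
print("V1/2 is the voltage of half-maximal activation; k sets how steeply "
      "open probability rises with hyperpolarization.")
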