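"""Helix bend angle, unwinding detection, and labelled-atom displacement.

Voltage-sensor S4 helices bend mid-helix and unwind at their intracellular
end during gating; this example measures both on generated helices with
known ground truth, and shows the displacement metric used to track gating
charges between conformational states.
"""

import numpy as np

import porekinetics as pk

kinked, truth = pk.generate_kinked_helix(30, kink_after=15, bend_deg=30.0)
geom = pk.helix_axes_and_bend(kinked, (1, 15), (16, 30))
print(f"built bend: {truth['bend_deg']:.0f}°, "
      f"measured: {geom.bend_angle:.1f}°")

tailed, truth = pk.generate_kinked_helix(30, unwound_tail=7)
prof = pk.helicity_profile(tailed, (1, 30))
run = prof["runs"][0]
print(f"unwound run: residues {run['start']}-{run['end']} "
      f"({run['length']} residues ≈ {run['turns']:.1f} helical turns)")
print("A ~2-turn unwinding shortens the helix the way the S4 C-terminus "
      "does on activation.\n")

# displacement of labelled atoms after superposition on an unmoved segment
model, _ = pk.generate_kinked_helix(30)
coords = model.coords.copy()
labels = [("R4", 25, "CA"), ("R5", 28, "CA")]
idx = [i for i, a in enumerate(model.atoms)
       if a.resid in (25, 28) and a.name == "CA"]
coords[idx] += np.array([0.0, 0.0, 5.0])
moved = model.with_coords(coords)
disp = pk.charge_displacement(model, moved, labels,
                              align_expr="resid 1-20 and backbone")
for label, resid, _ in labels:
    print(f"{label} (residue {resid}) displacement: "
          f"{disp[label]['magnitude']:.2f} Å")
print("After aligning on the static segment, each labelled Cα reports its "
      "true 5 Å shift.")
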