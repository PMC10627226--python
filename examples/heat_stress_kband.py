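"""Directional heat-stress response: K band rises, phi_Po falls.

Applies the severe-heat scenario (raised F0, collapsed Fm, prominent K band
at 300 us) to the control kinetics and compares mean JIP parameters over
100 noisy traces per condition.  The Fk/Fj ratio above ~0.6 is the classic
indicator of donor-side (oxygen-evolving complex) damage.
"""

import numpy as np

from ojip import HEAT_SCENARIO, KineticPreset, apply_scenario, compute_jip_parameters, simulate_transient

base = KineticPreset()
heat = apply_scenario(base, HEAT_SCENARIO)

ctrl = [compute_jip_parameters(simulate_transient(base, seed=s)) for s in range(100)]
hot = [compute_jip_parameters(simulate_transient(heat, seed=10_000 + s)) for s in range(100)]

for name, grp in [("control", ctrl), ("severe heat", hot)]:
    print(f"{name:>12}:  mean Fk/Fj = {np.mean([p.Fk_Fj for p in grp]):.3f}   "
          f"mean phi_Po = {np.mean([p.phi_Po for p in grp]):.3f}   "
          f"OEC flag rate = {np.mean([p.oec_flag for p in grp]):.2f}")

print("\nHeat raises the K-band ratio (donor-side damage) and lowers the "
      "maximum PSII yield; both shifts are the diagnostic signature of "
      "oxygen-evolving-complex injury under high temperature.  Note the "
      "default kinetics already sit above the 0.6 flag limit, so on "
      "synthetic data the comparative shift in Fk/Fj, not the absolute "
      "flag, carries the signal.")
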