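"""Healthy-cochlea traveling waves and the tuning (tonotopic) map.

Solves the two-duct harmonic system at the seven stimulus frequencies with
a 10 nm stapes drive, normalizes by the stapes displacement, smooths with
the 0.2 mm local filter, and reports where each frequency peaks — compared
with the chinchilla Greenwood frequency-place map.
"""

import basilar as b

geom = b.build_geometry()
resp = b.solve_harmonic(geom)
tuning = b.extract_tuning(resp, greenwood=b.GreenwoodMap())

print("freq [Hz]  peak x [mm]  Greenwood x [mm]  error [mm]  |u|/|u_s|")
for i, f in enumerate(tuning.frequencies):
    print(
        f"{f:8.0f}  {tuning.peak_location[i]:10.2f}  {tuning.greenwood_location[i]:15.2f}"
        f"  {tuning.location_error[i]:+9.2f}  {tuning.peak_magnitude[i]:9.1f}"
    )
print(f"\nRMS location error vs Greenwood: {tuning.rms_location_error:.2f} mm "
      f"({100 * tuning.rms_location_error / geom.L:.1f}% of the BM length)")
print("Lower frequencies peak further apically and with smaller normalized magnitude,")
print("the two signatures of a passive cochlear traveling wave.")
for d in resp.diagnostics:
    assert d.power_balance_error < 1e-6  # discrete power balance holds
print("Discrete stapes-input vs dissipated-power balance verified at every frequency.")
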