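"""Evaluate the graded material laws and the partition reduction.

The basilar membrane's elastic modulus falls exponentially from base to
apex (7.1e4 * exp(-0.21 x) Pa, x in mm) while its damping coefficient
grows (2.3e-8 * exp(0.52 x) s); together with the thickness and width
tapers this produces the stiffness gradient that underlies tonotopy.
"""

import numpy as np

import basilar as b
from basilar.materials import material_frame

mat = b.MaterialTable.default()
for x in (0.0, 9.15, 18.3):
    print(f"x = {x:5.2f} mm: E_bm = {mat.bm.E(x):10.1f} Pa, beta_bm = {mat.bm.beta(x):.3e} s")

geom = b.build_geometry()
params = b.partition_params(geom, mat)
cf = np.sqrt(params.stiffness / params.mass) / (2 * np.pi)
print(f"\npartition stiffness K : {params.stiffness[0]:.3e} -> {params.stiffness[-1]:.3e} Pa/m")
print(f"resonance frequency   : {cf[0]:.0f} Hz at the base -> {cf[-1]:.0f} Hz at the apex")
print(f"stiffness/mass span   : {params.stiffness[0]/params.mass[0]/(params.stiffness[-1]/params.mass[-1]):.0f}x")

print("\nfull material audit table (first rows):")
print(material_frame(mat).head(8).to_string(index=False))
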