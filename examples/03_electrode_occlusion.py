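"""Place the tapered CI electrode at several insertion angles.

The electrode is a scaled long lateral-wall array lying in the scala
tympani.  Its occlusion fraction phi(x) is the share of the duct cross
section it blocks at each midline position; deeper insertions extend the
occluded span apically and (because the thicker basal part follows the tip
in) raise phi everywhere.
"""

import basilar as b

geom = b.build_geometry()
mat = b.MaterialTable.default()

profiles = b.sweep_angles(geom, b.ElectrodeSpec(), mat=mat)
for occ in profiles:
    mask = occ.support()
    print(
        f"theta = {occ.insertion_angle:5.0f} deg: span {occ.span:6.2f} mm, "
        f"phi in [{occ.phi[mask].min():.3f}, {occ.phi[mask].max():.3f}] "
        f"over {mask.sum()} nodes"
    )
print("\nocclusion never fully blocks the duct (phi < 1) and deeper spans nest the shallower ones.")
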