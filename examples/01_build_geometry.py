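"""Build the parametric chinchilla cochlea and inspect its dimensions.

The geometry is a synthetic stand-in for a scan-derived mesh: a coiled
spiral midline scaled to the chinchilla-average basilar-membrane length of
18.3 mm, with thickness tapering from 16.5 um at the base to 5 um at the
apex, plus duct cross-sections and the angle <-> arc-length map used to
express electrode insertion depth in degrees.
"""

import basilar as b

geom = b.build_geometry()

print(f"BM midline length      : {geom.L} mm  ({geom.n_nodes} grid nodes, dx = {geom.dx} mm)")
print(f"thickness  base -> apex: {geom.thickness[0]} -> {geom.thickness[-1]} um")
print(f"width      base -> apex: {geom.width[0]} -> {geom.width[-1]} mm")
print(f"scala tympani area     : {geom.area_st[0]} -> {geom.area_st[-1]} mm^2")
for theta in (180.0, 360.0, 540.0, 720.0, 900.0):
    s = geom.x_of_angle(theta)
    print(f"insertion angle {theta:5.0f} deg reaches x = {s:6.2f} mm "
          f"({100 * s / geom.L:.0f}% of the midline)")
# the angle map is the inverse of the arc-length map
print(f"round trip 540 deg -> {geom.angle_of_x(geom.x_of_angle(540.0)):.6f} deg")
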