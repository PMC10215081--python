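"""Cochlear-implant electrode placement and duct occlusion.

The electrode is a tapered cylindrical body (a scaled long lateral-wall
array) lying along the scala tympani from the round-window entry up to a
configurable insertion angle, at most 900 degrees.  Its leading-order
mechanical effect in a two-duct model is occlusion: at each midline position
it blocks a fraction of the scala-tympani cross section.  Its material
constants (E, rho, beta) feed a compliant shunt branch and an optional
mass-loading term in the solver.

The physical array has a fixed taper from its basal to its apical end;
partial insertion puts the thin distal portion into the cochlea, so the
diameter seen at midline position x depends on how deep the tip sits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MAX_INSERTION_ANGLE_DEG, CochlearGeometry
from .materials import Isotropic, MaterialTable

__all__ = ["ElectrodeSpec", "OcclusionProfile", "place_electrode", "sweep_angles",
           "DEFAULT_SWEEP_ANGLES", "occlusion_frame"]

DEFAULT_SWEEP_ANGLES = (180.0, 360.0, 540.0, 720.0, 900.0)


@dataclass(frozen=True)
class ElectrodeSpec:
    """Electrode array geometry and material.

    Diameters are the chinchilla-scaled defaults of a long tapered
    lateral-wall array (not measured values).  ``section_size`` is the sweep
    granularity in degrees.  ``coupling`` selects how the body loads the
    partition: ``"occlusion"`` (area reduction + compliant damping branch,
    default) or ``"mass_loading"`` (additionally adds the electrode mass to
    the partition).
    """

    insertion_angle: float = 900.0  # degrees
    basal_diameter: float = 0.55  # mm
    apical_diameter: float = 0.25  # mm
    section_size: float = 180.0  # degrees
    coupling: str = "occlusion"
    material: Isotropic | None = None  # defaults to MaterialTable.electrode

    def __post_init__(self) -> None:
        if not 0.0 <= self.insertion_angle <= MAX_INSERTION_ANGLE_DEG:
            raise ValueError(
                f"insertion_angle={self.insertion_angle} deg outside "
                f"[0, {MAX_INSERTION_ANGLE_DEG}]"
            )
        if self.apical_diameter <= 0 or self.basal_diameter <= 0:
            raise ValueError("electrode diameters must be > 0")
        if self.basal_diameter < self.apical_diameter:
            raise ValueError("basal_diameter must be >= apical_diameter")
        if self.coupling not in ("occlusion", "mass_loading"):
            raise ValueError(f"unknown coupling mode {self.coupling!r}")

    def resolved_material(self, mat: MaterialTable) -> Isotropic:
        return self.material if self.material is not None else mat.electrode


@dataclass(frozen=True)
class OcclusionProfile:
    """Per-node electrode loading on the geometry grid.

    ``phi`` is the occluded fraction of the scala-tympani area, in [0, 1);
    zero beyond the inserted arc length.  ``added_mass`` (kg/m^2, nonzero
    only in ``mass_loading`` coupling) is the electrode mass referred to the
    BM area.  ``electrode_area`` (mm^2) is the body cross section itself, and
    feeds the compliant damping branch together with the material constants.
    """

    insertion_angle: float  # degrees
    span: float  # mm of midline covered
    x_grid: np.ndarray
    phi: np.ndarray
    electrode_area: np.ndarray  # mm^2
    added_mass: np.ndarray  # kg/m^2
    material: Isotropic = field(repr=False)

    def support(self) -> np.ndarray:
        """Boolean mask of grid nodes with nonzero occlusion."""
        return self.phi > 0.0


def place_electrode(geom: CochlearGeometry, spec: ElectrodeSpec,
                    mat: MaterialTable | None = None) -> OcclusionProfile:
    """Insert the electrode to ``spec.insertion_angle`` and compute occlusion.

    The inserted midline span is [0, s(theta)].  A full-insertion array
    (900 deg) carries the full basal-to-apical taper; for shallower
    insertions only its distal portion is inside, so the diameter at x is
    interpolated along the array measured from the tip.  Occlusion ramps to
    zero over the final grid cell at the tip to avoid a discontinuity.

    Raises ``ValueError`` naming the first position where the electrode cross
    section meets or exceeds the duct area.
    """
    mat = mat or MaterialTable.default()
    material = spec.resolved_material(mat)
    theta = spec.insertion_angle
    if theta > geom.spiral.total_angle:
        raise ValueError(
            f"insertion angle {theta} exceeds the coil ({geom.spiral.total_angle} deg)"
        )
    x = geom.x_grid
    phi = np.zeros_like(x)
    area = np.zeros_like(x)
    added_mass = np.zeros_like(x)
    if theta <= 0.0:
        return OcclusionProfile(theta, 0.0, x, phi, area, added_mass, material)

    full_len = geom.x_of_angle(MAX_INSERTION_ANGLE_DEG)
    s_ins = geom.x_of_angle(theta)
    inside = x <= s_ins + 1e-12
    # distance from the tip, along the array
    ell = np.clip(s_ins - x[inside], 0.0, full_len)
    d = spec.apical_diameter + (spec.basal_diameter - spec.apical_diameter) * ell / full_len
    a_e = np.pi * d**2 / 4.0
    # tip ramp: taper occlusion to zero across the last cell
    ramp = np.clip((s_ins - x[inside]) / geom.dx, 0.0, 1.0)
    area[inside] = a_e * ramp
    phi_in = area[inside] / geom.area_st[inside]
    bad = np.flatnonzero(phi_in >= 1.0)
    if bad.size:
        xb = x[inside][bad[0]]
        raise ValueError(
            f"electrode cross-section fills the scala tympani at x = {xb:.3f} mm "
            f"(occlusion {phi_in[bad[0]]:.2f} >= 1); reduce the diameters"
        )
    phi[inside] = phi_in
    if spec.coupling == "mass_loading":
        # electrode mass per unit duct length, referred to the BM strip area
        added_mass[inside] = material.density * (area[inside] * 1e-6) / (geom.width[inside] * 1e-3)
    return OcclusionProfile(theta, float(s_ins), x, phi, area, added_mass, material)


def sweep_angles(
    geom: CochlearGeometry,
    base_spec: ElectrodeSpec,
    angles: "list[float] | tuple[float, ...]" = DEFAULT_SWEEP_ANGLES,
    mat: MaterialTable | None = None,
) -> list[OcclusionProfile]:
    """One occlusion profile per insertion angle, in the order given."""
    from dataclasses import replace

    return [
        place_electrode(geom, replace(base_spec, insertion_angle=a), mat)
        for a in angles
    ]


def occlusion_frame(profiles: "list[OcclusionProfile]") -> pd.DataFrame:
    """Long-format table (x_mm, angle_deg, occlusion_fraction) for export."""
    frames = [
        pd.DataFrame(
            {
                "x_mm": p.x_grid,
                "angle_deg": p.insertion_angle,
                "occlusion_fraction": p.phi,
            }
        )
        for p in profiles
    ]
    return pd.concat(frames, ignore_index=True)
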