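"""Parametric cochlear geometry.

Builds a synthetic stand-in for a scan-derived chinchilla cochlea: a coiled
spiral centerline, the basilar-membrane (BM) dimension profiles along it, and
the cross-sectional areas of the two fluid ducts (scala vestibuli + media
lumped above the BM, scala tympani below).  The whole construction is scaled
so the BM midline has a prescribed length (default 18.3 mm, the chinchilla
average), with thickness tapering from 16.5 um at the base to 5 um at the
apex.

Units: positions and lengths in mm, thickness in um, areas in mm^2, angles in
degrees.  Conversion to SI happens in the materials/solver layers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "SpiralSpec",
    "GridSpec",
    "CochlearGeometry",
    "build_geometry",
    "thickness_at",
    "angle_to_arclength",
    "arclength_to_angle",
    "geometry_to_frame",
    "export_csv",
    "export_vtk",
]

MAX_INSERTION_ANGLE_DEG = 900.0


@dataclass(frozen=True)
class SpiralSpec:
    """Coiled centerline of the cochlea.

    ``form="log"`` (default) is a logarithmic spiral r(theta) =
    basal_radius * exp(-taper_rate * theta); ``form="archimedean"`` is
    r(theta) = basal_radius * (1 - taper_rate * theta), theta in radians.
    The radius must stay strictly positive and strictly decreasing out to
    ``total_angle``, which must be at least 900 degrees so the deepest
    electrode insertion fits on the coil.
    """

    total_angle: float = 1080.0  # degrees
    basal_radius: float = 2.0  # mm
    taper_rate: float = 0.08  # per radian
    form: str = "log"

    def __post_init__(self) -> None:
        if self.total_angle < MAX_INSERTION_ANGLE_DEG:
            raise ValueError(
                f"total_angle={self.total_angle} deg must be >= "
                f"{MAX_INSERTION_ANGLE_DEG} deg to accommodate a full electrode"
            )
        if self.basal_radius <= 0:
            raise ValueError(f"basal_radius={self.basal_radius} must be > 0")
        if self.taper_rate <= 0:
            raise ValueError(f"taper_rate={self.taper_rate} must be > 0")
        if self.form not in ("log", "archimedean"):
            raise ValueError(f"unknown spiral form {self.form!r}")
        if self.form == "archimedean":
            theta_max = np.deg2rad(self.total_angle)
            if 1.0 - self.taper_rate * theta_max <= 0:
                raise ValueError(
                    "archimedean spiral radius reaches zero before total_angle; "
                    "reduce taper_rate"
                )

    def radius(self, theta_rad: np.ndarray | float) -> np.ndarray | float:
        if self.form == "log":
            return self.basal_radius * np.exp(-self.taper_rate * np.asarray(theta_rad, float))
        return self.basal_radius * (1.0 - self.taper_rate * np.asarray(theta_rad, float))

    def speed(self, theta_rad: np.ndarray | float) -> np.ndarray | float:
        """|d(position)/d(theta)| of the centerline, mm per radian."""
        theta_rad = np.asarray(theta_rad, float)
        if self.form == "log":
            return self.radius(theta_rad) * np.hypot(1.0, self.taper_rate)
        r = self.radius(theta_rad)
        return np.hypot(r, self.basal_radius * self.taper_rate)

    def total_arclength(self) -> float:
        return angle_to_arclength(self, self.total_angle)


def angle_to_arclength(spiral: SpiralSpec, theta: float) -> float:
    """Arc length (mm) along the centerline from the base to angle ``theta`` (deg)."""
    if not 0.0 <= theta <= spiral.total_angle:
        raise ValueError(
            f"theta={theta} deg outside [0, {spiral.total_angle}]"
        )
    th = np.deg2rad(theta)
    if spiral.form == "log":
        b = spiral.taper_rate
        # closed form: integral of r0*sqrt(1+b^2)*exp(-b*t)
        return spiral.basal_radius * np.sqrt(1.0 + b * b) / b * (1.0 - np.exp(-b * th))
    val, _ = quad(spiral.speed, 0.0, th, epsrel=1e-12, limit=200)
    return val


def arclength_to_angle(spiral: SpiralSpec, s: float) -> float:
    """Inverse of :func:`angle_to_arclength`; ``s`` in mm, result in degrees."""
    total = spiral.total_arclength()
    if not 0.0 <= s <= total * (1.0 + 1e-12):
        raise ValueError(f"s={s} mm outside [0, {total}]")
    s = min(s, total)
    if spiral.form == "log":
        b = spiral.taper_rate
        c = spiral.basal_radius * np.sqrt(1.0 + b * b) / b
        return float(np.rad2deg(-np.log(max(1.0 - s / c, 1e-300)) / b))
    if s == 0.0:
        return 0.0
    return brentq(
        lambda th: angle_to_arclength(spiral, th) - s,
        0.0,
        spiral.total_angle,
        xtol=1e-10,
    )


@dataclass(frozen=True)
class GridSpec:
    """Uniform discretization of the BM midline.

    ``dx`` is a target step; the actual step is adjusted (downward) so an
    integer number of cells spans the midline exactly.  The default 0.025 mm
    resolves the shortest physical wavelength the partition supports (the
    BM's longitudinal bending cutoff, ~0.1 mm at the base).
    """

    dx: float = 0.025  # mm

    def __post_init__(self) -> None:
        if not 0.0 < self.dx <= 0.5:
            raise ValueError(f"dx={self.dx} must lie in (0, 0.5] mm")

    def n_nodes(self, length: float) -> int:
        n_cells = int(np.ceil(length / self.dx - 1e-9))
        if n_cells < 50:
            raise ValueError(
                f"grid too coarse: L/dx = {length / self.dx:.1f} < 50"
            )
        return n_cells + 1


@dataclass(frozen=True)
class CochlearGeometry:
    """Discretized two-duct cochlea on the (uncoiled) BM midline.

    ``x_grid`` runs from the base (x=0) to the apex (x=L) in mm; all profile
    arrays are nodal.  ``spiral`` is the centerline *after* scaling to L, so
    arc length along it and distance along ``x_grid`` agree.
    """

    L: float
    x_grid: np.ndarray
    thickness: np.ndarray  # um
    width: np.ndarray  # mm
    area_sv: np.ndarray  # mm^2, scala vestibuli + media
    area_st: np.ndarray  # mm^2, scala tympani
    spiral: SpiralSpec
    angle: np.ndarray = field(repr=False)  # degrees, angle_of_x at nodes

    @property
    def dx(self) -> float:
        return float(self.x_grid[1] - self.x_grid[0])

    @property
    def n_nodes(self) -> int:
        return self.x_grid.size

    def angle_of_x(self, x: float) -> float:
        """Insertion angle (deg) reached at midline position ``x`` (mm)."""
        return arclength_to_angle(self.spiral, x)

    def x_of_angle(self, theta: float) -> float:
        """Midline position (mm) reached at insertion angle ``theta`` (deg)."""
        return angle_to_arclength(self.spiral, theta)


def _linear_profile(x: np.ndarray, base: float, apex: float, L: float) -> np.ndarray:
    return base + (apex - base) * (x / L)


_PROFILE_KINDS = ("linear", "exponential")


def _taper(x: np.ndarray, base: float, apex: float, L: float, kind: str) -> np.ndarray:
    if kind == "linear":
        return _linear_profile(x, base, apex, L)
    if kind == "exponential":
        return base * (apex / base) ** (x / L)
    raise ValueError(f"unknown profile kind {kind!r}; choose from {_PROFILE_KINDS}")


def build_geometry(
    *,
    length: float = 18.3,
    spiral: SpiralSpec | None = None,
    grid: GridSpec | None = None,
    thickness_base: float = 16.5,
    thickness_apex: float = 5.0,
    thickness_profile: str = "linear",
    width_base: float = 0.08,
    width_apex: float = 0.25,
    area_sv_base: float = 1.1,
    area_sv_apex: float = 0.35,
    area_st_base: float = 1.1,
    area_st_apex: float = 0.35,
) -> CochlearGeometry:
    """Build and scale the parametric cochlea.

    The spiral centerline is built at its nominal size, then every length is
    multiplied by a single factor so the midline is exactly ``length`` mm.
    Dimension profiles are functions of relative position x/L and are
    therefore independent of the pre-scale spiral size.

    The width and duct-area defaults are calibrated stand-ins, not measured
    values: widths are set so the basal characteristic frequency lands in
    the chinchilla's upper audible range (~29 kHz) and the tuning map tracks
    the species' Greenwood function; duct areas follow chinchilla scala
    cross-section scale.  Both are plain keyword overrides for sensitivity
    runs.
    """
    spiral = spiral or SpiralSpec()
    grid = grid or GridSpec()
    for name, val in [
        ("length", length),
        ("thickness_base", thickness_base),
        ("thickness_apex", thickness_apex),
        ("width_base", width_base),
        ("width_apex", width_apex),
        ("area_sv_base", area_sv_base),
        ("area_sv_apex", area_sv_apex),
        ("area_st_base", area_st_base),
        ("area_st_apex", area_st_apex),
    ]:
        if val <= 0:
            raise ValueError(f"{name}={val} must be > 0")
    if thickness_apex > thickness_base:
        raise ValueError("thickness_apex must not exceed thickness_base")

    raw_len = spiral.total_arclength()
    scale = length / raw_len
    scaled_spiral = replace(spiral, basal_radius=spiral.basal_radius * scale)

    n = grid.n_nodes(length)
    x = np.linspace(0.0, length, n)
    t = _taper(x, thickness_base, thickness_apex, length, thickness_profile)
    w = _linear_profile(x, width_base, width_apex, length)
    a_sv = _linear_profile(x, area_sv_base, area_sv_apex, length)
    a_st = _linear_profile(x, area_st_base, area_st_apex, length)
    ang = np.array([arclength_to_angle(scaled_spiral, xi) for xi in x])
    return CochlearGeometry(
        L=length,
        x_grid=x,
        thickness=t,
        width=w,
        area_sv=a_sv,
        area_st=a_st,
        spiral=scaled_spiral,
        angle=ang,
    )


def thickness_at(geom: CochlearGeometry, x: float) -> float:
    """BM thickness (um) at midline position ``x`` (mm), interpolated."""
    if not 0.0 <= x <= geom.L:
        raise ValueError(f"x={x} mm outside [0, {geom.L}]")
    return float(np.interp(x, geom.x_grid, geom.thickness))


# ---------------------------------------------------------------------------
# export


def geometry_to_frame(geom: CochlearGeometry) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_mm": geom.x_grid,
            "thickness_um": geom.thickness,
            "width_mm": geom.width,
            "A_sv_mm2": geom.area_sv,
            "A_st_mm2": geom.area_st,
            "angle_deg": geom.angle,
        }
    )


def export_csv(geom: CochlearGeometry, path: str) -> None:
    geometry_to_frame(geom).to_csv(path, index=False, float_format="%.10g")


def export_vtk(geom: CochlearGeometry, path: str) -> None:
    """Write the coiled centerline as a legacy-VTK ASCII polyline.

    Point data carries the nodal profiles so the coil can be inspected in any
    VTK viewer.  The centerline is embedded in the z=0 plane.
    """
    th = np.deg2rad(geom.angle)
    r = geom.spiral.radius(th)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros_like(th)])
    n = len(pts)
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\ncochlear centerline\nASCII\n")
    buf.write("DATASET POLYDATA\n")
    buf.write(f"POINTS {n} double\n")
    for p in pts:
        buf.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    buf.write(f"LINES 1 {n + 1}\n")
    buf.write(" ".join([str(n)] + [str(i) for i in range(n)]) + "\n")
    buf.write(f"POINT_DATA {n}\n")
    for name, arr in [
        ("thickness_um", geom.thickness),
        ("width_mm", geom.width),
        ("A_sv_mm2", geom.area_sv),
        ("A_st_mm2", geom.area_st),
        ("angle_deg", geom.angle),
    ]:
        buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        buf.write("\n".join(f"{v:.10g}" for v in arr) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
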