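"""Material constants and graded laws of the inner-ear model.

Every structure of the mechanical model carries its density, elastic modulus
and stiffness-proportional Rayleigh damping coefficient beta; the basilar
membrane (BM) and Reissner's membrane (RM) have position-dependent moduli and
damping, graded along the cochlear midline.  In a harmonic analysis beta
enters as a complex modulus E*(1 + i*omega*beta).

The positional argument x of the graded laws is the midline distance from the
base in **millimetres**: with an 18.3 mm BM this gives a ~47x basal-to-apical
modulus gradient, the physiologically meaningful reading of the exponents.

Vestibular constants (cupulae, maculae, membranous labyrinth) are carried for
completeness but no vestibular mechanics is solved; bone is likewise carried
although the bony walls are treated as rigid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import CochlearGeometry

__all__ = [
    "Isotropic",
    "GradedMembrane",
    "Fluid",
    "MaterialTable",
    "PartitionImpedanceParams",
    "bm_modulus",
    "bm_damping",
    "rm_modulus",
    "rm_damping",
    "partition_params",
    "material_frame",
    "BONE_MODULUS_ALT_PA",
    "DEFAULT_PLATE_CONSTANT",
]

#: Alternative bone modulus (14.1 GPa) that circulates alongside the tabulated
#: 13.4e10 Pa; both are recorded, neither enters the solved system because the
#: bony walls are rigid.
BONE_MODULUS_ALT_PA = 14.1e9

#: Plate constant of the clamped-strip reduction, see :func:`partition_params`.
DEFAULT_PLATE_CONSTANT = 60.0

#: Floor (mm) applied to the RM modulus law 1e4*x, which is zero at the base.
RM_MODULUS_FLOOR_MM = 0.1


def bm_modulus(x: float | np.ndarray) -> float | np.ndarray:
    """BM elastic modulus, Pa: 7.1e4 * exp(-0.21 x), x in mm from the base."""
    x = _check_x(x)
    return 7.1e4 * np.exp(-0.21 * x)


def bm_damping(x: float | np.ndarray) -> float | np.ndarray:
    """BM Rayleigh beta coefficient, s: 2.3e-8 * exp(0.52 x), x in mm."""
    x = _check_x(x)
    return 2.3e-8 * np.exp(0.52 * x)


def rm_modulus(x: float | np.ndarray) -> float | np.ndarray:
    """RM elastic modulus, Pa: 1e4 * x with x floored at 0.1 mm."""
    x = _check_x(x)
    return 1.0e4 * np.maximum(x, RM_MODULUS_FLOOR_MM)


def rm_damping(x: float | np.ndarray) -> float | np.ndarray:
    """RM Rayleigh beta coefficient, s: 6e-6 * exp(0.158 x), x in mm."""
    x = _check_x(x)
    return 6.0e-6 * np.exp(0.158 * x)


def _check_x(x):
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0 (mm from the base)")
    out = x if x.ndim else float(x)
    return out


@dataclass(frozen=True)
class Isotropic:
    """Homogeneous solid: density (kg/m^3), modulus E (Pa), damping beta (s)."""

    density: float
    E: float
    beta: float = 0.0


@dataclass(frozen=True)
class GradedMembrane:
    """Membrane with position-dependent modulus and damping laws (x in mm)."""

    density: float
    E: Callable[[float], float]
    beta: Callable[[float], float]
    poisson: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.poisson < 0.5:
            raise ValueError(f"poisson={self.poisson} must lie in (0, 0.5)")


@dataclass(frozen=True)
class Fluid:
    """Lymphatic fluid (endolymph and perilymph treated as identical)."""

    density: float = 1.0e3
    bulk_modulus: float = 2.6e9  # tabulated as an elastic modulus, Pa
    beta: float = 1.5e-4
    viscosity: float = 1.0e-3  # Pa s
    speed_of_sound: float = 1498.0  # m/s

    def consistency_ratio(self) -> float:
        """sqrt(K/rho) relative to the tabulated speed of sound."""
        return float(np.sqrt(self.bulk_modulus / self.density) / self.speed_of_sound)


@dataclass(frozen=True)
class MaterialTable:
    """All material constants of the model, keyed by structure.

    The tabulated fluid bulk modulus and speed of sound are mutually
    inconsistent at the tabulated density (sqrt(2.6e9/1e3) = 1612 m/s vs the
    printed 1498 m/s); construction surfaces this as a warning and the solver
    takes the speed of sound as primary.
    """

    bm: GradedMembrane = field(
        default_factory=lambda: GradedMembrane(1.0e3, bm_modulus, bm_damping, 0.4)
    )
    rm: GradedMembrane = field(
        default_factory=lambda: GradedMembrane(1.0e3, rm_modulus, rm_damping, 0.4)
    )
    fluid: Fluid = field(default_factory=Fluid)
    owm: Isotropic = field(default_factory=lambda: Isotropic(1.0e3, 3.5e5, 5.0e-4))
    rwm: Isotropic = field(default_factory=lambda: Isotropic(1.5e3, 3.5e5, 5.0e-4))
    electrode: Isotropic = field(default_factory=lambda: Isotropic(3.4e3, 4.0e5, 7.7e-2))
    bone: Isotropic = field(default_factory=lambda: Isotropic(1.2e3, 13.4e10, 0.45))
    cupula: Isotropic = field(default_factory=lambda: Isotropic(1.0e3, 2.8))
    macula_gel: Isotropic = field(default_factory=lambda: Isotropic(1.0e3, 10.0))
    macula_otoconial: Isotropic = field(default_factory=lambda: Isotropic(2.71e3, 500.0))
    membranous_labyrinth: Isotropic = field(
        default_factory=lambda: Isotropic(1.0e3, 1.3e4, 0.14)
    )

    def __post_init__(self) -> None:
        for name in (
            "owm", "rwm", "electrode", "bone", "cupula",
            "macula_gel", "macula_otoconial", "membranous_labyrinth",
        ):
            s: Isotropic = getattr(self, name)
            if s.density <= 0 or s.E <= 0:
                raise ValueError(f"{name}: density and modulus must be > 0")
        ratio = self.fluid.consistency_ratio()
        if abs(ratio - 1.0) > 0.02:
            warnings.warn(
                "fluid bulk modulus and speed of sound are inconsistent: "
                f"sqrt(K/rho) = {ratio:.3f} x the tabulated c; the solver uses "
                "the speed of sound as primary",
                stacklevel=2,
            )

    @classmethod
    def default(cls) -> "MaterialTable":
        with warnings.catch_warnings():
            # the stock table is knowingly inconsistent; warn only on custom tables
            warnings.simplefilter("ignore")
            return cls()


@dataclass(frozen=True)
class PartitionImpedanceParams:
    """Locally reacting partition parameters on the geometry grid.

    ``stiffness`` K(x) is the trans-partition pressure per unit mean
    deflection (Pa/m), ``mass`` m(x) the BM mass per unit area (kg/m^2);
    ``beta`` the Rayleigh damping coefficient (s).  The complex stiffness at
    angular frequency omega is K*(1 + i*omega*beta).
    """

    x_grid: np.ndarray  # mm, shared with the geometry
    stiffness: np.ndarray  # Pa/m
    mass: np.ndarray  # kg/m^2
    beta: np.ndarray  # s
    plate_constant: float

    def impedance(self, omega: float) -> np.ndarray:
        """Partition impedance per unit area Z_p(x, omega), Pa s/m."""
        k_complex = self.stiffness * (1.0 + 1j * omega * self.beta)
        return (k_complex - omega**2 * self.mass) / (1j * omega)


def partition_params(
    geom: CochlearGeometry,
    mat: MaterialTable,
    plate_constant: float = DEFAULT_PLATE_CONSTANT,
) -> PartitionImpedanceParams:
    """Reduce the graded elastic BM to per-position partition parameters.

    The BM strip of width w and thickness t, clamped at both edges and loaded
    by a uniform trans-partition pressure, deflects with mean value
    q*w^4/(720*D), D = E*t^3/(12*(1-nu^2)).  Defining stiffness against the
    mean deflection (the quantity that carries volume velocity in a
    transmission-line model) gives

        K(x) = C * E(x) * t(x)^3 / ((1 - nu^2) * w(x)^4),   C = 720/12 = 60.

    ``plate_constant`` C is exposed for sensitivity studies (e.g. 32 for the
    midpoint-deflection convention, 16/3 for a simply-supported strip).
    """
    if plate_constant <= 0:
        raise ValueError("plate_constant must be > 0")
    t_m = geom.thickness * 1e-6
    w_m = geom.width * 1e-3
    e_pa = np.asarray(mat.bm.E(geom.x_grid), float)
    nu = mat.bm.poisson
    stiffness = plate_constant * e_pa * t_m**3 / ((1.0 - nu**2) * w_m**4)
    mass = mat.bm.density * t_m
    beta = np.asarray(mat.bm.beta(geom.x_grid), float)
    return PartitionImpedanceParams(
        x_grid=geom.x_grid,
        stiffness=stiffness,
        mass=mass,
        beta=beta,
        plate_constant=plate_constant,
    )


def material_frame(mat: MaterialTable) -> pd.DataFrame:
    """Flat audit table (structure, parameter, value) mirroring the model table.

    Graded laws are reported by their basal (x=0) value with the law spelled
    out in the ``law`` column.
    """
    rows: list[tuple[str, str, float, str]] = []

    def iso(name: str, s: Isotropic) -> None:
        rows.append((name, "density_kg_m3", s.density, ""))
        rows.append((name, "elastic_modulus_Pa", s.E, ""))
        rows.append((name, "beta_damping", s.beta, ""))

    rows.append(("basilar_membrane", "density_kg_m3", mat.bm.density, ""))
    rows.append(("basilar_membrane", "elastic_modulus_Pa", float(mat.bm.E(0.0)),
                 "7.1e4*exp(-0.21*x_mm)"))
    rows.append(("basilar_membrane", "beta_damping", float(mat.bm.beta(0.0)),
                 "2.3e-8*exp(0.52*x_mm)"))
    rows.append(("basilar_membrane", "poisson_ratio", mat.bm.poisson, ""))
    rows.append(("reissners_membrane", "density_kg_m3", mat.rm.density, ""))
    rows.append(("reissners_membrane", "elastic_modulus_Pa",
                 float(mat.rm.E(1.0)), "1e4*x_mm (floored at 0.1 mm)"))
    rows.append(("reissners_membrane", "beta_damping", float(mat.rm.beta(0.0)),
                 "6e-6*exp(0.158*x_mm)"))
    rows.append(("reissners_membrane", "poisson_ratio", mat.rm.poisson, ""))
    rows.append(("lymphatic_fluid", "density_kg_m3", mat.fluid.density, ""))
    rows.append(("lymphatic_fluid", "elastic_modulus_Pa", mat.fluid.bulk_modulus, ""))
    rows.append(("lymphatic_fluid", "beta_damping", mat.fluid.beta, ""))
    rows.append(("lymphatic_fluid", "viscosity_Pa_s", mat.fluid.viscosity, ""))
    rows.append(("lymphatic_fluid", "speed_of_sound_m_s", mat.fluid.speed_of_sound, ""))
    iso("oval_window_membrane", mat.owm)
    iso("round_window_membrane", mat.rwm)
    iso("cochlear_implant", mat.electrode)
    iso("bone", mat.bone)
    iso("cupula", mat.cupula)
    iso("macula_gel", mat.macula_gel)
    iso("macula_otoconial", mat.macula_otoconial)
    iso("membranous_labyrinth", mat.membranous_labyrinth)
    return pd.DataFrame(rows, columns=["structure", "parameter", "value", "law"])
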