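"""Run configuration: YAML schema, validation, and object construction.

A run config is a nested mapping with blocks ``geometry``, ``materials``,
``electrode``, ``stimulus``, ``solver``, ``analysis`` and ``output``.  Every
key has a default; unknown keys are rejected so typos cannot silently fall
back to defaults.  ``RunConfig.load`` records the file's SHA-256 so outputs
can be traced to the exact configuration.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .analysis import GreenwoodMap
from .electrode import DEFAULT_SWEEP_ANGLES, ElectrodeSpec
from .geometry import CochlearGeometry, GridSpec, SpiralSpec, build_geometry
from .materials import (
    DEFAULT_PLATE_CONSTANT,
    Fluid,
    GradedMembrane,
    Isotropic,
    MaterialTable,
)
from .solver import DEFAULT_FREQUENCIES_HZ, SolverSettings, StimulusSpec

__all__ = ["ConfigError", "RunConfig", "default_config_dict"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def default_config_dict() -> dict[str, Any]:
    """The full default configuration as a plain mapping (YAML-serializable)."""
    return {
        "geometry": {
            "length_mm": 18.3,
            "spiral": {
                "total_angle_deg": 1080.0,
                "basal_radius_mm": 2.0,
                "taper_rate": 0.08,
                "form": "log",
            },
            "grid": {"dx_mm": 0.025},
            "thickness_um": {"base": 16.5, "apex": 5.0, "profile": "linear"},
            "width_mm": {"base": 0.08, "apex": 0.25},
            "area_sv_mm2": {"base": 1.1, "apex": 0.35},
            "area_st_mm2": {"base": 1.1, "apex": 0.35},
        },
        "materials": {
            "plate_constant": DEFAULT_PLATE_CONSTANT,
            "bm": {
                "density": 1.0e3,
                "poisson": 0.4,
                "modulus_prefactor_Pa": 7.1e4,
                "modulus_rate_per_mm": -0.21,
                "beta_prefactor_s": 2.3e-8,
                "beta_rate_per_mm": 0.52,
            },
            "fluid": {
                "density": 1.0e3,
                "bulk_modulus_Pa": 2.6e9,
                "beta": 1.5e-4,
                "viscosity_Pa_s": 1.0e-3,
                "speed_of_sound_m_s": 1498.0,
            },
            "electrode": {"density": 3.4e3, "E": 4.0e5, "beta": 7.7e-2},
        },
        "electrode": {
            "insertion_angle_deg": 900.0,
            "basal_diameter_mm": 0.55,
            "apical_diameter_mm": 0.25,
            "section_size_deg": 180.0,
            "coupling": "occlusion",
            "sweep_angles_deg": list(DEFAULT_SWEEP_ANGLES),
        },
        "stimulus": {
            "frequencies_hz": list(DEFAULT_FREQUENCIES_HZ),
            "stapes_displacement_m": 1.0e-8,
            "level_db": 90.0,
            "stapes_area_mm2": 0.8,
        },
        "solver": {
            "formulation": "incompressible",
            "longitudinal_coupling": True,
            "viscous_walls": True,
            "helicotrema": "matched",
            "tolerance": 1.0e-10,
        },
        "analysis": {
            "smooth_window_mm": 0.2,
            "greenwood": {
                "species": "chinchilla",
                "A": 163.5,
                "a": 2.1,
                "k": 0.85,
            },
            "thresholds": {"location_shift_mm": 0.1, "magnitude_db": 3.0},
        },
        "output": {"directory": "runs/latest"},
    }


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with constructors for every model object."""

    data: dict[str, Any]
    source_path: str | None = None
    checksum: str | None = None
    warnings_: tuple[str, ...] = field(default=(), repr=False)

    @classmethod
    def from_dict(cls, raw: dict[str, Any] | None, source_path: str | None = None,
                  checksum: str | None = None) -> "RunConfig":
        raw = raw or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        merged = _merge(default_config_dict(), raw)
        cfg = cls(merged, source_path, checksum)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        checksum = hashlib.sha256(text.encode()).hexdigest()
        return cls.from_dict(raw, str(path), checksum)

    # -- constructors -------------------------------------------------------

    def validate(self) -> None:
        """Build every object once; any inconsistency raises ConfigError."""
        try:
            geom = self.geometry()
            self.materials()
            spec = self.electrode_spec()
            if spec.insertion_angle > geom.spiral.total_angle:
                raise ValueError(
                    "electrode insertion angle exceeds the spiral's total angle"
                )
            self.stimulus()
            self.solver_settings()
            self.greenwood()
            thr = self.data["analysis"]["thresholds"]
            if thr["location_shift_mm"] <= 0 or thr["magnitude_db"] <= 0:
                raise ValueError("analysis thresholds must be positive")
            if self.data["analysis"]["smooth_window_mm"] < geom.dx:
                raise ValueError("smooth_window_mm must be >= the grid step")
        except ConfigError:
            raise
        except (ValueError, TypeError, KeyError) as exc:
            raise ConfigError(str(exc)) from exc

    def geometry(self) -> CochlearGeometry:
        g = self.data["geometry"]
        spiral = SpiralSpec(
            total_angle=float(g["spiral"]["total_angle_deg"]),
            basal_radius=float(g["spiral"]["basal_radius_mm"]),
            taper_rate=float(g["spiral"]["taper_rate"]),
            form=str(g["spiral"]["form"]),
        )
        return build_geometry(
            length=float(g["length_mm"]),
            spiral=spiral,
            grid=GridSpec(dx=float(g["grid"]["dx_mm"])),
            thickness_base=float(g["thickness_um"]["base"]),
            thickness_apex=float(g["thickness_um"]["apex"]),
            thickness_profile=str(g["thickness_um"]["profile"]),
            width_base=float(g["width_mm"]["base"]),
            width_apex=float(g["width_mm"]["apex"]),
            area_sv_base=float(g["area_sv_mm2"]["base"]),
            area_sv_apex=float(g["area_sv_mm2"]["apex"]),
            area_st_base=float(g["area_st_mm2"]["base"]),
            area_st_apex=float(g["area_st_mm2"]["apex"]),
        )

    def materials(self) -> MaterialTable:
        m = self.data["materials"]
        bm = m["bm"]
        e0, er = float(bm["modulus_prefactor_Pa"]), float(bm["modulus_rate_per_mm"])
        b0, br = float(bm["beta_prefactor_s"]), float(bm["beta_rate_per_mm"])

        def bm_e(x):
            return e0 * np.exp(er * np.asarray(x, float))

        def bm_b(x):
            return b0 * np.exp(br * np.asarray(x, float))

        fluid = Fluid(
            density=float(m["fluid"]["density"]),
            bulk_modulus=float(m["fluid"]["bulk_modulus_Pa"]),
            beta=float(m["fluid"]["beta"]),
            viscosity=float(m["fluid"]["viscosity_Pa_s"]),
            speed_of_sound=float(m["fluid"]["speed_of_sound_m_s"]),
        )
        electrode = Isotropic(
            density=float(m["electrode"]["density"]),
            E=float(m["electrode"]["E"]),
            beta=float(m["electrode"]["beta"]),
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = MaterialTable(
                bm=GradedMembrane(
                    density=float(bm["density"]),
                    E=bm_e,
                    beta=bm_b,
                    poisson=float(bm["poisson"]),
                ),
                fluid=fluid,
                electrode=electrode,
            )
        object.__setattr__(
            self, "warnings_", tuple(str(w.message) for w in caught)
        )
        return table

    def plate_constant(self) -> float:
        return float(self.data["materials"]["plate_constant"])

    def electrode_spec(self, insertion_angle: float | None = None) -> ElectrodeSpec:
        e = self.data["electrode"]
        return ElectrodeSpec(
            insertion_angle=(
                float(e["insertion_angle_deg"])
                if insertion_angle is None
                else float(insertion_angle)
            ),
            basal_diameter=float(e["basal_diameter_mm"]),
            apical_diameter=float(e["apical_diameter_mm"]),
            section_size=float(e["section_size_deg"]),
            coupling=str(e["coupling"]),
        )

    def sweep_angles(self) -> tuple[float, ...]:
        return tuple(float(a) for a in self.data["electrode"]["sweep_angles_deg"])

    def stimulus(self) -> StimulusSpec:
        s = self.data["stimulus"]
        amp = s["stapes_displacement_m"]
        if isinstance(amp, dict):
            amp = {float(k): float(v) for k, v in amp.items()}
        else:
            amp = float(amp)
        return StimulusSpec(
            frequencies=tuple(sorted(float(f) for f in s["frequencies_hz"])),
            stapes_displacement=amp,
            level_db=float(s["level_db"]),
            stapes_area=float(s["stapes_area_mm2"]),
        )

    def solver_settings(self) -> SolverSettings:
        s = self.data["solver"]
        heli = s["helicotrema"]
        if isinstance(heli, dict):
            heli = complex(float(heli["re"]), float(heli["im"]))
        return SolverSettings(
            formulation=str(s["formulation"]),
            longitudinal_coupling=bool(s["longitudinal_coupling"]),
            viscous_walls=bool(s["viscous_walls"]),
            helicotrema=heli,
            tolerance=float(s["tolerance"]),
            plate_constant=self.plate_constant(),
        )

    def greenwood(self) -> GreenwoodMap:
        g = self.data["analysis"]["greenwood"]
        return GreenwoodMap(
            A=float(g["A"]),
            a=float(g["a"]),
            k=float(g["k"]),
            length=float(self.data["geometry"]["length_mm"]),
            species=str(g["species"]),
        )

    def smooth_window(self) -> float:
        return float(self.data["analysis"]["smooth_window_mm"])

    def thresholds(self) -> tuple[float, float]:
        t = self.data["analysis"]["thresholds"]
        return float(t["location_shift_mm"]), float(t["magnitude_db"])

    def output_dir(self) -> str:
        return str(self.data["output"]["directory"])

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True, default_flow_style=False)
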