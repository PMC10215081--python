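"""Frequency-domain two-duct cochlear solver.

The three-chambered cochlea is reduced to a classical two-duct transmission
line: scala vestibuli and scala media are lumped into one fluid duct above
the basilar membrane (BM), the scala tympani forms the duct below, and the
BM couples them.  For the trans-partition pressure p(x) = p_sv - p_st and
the BM displacement d(x) (taken toward the scala tympani) at angular
frequency omega, volume-velocity conservation and momentum balance give

    dp/dx = -Z'(x) U(x),        dU/dx = -i*omega*w(x)*d(x) - Y_x(x) p(x),

with series impedance per unit length

    Z'(x) = i*omega*rho*(1/A_sv + 1/A_st_eff)  [+ viscous wall drag],

A_st_eff = A_st*(1 - phi) under electrode occlusion, and extra shunt paths
Y_x collecting the electrode compliance branch and (in the acoustic
formulation) fluid-column compressibility.  The partition obeys a graded
plate-strip equation that retains the BM's longitudinal bending stiffness,

    [K(x)(1 + i*omega*beta) - omega^2 m(x)] d
        + (1/w) d^2/dx^2 [ D(x) w (1 + i*omega*beta) d^2 d/dx^2 ] = p,

with K(x) the clamped-strip stiffness per unit area and D = E t^3/(12(1-nu^2))
the flexural rigidity per unit width.  The bending term imposes a physical
short-wavelength cutoff (lambda_c ~ 1.2 w); without it the locally reacting
partition, whose basal damping is very light, supports arbitrarily short
waves at the characteristic place.  The traveling wave slows and peaks just
basal of the local resonance, which migrates apically as frequency falls —
the tonotopic map.

Viscous drag of the oscillatory fluid on the duct walls (Stokes boundary
layer of the tabulated viscosity) adds (1+i)*sqrt(omega*rho*mu/2)*P/A^2 per
duct to Z', with P the wetted perimeter.

Boundary conditions: the stapes footplate prescribes an oval-window volume
velocity U_s = i*omega*u_s*A_fp at the base (the round window provides the
pressure release that closes the fluid circuit) and the apex is terminated
by a helicotrema impedance, by default matched to the local characteristic
impedance sqrt(Z'/Y') so the residual wave is absorbed.  The BM strip has
free (natural) ends.

Discretization is a second-order finite-volume scheme for the fluid line
plus a variational stencil for the bending operator; the sparse complex
block system is solved directly.  The scheme conserves discrete power:
stapes input equals partition + electrode + viscous + helicotrema
dissipation to solver precision.

Sign convention: positive BM displacement u = -d points toward the scala
vestibuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrode import OcclusionProfile
from .geometry import CochlearGeometry
from .materials import MaterialTable, PartitionImpedanceParams, partition_params

__all__ = [
    "StimulusSpec",
    "SolverSettings",
    "SolveDiagnostics",
    "BMResponse",
    "assemble_system",
    "solve_harmonic",
    "DEFAULT_FREQUENCIES_HZ",
]

DEFAULT_FREQUENCIES_HZ = (400.0, 1000.0, 2000.0, 4000.0, 6000.0, 8000.0, 10000.0)

MM = 1e-3
MM2 = 1e-6
UM = 1e-6


@dataclass(frozen=True)
class StimulusSpec:
    """Stapes-footplate displacement drive.

    ``stapes_displacement`` is either a single amplitude (m) applied at every
    frequency or a mapping frequency -> amplitude; the default flat 10 nm
    stands in for a measured 90 dB SPL stapes table — every reported output
    is normalized by the stapes displacement, so the absolute level cancels.
    """

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    stapes_displacement: float | Mapping[float, float] = 1.0e-8  # m
    level_db: float = 90.0
    stapes_area: float = 0.8  # mm^2, footplate

    def __post_init__(self) -> None:
        f = tuple(float(v) for v in self.frequencies)
        if len(f) == 0:
            raise ValueError("stimulus needs at least one frequency")
        if any(v <= 0 for v in f):
            raise ValueError("frequencies must be positive")
        if list(f) != sorted(f):
            raise ValueError("frequencies must be sorted ascending")
        object.__setattr__(self, "frequencies", f)
        if self.stapes_area <= 0:
            raise ValueError("stapes_area must be > 0")
        for amp in self.amplitudes():
            if amp <= 0:
                raise ValueError("stapes displacement amplitudes must be > 0")

    def amplitude(self, f: float) -> float:
        if isinstance(self.stapes_displacement, Mapping):
            try:
                return float(self.stapes_displacement[f])
            except KeyError:
                raise KeyError(f"no stapes amplitude configured for {f} Hz") from None
        return float(self.stapes_displacement)

    def amplitudes(self) -> np.ndarray:
        return np.array([self.amplitude(f) for f in self.frequencies])


@dataclass(frozen=True)
class SolverSettings:
    """Numerical and formulation settings of the harmonic solve.

    ``formulation``: ``"incompressible"`` (long-wave, default) or
    ``"acoustic"`` (adds the fluid-column compressibility term with the
    tabulated speed of sound).  ``longitudinal_coupling`` retains the BM's
    longitudinal bending stiffness (default on; switching it off recovers
    the locally reacting transmission line, whose assembled system is purely
    tridiagonal).  ``viscous_walls`` adds the Stokes-layer drag of the duct
    walls.  ``helicotrema`` is ``"matched"`` or a complex impedance in
    Pa s/m^3.  ``tolerance`` bounds the relative residual of the linear
    solve.
    """

    formulation: str = "incompressible"
    longitudinal_coupling: bool = True
    viscous_walls: bool = True
    helicotrema: "str | complex" = "matched"
    tolerance: float = 1.0e-10
    plate_constant: float | None = None  # forwarded to partition_params
    estimate_condition: bool = False

    def __post_init__(self) -> None:
        if self.formulation not in ("incompressible", "acoustic"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if not 0.0 < self.tolerance <= 1.0e-6:
            raise ValueError("tolerance must lie in (0, 1e-6]")
        if isinstance(self.helicotrema, str) and self.helicotrema != "matched":
            raise ValueError("helicotrema must be 'matched' or a complex impedance")


@dataclass(frozen=True)
class SolveDiagnostics:
    frequency: float
    residual: float
    power_input: float
    power_partition: float
    power_electrode: float
    power_viscous: float
    power_helicotrema: float
    condition_estimate: float | None = None

    @property
    def power_balance_error(self) -> float:
        """Relative mismatch of stapes input vs total dissipated power."""
        out = (
            self.power_partition
            + self.power_electrode
            + self.power_viscous
            + self.power_helicotrema
        )
        return abs(self.power_input - out) / abs(self.power_input)


@dataclass(frozen=True)
class BMResponse:
    """Complex BM displacement u(x) per stimulus frequency.

    ``u`` has shape (n_frequencies, n_nodes), in metres, positive toward the
    scala vestibuli; ``stapes_displacement`` holds the drive amplitude used
    at each frequency.
    """

    frequencies: np.ndarray
    x_grid: np.ndarray  # mm
    u: np.ndarray  # complex, (n_f, n_x)
    stapes_displacement: np.ndarray  # m, per frequency
    diagnostics: tuple[SolveDiagnostics, ...] = field(repr=False, default=())

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies

    def magnitude(self) -> np.ndarray:
        return np.abs(self.u)


def _series_impedance(geom, occ, omega, mat, settings):
    """Z'(x) per unit length, Pa s/m^4, including optional wall viscosity."""
    rho = mat.fluid.density
    a_sv = geom.area_sv * MM2
    a_st = geom.area_st * MM2
    phi = occ.phi if occ is not None else np.zeros_like(a_st)
    a_st_eff = a_st * (1.0 - phi)
    z = 1j * omega * rho * (1.0 / a_sv + 1.0 / a_st_eff)
    if settings.viscous_walls:
        mu = mat.fluid.viscosity
        z_surf = (1.0 + 1j) * np.sqrt(omega * rho * mu / 2.0)
        # circular-equivalent wetted perimeters of the two ducts
        p_sv = 2.0 * np.sqrt(np.pi * a_sv)
        p_st = 2.0 * np.sqrt(np.pi * a_st_eff)
        z = z + z_surf * (p_sv / a_sv**2 + p_st / a_st_eff**2)
    return z, a_sv, a_st_eff


def _extra_shunt(geom, occ, omega, mat, settings, a_sv, a_st_eff):
    """Shunt admittance per unit length that is NOT the partition branch."""
    y = np.zeros(geom.n_nodes, dtype=complex)
    if occ is not None:
        e_mat = occ.material
        # compliant branch of the electrode body: volume compliance per unit
        # length a_e/E with the silicone loss factor omega*beta
        c_e = (occ.electrode_area * MM2) / e_mat.E
        y = y + 1j * omega * c_e / (1.0 + 1j * omega * e_mat.beta)
    if settings.formulation == "acoustic":
        c = mat.fluid.speed_of_sound
        a_h = 2.0 / (1.0 / a_sv + 1.0 / a_st_eff)
        y = y + 1j * omega * a_h / (2.0 * mat.fluid.density * c**2)
    return y


def assemble_system(
    geom: CochlearGeometry,
    params: PartitionImpedanceParams,
    occ: OcclusionProfile | None,
    frequency: float,
    settings: SolverSettings | None = None,
    mat: MaterialTable | None = None,
    stim: StimulusSpec | None = None,
):
    """Assemble the sparse complex system for one frequency.

    Returns ``(A, b, aux)``.  Without longitudinal coupling the unknowns are
    the nodal pressures p and ``A`` is symmetric tridiagonal; with coupling
    (the default) the unknown vector is ``[p; d]`` and ``A`` is a 2x2 block
    matrix pairing the fluid line with the bending-plate partition rows.

    Finite-volume fluid balance at interior node i:

        g_{i-1/2}(p_i - p_{i-1}) + g_{i+1/2}(p_i - p_{i+1})
            + dx*(i*omega*w_i*d_i + Y_x,i*p_i) = 0,

    g = 1/(Z' dx) at faces; the basal half-cell receives the stapes volume
    velocity, the apical half-cell drains into the helicotrema impedance.
    """
    settings = settings or SolverSettings()
    mat = mat or MaterialTable.default()
    stim = stim or StimulusSpec()
    if geom.x_grid.shape != params.x_grid.shape or not np.allclose(
        geom.x_grid, params.x_grid
    ):
        raise ValueError("geometry and partition parameters use different grids")
    if occ is not None and occ.x_grid.shape != geom.x_grid.shape:
        raise ValueError("occlusion profile grid does not match the geometry")

    omega = 2.0 * np.pi * frequency
    n = geom.n_nodes
    dx = geom.dx * MM
    w = geom.width * MM

    z_series, a_sv, a_st_eff = _series_impedance(geom, occ, omega, mat, settings)
    y_extra = _extra_shunt(geom, occ, omega, mat, settings, a_sv, a_st_eff)
    z_face = 0.5 * (z_series[:-1] + z_series[1:])
    g = 1.0 / (z_face * dx)

    k_complex = params.stiffness * (1.0 + 1j * omega * params.beta)
    z_p = (k_complex - omega**2 * params.mass) / (1j * omega)
    added_mass = occ.added_mass if occ is not None else 0.0
    partition_scalar = k_complex - omega**2 * (params.mass + added_mass)

    if isinstance(settings.helicotrema, str):  # matched termination
        z_h = complex(np.sqrt(z_series[-1] / (w[-1] / z_p[-1] + y_extra[-1])))
    else:
        z_h = complex(settings.helicotrema)

    cell = np.full(n, dx)
    cell[0] = cell[-1] = 0.5 * dx

    diag = cell * y_extra
    diag[:-1] += g
    diag[1:] += g
    diag[-1] += 1.0 / z_h

    u_s = 1j * omega * stim.amplitude(frequency) * (stim.stapes_area * MM2)

    aux = {
        "omega": omega,
        "dx": dx,
        "cell": cell,
        "z_series": z_series,
        "z_face": z_face,
        "y_extra": y_extra,
        "z_helicotrema": z_h,
        "u_stapes_volume_velocity": u_s,
        "z_partition": z_p,
        "coupled": settings.longitudinal_coupling,
        "width_m": w,
    }

    if not settings.longitudinal_coupling:
        # locally reacting partition folds into the shunt: tridiagonal in p
        diag_lr = diag + cell * w / z_p
        a_mat = sp.diags(
            [-g, diag_lr, -g], offsets=(-1, 0, 1), format="csc", dtype=complex
        )
        b = np.zeros(n, dtype=complex)
        b[0] = u_s
        return a_mat, b, aux

    fluid_block = sp.diags([-g, diag, -g], offsets=(-1, 0, 1), dtype=complex)
    couple_block = sp.diags(cell * 1j * omega * w)
    # variational bending operator with free (natural) ends:
    # energy = 1/2 * sum_i D_i w_i |d''_i|^2 dx over interior nodes
    t_m = geom.thickness * UM
    e_pa = np.asarray(mat.bm.E(geom.x_grid), float)
    nu = mat.bm.poisson
    d_rigid = e_pa * t_m**3 / (12.0 * (1.0 - nu**2))
    d_int = d_rigid[1:-1] * w[1:-1] * (1.0 + 1j * omega * params.beta[1:-1])
    second_diff = sp.diags(
        [np.ones(n - 2), -2.0 * np.ones(n - 2), np.ones(n - 2)],
        offsets=(0, 1, 2),
        shape=(n - 2, n),
    )
    bend = (second_diff.T @ sp.diags(d_int) @ second_diff) / dx**3
    partition_block = sp.diags(partition_scalar) + sp.diags(1.0 / (w * cell)) @ bend
    a_mat = sp.bmat(
        [
            [fluid_block, couple_block],
            [sp.diags(-np.ones(n)), partition_block],
        ],
        format="csc",
    )
    b = np.zeros(2 * n, dtype=complex)
    b[0] = u_s
    return a_mat, b, aux


def _powers(p: np.ndarray, d: np.ndarray | None, aux) -> dict[str, float]:
    cell = aux["cell"]
    omega = aux["omega"]
    p_in = 0.5 * float(np.real(aux["u_stapes_volume_velocity"] * np.conj(p[0])))
    if d is None:
        y_part = aux["width_m"] / aux["z_partition"]
        p_part = 0.5 * float(np.sum(cell * np.abs(p) ** 2 * np.real(y_part)))
    else:
        # power delivered by the fluid to the partition, all dissipated there
        p_part = 0.5 * float(
            np.real(np.sum(cell * aux["width_m"] * p * np.conj(1j * omega * d)))
        )
    p_elec = 0.5 * float(np.sum(cell * np.abs(p) ** 2 * np.real(aux["y_extra"])))
    dp = np.diff(p)
    zf = aux["z_face"]
    p_visc = 0.5 * float(
        np.sum(np.abs(dp) ** 2 * np.real(zf) / np.abs(zf) ** 2 / aux["dx"])
    )
    p_heli = 0.5 * float(np.abs(p[-1]) ** 2 * np.real(1.0 / aux["z_helicotrema"]))
    return {
        "input": p_in,
        "partition": p_part,
        "electrode": p_elec,
        "viscous": p_visc,
        "helicotrema": p_heli,
    }


def _solve_one(a_mat, b, aux, frequency, settings):
    sol = spla.spsolve(a_mat, b)
    if not np.all(np.isfinite(sol)):
        raise RuntimeError(f"singular system at {frequency} Hz (non-finite solution)")
    # normwise backward error: robust to the disparate physical scales of the
    # fluid (volume-velocity) and partition (pressure) rows
    r = a_mat @ sol - b
    denom = spla.norm(a_mat, np.inf) * np.linalg.norm(sol, np.inf) + np.linalg.norm(
        b, np.inf
    )
    resid = float(np.linalg.norm(r, np.inf) / denom)
    if resid > max(settings.tolerance * 1e2, 1e-8):
        raise RuntimeError(
            f"linear solve did not converge at {frequency} Hz: residual {resid:.3e}"
        )
    n = aux["cell"].size
    if aux["coupled"]:
        p, d = sol[:n], sol[n:]
    else:
        p, d = sol, None
    pw = _powers(p, d, aux)
    cond = None
    if settings.estimate_condition:
        lu = spla.splu(a_mat)
        inv_norm = spla.onenormest(
            spla.LinearOperator(a_mat.shape, matvec=lu.solve, dtype=complex)
        )
        cond = float(spla.onenormest(a_mat) * inv_norm)
    diag = SolveDiagnostics(
        frequency=frequency,
        residual=resid,
        power_input=pw["input"],
        power_partition=pw["partition"],
        power_electrode=pw["electrode"],
        power_viscous=pw["viscous"],
        power_helicotrema=pw["helicotrema"],
        condition_estimate=cond,
    )
    # displacement positive toward the scala vestibuli
    if d is None:
        u = -p / (1j * aux["omega"] * aux["z_partition"])
    else:
        u = -d
    return u, diag


def solve_harmonic(
    geom: CochlearGeometry,
    mat: MaterialTable | None = None,
    occ: OcclusionProfile | None = None,
    stim: StimulusSpec | None = None,
    settings: SolverSettings | None = None,
    params: PartitionImpedanceParams | None = None,
) -> BMResponse:
    """Solve the harmonic two-duct system at every stimulus frequency.

    Deterministic for fixed inputs.  ``params`` may be supplied to reuse a
    precomputed partition reduction; otherwise it is built from the material
    table (honouring ``settings.plate_constant``).
    """
    mat = mat or MaterialTable.default()
    stim = stim or StimulusSpec()
    settings = settings or SolverSettings()
    if params is None:
        kwargs = {}
        if settings.plate_constant is not None:
            kwargs["plate_constant"] = settings.plate_constant
        params = partition_params(geom, mat, **kwargs)

    n_f = len(stim.frequencies)
    u = np.zeros((n_f, geom.n_nodes), dtype=complex)
    diags: list[SolveDiagnostics] = []
    for k, f in enumerate(stim.frequencies):
        a_mat, b, aux = assemble_system(geom, params, occ, f, settings, mat, stim)
        u[k], d = _solve_one(a_mat, b, aux, f, settings)
        diags.append(d)
    return BMResponse(
        frequencies=np.array(stim.frequencies),
        x_grid=geom.x_grid,
        u=u,
        stapes_displacement=stim.amplitudes(),
        diagnostics=tuple(diags),
    )
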