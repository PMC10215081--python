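import numpy as np
import pytest

import basilar as b
from basilar.geometry import CochlearGeometry, SpiralSpec
from basilar.materials import PartitionImpedanceParams


@pytest.fixture(scope="session")
def mat():
    return b.MaterialTable.default()


@pytest.fixture(scope="session")
def default_geom():
    return b.build_geometry()


@pytest.fixture(scope="session")
def healthy_response(default_geom, mat):
    return b.solve_harmonic(default_geom, mat)


@pytest.fixture(scope="session")
def healthy_tuning(healthy_response):
    return b.extract_tuning(healthy_response, greenwood=b.GreenwoodMap())


@pytest.fixture(scope="session")
def sweep_results(default_geom, mat, healthy_tuning):
    """Implanted tuning and deltas for the default 5-angle sweep."""
    out = {}
    for angle in b.DEFAULT_SWEEP_ANGLES:
        occ = b.place_electrode(
            default_geom, b.ElectrodeSpec(insertion_angle=angle), mat
        )
        tun = b.extract_tuning(b.solve_harmonic(default_geom, mat, occ=occ))
        out[angle] = b.residual_hearing_delta(healthy_tuning, tun, angle)
    return out


def make_uniform_geometry(
    n=367,
    L=18.3,
    thickness=10.0,
    width=0.2,
    area=1.0,
):
    """Uniform-profile geometry built directly (bypasses taper validation)."""
    x = np.linspace(0.0, L, n)
    spiral = SpiralSpec(total_angle=1080.0, basal_radius=2.0, taper_rate=0.08)
    from dataclasses import replace

    scale = L / spiral.total_arclength()
    spiral = replace(spiral, basal_radius=spiral.basal_radius * scale)
    from basilar.geometry import arclength_to_angle

    ang = np.array([arclength_to_angle(spiral, xi) for xi in x])
    return CochlearGeometry(
        L=L,
        x_grid=x,
        thickness=np.full(n, thickness),
        width=np.full(n, width),
        area_sv=np.full(n, area),
        area_st=np.full(n, area),
        spiral=spiral,
        angle=ang,
    )


def make_uniform_params(geom, stiffness=1.0e8, mass=0.01, beta=4.0e-6):
    n = geom.n_nodes
    return PartitionImpedanceParams(
        x_grid=geom.x_grid,
        stiffness=np.full(n, stiffness),
        mass=np.full(n, mass),
        beta=np.full(n, beta),
        plate_constant=60.0,
    )
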