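import numpy as np
import pytest

from osteosim import geometry as geo


@pytest.fixture(scope="session")
def healthy_geom():
    return geo.build_geometry("healthy")


@pytest.fixture(scope="session")
def t2dm_geom():
    return geo.build_geometry("t2dm")


@pytest.fixture(scope="session")
def desk_mesh(healthy_geom):
    return geo.generate_mesh(healthy_geom, scale=4)


@pytest.fixture(scope="session")
def desk_lattice(healthy_geom, desk_mesh):
    return geo.build_lattice(healthy_geom, desk_mesh, spacing_um=100.0)


def make_open_lattice(n: int = 12, spacing_um: float = 10.0) -> geo.Lattice:
    """A free-standing cubic lattice (every interior site in-domain, all sites
    mapped to element 0) for isolated cell-process tests."""
    shape = (n + 2, n + 2, n + 2)
    occ = np.full(shape, geo.OUTSIDE, dtype=np.int8)
    occ[1:-1, 1:-1, 1:-1] = geo.EMPTY
    elem = np.full(shape, -1, dtype=np.int64)
    elem[1:-1, 1:-1, 1:-1] = 0
    empty_band = np.zeros(shape, dtype=bool)
    dummy = geo.FemurGeometry(group="healthy", periosteal_radius=2.0,
                              endosteal_radius=1.3, include_plate=False)
    return geo.Lattice(geom=dummy, spacing_um=spacing_um,
                       origin=np.zeros(3), shape=shape,
                       occupancy=occ.ravel(), site_element=elem.ravel(),
                       periosteal_band=empty_band.ravel(),
                       marrow_band=empty_band.ravel())


@pytest.fixture
def open_lattice():
    return make_open_lattice()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
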