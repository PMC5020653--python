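import numpy as np
import pytest

from memcurv import EnergyParams, McState, build_triangulated_sphere


@pytest.fixture(scope="session")
def sphere_642():
    return build_triangulated_sphere(642, 10.0)


@pytest.fixture(scope="session")
def sphere_1002():
    return build_triangulated_sphere(1002, 10.0)


@pytest.fixture()
def unit_cube_mesh():
    """Unit cube triangulated into 12 outward-oriented faces."""
    from memcurv import TriMesh

    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
    # index: bit pattern (x<<2 | y<<1 | z); windings outward
    faces = [
        (0, 1, 3), (0, 3, 2),      # x = 0
        (4, 6, 7), (4, 7, 5),      # x = 1
        (0, 4, 5), (0, 5, 1),      # y = 0
        (2, 7, 6), (2, 3, 7),      # y = 1
        (0, 2, 6), (0, 6, 4),      # z = 0
        (1, 5, 7), (1, 7, 3),      # z = 1
    ]
    return TriMesh(v, np.array(faces))


@pytest.fixture()
def vesicle_params(sphere_1002):
    m = sphere_1002.measure()
    return EnergyParams(kappa=21.0).with_targets(
        A_t=1.05 * m.total_area, V_t=m.enclosed_volume)


@pytest.fixture()
def small_mc_state(sphere_642):
    m = sphere_642.measure()
    params = EnergyParams(kappa=21.0).with_targets(
        A_t=1.05 * m.total_area, V_t=m.enclosed_volume)
    return McState.from_mesh(sphere_642, [], params, seed=11)
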