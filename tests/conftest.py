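import numpy as np
import pytest

from brainmodes import (
    MaterialSet,
    PhantomConfig,
    apply_dirichlet,
    assemble,
    build_bar_mesh,
    build_layered_phantom,
    solve_modes,
    strip_skull,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def coarse_config():
    return PhantomConfig(target_edge_length=10.0)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_config):
    return build_layered_phantom(coarse_config)


@pytest.fixture(scope="session")
def brain_mesh(coarse_phantom):
    return strip_skull(coarse_phantom)


@pytest.fixture(scope="session")
def sphere_mesh():
    cfg = PhantomConfig(shell_radii=(50.0,), target_edge_length=8.0,
                        axis_ratios=(1.0, 1.0, 1.0), jitter_frac=0.0)
    return build_layered_phantom(cfg)


@pytest.fixture(scope="session")
def ellipsoid_mesh():
    """Single-region ellipsoidal body; asymmetry splits eigenvalue
    degeneracies so mode-by-mode comparisons are well posed."""
    cfg = PhantomConfig(shell_radii=(50.0,), target_edge_length=8.0)
    return build_layered_phantom(cfg)


@pytest.fixture(scope="session")
def small_bar():
    """10-division bar: 44 nodes, 120 free DOFs once one end is fixed."""
    return build_bar_mesh(100.0, 10.0, 10)


@pytest.fixture(scope="session")
def bar_material():
    return MaterialSet.homogeneous(E=1.0, rho=1e-9, nu=0.3)


@pytest.fixture(scope="session")
def fixed_bar_system(small_bar, bar_material):
    system = assemble(small_bar, bar_material)
    return apply_dirichlet(system, small_bar, "fixed_end")


@pytest.fixture(scope="session")
def fixed_bar_modes(fixed_bar_system):
    return solve_modes(fixed_bar_system, n_modes=12, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
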