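import numpy as np
import pytest

from corollafold import ElasticParams, default_initial_mesh
from corollafold.growth import GrowthConfig, run_growth

PAPER_PARAMS = ElasticParams(E=3.0e6, nu=0.4, alpha=0.1, beta=0.9)
ISO_PARAMS = ElasticParams(E=3.0e6, nu=0.4, alpha=0.0, beta=0.9)
P_TURGOR = 4.0e4
FREE_STRAIN = P_TURGOR * (1 - 0.4) / 3.0e6  # 0.008, isotropic free expansion


@pytest.fixture(scope="session")
def mesh0():
    return default_initial_mesh()


@pytest.fixture(scope="session")
def growth_runs(mesh0):
    """Full 200-step growth trajectories for the friction values studied.

    Session-scoped: these are the expensive runs shared by the buckling,
    stress-monotonicity and straight-growth checks.
    """
    return {
        eta: run_growth(mesh0, GrowthConfig(eta=eta))
        for eta in (0.0, 0.4, 0.7)
    }


@pytest.fixture(scope="session")
def fine_growth_runs():
    """Same runs with both mesh subdivisions doubled (8 x 64)."""
    from corollafold import rectangle_mesh

    mesh = rectangle_mesh(0.1, 0.8, 8, 64)
    return {
        eta: run_growth(mesh, GrowthConfig(eta=eta))
        for eta in (0.0, 0.4, 0.7)
    }


def mirror_node_map(mesh, width):
    """Index map m with node m[i] at the mirror image (width - x_i, y_i)."""
    lookup = {
        (round(x, 9), round(y, 9)): i for i, (x, y) in enumerate(mesh.nodes)
    }
    return np.array(
        [lookup[(round(width - x, 9), round(y, 9))] for x, y in mesh.nodes]
    )
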