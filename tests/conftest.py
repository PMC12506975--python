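import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from duotomo.geometry import assign_element_roles, build_grid, build_half_ring_geometry
from duotomo.phantom_forward import VesselPhantom, benign_archetype

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_geom():
    """16-element half ring, radius 40 mm, no emitters: fast PA test rig."""
    return assign_element_roles(build_half_ring_geometry(16, 40.0, 176.0), 0)


@pytest.fixture(scope="session")
def toy_grid():
    return build_grid(16.0, 16.0, 0.5, (0.0, 0.0))


def make_phantom(grid, absorption=None, scatterer=None, skin_depth_mm=4.0,
                 tumor_mask=None, seed=0):
    """Hand-built phantom for forward-model tests (no generator involved)."""
    shape = (grid.n_y, grid.n_x)
    zeros = np.zeros(shape)
    depth = grid.depth_of_row_mm[:, None]
    skin = np.full(grid.n_x, skin_depth_mm)
    return VesselPhantom(
        grid=grid,
        absorption_map=zeros if absorption is None else absorption,
        scatterer_map=zeros if scatterer is None else scatterer,
        vessel_paths=[],
        tumor_mask=np.zeros(shape, bool) if tumor_mask is None else tumor_mask,
        skin_line=skin,
        label="benign",
        archetype_params=benign_archetype(),
        seed=seed,
        breast_mask=depth > skin[None, :],
        chest_line=np.full(grid.n_x, grid.depth_mm),
    )


@pytest.fixture(scope="session")
def cohort_ablation():
    """Default 160-mass study, simulated once and shared across tests.

    Returns the modality-ablation result: three fitted arms (pact / urct /
    combined) over identical splits, plus the comparison summary.
    """
    from duotomo.pipeline import StudyConfig, run_modality_ablation

    return run_modality_ablation(StudyConfig())
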