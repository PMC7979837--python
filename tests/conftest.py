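import pytest
from hypothesis import HealthCheck, settings

from embryovar import geometry, synthetic

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: one embryo seed shared by the full-scale fixtures
EMBRYO_SEED = 17


@pytest.fixture(scope="session")
def default_embryo():
    """Full-scale synthetic embryo under default (noisy-membrane) conditions."""
    return synthetic.generate_embryo(synthetic.SimParams(seed=EMBRYO_SEED))


@pytest.fixture(scope="session")
def default_polygons(default_embryo):
    polygons, degenerate = geometry.build_cell_polygons(default_embryo.membrane_spots)
    assert not degenerate
    return polygons


@pytest.fixture(scope="session")
def default_contact_graph(default_polygons):
    return geometry.detect_contact_neighbours(default_polygons, expansion_um=0.6)


@pytest.fixture(scope="session")
def noiseless_embryo():
    """Full-scale embryo with zero membrane jitter: hulls are exact prisms."""
    return synthetic.generate_embryo(
        synthetic.SimParams(seed=EMBRYO_SEED, membrane_jitter_um=0.0)
    )


@pytest.fixture(scope="session")
def noiseless_polygons(noiseless_embryo):
    polygons, degenerate = geometry.build_cell_polygons(noiseless_embryo.membrane_spots)
    assert not degenerate
    return polygons


@pytest.fixture(scope="session")
def small_embryo():
    """~60-cell embryo for cheap end-to-end unit checks."""
    return synthetic.generate_embryo(synthetic.SimParams(n_cells_target=60, seed=1))
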