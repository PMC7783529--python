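import numpy as np
import pytest

from wormvol.mesh_io import TriangleMesh
from wormvol.synthetic import generate_worm, make_box
from wormvol.volumetrics import ValidationReport, VolumeMeasurement


@pytest.fixture
def cube100() -> TriangleMesh:
    """Reference cube, edge 100 model units."""
    return make_box((100.0, 100.0, 100.0), name="100um_cube")


@pytest.fixture
def unit_cube() -> TriangleMesh:
    return make_box((1.0, 1.0, 1.0), name="unit_cube")


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    """Unit right tetrahedron, outward-oriented; volume 1/6 exactly."""
    return TriangleMesh(
        name="tet",
        vertices=[(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)],
        faces=[(0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3)],
    )


@pytest.fixture(scope="session")
def worm(tmp_path_factory):
    """One seeded synthetic worm shared across the session."""
    out = tmp_path_factory.mktemp("worm") / "w"
    manifest = generate_worm(out, seed=42)
    return out, manifest


def clean_report(name: str) -> ValidationReport:
    return ValidationReport(
        name=name,
        watertight=True,
        boundary_edge_count=0,
        non_manifold_edge_count=0,
        orientation_consistent=True,
        duplicate_vertex_count=0,
    )


def mk_measurement(
    cell: str, tissue: str, volume: float, factor: float = 1.0
) -> VolumeMeasurement:
    """A trusted measurement with a given calibrated volume (um^3)."""
    return VolumeMeasurement(
        cell=cell,
        collection=tissue,
        raw_volume=volume / factor,
        calibrated_volume=volume,
        validation=clean_report(cell),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
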