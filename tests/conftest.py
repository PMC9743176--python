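import numpy as np
import pytest
import trimesh

from conchrock.hydrostatics import ComponentSpec
from conchrock.meshgeom import TriangleMesh


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_components(rng):
    """Factory for random positive-mass component sets."""

    def make(n=5, spread=5.0):
        return [
            ComponentSpec(
                name=f"c{i}",
                mass=float(rng.uniform(1.0, 500.0)),
                center=tuple(rng.uniform(-spread, spread, 3)),
            )
            for i in range(n)
        ]

    return make


@pytest.fixture
def unit_cube_mesh():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    box.apply_translation((0.5, 0.5, 0.5))  # on [0, 1]^3
    return TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture
def icosphere_mesh():
    s = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))
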