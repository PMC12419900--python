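import numpy as np
import pytest

import stylocom as sc


@pytest.fixture(scope="session")
def study_fixture():
    """One shared miniature synthetic study (57 extant taxa, 24 fossils)."""
    return sc.make_study_fixture(seed=7)


@pytest.fixture
def unit_cube():
    import trimesh

    mesh = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    mesh.apply_translation((0.5, 0.5, 0.5))
    return sc.SegmentMesh(
        name="cube",
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
        density=1.0,
    )


def make_cube(center, density=1.0, name="cube"):
    import trimesh

    mesh = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    mesh.apply_translation(center)
    return sc.SegmentMesh(
        name=name,
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
        density=density,
    )
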