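import numpy as np
import pytest

from tissuetracks import (GrowthSpec, Mesh, Morphomovie, PatternSpec,
                          build_lineage_graph, extract_tracks,
                          generate_morphomovie, synthesize_dataset)


@pytest.fixture(scope="session")
def small_movie():
    """A 6-hour synthetic movie (~200 triangles) shared across tests."""
    return generate_morphomovie(GrowthSpec(T=6, seed=1))


@pytest.fixture(scope="session")
def small_graph(small_movie):
    return build_lineage_graph(small_movie)


@pytest.fixture(scope="session")
def small_tracks(small_graph):
    return extract_tracks(small_graph)


@pytest.fixture(scope="session")
def simple_dataset():
    """Noiseless 12-hour dataset with one image per hour, sweeping-front pattern."""
    return synthesize_dataset(GrowthSpec(T=12, seed=3),
                              PatternSpec(kind="simple_front", duration_hours=12))


@pytest.fixture(scope="session")
def complex_dataset():
    """Noiseless 12-hour dataset with one image per hour, branching-stripes pattern."""
    return synthesize_dataset(GrowthSpec(T=12, seed=3),
                              PatternSpec(kind="complex_stripes", duration_hours=12))


def identity_movie(T=4):
    """The same single-square mesh repeated T times (no growth, no remesh)."""
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    meshes = [Mesh(vertices=verts.copy(), triangles=tris.copy(), timepoint=t)
              for t in range(T)]
    return Morphomovie(hourly_meshes=meshes)


def split_movie():
    """Hour 0: one triangle; hour 1: the same triangle split into 4 at edge midpoints."""
    v0 = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
    m0 = Mesh(vertices=v0, triangles=np.array([[0, 1, 2]]), timepoint=0)
    v1 = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0],
                   [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    t1 = np.array([[0, 3, 5], [3, 1, 4], [5, 4, 2], [3, 4, 5]])
    m1 = Mesh(vertices=v1, triangles=t1, timepoint=1)
    return Morphomovie(hourly_meshes=[m0, m1])
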