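import numpy as np
import pytest

import microvasc as mv
from microvasc.types import TissueMask

ISO = (0.5, 0.5, 0.5)
ANISO = (0.5, 0.5, 1.5)


def full_tissue(shape):
    return TissueMask(mask=np.ones(shape, dtype=bool))


def graph_from_tubes(tubes, size=(50, 50, 50), spacing=ISO, seed=1, noise=None):
    """Rasterize tubes, segment the vessel channel, extract the graph."""
    spec = mv.PhantomSpec(volume_size=size, spacing=spacing, tubes=tubes)
    img, truth = mv.generate_vascular_phantom(spec, noise=noise, seed=seed)
    tissue = full_tissue(img.shape)
    vessel = mv.segment_channel(img.channels["vessel"], tissue=tissue,
                                spacing=spacing)
    graph = mv.skeletonize_and_graph(vessel, spacing)
    return img, truth, tissue, vessel, graph


@pytest.fixture(scope="session")
def cylinder_case():
    """Straight tube r=2 µm, L=50 µm spanning a 50³ µm³ volume."""
    return graph_from_tubes([mv.straight_tube((0, 25, 25), (50, 25, 25), 2.0)])


@pytest.fixture(scope="session")
def y_junction_case():
    tubes = mv.y_junction((5, 25, 25), (25, 25, 25), (45, 10, 25),
                          (45, 40, 25), 2.0)
    return graph_from_tubes(tubes, seed=2)


@pytest.fixture(scope="session")
def ring_case():
    return graph_from_tubes([mv.ring_tube((25, 25, 25), 15.0, 2.0)], seed=3)


@pytest.fixture(scope="session")
def arc_case():
    tube = mv.arc_tube((25, 10, 25), 15.0, 2.0, 0.0, np.pi, plane="xy")
    return graph_from_tubes([tube], seed=4)


@pytest.fixture(scope="session")
def grid_case():
    """6×6 grid of z-parallel capillaries, pitch 8 µm, in a thin section."""
    tubes = mv.parallel_grid(pitch=8.0, radius=1.0, volume_size=(48, 48, 15),
                             axis=2)
    return graph_from_tubes(tubes, size=(48, 48, 15), spacing=ANISO, seed=5)


@pytest.fixture(scope="session")
def cell_phantom():
    """Two vessels plus nuclei of every class, with known counts."""
    tubes = [mv.straight_tube((5, 12, 7.5), (43, 12, 7.5), 2.0, sma=True),
             mv.straight_tube((5, 36, 7.5), (43, 36, 7.5), 1.2)]
    spec = mv.PhantomSpec(
        volume_size=(48, 48, 15), spacing=ANISO, tubes=tubes,
        n_nuclei={"endothelial": 5, "sma_perivascular": 3,
                  "myofibroblast": 4, "other": 2})
    img, truth = mv.generate_vascular_phantom(spec, seed=7)
    return img, truth
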