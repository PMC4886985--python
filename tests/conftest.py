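"""Shared fixtures: all synthetic, generated at test time."""

import numpy as np
import pytest

from harmalign.models import PointModel
from harmalign.synthetic import ShapeSpec, generate_beads


def random_point_model(seed: int, n: int = 20, extent: float = 10.0,
                       centered: bool = True) -> PointModel:
    """Seeded random weighted point cloud (asymmetric, no lattice)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-extent, extent, (n, 3))
    weights = rng.uniform(0.5, 2.0, n)
    if centered:
        coords = coords - weights @ coords / weights.sum()
    return PointModel(coords, weights)


@pytest.fixture(scope="session")
def ellipsoid_beads() -> PointModel:
    """Triaxial ellipsoid bead envelope, ~200 beads, D_max 40 Å."""
    return generate_beads(ShapeSpec(kind="ellipsoid", size=(20.0, 15.0, 10.0),
                                    spacing=4.0))


@pytest.fixture(scope="session")
def multilobe_envelope() -> PointModel:
    """Chiral asymmetric 4-lobe envelope: the pose-recovery workhorse."""
    return generate_beads(ShapeSpec(kind="multilobe", size=(20.0,),
                                    spacing=7.0))


@pytest.fixture(scope="session")
def chiral_tetra() -> PointModel:
    """Five points with distinct pairwise distances and nonzero chirality."""
    return generate_beads(ShapeSpec(kind="chiral-tetra", size=(10.0,)))


@pytest.fixture(scope="session")
def lshape_beads() -> PointModel:
    """Chiral 3D corner piece (three unequal axis-aligned arms)."""
    return generate_beads(ShapeSpec(kind="lshape", size=(36.0, 22.0, 12.0, 6.0),
                                    spacing=3.0))
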