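import numpy as np
import pytest
from hypothesis import settings

import mtquant as mq

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def circle_geometry(center=(128.0, 128.0), radius=100.0, n_vertices=360) -> mq.CellGeometry:
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )
    return mq.CellGeometry(center, verts)


@pytest.fixture
def circle_geo() -> mq.CellGeometry:
    return circle_geometry()


@pytest.fixture
def cell_geo_256() -> mq.CellGeometry:
    """Circular cell of radius 11 µm inside a 256 px image at 0.1 µm/px."""
    return circle_geometry(center=(128.0, 128.0), radius=110.0)
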