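import numpy as np
import pytest

import adhesim as A
from adhesim import adhesion, engine, mechanics


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def quiet_motion():
    """Motion params with every stochastic scale zero."""
    return A.MotionParams(sigma_body=0.0, sigma_centre=0.0, v_edge=0.0,
                          p_new_edge=0.0)


@pytest.fixture
def single_cell_field():
    return mechanics.CellField(np.array([[0.0, 0.0]]), [mechanics.RED])


def make_field(centres, types=None, r_cell=1.5):
    centres = np.asarray(centres, dtype=float)
    if types is None:
        types = np.zeros(len(centres), dtype=int)
    return mechanics.CellField(centres, types, r_cell=r_cell)


def zero_rate_config(n_cells=2, **kwargs):
    """SimConfig in which every stochastic rate is zero."""
    return A.SimConfig(
        n_cells=n_cells,
        motion=A.MotionParams(sigma_body=0, sigma_centre=0, v_edge=0,
                              p_new_edge=0),
        exclusion=A.ExclusionParams(p_repel=0.0),
        adhesion=A.AdhesionParams(unhook=0.0, p_hook=0.0),
        **kwargs,
    )
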