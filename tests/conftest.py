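import numpy as np
import pytest

from carbodyn.io import CellSpec, Frame


@pytest.fixture
def free_cell() -> CellSpec:
    """A huge open cell: effectively non-periodic geometry."""
    return CellSpec((1000.0, 1000.0, 1000.0), periodic=(False, False, False))


@pytest.fixture
def box10() -> CellSpec:
    return CellSpec((10.0, 10.0, 10.0))


def make_frame(species, coords, cell, index=0, time=0.0) -> Frame:
    return Frame(index=index, time=time, species=np.asarray(species),
                 coords=np.asarray(coords, dtype=float), cell=cell)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
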