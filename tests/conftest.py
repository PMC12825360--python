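import numpy as np
import pandas as pd
import pytest

from idas.datatypes import ObservationDesign, PseudobulkMatrix, SingleCellDataset


@pytest.fixture
def design_2x2():
    """Balanced 2x2 with m=2, observations ordered (1,1),(1,2),(2,1),(2,2)."""
    return ObservationDesign(
        obs_ids=[f"o{i}" for i in range(8)],
        f1=np.array(["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"]),
        f2=np.array(["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"]),
    )


@pytest.fixture
def y_2x2():
    """Cell means (2,3,6,7) are exactly additive; within-cell spread 1."""
    return np.array([1.0, 3.0, 2.0, 4.0, 5.0, 7.0, 6.0, 8.0])


@pytest.fixture
def small_sc():
    """3 genes x 4 cells, two samples x two states, one cell per group."""
    meta = pd.DataFrame(
        {
            "sample_id": ["A", "A", "B", "B"],
            "state": ["s1", "s2", "s1", "s2"],
            "phenotype": ["R", "R", "NR", "NR"],
        },
        index=["c1", "c2", "c3", "c4"],
    )
    values = np.array([[2.0, 4.0, 6.0, 8.0],
                       [0.0, 0.0, 0.0, 0.0],
                       [1.0, 1.0, 1.0, 1.0]])
    return SingleCellDataset(values=values, gene_ids=["g1", "g2", "g3"],
                             cell_ids=["c1", "c2", "c3", "c4"], cell_meta=meta)


def random_design(rng, I, J, n):
    """A random (possibly unbalanced) two-factor design with all levels present."""
    f1 = np.concatenate([np.arange(I), rng.integers(0, I, size=n - I)])
    f2 = np.concatenate([np.arange(J), rng.integers(0, J, size=n - J)])
    rng.shuffle(f1)
    rng.shuffle(f2)
    # re-guarantee presence after the shuffle
    f1[:I] = np.arange(I)
    f2[:J] = np.arange(J)
    return ObservationDesign(
        obs_ids=[f"o{i}" for i in range(n)],
        f1=np.array([f"a{v}" for v in f1]),
        f2=np.array([f"b{v}" for v in f2]),
    )
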