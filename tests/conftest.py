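import numpy as np
import pytest

from batchfree.containers import BatchCollection, RawMatrix


@pytest.fixture
def toy_counts():
    """6x6 count matrix with known expressed-gene/cell structure."""
    rng = np.random.default_rng(11)
    values = rng.integers(0, 5, size=(6, 6)).astype(float)
    values[:, 0] = 0.0          # gene expressed in 0 cells
    values[0:3, 1] = [1, 2, 3]  # gene expressed in exactly 3 cells
    values[3:, 1] = 0.0
    return RawMatrix(values, [f"c{i}" for i in range(6)],
                     [f"g{j}" for j in range(6)], "toy")


@pytest.fixture
def two_batch_1d():
    """Two 1-D clouds differing by a pure shift of 3.0."""
    rng = np.random.default_rng(42)
    x0 = np.abs(rng.normal(5.0, 1.0, size=(2000, 1)))
    x1 = x0 + 3.0
    coll = BatchCollection([x0, x1], ["a", "b"], ["g0"], scale="lognorm")
    w1 = float(np.mean(np.abs(np.sort(x1.ravel()) - np.sort(x0.ravel()))))
    return coll, w1


@pytest.fixture
def small_collection():
    rng = np.random.default_rng(3)
    mats = [np.abs(rng.normal(1.0, 0.5, size=(40, 12))),
            np.abs(rng.normal(1.5, 0.5, size=(30, 12)))]
    return BatchCollection(mats, ["b0", "b1"], [f"g{j}" for j in range(12)],
                           scale="lognorm")
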