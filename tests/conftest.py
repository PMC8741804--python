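import numpy as np
import pytest

from refstab import CtMatrix, default_params, simulate_ct_matrix
from refstab.ct_io import as_collapsed


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_ct(rng):
    """4 genes x 6 samples, complete, ungrouped."""
    vals = rng.uniform(18, 30, size=(4, 6))
    return CtMatrix(vals, [f"g{i}" for i in range(4)], [f"s{j}" for j in range(6)])


@pytest.fixture
def grouped_ct():
    """Seeded synthetic 12-gene panel over 4 tissue groups, collapsed."""
    m, truth = simulate_ct_matrix(default_params(seed=11))
    return as_collapsed(m), truth
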